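"""Volumetric image reconstruction: depth-compensated minimum-norm solvers
and the two-step hierarchical-Bayesian (HB) solver.

All three solvers invert the Rytov model Y = S X + noise for each
wavelength independently.  The minimum-norm (MN) family applies a
spatially variant depth weighting L_vv = sqrt(rho2_v + beta) -- the
WU variant fixes beta = 0.1, MN derives beta from the voxels around
20 mm depth -- and a Tikhonov inverse with the regularization constant
chosen by type-II maximum marginal likelihood.  The HB solver refines the
MN image with a variational automatic-relevance-determination iteration:
per-voxel prior variances on the cortex shrink toward the MN mean-square
image (lambda0) with confidence gamma0, while the scalp compartment is
represented on a smooth Gaussian basis with fixed broad variance, so
scalp and cortical activity are reconstructed simultaneously.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial import cKDTree

from .geometry import ExtinctionTable, SensitivityMatrix, VoxelGrid

log = logging.getLogger(__name__)

ALGORITHMS = ("HB", "MN", "MN_WU")


@dataclass
class ReconConfig:
    """Solver settings shared by the inverse algorithms.

    ``gamma0`` may be given directly; when None it defaults to
    ``gamma0_scale * L`` with L the retained sample count (default scale
    0.1, with {0.01, 0.001, 0.0001} the supported sweep values).
    """

    algorithm: str = "HB"
    beta: float | None = None          # None -> mode default
    alpha: float | None = None         # None -> evidence-selected
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-8, 2, 61))
    gamma0: float | None = None
    gamma0_scale: float = 0.1
    max_iter: int = 500
    tol: float = 1e-4
    eps: float = 1e-12                 # variance floor
    update_noise: bool = True
    sigma2: float | None = None        # initial / fixed noise variance
    scalp_basis_fwhm: float = 30.0     # mm
    depth_band: tuple[float, float] = (18.0, 22.0)
    # relative ridge constants (x mean Gram diagonal) of the two
    # deflation stages of the HB first step
    first_step_alpha_scalp: float = 0.01
    first_step_alpha_cortex: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma0 is not None and self.gamma0 < 0:
            raise ValueError("gamma0 must be >= 0")


@dataclass
class HBPrior:
    """Hierarchical prior for the HB second step."""

    lambda0: np.ndarray   # per-voxel prior variance mean
    gamma0: float         # confidence (count-like, ~ data length scale)


@dataclass
class DotImage:
    """Voxel x time hemodynamic estimates with provenance."""

    data: np.ndarray              # (V, T)
    grid: VoxelGrid
    algorithm: str
    species: str = "dmua"         # "dmua", "oxy", or "deoxy"
    wavelength: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def cortex(self) -> np.ndarray:
        return self.data[self.grid.cortex_mask]

    @property
    def scalp(self) -> np.ndarray:
        return self.data[self.grid.scalp_mask]


def depth_weights(S: SensitivityMatrix, mode: str = "MN_WU",
                  beta: float | None = None,
                  depth_band: tuple[float, float] = (18.0, 22.0),
                  wavelength: float | None = None) -> tuple[np.ndarray, float]:
    """Spatially variant depth-compensation weights L_vv = sqrt(rho2_v + beta).

    rho2 is the squared sensitivity column norm normalized by its maximum.
    In MN-WU mode beta = 0.1; in MN mode beta is the mean of rho2 over the
    voxels whose depth lies in ``depth_band`` (around 20 mm).
    """
    rho2 = S.rho2(wavelength)
    if beta is None:
        if mode.upper() in ("MN_WU", "MNWU", "HB"):
            beta = 0.1
        elif mode.upper() == "MN":
            band = (S.grid.depth >= depth_band[0]) & (S.grid.depth <= depth_band[1])
            if not band.any():
                raise ValueError(
                    f"no voxels with depth in {depth_band}; check the grid")
            beta = float(rho2[band].mean())
        else:
            raise ValueError(f"unknown depth-weight mode {mode!r}")
    return np.sqrt(rho2 + beta), float(beta)


def evidence_alpha(Y: np.ndarray, S_tilde: np.ndarray,
                   grid: np.ndarray | None = None,
                   ) -> tuple[float, dict]:
    """Regularization constant by type-II maximum marginal likelihood.

    Model: y_t = S~ x~_t + e with x~ ~ N(0, s I), e ~ N(0, sigma2 I) and
    alpha = sigma2 / s.  For each candidate alpha the signal scale s is
    profiled out in closed form using the eigendecomposition of S~ S~^T;
    the alpha maximizing the evidence is returned (smallest alpha among
    ties).  Also returns the profiled s and sigma2 at the optimum.

    The grid is interpreted relative to the mean Gram diagonal
    tr(S~ S~^T)/C, which makes the search invariant to the overall scale
    of the design; the returned alpha is absolute.
    """
    if grid is None:
        grid = np.logspace(-8, 2, 61)
    Y = np.atleast_2d(Y)
    if not np.any(Y):
        raise ValueError("cannot select alpha from all-zero data")
    C, T = Y.shape
    G = S_tilde @ S_tilde.T
    g0 = float(np.trace(G)) / C
    if g0 <= 0 or not np.isfinite(g0):
        raise ValueError("design matrix has zero or non-finite scale")
    grid = np.asarray(grid, dtype=float) * g0
    d, U = eigh(G)
    d = np.maximum(d, 0.0)
    z2 = ((U.T @ Y) ** 2).sum(axis=1)  # per-eigenmode data energy
    logev = np.full(len(grid), -np.inf)
    s_hat = np.zeros(len(grid))
    for i, a in enumerate(grid):
        da = d + a
        quad = float((z2 / da).sum())
        if quad <= 0 or not np.isfinite(quad):
            warnings.warn(f"non-finite evidence at alpha={a:g}; grid point skipped")
            continue
        # marginal covariance s (G + a I); profiling s gives, up to constants,
        # log ev = -T/2 [ C log s_hat + sum log(d + a) ] - CT/2
        s = quad / (C * T)
        logev[i] = -0.5 * T * (C * math.log(s) + float(np.log(da).sum())) - 0.5 * C * T
        s_hat[i] = s
    if not np.isfinite(logev).any():
        raise ValueError("evidence not finite at any grid point")
    best = int(np.flatnonzero(logev == logev.max())[0])  # smallest alpha wins ties
    alpha = float(grid[best])
    info = {"grid": np.asarray(grid), "log_evidence": logev,
            "s": float(s_hat[best]), "sigma2": float(alpha * s_hat[best])}
    return alpha, info


def mn_operator(S: np.ndarray, L: np.ndarray, alpha: float) -> np.ndarray:
    """Linear reconstruction operator A (V x C) of the depth-weighted
    minimum-norm estimate: x_t = A y_t with
    A = L^-1 S~^T (S~ S~^T + alpha I)^-1, S~ = S L^-1."""
    if alpha <= 0:
        raise ValueError("regularization alpha must be > 0 (system is singular)")
    St = S / L[None, :]
    M = St @ St.T
    M.flat[:: M.shape[0] + 1] += alpha
    c = cho_factor(M)
    A = cho_solve(c, St).T / L[:, None]
    return A


def mn_reconstruct(Y: np.ndarray, S: SensitivityMatrix | np.ndarray,
                   config: ReconConfig = ReconConfig(algorithm="MN_WU"),
                   grid: VoxelGrid | None = None,
                   channel_mask: np.ndarray | None = None,
                   wavelength: float | None = None,
                   return_operator: bool = False) -> DotImage | tuple[np.ndarray, dict]:
    """Depth-compensated minimum-norm reconstruction of one wavelength.

    ``Y`` is (channels, time) preprocessed OD.  When ``S`` is a
    :class:`SensitivityMatrix` the depth weights and grid are taken from
    it; a plain matrix requires explicit weights via ``config.beta`` and a
    ``grid``.  With ``config.alpha`` unset the evidence criterion selects
    the regularization constant.
    """
    if isinstance(S, SensitivityMatrix):
        mode = "MN" if config.algorithm == "MN" else "MN_WU"
        L, beta = depth_weights(S, mode, config.beta, config.depth_band, wavelength)
        Smat = S.matrix(wavelength)
        grid = S.grid
    else:
        Smat = np.asarray(S)
        beta = config.beta if config.beta is not None else 0.1
        nn = (Smat ** 2).sum(axis=0)
        L = np.sqrt(nn / nn.max() + beta)
    if channel_mask is not None:
        Smat = Smat[channel_mask]
        Y = Y[channel_mask]
    alpha = config.alpha
    info = {}
    if alpha is None:
        alpha, info = evidence_alpha(Y, Smat / L[None, :], config.alpha_grid)
    A = mn_operator(Smat, L, alpha)
    diag = {"alpha": alpha, "beta": beta, **info}
    if return_operator:
        return A, diag
    X = A @ Y
    return DotImage(X, grid, config.algorithm if config.algorithm != "HB" else "MN",
                    wavelength=wavelength, diagnostics=diag)


def compute_lambda0(mn_image: DotImage | np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-voxel temporal mean square of the first-step MN solution, floored
    at the variance floor; this is the prior variance mean of the HB step."""
    X = mn_image.data if isinstance(mn_image, DotImage) else np.asarray(mn_image)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need a (voxels, time) solution with T >= 1")
    return np.maximum((X ** 2).mean(axis=1), eps)


def scalp_basis(grid: VoxelGrid, fwhm: float = 30.0) -> np.ndarray:
    """Smooth Gaussian basis over the scalp compartment.

    Kernels sit on a lateral grid with spacing fwhm/2 and depend only on
    the lateral distance, so each basis function is uniform across the
    scalp depth layers (systemic scalp hemodynamics are depth-coherent).
    Returns B (n_scalp_voxels, K).
    """
    sc = grid.centers[grid.scalp_mask][:, :2]
    if len(sc) == 0:
        raise ValueError("grid has no scalp compartment")
    sigma = fwhm / math.sqrt(8.0 * math.log(2.0))
    spacing = fwhm / 2.0
    lo, hi = sc.min(axis=0), sc.max(axis=0)
    nx = max(1, int(math.ceil((hi[0] - lo[0]) / spacing)) + 1)
    ny = max(1, int(math.ceil((hi[1] - lo[1]) / spacing)) + 1)
    cx = np.linspace(lo[0], hi[0], nx)
    cy = np.linspace(lo[1], hi[1], ny)
    KX, KY = np.meshgrid(cx, cy, indexing="ij")
    kcent = np.column_stack([KX.ravel(), KY.ravel()])
    # drop kernels far from every scalp voxel (empty corners of merged grids)
    tree = cKDTree(sc)
    dmin, _ = tree.query(kcent)
    kcent = kcent[dmin <= spacing]
    d2 = ((sc[:, None, :] - kcent[None, :, :]) ** 2).sum(axis=2)
    B = np.exp(-0.5 * d2 / sigma ** 2)
    return B


def hb_first_step(Y: np.ndarray, S: SensitivityMatrix,
                  config: ReconConfig = ReconConfig(algorithm="HB"),
                  channel_mask: np.ndarray | None = None,
                  wavelength: float | None = None) -> dict:
    """First step of the HB scheme: a depth-compensated minimum-norm
    solve of the scalp+cortex model, providing the hierarchical prior.

    Scalp and cortex are solved in two deflation stages.  The scalp
    compartment, represented on the smooth Gaussian basis B, is fitted
    first with a light ridge: the superficial layer has overwhelmingly
    higher sensitivity, so globally coherent scalp-driven signal is
    attributed to the basis.  A depth-compensated ridge solve of the
    cortex then runs on the residual, so the cortical mean-square image
    (lambda0) stays focal instead of inheriting depth-amplified scalp
    leakage.  Two deliberate departures from the plain MN algorithm, both
    recorded in the methods note: the depth weights normalize rho2 within
    the cortex compartment (the compartment actually being compensated),
    and the ridge constants are fixed fractions of the mean Gram diagonal
    rather than evidence-maximized, because band-limited recordings carry
    fewer temporal degrees of freedom than channels and the iid-time
    evidence degenerates on them.  Returns lambda0 for the cortical
    voxels, the basis with its per-coefficient mean squares, and
    diagnostics.
    """
    grid = S.grid
    Smat = S.matrix(wavelength)
    if channel_mask is not None:
        Smat = Smat[channel_mask]
        Y = Y[channel_mask]
    Y = np.atleast_2d(Y)
    cortex = grid.cortex_mask
    scalp = ~cortex
    # cortex-normalized depth weights with the 20-mm beta rule
    nn = (Smat[:, cortex] ** 2).sum(axis=0)
    rho2 = nn / nn.max()
    depth_c = grid.depth[cortex]
    band = (depth_c >= config.depth_band[0]) & (depth_c <= config.depth_band[1])
    if not band.any():
        raise ValueError(f"no cortical voxels with depth in {config.depth_band}")
    beta = config.beta if config.beta is not None else float(rho2[band].mean())
    Lc = np.sqrt(rho2 + beta)
    Fc = Smat[:, cortex] / Lc[None, :]
    B = lam_basis = None
    alpha_scalp = None
    Yr = Y
    if scalp.any():
        B = scalp_basis(grid, config.scalp_basis_fwhm)
        Fs = Smat[:, scalp] @ B
        G = Fs @ Fs.T
        alpha_scalp = config.first_step_alpha_scalp * float(np.trace(G)) / G.shape[0]
        G.flat[:: G.shape[0] + 1] += alpha_scalp
        Ws = Fs.T @ cho_solve(cho_factor(G), Y)
        lam_basis = np.maximum((Ws ** 2).mean(axis=1), config.eps)
        Yr = Y - Fs @ Ws
    G = Fc @ Fc.T
    alpha = config.first_step_alpha_cortex * float(np.trace(G)) / G.shape[0]
    G.flat[:: G.shape[0] + 1] += alpha
    Xc = Fc.T @ cho_solve(cho_factor(G), Yr)
    lam0_c = np.maximum((Xc ** 2).mean(axis=1) / Lc ** 2, config.eps)
    return {"lambda0_cortex": lam0_c, "basis": B, "lambda_basis": lam_basis,
            "alpha": alpha, "alpha_scalp": alpha_scalp, "beta": beta}


def hb_reconstruct(Y: np.ndarray, S: SensitivityMatrix | np.ndarray,
                   compartments: np.ndarray | None = None,
                   prior: HBPrior | None = None,
                   config: ReconConfig = ReconConfig(algorithm="HB"),
                   grid: VoxelGrid | None = None,
                   channel_mask: np.ndarray | None = None,
                   wavelength: float | None = None,
                   return_operator: bool = False,
                   first_step: dict | None = None,
                   lam_init: np.ndarray | None = None,
                   ) -> DotImage | tuple[np.ndarray, dict]:
    """Two-step hierarchical-Bayesian reconstruction of one wavelength.

    ``Y`` (channels, time) must NOT be scalp-regressed: the scalp
    compartment is estimated simultaneously on a smooth basis.  When
    ``prior`` is None the scalp+cortex first step (:func:`hb_first_step`)
    runs internally and its cortical mean-square image provides lambda0;
    a precomputed ``first_step`` dict may be passed to share the first
    step across gamma0 settings.  The second step is a variational ARD
    iteration:

    E-step: posterior mean X = Lam F^T (F Lam F^T + sigma2 I)^-1 Y with
    F = [S_cortex, S_scalp B] and per-latent variances Lam;
    M-step (cortex): lam_v <- (sum_t <x_v,t^2> + 2 gamma0 lambda0_v)
    / (T + 2 gamma0), with <x^2> the posterior second moment;
    scalp-basis variances stay fixed at their first-step mean squares;
    sigma2 is optionally re-estimated from the expected mean squared
    residual.  Iterates until the relative change in lam drops below
    ``config.tol``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if isinstance(S, SensitivityMatrix):
        Smat = S.matrix(wavelength)
        grid = S.grid
        if compartments is None:
            compartments = grid.compartment
    else:
        Smat = np.asarray(S)
    if prior is None and first_step is None:
        if not isinstance(S, SensitivityMatrix):
            raise ValueError("a prior (or SensitivityMatrix for the first "
                             "step) is required")
        first_step = hb_first_step(Y, S, config, channel_mask, wavelength)
    if channel_mask is not None:
        Smat = Smat[channel_mask]
        Y = Y[channel_mask]
    C, T = Y.shape
    V = Smat.shape[1]
    if compartments is None:
        compartments = np.full(V, "cortex")
    compartments = np.asarray(compartments)
    cortex = compartments == "cortex"
    scalp = ~cortex

    if prior is None:
        g0 = config.gamma0 if config.gamma0 is not None else config.gamma0_scale * T
        lam0_full = np.full(V, config.eps)
        lam0_full[cortex] = first_step["lambda0_cortex"]
        prior = HBPrior(lambda0=lam0_full, gamma0=g0)
    lam0_full = np.maximum(np.asarray(prior.lambda0, dtype=float), config.eps)
    gamma0 = float(prior.gamma0)
    sigma2 = config.sigma2
    if sigma2 is None:
        # start above the plausible noise floor and let the update shrink it;
        # a too-small start is a local trap (the model explains noise as signal)
        sigma2 = 0.1 * float((Y ** 2).mean())
    sigma2 = float(max(sigma2, 1e-300))

    # ---- assemble the latent design: cortex voxels + scalp basis ----
    Fc = Smat[:, cortex]
    nc = int(cortex.sum())
    if scalp.any() and grid is not None:
        if first_step is not None and first_step.get("basis") is not None:
            B = first_step["basis"]
            lam_basis = np.asarray(first_step["lambda_basis"], dtype=float)
        else:
            B = scalp_basis(grid, config.scalp_basis_fwhm)
            # broad fixed variance so that B w reproduces the prior scalp power
            lam_scalp_target = float(lam0_full[scalp].mean())
            lam_basis = np.full(B.shape[1], lam_scalp_target /
                                max(float((B ** 2).sum(axis=1).mean()), 1e-30))
        Fs = Smat[:, scalp] @ B
        F = np.hstack([Fc, Fs])
        lam = np.concatenate([lam0_full[cortex], lam_basis])
        fixed = np.zeros(F.shape[1], dtype=bool)
        fixed[nc:] = True
    else:
        B = None
        F = Fc
        lam = lam0_full[cortex].copy()
        fixed = np.zeros(F.shape[1], dtype=bool)
    lam0 = lam.copy()  # cortex part is the prior mean; scalp part unused
    if lam_init is not None:
        # warm start, e.g. from a converged solve at a nearby gamma0
        lam = np.asarray(lam_init, dtype=float).copy()
    lam = np.maximum(lam, config.eps)

    Cyy = Y @ Y.T
    n_iter, rel = 0, np.inf
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        Fl = F * lam[None, :]                     # F Lam, (C, Vaug)
        M = Fl @ F.T
        M.flat[:: C + 1] += sigma2
        c = cho_factor(M)
        A = cho_solve(c, Fl).T                    # Lam F^T M^-1, (Vaug, C)
        ACyy = A @ Cyy
        sum_xhat2 = np.einsum("vc,vc->v", ACyy, A)
        post_var = lam - np.einsum("vc,cv->v", A, Fl)
        Ex2 = sum_xhat2 + T * np.maximum(post_var, 0.0)
        lam_new = lam.copy()
        upd = ~fixed
        lam_new[upd] = (Ex2[upd] + 2.0 * gamma0 * lam0[upd]) / (T + 2.0 * gamma0)
        lam_new = np.maximum(lam_new, config.eps)
        if not np.isfinite(lam_new).all():
            raise FloatingPointError(
                f"non-finite variances at iteration {n_iter}; sigma2={sigma2:g}")
        if config.update_noise:
            Bm = F @ A                            # (C, C)
            IB = np.eye(C) - Bm
            resid2 = float(np.einsum("ij,jk,ik->", IB, Cyy, IB))
            trpost = float(np.trace(IB @ (M - sigma2 * np.eye(C))))
            sigma2 = max((resid2 + T * max(trpost, 0.0)) / (C * T), 1e-300)
        # scale-relative criterion: changes in variances far below the
        # dominant scale do not move the solution
        denom = max(float(lam[upd].max()) if upd.any() else 0.0, config.eps)
        rel = float(np.max(np.abs(lam_new[upd] - lam[upd]))) / denom if upd.any() else 0.0
        lam = lam_new
        if rel < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"HB iteration did not converge in {config.max_iter} "
                      f"iterations (last relative change {rel:.2e})")

    Fl = F * lam[None, :]
    M = Fl @ F.T
    M.flat[:: C + 1] += sigma2
    A = cho_solve(cho_factor(M), Fl).T
    diag = {"iterations": n_iter, "converged": converged, "final_change": rel,
            "sigma2": sigma2, "gamma0": gamma0,
            "lambda": lam, "n_basis": 0 if B is None else B.shape[1]}
    if first_step is not None:
        diag["alpha_first_step"] = first_step.get("alpha")
    # voxel-space reconstruction operator (V, C)
    A_vox = np.zeros((V, A.shape[1]))
    A_vox[cortex] = A[:nc]
    if B is not None:
        A_vox[scalp] = B @ A[nc:]
    if return_operator:
        return A_vox, diag
    X = A_vox @ Y
    return DotImage(X, grid, "HB", wavelength=wavelength, diagnostics=diag)


def hb_m_step(Ex2: np.ndarray, lambda0: np.ndarray, gamma0: float,
              T: int, eps: float = 1e-12) -> np.ndarray:
    """One hierarchical M-step, exposed for the algebraic limit checks:
    gamma0 = 0 reduces to the pure data-driven ARD rule Ex2 / T; gamma0 ->
    infinity pins the variances at lambda0."""
    return np.maximum((Ex2 + 2.0 * gamma0 * np.asarray(lambda0)) / (T + 2.0 * gamma0),
                      eps)


def unmix_hemoglobin(images: dict[float, np.ndarray] | list[np.ndarray],
                     E: ExtinctionTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel least-squares conversion of per-wavelength absorption-change
    images into (oxy, deoxy) hemoglobin images.

    ``images`` maps wavelength -> (V, T) array (or is a list ordered like
    ``E.wavelengths``).  Exact when the absorption changes lie in the
    column space of the extinction matrix.
    """
    if isinstance(images, dict):
        stack = np.stack([images[w] for w in E.wavelengths])
    else:
        stack = np.stack(list(images))
    if stack.shape[0] != E.E.shape[0]:
        raise ValueError("number of images must match extinction wavelengths")
    hb = E.unmix(stack)
    return hb[0], hb[1]


def build_smoother(grid: VoxelGrid, fwhm: float = 8.0,
                   within_compartment: bool = True) -> "object":
    """Sparse Gaussian smoothing operator on the voxel grid.

    Kernel weights exp(-d^2 / (2 sigma^2)) with sigma = fwhm / sqrt(8 ln 2),
    truncated at 3 sigma and row-normalized (a constant image is exactly
    preserved).  Smoothing does not mix the scalp and cortex compartments
    by default.  Returns a scipy.sparse CSR matrix (V, V).
    """
    from scipy import sparse

    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if fwhm < grid.voxel_size:
        warnings.warn("smoothing FWHM below the voxel size; kernel is near-delta")
    sigma = fwhm / math.sqrt(8.0 * math.log(2.0))
    radius = 3.0 * sigma
    tree = cKDTree(grid.centers)
    pairs = tree.sparse_distance_matrix(tree, radius, output_type="coo_matrix")
    w = np.exp(-0.5 * (pairs.data / sigma) ** 2)
    if within_compartment:
        same = grid.compartment[pairs.row] == grid.compartment[pairs.col]
        K = sparse.coo_matrix((w[same], (pairs.row[same], pairs.col[same])),
                              shape=pairs.shape)
    else:
        K = sparse.coo_matrix((w, (pairs.row, pairs.col)), shape=pairs.shape)
    K = K.tocsr()
    rowsum = np.asarray(K.sum(axis=1)).ravel()
    K = sparse.diags(1.0 / np.maximum(rowsum, 1e-300)) @ K
    return K


def smooth_image(image: DotImage | np.ndarray, grid: VoxelGrid | None = None,
                 fwhm: float = 8.0) -> DotImage | np.ndarray:
    """Spatial Gaussian smoothing (default 8 mm FWHM) of a voxel image."""
    if isinstance(image, DotImage):
        K = build_smoother(image.grid, fwhm)
        out = DotImage(K @ image.data, image.grid, image.algorithm,
                       species=image.species, wavelength=image.wavelength,
                       diagnostics={**image.diagnostics, "smooth_fwhm": fwhm})
        return out
    if grid is None:
        raise ValueError("grid required for plain-array smoothing")
    K = build_smoother(grid, fwhm)
    return K @ np.asarray(image)
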