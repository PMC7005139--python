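"""Synthetic multi-subject resting-state fNIRS studies with known truth.

The generator emulates a high-density optical montage recording two
10-minute resting runs per subject at 18.5 Hz: band-limited
(0.009--0.08 Hz) cortical ROI dynamics with a prescribed partial-
correlation structure, scalp interference that is deliberately spatially
inhomogeneous (a global systemic component plus a smooth random field
plus cardiac tone), instrument noise, and the artifacts the
preprocessing stages exist for (high-CV channels, one saturated channel,
motion spikes).  A noiseless "reference modality" -- the ROI latents with
a small independent noise floor -- stands in for a concurrent
hemodynamic reference measurement.

Channel voltages are produced by pushing the hemoglobin fields through
the same Rytov forward model the reconstruction uses, so a no-noise
configuration is exactly consistent with the inverse solvers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from .geometry import (ExtinctionTable, ProbeLayout, SensitivityMatrix,
                       TissueOptics, VoxelGrid, build_probe_layout,
                       build_sensitivity, build_voxel_grid,
                       default_layout_config, extinction_matrix)
from .preprocess import ChannelTimeSeries
from .rsfc import Parcellation

log = logging.getLogger(__name__)


@dataclass
class TruthSpec:
    """Study-level generative settings.

    Defaults mirror the target acquisition: two 10-min runs per subject
    at 18.5 Hz, 20 subjects, 19 available ROIs, cortical band
    0.009--0.08 Hz.  Amplitudes are in mM of hemoglobin concentration
    change; the scalp signal is 1.5x the cortical amplitude and channel
    noise is set by a target long-channel SNR of 5.
    """

    n_rois: int = 19
    sparsity: float = 0.25           # fraction of ROI pairs with an edge
    strength: float = 0.6            # precision off-diagonal scale
    band: tuple[float, float] = (0.009, 0.08)   # Hz
    n_subjects: int = 20
    n_runs: int = 2
    duration: float = 600.0          # s per run
    fs: float = 18.5                 # Hz
    # amplitudes, expressed at the channel level: the clean cortical signal
    # is scaled so its mean long-channel OD SD equals ``cortical_od``, and
    # the scalp interference so its long-channel OD SD is
    # ``scalp_amp_ratio`` times that (short channels then carry a larger
    # scalp share purely through the sensitivity geometry)
    cortical_od: float = 5e-4        # OD units at the middle wavelength
    deoxy_ratio: float = -1.0 / 3.0  # deoxy = ratio * oxy dynamics
    voxel_noise: float = 0.3         # relative voxel-level noise SD
    scalp_amp_ratio: float = 1.5     # scalp / cortical long-channel OD SD
    scalp_global_freqs: tuple[float, ...] = (0.01, 0.04, 0.1)
    scalp_field_band: tuple[float, float] = (0.01, 0.1)  # Hz
    scalp_field_fraction: float = 0.6  # share of scalp variance in the field
    scalp_corr_length: float = 40.0  # mm
    cardiac_freq: float = 1.1        # Hz
    channel_snr: float = 5.0         # long-channel clean SD / noise SD
    pink_fraction: float = 0.5       # share of noise variance that is 1/f
    # artifacts
    n_bad_channels: int = 2
    bad_channel_drift: float = 0.12  # OD amplitude forcing CV > 15%
    n_saturated: int = 1
    adc_ceiling: float = 2.5         # volts
    motion_rate: float = 3.0         # spikes per run (Poisson)
    motion_amp: float = 20.0         # x clean channel SD
    motion_duration: tuple[float, float] = (0.5, 2.0)  # s
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("need at least 3 ROIs")
        hi = max(max(self.scalp_global_freqs), self.cardiac_freq, self.band[1])
        if self.fs <= 2.0 * hi:
            raise ValueError("sampling rate below Nyquist for simulated content")


def make_truth_connectivity(R: int, sparsity: float = 0.25,
                            strength: float = 0.6, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Random sparse SPD precision matrix and its partial correlations.

    Off-diagonal precision entries are +/- strength (random sign) on a
    random ``sparsity`` fraction of pairs; rows are scaled to diagonal
    dominance so the matrix is SPD by construction, then verified (with a
    logged redraw on failure).  Returns (precision, partial_correlation).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        P = np.zeros((R, R))
        iu = np.triu_indices(R, k=1)
        n_pairs = len(iu[0])
        edges = rng.random(n_pairs) < sparsity
        vals = strength * rng.choice([-1.0, 1.0], size=n_pairs) * edges
        P[iu] = vals
        P = P + P.T
        rowsum = np.abs(P).sum(axis=1)
        np.fill_diagonal(P, rowsum * 1.25 + 1.0)
        # normalize to unit diagonal precision
        d = np.sqrt(np.diag(P))
        P = P / np.outer(d, d)
        if np.linalg.eigvalsh(P).min() > 1e-8:
            break
        log.info("precision draw %d not SPD; redrawing", attempt)
    else:
        raise RuntimeError("could not construct an SPD precision matrix")
    dd = np.sqrt(np.diag(P))
    pc = -P / np.outer(dd, dd)
    np.fill_diagonal(pc, 1.0)
    return P, pc


def partial_corr_of_precision(P: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def make_parcellation(grid: VoxelGrid, n_rois: int,
                      mask: np.ndarray | None = None) -> Parcellation:
    """Deterministic balanced tiling of (masked) cortical voxels into ROIs.

    Voxels are sorted by x into roughly sqrt(n_rois) slabs, each slab then
    split by y into contiguous tiles of near-equal voxel count.  Voxels
    outside ``mask`` (default: the cortex compartment) keep label 0.
    """
    if mask is None:
        mask = grid.cortex_mask
    idx = np.flatnonzero(mask)
    if len(idx) < n_rois:
        raise ValueError(f"only {len(idx)} voxels available for {n_rois} ROIs")
    labels = np.zeros(grid.n_voxels, dtype=int)
    pts = grid.centers[idx][:, :2]
    n_slabs = max(1, int(round(math.sqrt(n_rois))))
    per_slab = [n_rois // n_slabs + (1 if i < n_rois % n_slabs else 0)
                for i in range(n_slabs)]
    order_x = idx[np.argsort(pts[:, 0], kind="stable")]
    total = len(order_x)
    weights = np.array(per_slab) / n_rois
    bounds = np.concatenate([[0], np.cumsum(np.round(weights * total)).astype(int)])
    bounds[-1] = total
    roi = 1
    for s in range(n_slabs):
        slab = order_x[bounds[s]:bounds[s + 1]]
        slab = slab[np.argsort(grid.centers[slab, 1], kind="stable")]
        k = per_slab[s]
        cuts = np.linspace(0, len(slab), k + 1).round().astype(int)
        for t in range(k):
            labels[slab[cuts[t]:cuts[t + 1]]] = roi
            roi += 1
    return Parcellation(labels)


@dataclass
class StudyAssets:
    """Shared geometry/forward-model objects for one synthetic study."""

    layout: ProbeLayout
    grid: VoxelGrid
    S: SensitivityMatrix
    E: ExtinctionTable
    parcellation: Parcellation
    roi_voxels: dict[int, np.ndarray]


def build_study_assets(spec: TruthSpec, n_arrays: int = 4,
                       medium: TissueOptics | None = None,
                       sensitivity_threshold: float = 0.5) -> StudyAssets:
    """Montage, grid, sensitivity, extinction table and parcellation.

    The parcellation tiles the voxels that will pass the sensitive-voxel
    rule (normalized sensitivity > threshold), so the configured ROI
    count matches the number of available ROIs.
    """
    layout = build_probe_layout(default_layout_config(n_arrays=n_arrays))
    grid = build_voxel_grid(layout)
    S = build_sensitivity(layout, grid, medium=medium)
    E = extinction_matrix()
    ns = S.normalized_sensitivity("cortex")
    parc = make_parcellation(grid, spec.n_rois, mask=ns > sensitivity_threshold)
    roi_voxels = {int(r): np.flatnonzero(parc.labels == r) for r in parc.roi_ids}
    return StudyAssets(layout, grid, S, E, parc, roi_voxels)


def _bandlimited_noise(rng: np.random.Generator, n_series: int, T: int,
                       fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance rows of zero-phase band-passed white noise."""
    x = rng.standard_normal((n_series, T))
    sos_hp = signal.butter(3, band[0], "highpass", fs=fs, output="sos")
    sos_lp = signal.butter(7, band[1], "lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, x, axis=1), axis=1)
    y -= y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    return y / np.maximum(sd, 1e-30)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rows of unit-variance 1/f-amplitude noise via spectral shaping."""
    n, T = shape
    spec = np.fft.rfft(rng.standard_normal((n, T)), axis=1)
    f = np.fft.rfftfreq(T)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    y = np.fft.irfft(spec * scale[None, :], n=T, axis=1)
    y -= y.mean(axis=1, keepdims=True)
    return y / np.maximum(y.std(axis=1, keepdims=True), 1e-30)


def roi_latents(spec: TruthSpec, truth_corr: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """ROI latent dynamics (R, T): AR(1)-innovated, band-passed,
    empirically whitened and colored so the sample covariance equals the
    target correlation exactly."""
    R, T = spec.n_rois, spec.n_samples
    phi = 0.3  # mild temporal smoothing of the innovations
    eps = rng.standard_normal((R, T))
    ar = signal.lfilter([1.0], [1.0, -phi], eps, axis=1)
    sos_hp = signal.butter(3, spec.band[0], "highpass", fs=spec.fs, output="sos")
    sos_lp = signal.butter(7, spec.band[1], "lowpass", fs=spec.fs, output="sos")
    z = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, ar, axis=1), axis=1)
    z -= z.mean(axis=1, keepdims=True)
    # exact empirical whitening, then coloring by the target square root
    cov = (z @ z.T) / T
    Lw = np.linalg.cholesky(cov)
    white = np.linalg.solve(Lw, z)
    Lc = np.linalg.cholesky(truth_corr)
    return Lc @ white


@dataclass
class RunData:
    """One simulated run for one subject."""

    channels: ChannelTimeSeries          # raw voltages with artifacts
    reference: np.ndarray                # (T, R) reference-modality series
    latents: np.ndarray                  # (R, T) ground-truth ROI dynamics
    truth_cortex: np.ndarray | None      # (Vc, T) oxy-Hb, optional
    truth_scalp: np.ndarray | None       # (Vs, T) oxy-Hb, optional
    injected: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """All runs of a simulated study plus the generating truth."""

    spec: TruthSpec
    assets: StudyAssets
    precision: np.ndarray
    truth_pc: np.ndarray
    runs: dict[tuple[int, int], RunData]   # (subject, run) -> data
    provenance: dict = field(default_factory=dict)


def simulate_run(spec: TruthSpec, assets: StudyAssets, truth_corr: np.ndarray,
                 rng: np.random.Generator, store_truth_voxels: bool = False,
                 clean: bool = False) -> RunData:
    """Simulate one run: latents -> hemoglobin fields -> channel voltages.

    With ``clean=True`` all noise, scalp interference and artifacts are
    disabled, leaving channels exactly equal to the forward projection of
    the cortical truth (the forward-consistency contract).
    """
    grid, S, E = assets.grid, assets.S, assets.E
    layout = assets.layout
    T = spec.n_samples
    R = spec.n_rois
    C = layout.n_channels
    cortex = np.flatnonzero(grid.cortex_mask)
    scalp = np.flatnonzero(grid.scalp_mask)
    Smat = S.matrix()  # optics shared across wavelengths
    S_cor = Smat[:, cortex]
    S_sca = Smat[:, scalp]
    W = len(E.wavelengths)
    # species mixing per wavelength: dmua = (E0 + ratio * E1) * oxy_dynamics
    mix = E.E[:, 0] + spec.deoxy_ratio * E.E[:, 1]          # (W,)

    lat = roi_latents(spec, truth_corr, rng)                 # (R, T)

    long_mask = ~layout.short_mask
    mix_ref = float(mix[len(mix) // 2])      # middle-wavelength species mix

    # --- cortical contribution, calibrated at the channel level ---
    member = np.zeros((len(cortex), R))
    labels_cor = assets.parcellation.labels[cortex]
    for k, roi in enumerate(assets.parcellation.roi_ids):
        member[labels_cor == roi, k] = 1.0
    ch_sig = (S_cor @ member) @ lat                          # (C, T), per unit mix
    raw_sd = float(ch_sig[long_mask].std(axis=1).mean()) * abs(mix_ref)
    amp = spec.cortical_od / max(raw_sd, 1e-300)             # voxel oxy amplitude
    ch_sig *= amp
    # voxel-level noise, projected to channels in chunks (two species)
    ch_vnoise_oxy = np.zeros((C, T))
    ch_vnoise_deo = np.zeros((C, T))
    truth_cor = None
    if store_truth_voxels:
        truth_cor = member @ lat * amp
    if not clean and spec.voxel_noise > 0:
        for lo in range(0, len(cortex), 512):
            hi = min(lo + 512, len(cortex))
            n1 = rng.standard_normal((hi - lo, T))
            n2 = rng.standard_normal((hi - lo, T))
            ch_vnoise_oxy += S_cor[:, lo:hi] @ n1
            ch_vnoise_deo += S_cor[:, lo:hi] @ n2
            if truth_cor is not None:
                truth_cor[lo:hi] += amp * spec.voxel_noise * n1
        ch_vnoise_oxy *= amp * spec.voxel_noise
        ch_vnoise_deo *= amp * spec.voxel_noise

    # --- scalp interference: global sinusoids + smooth field + cardiac ---
    truth_sca = None
    ch_scalp = np.zeros((C, T))
    if not clean and spec.scalp_amp_ratio > 0:
        t = np.arange(T) / spec.fs
        n_s = len(scalp)
        ones = np.ones(n_s)
        # global systemic component: slow sinusoids plus cardiac tone,
        # coherent over the whole scalp sheet
        glob = np.zeros(T)
        for f in spec.scalp_global_freqs:
            ph = rng.uniform(0, 2 * np.pi)
            glob += np.sqrt(2.0) * np.sin(2 * np.pi * f * t + ph)
        ph = rng.uniform(0, 2 * np.pi)
        glob += 0.25 * np.sqrt(2.0) * np.sin(2 * np.pi * spec.cardiac_freq * t + ph)
        glob /= max(glob.std(), 1e-30)
        # inhomogeneous smooth field: spatially smoothed, band-limited
        # noise with full temporal rank (not removable by conditioning on
        # a few components), correlation length set by the kernel width
        sigma = spec.scalp_corr_length / 2.0
        pts = grid.centers[scalp][:, :2]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        Ksm = np.exp(-0.5 * d2 / sigma ** 2)
        Ksm /= np.sqrt((Ksm ** 2).sum(axis=1, keepdims=True))  # unit variance rows
        ch_field = np.zeros((C, T))
        P = S_sca @ Ksm        # channel footprint of each field generator
        field_vox = np.zeros((n_s, T)) if store_truth_voxels else None
        for lo in range(0, n_s, 512):
            hi = min(lo + 512, n_s)
            Z = _bandlimited_noise(rng, hi - lo, T, spec.fs,
                                   spec.scalp_field_band)
            ch_field += P[:, lo:hi] @ Z
            if field_vox is not None:
                field_vox += Ksm[:, lo:hi] @ Z
        # combine with the configured variance split, then calibrate the
        # scalp-driven long-channel OD SD to scalp_amp_ratio x cortical
        ch_glob = np.outer(S_sca @ ones, glob)
        f_frac = spec.scalp_field_fraction
        sd_f = float(ch_field[long_mask].std(axis=1).mean())
        sd_g = float(ch_glob[long_mask].std(axis=1).mean())
        w_f = math.sqrt(f_frac) / max(sd_f, 1e-300)
        w_g = math.sqrt(1.0 - f_frac) / max(sd_g, 1e-300)
        ch_scalp = w_f * ch_field + w_g * ch_glob
        raw_sd = float(ch_scalp[long_mask].std(axis=1).mean()) * abs(mix_ref)
        kappa = spec.scalp_amp_ratio * spec.cortical_od / max(raw_sd, 1e-300)
        ch_scalp *= kappa
        if store_truth_voxels:
            truth_sca = kappa * (w_f * field_vox + w_g * np.outer(ones, glob))

    # --- assemble OD per wavelength, add channel noise ---
    od = np.empty((T, C, W))
    clean_core = ch_sig  # per unit mix
    for w in range(W):
        od_w = mix[w] * clean_core
        od_w = od_w + E.E[w, 0] * (ch_vnoise_oxy + ch_scalp) \
            + E.E[w, 1] * (spec.deoxy_ratio * (ch_vnoise_deo + ch_scalp))
        if not clean and spec.channel_snr > 0:
            long_sd = od_w[~layout.short_mask].std(axis=1).mean()
            nsd = long_sd / spec.channel_snr
            white = rng.standard_normal((C, T))
            pink = _pink_noise(rng, (C, T))
            pf = spec.pink_fraction
            od_w = od_w + nsd * (math.sqrt(1 - pf) * white + math.sqrt(pf) * pink)
        od[:, :, w] = od_w.T

    injected: dict = {"bad_channels": [], "saturated": [], "motion_windows": []}
    if not clean:
        # motion spikes: common windows, channel-specific random amplitude
        n_spk = rng.poisson(spec.motion_rate)
        sd_ch = od.std(axis=0)                               # (C, W)
        for _ in range(n_spk):
            dur = int(rng.uniform(*spec.motion_duration) * spec.fs)
            start = int(rng.integers(0, max(T - dur, 1)))
            sgn = rng.choice([-1.0, 1.0], size=(1, C, 1))
            od[start:start + dur] += spec.motion_amp * sd_ch[None] * sgn
            injected["motion_windows"].append((start, start + dur))
        # bad (high-CV) channels: large slow OD drift
        candidates = rng.permutation(C)
        bad = candidates[: spec.n_bad_channels]
        t = np.arange(T) / spec.fs
        for ch in bad:
            ph = rng.uniform(0, 2 * np.pi)
            drift = spec.bad_channel_drift * np.sin(2 * np.pi * 0.003 * t + ph)
            od[:, ch, :] += drift[:, None]
        injected["bad_channels"] = [int(b) for b in bad]
        injected["saturated"] = [int(c) for c in
                                 candidates[spec.n_bad_channels:
                                            spec.n_bad_channels + spec.n_saturated]]

    # --- voltages ---
    v0 = rng.uniform(0.5, 2.0, size=(1, C, 1))
    volts = v0 * 10.0 ** (-od)
    for ch in injected["saturated"]:
        q95 = np.quantile(volts[:, ch, :], 0.95, axis=0)
        volts[:, ch, :] *= spec.adc_ceiling / q95[None, :]
        np.clip(volts[:, ch, :], None, spec.adc_ceiling, out=volts[:, ch, :])

    cts = ChannelTimeSeries(
        volts, fs=spec.fs, wavelengths=E.wavelengths,
        channel_class=layout.channel_class, channel_array=layout.channel_array,
        units="V")
    ref = (lat + 0.1 * rng.standard_normal(lat.shape)).T     # (T, R)
    return RunData(cts, ref, lat, truth_cor, truth_sca, injected)


def make_phantom(seed: int = 0, scalp_only: bool = False,
                 scalp_cortex_ratio: float = 1.5, noise: float = 0.05,
                 T: int = 1000, fs: float = 18.5, voxel_size: float = 6.0,
                 n_arrays: int = 2,
                 ) -> tuple[StudyAssets, np.ndarray, tuple[int, int], np.ndarray]:
    """Two-layer localization phantom: two focal cortical sources under an
    inhomogeneous scalp field.

    Two active voxels sit in the top cortical layer under different
    arrays; the scalp carries a global oscillation plus a smooth random
    field, calibrated so its long-channel OD SD is ``scalp_cortex_ratio``
    times the cortical one; iid channel noise is added at ``noise``
    relative to the long-channel signal SD.  Returns (assets-like tuple
    of layout/grid/sensitivity, channel OD (C, T), the two truth voxel
    indices, the truth voxel field (V, T)).
    """
    rng = np.random.default_rng(seed)
    layout = build_probe_layout(default_layout_config(n_arrays=n_arrays))
    grid = build_voxel_grid(layout, voxel_size=voxel_size,
                            diagonal_extension=1.0)
    S = build_sensitivity(layout, grid)
    M = S.matrix()
    long = ~layout.short_mask
    cortex = np.flatnonzero(grid.cortex_mask)
    scalp = np.flatnonzero(grid.scalp_mask)
    ns = S.normalized_sensitivity("cortex")
    top_depth = grid.depth[cortex].min()
    top = cortex[grid.depth[cortex] == top_depth]
    arrays = np.unique(grid.array[top])
    v0 = top[grid.array[top] == arrays[0]]
    v0 = v0[np.argmax(ns[v0])]
    v1 = top[grid.array[top] == arrays[-1]]
    v1 = v1[np.argmax(ns[v1])]

    def _band(n: int) -> np.ndarray:
        x = rng.standard_normal((n, T))
        sos = signal.butter(4, [0.01, 0.08], "bandpass", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, x, axis=1)
        return y / y.std(axis=1, keepdims=True)

    X = np.zeros((grid.n_voxels, T))
    if not scalp_only:
        Xc = np.zeros((grid.n_voxels, T))
        Xc[[v0, v1]] = _band(2)
        Xc /= (M @ Xc)[long].std(axis=1).mean()   # unit long-channel OD SD
        X += Xc
    pts = grid.centers[scalp][:, :2]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / 20.0 ** 2)
    pats = K @ rng.standard_normal((len(scalp), 4))
    pats /= np.abs(pats).max(axis=0, keepdims=True)
    Xs = np.zeros((grid.n_voxels, T))
    Xs[scalp] = np.outer(np.ones(len(scalp)), _band(1)[0]) + pats @ _band(4)
    Xs *= scalp_cortex_ratio / (M @ Xs)[long].std(axis=1).mean()
    X += Xs
    Y = M @ X
    Y += noise * Y[long].std(axis=1).mean() * rng.standard_normal(Y.shape)
    return (layout, grid, S), Y, (int(v0), int(v1)), X


def cortical_peak_error(image_data: np.ndarray, grid: VoxelGrid,
                        truth_voxels: Sequence[int] | tuple[int, int],
                        suppress_radius: float = 25.0) -> float:
    """Worst distance (mm) from the top cortical activity peaks to the
    nearest true source.

    Peaks are the greedy maxima of the temporal-SD map over the cortex,
    suppressing a neighborhood around each found peak; one peak is
    extracted per true source.
    """
    sd = np.asarray(image_data).std(axis=1).copy()
    sd[~grid.cortex_mask] = 0.0
    truth = np.asarray(list(truth_voxels), dtype=int)
    errs = []
    for _ in range(len(truth)):
        p = int(np.argmax(sd))
        d = np.linalg.norm(grid.centers[truth] - grid.centers[p], axis=1)
        errs.append(float(d.min()))
        near = np.linalg.norm(grid.centers - grid.centers[p], axis=1) < suppress_radius
        sd[near] = 0.0
    return max(errs)


def simulate_study(spec: TruthSpec, assets: StudyAssets | None = None,
                   n_arrays: int = 4, store_truth_voxels: bool = False,
                   ) -> SyntheticStudy:
    """Simulate the full study: n_subjects x n_runs runs.

    Per-subject sub-seeds are spawned from the master seed, so
    regeneration under the same spec is bit-identical.
    """
    if assets is None:
        assets = build_study_assets(spec, n_arrays=n_arrays)
    P, pc = make_truth_connectivity(spec.n_rois, spec.sparsity,
                                    spec.strength, spec.seed)
    corr = np.linalg.inv(P)
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    master = np.random.SeedSequence(spec.seed)
    subj_seeds = master.spawn(spec.n_subjects)
    runs: dict[tuple[int, int], RunData] = {}
    for s in range(spec.n_subjects):
        run_seeds = subj_seeds[s].spawn(spec.n_runs)
        for r in range(spec.n_runs):
            rng = np.random.default_rng(run_seeds[r])
            runs[(s, r)] = simulate_run(spec, assets, corr, rng,
                                        store_truth_voxels=store_truth_voxels)
    prov = {"spec": asdict(spec), "seed": spec.seed,
            "n_channels": assets.layout.n_channels,
            "n_voxels": assets.grid.n_voxels}
    return SyntheticStudy(spec, assets, P, pc, runs, prov)
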