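"""Probe geometry, voxel grids, and the analytic photon-diffusion forward model.

The forward model maps absorption changes in a two-compartment (scalp /
cortex) voxel grid to optical-density changes at source--detector channels
through a Rytov-linearized sensitivity matrix.  Photon transport is modelled
with the semi-infinite homogeneous diffusion Green's function with an
extrapolated boundary, which preserves the banana-shaped sensitivity
profiles and their deepening with source--detector separation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

LN10 = math.log(10.0)

#: Baseline tissue optical properties (absorption mm^-1, scattering mm^-1,
#: anisotropy, refractive index), common to the three wavelengths.
DEFAULT_TISSUE_OPTICS: dict[str, tuple[float, float, float, float]] = {
    "scalp_skull": (0.019, 7.8, 0.89, 1.37),
    "CSF": (0.004, 0.009, 0.89, 1.37),
    "gray": (0.02, 9.0, 0.89, 1.37),
    "white": (0.08, 40.9, 0.84, 1.37),
}

DEFAULT_WAVELENGTHS = (780.0, 805.0, 830.0)

#: Molar extinction coefficients in mm^-1 mM^-1 for (oxy-Hb, deoxy-Hb).
#: Literature values interpolated to the instrument wavelengths.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    780.0: (0.0710, 0.1075),
    805.0: (0.0830, 0.0795),
    830.0: (0.0974, 0.0693),
}


class ConfigurationError(ValueError):
    """Raised when a layout/grid configuration cannot produce a valid model."""


@dataclass(frozen=True)
class TissueOptics:
    """Optical properties of one tissue type."""

    mua: float  # absorption coefficient, mm^-1
    mus: float  # scattering coefficient, mm^-1
    g: float    # scattering anisotropy
    n: float    # refractive index

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.mus <= 0 or self.n <= 0:
            raise ValueError("optical parameters must be positive")
        if not 0.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (0, 1)")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus' = mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)

    @property
    def mueff(self) -> float:
        """Effective attenuation sqrt(3 * mua * (mua + mus')), mm^-1."""
        return math.sqrt(3.0 * self.mua * (self.mua + self.musp))


@dataclass(frozen=True)
class OpticalParameters:
    """Per-tissue baseline optics for the head model."""

    tissues: Mapping[str, TissueOptics] = field(
        default_factory=lambda: {
            name: TissueOptics(*vals) for name, vals in DEFAULT_TISSUE_OPTICS.items()
        }
    )

    def __getitem__(self, tissue: str) -> TissueOptics:
        return self.tissues[tissue]


@dataclass(frozen=True)
class Channel:
    """One source--detector measurement pair."""

    source: int
    detector: int
    separation: float  # mm
    cls: str  # "short" or "long"
    array: int


@dataclass
class ProbeLayout:
    """Source/detector coordinates (mm) and the enumerated channels."""

    sources: np.ndarray       # (n_src, 3)
    detectors: np.ndarray     # (n_det, 3)
    channels: list[Channel]
    source_array: np.ndarray  # array membership per source
    detector_array: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def separations(self) -> np.ndarray:
        return np.array([c.separation for c in self.channels])

    @property
    def channel_class(self) -> np.ndarray:
        return np.array([c.cls for c in self.channels])

    @property
    def short_mask(self) -> np.ndarray:
        return self.channel_class == "short"

    @property
    def channel_array(self) -> np.ndarray:
        return np.array([c.array for c in self.channels])

    def counts(self) -> dict[str, int]:
        cls = self.channel_class
        return {"short": int((cls == "short").sum()), "long": int((cls == "long").sum())}


def default_layout_config(n_arrays: int = 4, pitch: float = 13.0,
                          grid_shape: tuple[int, int] = (4, 4),
                          gap: float = 39.0) -> dict:
    """Checkerboard multi-array montage.

    Arrays are laid side by side along x with ``gap`` mm between array
    centers beyond the array width, emulating separate probe holders.
    """
    width = (grid_shape[0] - 1) * pitch
    centers = []
    # 2 x ceil(n/2) arrangement: frontal / parietal rows
    ncol = (n_arrays + 1) // 2
    for i in range(n_arrays):
        row, col = divmod(i, ncol)
        centers.append([col * (width + gap), row * (width + gap)])
    return {
        "arrays": [
            {"center": c, "shape": list(grid_shape), "pitch": pitch,
             "first_probe": "source"}
            for c in centers
        ],
        "short_separation": pitch,
        "long_separation": math.sqrt(5.0) * pitch,
        "tolerance": 1.0,
    }


def build_probe_layout(config: dict, strict: bool = True) -> ProbeLayout:
    """Build a :class:`ProbeLayout` from a configuration dictionary.

    Two configuration styles are supported: per-array checkerboard grids
    (``arrays`` entries with center/shape/pitch) or explicit coordinates
    (``sources`` / ``detectors`` lists, optionally with ``arrays``
    membership).  Channels are every source--detector pair whose separation
    is within ``tolerance`` (default 1 mm) of the short or long nominal
    separation (defaults 13 mm and sqrt(5)*13 ~ 29.07 mm).

    With ``strict=True`` a montage yielding zero short or zero long
    channels is treated as a configuration error; pass ``strict=False``
    for intentionally degenerate layouts (e.g. a single 2x2 array, which
    has no long pairs).
    """
    short_nom = float(config.get("short_separation", 13.0))
    long_nom = float(config.get("long_separation", math.sqrt(5.0) * 13.0))
    tol = float(config.get("tolerance", 1.0))

    src, det, src_arr, det_arr = [], [], [], []
    if "arrays" in config and "sources" not in config:
        for ai, arr in enumerate(config["arrays"]):
            cx, cy = arr["center"]
            ni, nj = arr.get("shape", (4, 4))
            pitch = float(arr.get("pitch", 13.0))
            first = arr.get("first_probe", "source")
            x0 = cx - (ni - 1) * pitch / 2.0
            y0 = cy - (nj - 1) * pitch / 2.0
            for i in range(ni):
                for j in range(nj):
                    pos = [x0 + i * pitch, y0 + j * pitch, 0.0]
                    is_source = ((i + j) % 2 == 0) == (first == "source")
                    if is_source:
                        src.append(pos)
                        src_arr.append(ai)
                    else:
                        det.append(pos)
                        det_arr.append(ai)
    else:
        src = [list(map(float, p)) for p in config["sources"]]
        det = [list(map(float, p)) for p in config["detectors"]]
        src_arr = list(config.get("source_arrays", [0] * len(src)))
        det_arr = list(config.get("detector_arrays", [0] * len(det)))
        for p in src + det:
            if len(p) == 2:
                p.append(0.0)

    sources = np.asarray(src, dtype=float)
    detectors = np.asarray(det, dtype=float)
    allpos = np.vstack([sources, detectors])
    if len(np.unique(np.round(allpos, 6), axis=0)) != len(allpos):
        raise ConfigurationError("duplicate probe coordinates in layout")

    channels: list[Channel] = []
    d = np.linalg.norm(sources[:, None, :] - detectors[None, :, :], axis=2)
    for si in range(len(sources)):
        for di in range(len(detectors)):
            sep = d[si, di]
            if abs(sep - short_nom) <= tol:
                cls = "short"
            elif abs(sep - long_nom) <= tol:
                cls = "long"
            else:
                continue
            channels.append(Channel(si, di, float(sep), cls, int(src_arr[si])))

    layout = ProbeLayout(sources, detectors, channels,
                         np.asarray(src_arr), np.asarray(det_arr))
    counts = layout.counts()
    if layout.n_channels == 0:
        raise ConfigurationError("layout produced no channels")
    if strict and (counts["short"] == 0 or counts["long"] == 0):
        raise ConfigurationError(
            f"layout produced {counts['short']} short / {counts['long']} long "
            "channels; pass strict=False if this is intentional"
        )
    return layout


DEFAULT_LAYER_DEPTHS: dict[str, tuple[float, float]] = {
    "scalp_skull": (0.0, 11.0),
    "CSF": (11.0, 13.0),
    "gray": (13.0, math.inf),
}


@dataclass
class VoxelGrid:
    """Voxelized two-compartment reconstruction region under the probe arrays."""

    centers: np.ndarray      # (V, 3) mm; z is depth below the scalp surface
    voxel_size: float        # mm, isotropic
    layer: np.ndarray        # tissue layer name per voxel
    compartment: np.ndarray  # "scalp" or "cortex"
    array: np.ndarray        # probe array each voxel sits beneath

    @property
    def n_voxels(self) -> int:
        return len(self.centers)

    @property
    def depth(self) -> np.ndarray:
        """Depth of each voxel center below the scalp surface, mm."""
        return self.centers[:, 2]

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.compartment == "cortex"

    @property
    def scalp_mask(self) -> np.ndarray:
        return self.compartment == "scalp"


def build_voxel_grid(layout: ProbeLayout, voxel_size: float = 4.0,
                     depth: float = 28.0, diagonal_extension: float = 1.5,
                     layer_depths: Mapping[str, tuple[float, float]] | None = None,
                     ) -> VoxelGrid:
    """Cuboid reconstruction region beneath each probe array.

    The lateral footprint of each array is its probe bounding square with
    the diagonals extended by ``diagonal_extension`` (half-extents scaled
    about the array center).  Voxels are labelled with the tissue layer
    containing their center depth; the scalp/skull layer forms the scalp
    compartment, deeper layers the cortex compartment.  Overlapping array
    regions are merged (voxels deduplicated).
    """
    if layer_depths is None:
        layer_depths = DEFAULT_LAYER_DEPTHS
    arrays = np.unique(np.concatenate([layout.source_array, layout.detector_array]))
    centers_list, arr_list = [], []
    nz = int(math.ceil(depth / voxel_size))
    zc = (np.arange(nz) + 0.5) * voxel_size
    zc = zc[zc <= depth]
    for ai in arrays:
        pts = np.vstack([
            layout.sources[layout.source_array == ai],
            layout.detectors[layout.detector_array == ai],
        ])
        lo, hi = pts[:, :2].min(axis=0), pts[:, :2].max(axis=0)
        c = (lo + hi) / 2.0
        half = (hi - lo) / 2.0 * diagonal_extension
        half = np.maximum(half, voxel_size)  # degenerate (linear) arrays
        nxy = np.ceil(2 * half / voxel_size).astype(int)  # rounded outward
        xs = c[0] - (nxy[0] / 2.0 - 0.5) * voxel_size + np.arange(nxy[0]) * voxel_size
        ys = c[1] - (nxy[1] / 2.0 - 0.5) * voxel_size + np.arange(nxy[1]) * voxel_size
        gx, gy, gz = np.meshgrid(xs, ys, zc, indexing="ij")
        pts3 = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        centers_list.append(pts3)
        arr_list.append(np.full(len(pts3), ai))
    centers = np.vstack(centers_list)
    arr_id = np.concatenate(arr_list)
    # merge overlapping array regions
    _, keep = np.unique(np.round(centers, 6), axis=0, return_index=True)
    keep = np.sort(keep)
    centers, arr_id = centers[keep], arr_id[keep]

    layer = np.empty(len(centers), dtype=object)
    for name, (lo, hi) in layer_depths.items():
        sel = (centers[:, 2] >= lo) & (centers[:, 2] < hi)
        layer[sel] = name
    if (layer == None).any():  # noqa: E711 - object array sentinel
        raise ConfigurationError("layer_depths do not partition [0, depth]")
    compartment = np.where(layer == "scalp_skull", "scalp", "cortex")
    return VoxelGrid(centers, float(voxel_size), layer.astype(str),
                     compartment.astype(str), arr_id)


def _effective_reflection(n: float) -> float:
    """Effective internal reflection coefficient for a tissue/air boundary.

    Groenhuis-style polynomial approximation in the relative index.
    """
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def diffusion_constants(optics: TissueOptics) -> tuple[float, float, float, float]:
    """Return (D, mueff, z0, zb) for a homogeneous semi-infinite medium."""
    musp = optics.musp
    D = 1.0 / (3.0 * (optics.mua + musp))
    mueff = optics.mueff
    z0 = 1.0 / musp
    reff = _effective_reflection(optics.n)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return D, mueff, z0, zb


def fluence_green(point_a: np.ndarray, point_b: np.ndarray,
                  medium: TissueOptics, min_distance: float = 2.0) -> np.ndarray:
    """Diffusion-equation Green's function in a semi-infinite medium.

    Uses the extrapolated-boundary image-source construction: the fluence
    between two interior points is the free-space term minus the
    contribution of the image of one point mirrored about the plane
    z = -zb.  Symmetric in its two arguments and strictly decreasing with
    distance.  Distances are clamped below at ``min_distance`` (half a
    voxel by default) to avoid the 1/r singularity.
    """
    a = np.atleast_2d(np.asarray(point_a, dtype=float))
    b = np.atleast_2d(np.asarray(point_b, dtype=float))
    D, mueff, _z0, zb = diffusion_constants(medium)
    d1 = np.linalg.norm(a - b, axis=-1)
    b_img = b.copy()
    b_img[..., 2] = -b_img[..., 2] - 2.0 * zb
    d2 = np.linalg.norm(a - b_img, axis=-1)
    d1 = np.maximum(d1, min_distance)
    d2 = np.maximum(d2, min_distance)
    phi = (np.exp(-mueff * d1) / d1 - np.exp(-mueff * d2) / d2) / (4.0 * math.pi * D)
    return phi if phi.shape != (1,) else float(phi[0])


@dataclass
class SensitivityMatrix:
    """Rytov sensitivity (channels x voxels) per wavelength.

    Entries are the base-10 optical-density change per unit absorption
    change (mm^-1) in one voxel, including the voxel volume factor.
    """

    matrices: dict[float, np.ndarray]  # wavelength -> (C, V)
    grid: VoxelGrid
    layout: ProbeLayout
    medium: TissueOptics
    kernel: str = "diffusion-semi-infinite"

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.matrices)

    def matrix(self, wavelength: float | None = None) -> np.ndarray:
        if wavelength is None:
            wavelength = self.wavelengths[0]
        return self.matrices[wavelength]

    def column_norms(self, wavelength: float | None = None) -> np.ndarray:
        """rho_v: Euclidean norm of each voxel's sensitivity column."""
        return np.linalg.norm(self.matrix(wavelength), axis=0)

    def rho2(self, wavelength: float | None = None) -> np.ndarray:
        """Squared column norms normalized by their maximum, in [0, 1]."""
        nn = self.column_norms(wavelength) ** 2
        return nn / nn.max()

    def normalized_sensitivity(self, compartment: str = "cortex") -> np.ndarray:
        """Per-voxel sensitivity value in [0, 1] used for the sensitive-voxel
        rule: column norms normalized by their maximum over the requested
        compartment; voxels outside the compartment get 0."""
        rho = self.column_norms()
        mask = self.grid.compartment == compartment
        out = np.zeros_like(rho)
        out[mask] = rho[mask] / rho[mask].max()
        return out


def build_sensitivity(layout: ProbeLayout, grid: VoxelGrid,
                      medium: TissueOptics | None = None,
                      wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
                      ) -> SensitivityMatrix:
    """Rytov sensitivity matrix from the analytic diffusion kernel.

    S(ch, v) = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) * voxel_volume / ln 10,
    the three-point Rytov kernel in base-10 OD convention.  Sources and
    detectors are represented as isotropic points one transport mean free
    path (z0 = 1/mus') below the surface.  The baseline optics are common
    to all wavelengths, so the per-wavelength matrices share one array.
    """
    if medium is None:
        medium = OpticalParameters()["scalp_skull"]
    _D, _mueff, z0, _zb = diffusion_constants(medium)
    clamp = grid.voxel_size / 2.0
    vol = grid.voxel_size ** 3

    src = layout.sources.copy()
    det = layout.detectors.copy()
    src[:, 2] += z0
    det[:, 2] += z0

    centers = grid.centers
    n_ch = layout.n_channels
    S = np.empty((n_ch, grid.n_voxels))
    g_sv = {}
    for i in range(len(src)):
        g_sv[("s", i)] = fluence_green(src[i], centers, medium, clamp)
    for i in range(len(det)):
        g_sv[("d", i)] = fluence_green(det[i], centers, medium, clamp)
    for ci, ch in enumerate(layout.channels):
        g_sd = fluence_green(src[ch.source], det[ch.detector][None, :], medium, clamp)
        g_sd = float(np.asarray(g_sd).ravel()[0])
        if g_sd <= 0:
            raise ValueError(f"channel {ci}: non-positive source-detector fluence")
        S[ci] = g_sv[("s", ch.source)] * g_sv[("d", ch.detector)] / g_sd
    S *= vol / LN10
    np.maximum(S, 0.0, out=S)
    matrices = {float(w): S for w in wavelengths}
    return SensitivityMatrix(matrices, grid, layout, medium)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients mapping hemoglobin changes to absorption.

    E is (n_wavelengths x 2); columns are (oxy-Hb, deoxy-Hb) in
    mm^-1 mM^-1, so E @ (d_oxy, d_deoxy) gives the absorption change
    (mm^-1) at each wavelength for concentration changes in mM.
    """

    wavelengths: tuple[float, ...]
    E: np.ndarray

    def unmix(self, dmua: np.ndarray) -> np.ndarray:
        """Least-squares (d_oxy, d_deoxy) from per-wavelength d_mua.

        ``dmua`` has wavelengths on the first axis; the result has the two
        species on the first axis.
        """
        pinv = np.linalg.pinv(self.E)  # (2, W)
        return np.tensordot(pinv, dmua, axes=(1, 0))


def extinction_matrix(wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
                      table: Mapping[float, tuple[float, float]] | None = None,
                      ) -> ExtinctionTable:
    """Build the extinction matrix for the given wavelengths.

    Raises if fewer than two wavelengths are given or if the resulting
    matrix is rank-deficient (the error names the offending wavelengths).
    """
    if table is None:
        table = DEFAULT_EXTINCTION
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelengths to unmix two species")
    rows = []
    for w in wavelengths:
        if float(w) not in table:
            raise KeyError(f"no extinction coefficients for {w} nm")
        rows.append(table[float(w)])
    E = np.asarray(rows, dtype=float)
    s = np.linalg.svd(E, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError(
            f"extinction table is rank-deficient for wavelengths {tuple(wavelengths)}"
        )
    return ExtinctionTable(tuple(float(w) for w in wavelengths), E)
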