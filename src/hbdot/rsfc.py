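"""ROI-level resting-state functional connectivity from volumetric images.

Connectivity is computed as the partial correlation between ROI-mean
time series, which removes the shared linear influence of all other ROIs
(and with it much of the globally coherent physiological signal).  ROIs
enter the analysis only where the optical montage can actually see them:
voxels whose normalized sensitivity exceeds 0.5 in every subject are
*sensitive*, and ROIs with at least 10 sensitive voxels are *available*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class Parcellation:
    """Integer ROI label per voxel; 0 means unassigned."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.labels < 0).any():
            raise ValueError("ROI labels must be non-negative")
        ids = self.roi_ids
        if not self.names:
            self.names = {i: f"ROI{i:03d}" for i in ids}
        for i, name in self.names.items():
            if i not in ids:
                raise ValueError(f"named ROI {name!r} ({i}) has no voxels")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


@dataclass
class SensitivityMask:
    """Per-voxel sensitive flag with the underlying values and threshold."""

    sensitive: np.ndarray          # bool (V,)
    values: np.ndarray             # (n_subjects, V) normalized sensitivities
    threshold: float


@dataclass
class ConnectivityMatrix:
    """ROI x ROI partial correlations with availability metadata."""

    matrix: np.ndarray
    roi_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        if self.matrix.shape != (len(self.roi_ids),) * 2:
            raise ValueError("matrix size must match the ROI list")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def lower_triangle(self) -> np.ndarray:
        """Strict lower-triangular entries as a flat vector."""
        i, j = np.tril_indices(self.n_rois, k=-1)
        return self.matrix[i, j]


def sensitive_mask(normalized_sensitivities: np.ndarray,
                   threshold: float = 0.5) -> SensitivityMask:
    """Voxels with normalized sensitivity strictly above ``threshold`` in
    every subject.

    ``normalized_sensitivities`` is (n_subjects, V) with values in [0, 1]
    (per-subject max-normalized sensitivity column norms).  A value equal
    to the threshold excludes the voxel; a voxel failing in any one
    subject is excluded for all.
    """
    vals = np.atleast_2d(np.asarray(normalized_sensitivities, dtype=float))
    flags = (vals > threshold).all(axis=0)
    if not flags.any():
        raise ValueError(
            f"no voxel exceeds sensitivity {threshold} in all subjects; "
            "review the threshold or the montage")
    return SensitivityMask(flags, vals, float(threshold))


def available_rois(parcellation: Parcellation, mask: SensitivityMask,
                   min_voxels: int = 10) -> np.ndarray:
    """ROIs containing at least ``min_voxels`` sensitive voxels."""
    if len(parcellation.labels) != len(mask.sensitive):
        raise ValueError("parcellation and mask are on different grids")
    ids = parcellation.roi_ids
    counts = np.array([
        int((mask.sensitive & (parcellation.labels == i)).sum()) for i in ids
    ])
    avail = ids[counts >= min_voxels]
    if len(avail) == 0:
        raise ValueError("no available ROIs (all below the sensitive-voxel minimum)")
    return avail


def roi_timeseries(image: np.ndarray, parcellation: Parcellation,
                   mask: SensitivityMask,
                   rois: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean over the sensitive voxels of each available ROI.

    ``image`` is (V, T); returns (T, R) and the ROI ids used.  ROIs not in
    the available set are skipped with a log entry.
    """
    if rois is None:
        rois = available_rois(parcellation, mask)
    image = np.asarray(image)
    out = np.empty((image.shape[1], len(rois)))
    for k, roi in enumerate(rois):
        sel = mask.sensitive & (parcellation.labels == roi)
        if not sel.any():
            log.info("ROI %d has no sensitive voxels; excluded", roi)
            continue
        out[:, k] = image[sel].mean(axis=0)
    return out, np.asarray(rois)


def partial_correlation(ts: np.ndarray, roi_ids: np.ndarray | None = None,
                        shrinkage: float = 0.0,
                        meta: dict | None = None) -> ConnectivityMatrix:
    """Partial-correlation matrix of ROI time series.

    ``ts`` is (T, R).  The partial correlation between two ROIs given all
    others is read off the precision matrix P = C^-1 as
    pc_ij = -P_ij / sqrt(P_ii P_jj), with unit diagonal by convention.
    For short segments (T < 3 R) a small ridge is added to the covariance
    diagonal (``shrinkage`` as a fraction of the mean variance; an
    automatic 1e-3 engages with a warning when left at 0).
    """
    ts = np.asarray(ts, dtype=float)
    T, R = ts.shape
    if roi_ids is None:
        roi_ids = np.arange(1, R + 1)
    if T < 3 * R and shrinkage == 0.0:
        warnings.warn(f"short segment (T={T} < 3R={3*R}); engaging ridge shrinkage")
        shrinkage = 1e-3
    C = np.cov(ts, rowvar=False)
    if shrinkage > 0:
        C = C + shrinkage * np.mean(np.diag(C)) * np.eye(R)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0 or not np.isfinite(logdet):
        cc = np.corrcoef(ts, rowvar=False)
        np.fill_diagonal(cc, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(cc)), cc.shape)
        raise np.linalg.LinAlgError(
            f"singular ROI covariance without shrinkage; most collinear pair: "
            f"ROI {roi_ids[i]} / ROI {roi_ids[j]} (r={cc[i, j]:.4f})")
    P = np.linalg.inv(C)
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)  # symmetrize rounding noise
    return ConnectivityMatrix(pc, roi_ids, meta or {})


def connectivity_from_image(image: np.ndarray, parcellation: Parcellation,
                            mask: SensitivityMask,
                            rois: np.ndarray | None = None,
                            shrinkage: float = 0.0,
                            meta: dict | None = None) -> ConnectivityMatrix:
    """ROI averaging followed by partial correlation, in one call."""
    ts, used = roi_timeseries(image, parcellation, mask, rois)
    return partial_correlation(ts, used, shrinkage, meta)
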