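"""Comparison battery for connectivity matrices.

Similarity between two connectivity matrices is the Pearson correlation
of their Fisher-z-transformed strict lower triangles, itself reported on
the Fisher-z scale.  Reproducibility across runs or run halves is
summarized per subject by that similarity and by the two-way consistency
intraclass correlations ICC(C,1) and ICC(C,k); group differences are
tested with one-way ANOVA followed by Tukey-Kramer pairwise comparisons,
and the intra-run versus half-length inter-run contrast with a two-sample
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rsfc import ConnectivityMatrix, partial_correlation

Z_CLIP = 1.0 - 1e-7

#: The four split-half designs: (half of run A, half of run B).
SPLIT_DESIGNS = {
    "intra_run1": (("run1", "FH"), ("run1", "SH")),
    "intra_run2": (("run2", "FH"), ("run2", "SH")),
    "inter_FH": (("run1", "FH"), ("run2", "FH")),
    "inter_SH": (("run1", "SH"), ("run2", "SH")),
}


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transformation atanh(r), with |r| clipped to 1 - 1e-7 so
    perfect correlations map to a large finite value."""
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) > 1.0 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -Z_CLIP, Z_CLIP))
    return float(z) if np.isscalar(r) else z


@dataclass
class SimilarityResult:
    """Similarity of two connectivity matrices."""

    r: float
    z: float
    pair: str = ""


def similarity(C1: ConnectivityMatrix | np.ndarray,
               C2: ConnectivityMatrix | np.ndarray,
               pair: str = "") -> SimilarityResult:
    """Fisher-z similarity of two connectivity matrices.

    The strict lower triangles are vectorized, Fisher-z transformed
    entrywise, Pearson-correlated, and the resulting coefficient is
    Fisher-z transformed again.  Matrices must share the same ROI set and
    ordering.
    """
    if isinstance(C1, ConnectivityMatrix) and isinstance(C2, ConnectivityMatrix):
        if not np.array_equal(C1.roi_ids, C2.roi_ids):
            only1 = sorted(set(C1.roi_ids) - set(C2.roi_ids))
            only2 = sorted(set(C2.roi_ids) - set(C1.roi_ids))
            raise ValueError(
                f"ROI sets differ: only in first {only1}, only in second {only2}")
        v1, v2 = C1.lower_triangle(), C2.lower_triangle()
    else:
        M1, M2 = np.asarray(C1), np.asarray(C2)
        if M1.shape != M2.shape:
            raise ValueError("connectivity matrices have different shapes")
        i, j = np.tril_indices(M1.shape[0], k=-1)
        v1, v2 = M1[i, j], M2[i, j]
    z1, z2 = fisher_z(v1), fisher_z(v2)
    r = float(np.corrcoef(z1, z2)[0, 1])
    return SimilarityResult(r=r, z=fisher_z(r), pair=pair)


def icc_consistency(data: np.ndarray, measure: str = "single") -> float:
    """Two-way mixed-model consistency intraclass correlation.

    ``data`` is (n items x k raters); items are Fisher-z connection values
    and raters are runs or run halves.  From the two-way ANOVA mean
    squares (rows MS_R, residual MS_E):

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)      [measure="single"]
    ICC(C,k) = (MS_R - MS_E) / MS_R                      [measure="average"]

    Returns NaN when the between-item variance is zero (undefined).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        return float("nan")
    if measure == "single":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    if measure == "average":
        return (ms_r - ms_e) / ms_r
    raise ValueError(f"unknown ICC measure {measure!r}")


def spearman_brown(icc1: float, k: int) -> float:
    """Average-measure reliability implied by a single-measure ICC."""
    return k * icc1 / (1.0 + (k - 1) * icc1)


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def anova_tukey(groups: list[np.ndarray], labels: list[str] | None = None,
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons.

    The F statistic comes from the between/within sums-of-squares
    decomposition; pairwise comparisons use the studentized-range
    distribution in the unequal-n (Tukey-Kramer) form.  Identical data in
    all groups yields F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    dfb, dfw = k - 1, N - k
    msb = ss_between / dfb
    msw = ss_within / dfw
    if msw == 0:
        F, p = (0.0, 1.0) if msb == 0 else (np.inf, 0.0)
    else:
        F = msb / msw
        p = float(stats.f.sf(F, dfb, dfw))
        if msb == 0:
            F, p = 0.0, 1.0
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if msw == 0:
                padj = 0.0 if diff != 0 else 1.0
                q = np.inf if diff != 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                padj = float(stats.studentized_range.sf(q, k, dfw))
            rows.append({"group1": labels[i], "group2": labels[j],
                         "diff": diff, "q": q, "p_adj": padj,
                         "significant": padj < alpha})
    return AnovaResult(F=float(F), p=float(p), df_between=dfb, df_within=dfw,
                       pairwise=pd.DataFrame(rows))


@dataclass
class ReliabilityReport:
    """Per-subject reproducibility for one design, with group summaries."""

    design: str
    r: np.ndarray          # per-subject Pearson r of z(C_low)
    icc1: np.ndarray       # per-subject ICC(C,1)
    icck: np.ndarray       # per-subject ICC(C,k)

    def summary(self) -> dict[str, float]:
        return {
            "design": self.design,
            "r_mean": float(np.nanmean(self.r)),
            "r_sd": float(np.nanstd(self.r, ddof=1)),
            "icc1_mean": float(np.nanmean(self.icc1)),
            "icc1_sd": float(np.nanstd(self.icc1, ddof=1)),
            "icck_mean": float(np.nanmean(self.icck)),
            "icck_sd": float(np.nanstd(self.icck, ddof=1)),
        }


def reproducibility(pairs: list[tuple[ConnectivityMatrix, ConnectivityMatrix]],
                    design: str = "inter_run") -> ReliabilityReport:
    """Per-subject r / ICC(C,1) / ICC(C,k) for a list of matrix pairs.

    Each pair contributes one subject: r is the Fisher-z similarity
    (reported on the r scale), and the ICCs treat the Fisher-z connection
    values as items rated by the two matrices.
    """
    def _tril(C):
        if isinstance(C, ConnectivityMatrix):
            return C.lower_triangle()
        M = np.asarray(C)
        i, j = np.tril_indices(M.shape[0], k=-1)
        return M[i, j]

    rs, icc1s, iccks = [], [], []
    for Ca, Cb in pairs:
        rs.append(similarity(Ca, Cb).r)
        data = np.column_stack([fisher_z(_tril(Ca)), fisher_z(_tril(Cb))])
        icc1s.append(icc_consistency(data, "single"))
        iccks.append(icc_consistency(data, "average"))
    return ReliabilityReport(design, np.array(rs), np.array(icc1s), np.array(iccks))


def split_timeseries(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split retained samples at the midpoint; with an odd count the first
    half gets the extra sample."""
    T = ts.shape[0]
    cut = (T + 1) // 2
    return ts[:cut], ts[cut:]


def split_half_analysis(subject_runs: dict[object, dict[str, np.ndarray]],
                        shrinkage: float = 0.0,
                        min_samples: int = 0,
                        ) -> tuple[dict[str, ReliabilityReport], dict]:
    """Intra-run and half-length inter-run reproducibility.

    ``subject_runs`` maps subject -> {"run1": (T x R) ROI series,
    "run2": ...}.  Each run is split at the midpoint of its retained
    samples, connectivity is computed per half, and the four designs
    intra_run1 / intra_run2 / inter_FH / inter_SH are evaluated with r,
    ICC(C,1) and ICC(C,k).  Subjects with any half shorter than
    ``min_samples`` are flagged and excluded from the group statistics.
    The returned info dict carries the intra vs half-length-inter
    two-sample t-test (unpaired, two-sided, equal variance) on the
    Fisher-z similarity values.
    """
    halves: dict[object, dict[tuple[str, str], ConnectivityMatrix]] = {}
    excluded = []
    for subj, runs in subject_runs.items():
        entry = {}
        ok = True
        for run in ("run1", "run2"):
            fh, sh = split_timeseries(np.asarray(runs[run]))
            if len(fh) < min_samples or len(sh) < min_samples:
                ok = False
                break
            entry[(run, "FH")] = partial_correlation(fh, shrinkage=shrinkage)
            entry[(run, "SH")] = partial_correlation(sh, shrinkage=shrinkage)
        if ok:
            halves[subj] = entry
        else:
            excluded.append(subj)
    if not halves:
        raise ValueError("no subject has two splittable runs")
    reports = {}
    for name, (a, b) in SPLIT_DESIGNS.items():
        pairs = [(halves[s][a], halves[s][b]) for s in halves]
        reports[name] = reproducibility(pairs, design=name)
    intra_z = fisher_z(np.concatenate([reports["intra_run1"].r,
                                       reports["intra_run2"].r]))
    inter_z = fisher_z(np.concatenate([reports["inter_FH"].r,
                                       reports["inter_SH"].r]))
    t, p = stats.ttest_ind(intra_z, inter_z, equal_var=True)
    info = {
        "excluded_subjects": excluded,
        "intra_mean_r": float(np.tanh(intra_z.mean())),
        "inter_mean_r": float(np.tanh(inter_z.mean())),
        "t": float(t),
        "p": float(p),
    }
    return reports, info


def reports_to_frame(reports: dict[str, ReliabilityReport]) -> pd.DataFrame:
    """Tidy per-subject table (design, subject index, r, ICCs)."""
    rows = []
    for name, rep in reports.items():
        for i in range(len(rep.r)):
            rows.append({"design": name, "subject": i, "r": rep.r[i],
                         "z": fisher_z(rep.r[i]),
                         "icc_c1": rep.icc1[i], "icc_ck": rep.icck[i]})
    return pd.DataFrame(rows)
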