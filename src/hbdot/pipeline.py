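"""End-to-end study driver: simulate -> preprocess -> reconstruct (three
algorithms) -> ROI connectivity -> comparison statistics.

The driver never materializes full voxel-by-time images for long runs:
each solver yields a linear voxel-space operator (voxels x channels),
which is composed with the smoothing and ROI-averaging operators into a
small (ROI x channels) projection applied to the channel data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .compare import (anova_tukey, fisher_z, reproducibility, similarity,
                      split_timeseries)
from .preprocess import PreprocessConfig, preprocess_run
from .reconstruct import (ReconConfig, build_smoother, hb_first_step,
                          hb_reconstruct, mn_reconstruct)
from .rsfc import (available_rois, partial_correlation, sensitive_mask)
from .simulate import TruthSpec, build_study_assets, simulate_study

log = logging.getLogger(__name__)

SPECIES = ("oxy", "deoxy")


@dataclass
class PipelineConfig:
    """Configuration of one synthetic-study pipeline execution."""

    spec: TruthSpec = field(default_factory=TruthSpec)
    algorithms: tuple[str, ...] = ("HB", "MN", "MN_WU")
    gamma0_scales: tuple[float, ...] = (0.1,)   # first entry = HB default
    n_arrays: int = 4
    smooth_fwhm: float = 8.0
    sensitivity_threshold: float = 0.5
    min_roi_voxels: int = 10
    max_iter: int = 150
    tol: float = 1e-3
    seed: int | None = None          # overrides spec.seed when set

    def __post_init__(self) -> None:
        for a in self.algorithms:
            if a not in ("HB", "MN", "MN_WU"):
                raise ValueError(f"unknown algorithm {a!r} in config")
        if self.seed is not None:
            self.spec.seed = int(self.seed)


def smoke_config(seed: int = 0) -> PipelineConfig:
    """Reduced-scale profile (2 subjects, 60 s runs) for end-to-end checks."""
    spec = TruthSpec(n_subjects=2, duration=60.0, n_rois=8, seed=seed)
    return PipelineConfig(spec=spec, n_arrays=2, max_iter=50)


@dataclass
class StudyResult:
    """Everything the comparison battery produces for one study."""

    config: PipelineConfig
    truth_pc: np.ndarray
    roi_ids: np.ndarray
    similarity_df: pd.DataFrame       # per (algorithm, species, subject, run, scale)
    reproducibility_df: pd.DataFrame  # inter-run, per subject
    split_df: pd.DataFrame            # split-half designs, per subject
    split_ttest: dict                 # intra vs half-length inter, per alg/species
    anova: dict                       # group tests
    gamma0_sweep: pd.DataFrame
    preprocess_info: list[dict]
    timings: dict

    def connectivity(self, algorithm: str, species: str, subject: int,
                     run: int, gamma0_scale: float | None = None):
        if algorithm == "HB" and gamma0_scale is None:
            gamma0_scale = self.config.gamma0_scales[0]
        return self._conn[(algorithm, species, subject, run, gamma0_scale)]


def _roi_operator(assets, mask, rois, fwhm: float) -> np.ndarray:
    """(R x V) operator: 8-mm smoothing followed by sensitive-voxel ROI
    averaging."""
    K = build_smoother(assets.grid, fwhm)
    V = assets.grid.n_voxels
    rows = np.zeros((len(rois), V))
    for k, roi in enumerate(rois):
        sel = mask.sensitive & (assets.parcellation.labels == roi)
        rows[k, sel] = 1.0 / sel.sum()
    return rows @ K


def run_study(config: PipelineConfig) -> StudyResult:
    """Execute the full synthetic-study pipeline and comparison battery."""
    t0 = time.time()
    spec = config.spec
    assets = build_study_assets(spec, n_arrays=config.n_arrays,
                                sensitivity_threshold=config.sensitivity_threshold)
    study = simulate_study(spec, assets)
    E = assets.E
    S = assets.S
    W = len(E.wavelengths)
    unmix = np.linalg.pinv(E.E)        # (2, W): species x wavelength

    ns = S.normalized_sensitivity("cortex")
    mask = sensitive_mask(ns[None, :], config.sensitivity_threshold)
    rois = available_rois(assets.parcellation, mask, config.min_roi_voxels)
    R_op = _roi_operator(assets, mask, rois, config.smooth_fwhm)
    truth_pc_sub = study.truth_pc[np.ix_(rois - 1, rois - 1)]
    t_setup = time.time() - t0

    pp_cfg = PreprocessConfig(saturation_ceiling=spec.adc_ceiling)
    variants = [("HB", s) for s in config.gamma0_scales if "HB" in config.algorithms]
    variants += [(a, None) for a in config.algorithms if a != "HB"]

    conn: dict = {}          # (alg, species, subject, run, scale) -> matrix
    halves: dict = {}        # same key -> (C_FH, C_SH)
    pp_infos = []
    t_pp = t_rec = 0.0
    for (subj, run), rd in study.runs.items():
        t1 = time.time()
        hb_branch, mn_branch, info = preprocess_run(rd.channels, pp_cfg)
        pp_infos.append({"subject": subj, "run": run,
                         "n_bad": info["n_bad_channels"],
                         "n_removed": info["n_removed"]})
        good = ~hb_branch.bad_channels
        T = hb_branch.n_samples
        t_pp += time.time() - t1

        t1 = time.time()
        # ROI x time series per variant, assembled per wavelength
        roi_ts = {v: np.zeros((2, len(rois), T)) for v in variants}
        for wi, wl in enumerate(E.wavelengths):
            # full-channel arrays; the solvers mask rows via channel_mask
            Y_hb = np.ascontiguousarray(hb_branch.data[:, :, wi].T)
            Y_mn = np.ascontiguousarray(mn_branch.data[:, :, wi].T)
            need_hb = any(a == "HB" for a, _ in variants)
            if need_hb:
                # shared scalp+cortex first step across gamma0 settings
                fs_cfg = ReconConfig(algorithm="HB", max_iter=config.max_iter,
                                     tol=config.tol)
                first = hb_first_step(Y_hb, S, fs_cfg, channel_mask=good,
                                      wavelength=wl)
            lam_prev = None
            for alg, scale in variants:
                if alg == "HB":
                    cfg = ReconConfig(algorithm="HB", max_iter=config.max_iter,
                                      tol=config.tol, gamma0=scale * T)
                    A, _diag = hb_reconstruct(Y_hb, S, config=cfg,
                                              channel_mask=good, wavelength=wl,
                                              return_operator=True,
                                              first_step=first,
                                              lam_init=lam_prev)
                    lam_prev = _diag["lambda"]
                    Y = Y_hb[good]
                else:
                    cfg = ReconConfig(algorithm=alg)
                    A, _diag = mn_reconstruct(Y_mn, S, cfg, channel_mask=good,
                                              wavelength=wl, return_operator=True)
                    Y = Y_mn[good]
                proj = R_op @ A                    # (R, C)
                ts_w = proj @ Y                    # (R, T)
                for sp in range(2):               # unmix into oxy / deoxy
                    roi_ts[(alg, scale)][sp] += unmix[sp, wi] * ts_w
        for (alg, scale), both in roi_ts.items():
            for sp, name in enumerate(SPECIES):
                ts = both[sp].T                   # (T, R)
                key = (alg, name, subj, run, scale)
                conn[key] = partial_correlation(ts, rois)
                fh, sh = split_timeseries(ts)
                halves[key] = (partial_correlation(fh, rois),
                               partial_correlation(sh, rois))
        t_rec += time.time() - t1

    # ---------- comparison battery ----------
    default_scale = config.gamma0_scales[0] if config.gamma0_scales else None

    sim_rows = []
    for (alg, sp, subj, run, scale), C in conn.items():
        res = similarity(C.matrix, truth_pc_sub)
        sim_rows.append({"algorithm": alg, "species": sp, "subject": subj,
                         "run": run, "gamma0_scale": scale,
                         "r": res.r, "z": res.z})
    sim_df = pd.DataFrame(sim_rows)

    def default_keys(alg, sp):
        scale = default_scale if alg == "HB" else None
        return alg, sp, scale

    rep_rows, split_rows = [], []
    split_ttest = {}
    anova_res = {}
    for sp in SPECIES:
        algs = list(config.algorithms)
        # inter-run reproducibility (full length)
        for alg in algs:
            a, s, scale = default_keys(alg, sp)
            pairs = [(conn[(a, s, subj, 0, scale)], conn[(a, s, subj, 1, scale)])
                     for subj in range(spec.n_subjects)] if spec.n_runs >= 2 else []
            if pairs:
                rep = reproducibility(pairs, design="inter_run")
                for i in range(len(rep.r)):
                    rep_rows.append({"algorithm": alg, "species": sp,
                                     "subject": i, "r": rep.r[i],
                                     "z": fisher_z(rep.r[i]),
                                     "icc_c1": rep.icc1[i],
                                     "icc_ck": rep.icck[i]})
        # split-half designs
        for alg in algs:
            a, s, scale = default_keys(alg, sp)
            designs = {
                "intra_run1": [(halves[(a, s, subj, 0, scale)][0],
                                halves[(a, s, subj, 0, scale)][1])
                               for subj in range(spec.n_subjects)],
                "intra_run2": [(halves[(a, s, subj, 1, scale)][0],
                                halves[(a, s, subj, 1, scale)][1])
                               for subj in range(spec.n_subjects)],
                "inter_FH": [(halves[(a, s, subj, 0, scale)][0],
                              halves[(a, s, subj, 1, scale)][0])
                             for subj in range(spec.n_subjects)],
                "inter_SH": [(halves[(a, s, subj, 0, scale)][1],
                              halves[(a, s, subj, 1, scale)][1])
                             for subj in range(spec.n_subjects)],
            } if spec.n_runs >= 2 else {}
            intra_r, inter_r = [], []
            for dname, pairs in designs.items():
                rep = reproducibility(pairs, design=dname)
                (intra_r if dname.startswith("intra") else inter_r).append(rep.r)
                for i in range(len(rep.r)):
                    split_rows.append({"algorithm": alg, "species": sp,
                                       "design": dname, "subject": i,
                                       "r": rep.r[i], "icc_c1": rep.icc1[i],
                                       "icc_ck": rep.icck[i]})
            if intra_r and inter_r:
                from scipy import stats as sstats
                zi = fisher_z(np.concatenate(intra_r))
                ze = fisher_z(np.concatenate(inter_r))
                t, p = sstats.ttest_ind(zi, ze, equal_var=True)
                split_ttest[(alg, sp)] = {
                    "intra_mean_r": float(np.tanh(zi.mean())),
                    "inter_mean_r": float(np.tanh(ze.mean())),
                    "t": float(t), "p": float(p)}
        # group ANOVA across algorithms (runs pooled as observations)
        if len(algs) >= 2:
            groups_sim = []
            for alg in algs:
                a, s, scale = default_keys(alg, sp)
                sel = sim_df[(sim_df.algorithm == a) & (sim_df.species == s)
                             & (sim_df.gamma0_scale.isna() if scale is None
                                else sim_df.gamma0_scale == scale)]
                groups_sim.append(sel["z"].to_numpy())
            anova_res[("similarity", sp)] = anova_tukey(groups_sim, algs)
            rep_df_tmp = pd.DataFrame(rep_rows)
            groups_rep = [
                rep_df_tmp[(rep_df_tmp.algorithm == alg)
                           & (rep_df_tmp.species == sp)]["z"].to_numpy()
                for alg in algs]
            if all(len(g) >= 2 for g in groups_rep):
                anova_res[("reproducibility", sp)] = anova_tukey(groups_rep, algs)

    # gamma0 sweep summary (HB similarity-to-truth per scale)
    sweep_rows = []
    if "HB" in config.algorithms:
        for sp in SPECIES:
            for scale in config.gamma0_scales:
                sel = sim_df[(sim_df.algorithm == "HB") & (sim_df.species == sp)
                             & (sim_df.gamma0_scale == scale)]
                sweep_rows.append({"species": sp, "gamma0_scale": scale,
                                   "mean_z": float(sel["z"].mean()),
                                   "mean_r": float(np.tanh(sel["z"]).mean())})
    result = StudyResult(
        config=config, truth_pc=truth_pc_sub, roi_ids=rois,
        similarity_df=sim_df,
        reproducibility_df=pd.DataFrame(rep_rows),
        split_df=pd.DataFrame(split_rows),
        split_ttest=split_ttest, anova=anova_res,
        gamma0_sweep=pd.DataFrame(sweep_rows),
        preprocess_info=pp_infos,
        timings={"setup": t_setup, "preprocess": t_pp, "reconstruct": t_rec,
                 "total": time.time() - t0},
    )
    result._conn = conn
    log.info("study complete: %s", result.timings)
    return result
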