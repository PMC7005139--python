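# hbdot

Hierarchical-Bayesian diffuse optical tomography (DOT) and resting-state
functional connectivity for high-density fNIRS.

## The problem

High-density fNIRS montages measure near-infrared light attenuation
between source–detector pairs at several separations: short (13 mm)
channels sample mostly the scalp, long (29 mm) channels reach the
cortex.  Estimating resting-state functional connectivity (RSFC) from
such recordings requires reconstructing volumetric hemodynamics from
the channel data — an ill-posed inverse problem — while keeping
systemic scalp physiology (which is spatially *inhomogeneous*, so a
global short-channel regression cannot fully remove it) out of the
cortical estimates.

`hbdot` implements and compares three reconstruction algorithms inside
one tested pipeline:

- **MN** — depth-compensated minimum-norm estimate with spatially
  variant weighting `L_vv = sqrt(rho2_v + beta)`, `beta` set from the
  voxels around 20 mm depth, regularization chosen by maximizing the
  marginal likelihood;
- **MN-WU** — the same family with `beta = 0.1`;
- **HB** — a two-step hierarchical-Bayesian solver: a depth-compensated
  first step provides per-voxel prior variance means `lambda0`, then a
  variational automatic-relevance-determination iteration with
  confidence parameter `gamma0` (default `0.1 L`, `L` = sample count)
  refines per-voxel variances, modelling a sparse cortex and a smooth
  scalp compartment *simultaneously*:

      E-step:  X = Λ Fᵀ (F Λ Fᵀ + σ²I)⁻¹ Y
      M-step:  λ_v ← (Σ_t ⟨x²_vt⟩ + 2 γ₀ λ0_v) / (T + 2 γ₀)

Connectivity is the ROI-level partial correlation
`pc_ij = -P_ij / sqrt(P_ii P_jj)` (P the inverse covariance of ROI-mean
series over *sensitive* voxels), and algorithms are compared by
Fisher-z similarity of connectivity matrices, inter-run and split-half
reproducibility (Pearson r, ICC(C,1), ICC(C,k)), one-way ANOVA with
Tukey–Kramer comparisons, and a gamma0 sensitivity sweep.

Because no public recordings accompany this problem, the package ships
a first-class synthetic-data generator: multi-subject two-run studies
with a known ROI partial-correlation structure, band-limited
(0.009–0.08 Hz) cortical dynamics, inhomogeneous scalp interference,
instrument noise, and the artifacts the preprocessing exists for
(high-CV channels, saturation, motion spikes).  See
`docs/methods.md` for the model details and design decisions.

## Worked example

```python
from hbdot.pipeline import run_study, smoke_config

result = run_study(smoke_config(seed=11))   # 2 subjects, 60-s runs, ~30 s
sim = result.similarity_df
print(sim.groupby(["species", "algorithm"])["r"].mean().unstack().round(3))
```

prints the mean similarity between each algorithm's estimated
connectivity and the generating truth:

```
algorithm     HB     MN  MN_WU
species
deoxy     -0.165  0.017  0.006
oxy       -0.010  0.127  0.132
```

At this smoke scale (60-second runs, ~1100 retained samples for 19 ROI
pairs of parameters) the estimates are noise — which is the point of
the smoke profile: it exercises every stage cheaply, not the science.
At the study scale the battery is designed for (5+ subjects, two
10-minute runs, 19 ROIs — `TruthSpec(n_subjects=5, duration=600.0,
n_rois=19)`), the similarity ordering stabilizes: the hierarchical
solver tracks the generating connectivity more closely than either
minimum-norm variant for both oxy- and deoxy-hemoglobin, and its
similarity is insensitive to `gamma0` over `{0.1, 0.01, 0.001} L`,
degrading only at `0.0001 L`.  (Inter-run reproducibility on this
synthetic world instead favors the smoother minimum-norm variants,
whose stable mixing bias inflates run-to-run agreement; see
`docs/methods.md`, *Known limitations*.)

A command-line interface mirrors the library stages:

```bash
hbdot simulate --seed 1 --out data/            # channel CSVs + manifest
hbdot run-all --smoke --seed 1 --out report/   # full pipeline, reduced scale
hbdot compare --reference a.csv --estimate b.csv
```

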