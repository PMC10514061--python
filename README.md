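# latentflow

Latent-space functional connectivity dynamics for BOLD-like time series.

After a stroke, resting-state functional connectivity (FC) shows a
characteristic signature: reduced interhemispheric (homotopic) coupling,
reduced network modularity, and — less widely appreciated — an increase
in the temporal *irreversibility* of the signal, i.e. how statistically
distinguishable the recordings are from their time-reversed versions.
`latentflow` implements an analysis pipeline for detecting and
exploiting these signatures, built around a nonlinear low-dimensional
embedding of the regional time series:

* **Autoencoder embedding** — concatenated, z-scored BOLD frames
  (one column per TR across all subjects) are compressed through a
  dense ReLU autoencoder into a d-dimensional bottleneck; the
  reconstruction-correlation curve over d selects the working dimension,
  and PCA provides the linear baseline.
* **Edge dynamics** — the edge time series e_ij(t) = z_i(t)·z_j(t)
  unwraps each Pearson correlation into frame-wise co-fluctuations
  (mean_t e_ij(t) = r_ij exactly); the root-sum-square (RSS) across
  edges yields an event trace whose peaks are validated against a
  circular-shift null (P < 0.001, 1000 iterations, |z| > 4.5 exclusion).
* **Dynamical features** — functional connectivity dynamics (FCD),
  edge metastability (SD of the RSS trace), signed modularity under the
  constant Potts null `Q(γ) = Σ_{i≠j} (w_ij − γ) δ(c_i,c_j) / Σ|w_ij|`
  optimized by Louvain bipartition sweeps, and functional complexity
  `C = 1 − (1/c_m) Σ_μ |p_μ − 1/m|` with `c_m = 2(m−1)/m`.
* **Irreversibility (arrow of time)** — pairwise
  `I_xy = |C_forward(Δt) − C_reversal(Δt)|` at Δt = 1 frame, where
  `C_forward = corr(x(t), y(t+Δt))` and `C_reversal` is the same
  quantity on the time-reversed signals; the upper-triangle mean indexes
  distance from equilibrium.
* **Classification & recovery** — random forests (1000 trees, repeated
  stratified 80/20 subject splits, ROC AUC) on FC or irreversibility
  upper triangles in source or latent space; recovery labels from
  median splits of behavioral domain recovery, FC distance to controls
  (Frobenius), and SC–FC coupling.

Because the clinical cohort this methodology targets is not publicly
downloadable, the package ships a first-class synthetic cohort
generator: stationary VAR(1) signals whose coupling carries planted
modular structure, severity-scaled homotopic damage, severity-scaled
temporal asymmetry, and longitudinal recovery with matched clinical
covariates (lesion volume, NIHSS, nine behavioral domains). Every
downstream claim is tested against these planted ground truths.

## Worked example

```python
import numpy as np
from latentflow import (generate_cohort, concatenate_for_training,
                        train_autoencoder, build_features, rf_classify,
                        zscore_rows, irreversibility_matrix,
                        mean_irreversibility)

cohort = generate_cohort(seed=1)                  # 30 controls + 60 patients
frames, _ = concatenate_for_training(cohort, "2wk")
model = train_autoencoder(frames, d=6, seed=1)
print(model.summary())

labels = np.array([r.group == "patient" for r in cohort.records], int)
feats = build_features(cohort, "latent", "irreversibility",
                       "upper_triangle", model)
feats.labels = labels
print(rf_classify(feats, seed=1).summary())
```

Output:

```
Autoencoder
  layer widths : 50 -> 128 -> 64 -> 6 -> 64 -> 128 -> 50
  bottleneck d : 6
  trained      : True
  epochs run   : 92
  best epoch   : 81
  best val MSE : 0.746602
latent/irreversibility vs labels: AUC = 0.931 +- 0.044 (10 x 20% held-out splits, 1000 trees)
```

The bottleneck compresses the 50 regional signals into 6 latent series;
the random forest separates patients from controls from the 15 pairwise
irreversibility values of those latent series alone, because patient
couplings are asymmetric in proportion to severity. A single subject's
irreversibility index is just:

```python
rec = cohort.patients()[0]
series = zscore_rows(cohort.get_series(rec.subject_id, "2wk"))
print(mean_irreversibility(irreversibility_matrix(series)))
```

On this cohort the controls average 0.049 (SD 0.006) while patients
average 0.291 (SD 0.188) — mild patients overlap the control range and
severe ones depart far from equilibrium.

The same experiments are scriptable from the shell:

```bash
latentflow simulate --outdir cohort_dir --seed 1
latentflow embed --dim-range 2:8 --seed 1
latentflow classify --seed 1 --outdir results/
latentflow recover --seed 1 --outdir results/
```

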