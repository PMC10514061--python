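# Methods

## Synthetic cohort model

Each subject's regional signal is a stationary first-order vector
autoregression,

    x(t+1) = W x(t) + ε,   ε ~ N(0, σ² I),

sampled at TR = 2 s. A discrete VAR was preferred to a continuous-time
Ornstein–Uhlenbeck process because BOLD-like data are TR-sampled and the
lag-1 statistics that the irreversibility index measures are directly
controlled by the coupling matrix: the stationary covariance S solves
the Lyapunov equation S = W S Wᵀ + σ² I (used as an analytic oracle in
the tests), and the asymmetry of the lag-1 cross-covariance W S is what
drives I above zero.

**Healthy coupling.** ROIs 0..n/2−1 form the left hemisphere, the rest
the right; ROI i and i + n/2 are homotopic mirrors and share a module,
so modules are bilateral networks. Off-diagonal weights are `within_w`
inside a module and `between_w` across modules; homotopic pairs are set
to `homotopic_w`; an antisymmetric N(0, asymmetry²) perturbation is
added; the matrix is rescaled to spectral radius `target_radius`.
Defaults: 50 ROIs, 2 modules, within 0.30, between −0.05, homotopic
0.30, asymmetry 0.02, radius 0.98, noise SD 1, 400 frames after a
100-frame burn-in. The slightly negative between-module coupling
emulates anticorrelated resting-state networks and gives the FC the
signed structure the constant-Potts modularity is designed for; with
weaker or positive between-module coupling the simulated within-network
correlations (~0.09) fall far below empirical resting-state levels and
no two-community resolution regime exists.

**Inter-subject variability.** Every subject (control or patient)
receives a private coupling: iid Gaussian jitter on all off-diagonal
entries with SD equal to `subject_jitter` (default 1.0) times the
off-diagonal RMS weight, re-capped at the group spectral radius. The
jitter's symmetric part spreads the FC across subjects; its
antisymmetric part gives healthy subjects a nonzero, variable baseline
irreversibility. Without this heterogeneity all controls are
statistical clones of one coupling matrix and any systematic patient
shift — however small — is trivially detectable, which saturates every
classifier at AUC ≈ 1 and empties the source-vs-latent comparison of
content. The damage coefficients below were then chosen once to put
each planted axis in a detectable but non-saturating regime
(per-cohort group contrasts around t ≈ 9, classifier AUCs in the
0.85–0.97 band rather than at ceiling), the regime in which the
methodology this package implements is actually interesting.

**Lesion model.** A patient with latent severity s ∈ [0, 1] has
homotopic weights scaled by (1 − k_homotopic·s) (default k = 0.2), an
extra antisymmetric perturbation of scale k_asym·s (default 0.15), and
round(s·n·`lesion_damp_frac`) randomly chosen ROIs (default 3%) whose
rows/columns are damped by 0.1 (shape-preserving lesion). The
*lesion-volume covariate* is kept on a coarser clinical scale,
round(s·n·0.15): reported lesion extent counts more tissue than the
handful of network nodes whose signals are effectively silenced, and
the median-split severity label needs a covariate with adequate range.
The three planted abnormality axes — reduced homotopic integration,
reduced modularity, increased temporal asymmetry — are all monotone in
one severity variable, which also generates NIHSS = round(20 s +
N(0,1)) clipped at 0, and nine behavioral domain scores
−β_d·s(τ) + N(0, 0.5) with β_d ~ U(1, 3) drawn once per cohort.

**Longitudinal recovery.** Severity decays exponentially,
s(τ) = s·exp(−ρτ) with ρ ~ Gamma(2, 0.5) per patient and τ ∈ {2 weeks,
3 months, 1 year}; each timepoint gets its own series from the
correspondingly lesioned coupling.

**What the generator does not emulate**: hemodynamic convolution and
scanner noise spectra, spatial lesion geometry, head-motion artifacts,
inter-subject anatomical variability. Passing tests therefore show that
the pipeline recovers the planted statistical structure — group
contrasts, recovery directions, classifier orderings — not that it
reproduces any empirical effect size.

## Embedding

The autoencoder is a dense stack n → 128 → 64 → d → 64 → 128 → n with
ReLU hidden units and linear output, trained by Adam (lr 1e-3) on
mini-batches of 256 frames for at most 100 epochs, minimizing MSE, with
a seeded 80/20 frame-wise train/validation split, early stopping after
10 stale epochs and restoration of the best validation weights. The
code layer itself is linear: a rectified code can saturate at zero and
produce constant latent rows, which the downstream correlation-based
features cannot tolerate. Hidden layers narrower than d are dropped, so
d = n degenerates gracefully to a near-identity map (used as a control).
The source–latent correlation is defined as the Pearson correlation
between validation frames and their reconstructions, flattened — the
natural reading of a reconstruction-quality criterion; the working
dimension is the smallest d whose correlation clears a configurable
threshold (default 0.9). All group statistics downstream use the
embedding fit once on the whole cohort; classification splits are made
at the subject level afterwards, so no subject's frames cross a
classification split, though embedding-level leakage is accepted as in
the two-stage protocol this mirrors.

## Event detection

Edge series are computed on population-SD z-scores (divide by n), which
makes mean_t e_ij(t) equal r_ij to machine precision. The null rotates
every ROI row by an independent uniform circular shift, preserving
autocorrelation while destroying cross-correlation; the event threshold
is the (1 − p) quantile of the null RSS values pooled over iterations
and frames (shifts make frames exchangeable, so per-frame thresholds
would only add noise). Flagged frames whose RSS z-score — relative to
the empirical trace's own mean and SD, since the exclusion is meant to
catch artifactual spikes in the observed trace — exceed ±4.5 are
excluded. Peak agreement between spaces counts exact frame coincidence
(hits / (hits + misses), 1 for two empty sets); a ±1-frame tolerance
was considered and rejected as a second free parameter. A top-10%
amplitude selection mode is available as an alternative to the null
rule.

## Dynamical features

FCD uses sliding windows of 30 frames, step 3 (standard practice at
TR = 2 s; robust at 400-frame desk scale), correlating upper triangles
of windowed FC matrices. Edge metastability is the population SD of the
RSS trace (global synchrony fluctuation); the mean per-edge SD is
available as a variant. Functional complexity uses m = 20 histogram
bins on the fixed range [−1, 1]. Modularity retains the full signed FC
and maximizes the constant-Potts quality normalized by total absolute
weight (for cross-subject comparability); Louvain (greedy local moves +
aggregation, 20 restarts for oracle work, 5 at cohort scale) is swept
over γ ∈ [0, 0.3] in steps of 0.025, the interval yielding exactly two
communities is refined with 10 finer samples, and the best-Q
bipartition is kept. When damage makes the community count jump from 1
straight to 4 (hemispheric fragmentation) the sweep bisects toward the
jump and finally optimizes a constrained two-community partition at the
jump resolution — every subject then contributes a bipartition quality
computed by the same formula.

## Irreversibility

I_xy = |C_forward − C_reversal| at Δt = 1 frame, with both series
reversed in C_reversal. Reversing both series maps the lagged pair set
onto itself with roles swapped, so C_reversal = C_forwardᵀ; the matrix
implementation uses this identity and is verified against the literal
per-pair loop to 1e-10. The diagonal is exactly zero (lag-1
autocorrelation is reversal-invariant) and the matrix exactly
symmetric. Latent-space irreversibility runs the identical code on the
d × d latent series.

## Outcomes and recovery labels

FC distance is the Frobenius norm to the mean control FC. SC–FC
coupling correlates FC and the structural template over structurally
connected pairs only (correlating against structural zeros mostly
measures sparsity). Behavioral recovery per domain is
(1yr − 2wk)/2wk (NaN-flagged at zero baselines; note the sign flips for
negative z-scored deficits). A domain counts as *recovered* when its
deficit both shrank and returned to the normal range
(|score| ≤ 0.75 = 1.5 control SDs): a mere improvement rule
(severe → moderate counts) makes the behavior label independent of
residual severity and hence of the other two criteria; the
any-improvement variant remains available via
`resolved_threshold=inf`. Median splits assign exact-median ties to the
smaller side in stable input order, so label counts differ by at most
one. The per-subject recovery aggregate `mean_deficit_change` (mean
change of deficit magnitude) is preferred over averaging the per-domain
relative changes, which blow up on near-zero baselines.

## Classification

Random forests with 1000 trees, scikit-learn defaults otherwise
(unlimited depth, √p features per split), over 10 stratified random
80/20 subject-level splits; AUC from held-out predicted probabilities,
reported mean ± SD. Behavior–metric correlations use scalar summaries
(mean upper-triangle FC or irreversibility per space), since a
per-feature correlation against a scalar domain score is not a single
association. t-SNE projections (perplexity min(30, (n−1)/3), PCA
initialization) are seeded and deterministic.

## Numerical choices and degenerate inputs

Zero-variance rows are detected with a relative tolerance
(sd ≤ 1e-12·(|mean| + 1)) and reported by ROI index. FC from a frame
subset requires ≥ 2 frames and errors on degenerate selections.
Louvain ties are broken by first-found under the seeded restart order.
All randomness flows from explicit integer seeds; cohort generation
documents its draw order, so identical seed and parameters give
bit-identical cohorts.

## Problem sizes

Desk-scale defaults (50 ROIs, 400 frames, 30 + 60 subjects) keep a full
pipeline run in minutes; the full-scale design (235 ROIs, 896 frames,
27 + 96 subjects) is a configuration preset
(`PipelineConfig.full_scale()`), not a code change. Group-contrast
benchmarks pool subjects across 5–10 independently seeded cohorts.

## Known limitations

Effect sizes are calibrated only to be detectable, not to match any
empirical cohort; the VAR(1) generator cannot produce the 1/f spectral
content or non-Gaussianity of real BOLD; the cohort signals are
essentially full-rank (independent innovations per ROI), so the
autoencoder's reconstruction correlation (~0.5 at d = 6 from 50 ROIs)
is far below what genuinely low-dimensional empirical data allow and
dimension-selection thresholds are data-dependent; and the constrained
bipartition fallback means severely damaged subjects' modularity is a
constrained optimum rather than an unconstrained Louvain solution.
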