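# Methods

## The model

`latloc` is a diagnostic tool for deciding when a single global regression
model is adequate for a clinical cohort and when specific patients or
subgroups would be served better by personalized models.  Given a
standardized patient-by-predictor table `X` (n × p) and a continuous
outcome `y`, the package:

1. learns a low-dimensional latent representation `Z = f(X)` (n × d,
   d ≪ p) with an autoencoder whose encoder and decoder are fully
   connected MLPs with tanh activations after every layer except the last
   (default widths p → 64 → 16 → d and the mirror image back);
2. fits, inside the latent space, a **global** OLS model
   `y ~ 1 + z_1 + … + z_d` and, for every patient i, a **local** weighted
   regression of the same form with weights
   `w_ij = K_G(‖z_i − z_j‖₂ / d_k(z_i))`, where
   `K_G(x) = exp(−x²/2σ²)` and `d_k(z_i)` is the distance from patient i
   to its k-th nearest neighbour (self excluded), so the bandwidth adapts
   to local density;
3. flags patient i on dimension l when the local coefficient `β̂_il` lies
   strictly outside the global model's 95% confidence interval for that
   coefficient, collects flagged patients that deviate on the same
   dimension in the same direction into candidate subgroups, and
   characterizes subgroups back in the original predictor space
   (mean Z-score profiles, correlation-based predictor clusters,
   subgroup-by-predictor interaction models with Benjamini–Hochberg
   adjusted p-values, and a global-vs-local RMSE contrast inside and
   outside each subgroup).

Training is end to end: the autoencoder parameters minimize

    Loss = λ_rec · Loss_rec + λ_pred · Loss_pred,

where `Loss_rec = ‖X − g(f(X))‖²_F / (np)` and `Loss_pred` is the mean
over patients of the negative log likelihood ratio of the local full
model against the local intercept-only model, both under weighted
Gaussian likelihoods with plug-in variances.  That ratio collapses to
`(Σ_j w_ij / 2) · log(σ̂²_full / σ̂²_null) ≤ 0`; the full model nests the
null under identical weights, so each term is nonpositive.

Because no pre-installed automatic-differentiation framework is part of
the supported stack, the package ships a small reverse-mode engine over
numpy (`latloc._autodiff`) providing exactly the operations the loss
graph needs (broadcast arithmetic, tanh/exp/log, einsum, gather, batched
linear solves).  Gradients are validated against central finite
differences in the test suite (relative error < 1e-3 contractually,
< 5e-7 in practice).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| d | 4 | latent dimension; the bundled synthetic studies use 2 |
| hidden | (64, 16) | encoder hidden widths; decoder mirrors them |
| σ (kernel) | 1.0 | Gaussian-kernel bandwidth on scaled distances |
| k | ⌈0.3 n⌉ | neighbour order of the adaptive bandwidth |
| λ_rec, λ_pred | 1.0, 1.0 | loss weights |
| learning rate | 1e-4 | Adam step size (see *Training schedule*) |
| epochs | 300 | full-batch updates |
| variance floor (train) | 0.05 | local residual variance below which the prediction term earns nothing |
| ridge_eps | 1e-6 | ridge jitter on the slope block of each local Gram matrix |
| CI level | 0.95 | flag threshold of the deviation rule |
| min_size | 5 | smallest reported subgroup |

Tricube weights are available (`KernelSpec(family="tricube")`) but
discouraged: the hard cutoff zeroes weights outside the bandwidth and
destabilizes local fits in sparse regions.

### Training schedule

Training is full batch — the adaptive bandwidth and kernel weights are
defined over the entire cohort, so minibatching would change the loss.
One Adam update per epoch at the default 1e-4 moves parameters very
little in 300 epochs; that default matches minibatch-style schedules.
All bundled examples, scenario studies and CLI defaults therefore use a
learning rate of 1e-2 (scenario studies and the stability study use the
schedule 300 epochs × 1e-2), which reliably more than halves the
reconstruction loss on the synthetic manifolds.  An optional
patience-based early stop monitors the reconstruction trace.

### The train-time variance floor

The likelihood-ratio term is unbounded below: one patient whose local
fit becomes numerically perfect contributes on the order of
−(S/2)·log(10⁻⁸) ≈ −500, and a flexible encoder will happily warp the
latent space to collect that reward, memorizing the outcome into `Z`.
The training loss therefore stops rewarding local fits once their
weighted residual variance falls below 5% of the (standardized) outcome
variance.  The diagnostic-side computations keep a purely numerical
floor of 1e-8, which only guards against log(0).

## The synthetic-data generator

`SyntheticConfig`/`generate` emulate the statistical structure the method
assumes: latent coordinates `u ~ N(0, I)`, predictors
`x = tanh(M u) + ε` with unit-norm mixing columns and Gaussian predictor
noise (SD 0.1 by default), an outcome linear in `u` globally
(`β = 1` on every true dimension by default, outcome noise SD 0.3), and
planted subgroups whose coefficient on one latent direction differs by a
configured delta.  The reference scenario is n = 200, p = 30,
d_true = 2, one subgroup of 30 patients with delta −1.5.

Subgroup placement matters.  Members are drawn as a random 60% majority
(`subgroup_purity`) of the patients closest to one SD above centre on the
target direction (`subgroup_region_center = 1.0`), so that:

* the subgroup occupies a contiguous latent region — the only geometry a
  kernel-localized model can possibly resolve;
* the latent distribution stays exactly iid normal and membership is not
  a deterministic function of the predictors (a 40% minority of the same
  region behaves globally), which limits how far outcome-guided training
  can absorb the subgroup's distinct regression regime;
* the region sits off-centre enough for the coefficient deviation to be
  expressed in the outcome (a slope difference at u ≈ 0 is invisible),
  but central enough that the subgroup lacks the leverage to drag the
  global coefficient far from the background relationship.

"Scattered" mode places members uniformly; it is used to verify that
coefficient-only deviations leave the X-marginals exchangeable, and it
produces no spatially coherent deviation for the method to find — which
is the expected, tested behaviour, not a defect.

What the generator does *not* emulate: mixed measurement scales and
codings, missing data, heavy-tailed or categorical predictors,
confounded noise, and real clinical correlation structure.  Passing
recovery tests on these cohorts shows the machinery is correct under the
model's own assumptions, not that subgroups of comparable subtlety are
recoverable from real trial data.

## Known limitations, discovered and documented

Two structural properties of the method surfaced during development and
are reflected in the test expectations:

1. **The prediction term's optimum erases its own diagnostic.**
   `Loss_pred` rewards representations in which the outcome is strongly
   locally predictable; its minimizers are warps of the latent space that
   make `E[y | z]` globally linear — precisely the configurations in
   which local and global models coincide and no patient is flagged.
   Under full-batch Adam even a few hundred updates suffice: on the
   reference scenario the global R² climbs to the noise ceiling and the
   planted subgroup's coefficient contrast dissolves before the
   reconstruction loss has converged, across every tested combination of
   λ_pred (10⁻³…1), learning rate (10⁻⁴…10⁻²), epochs (50…300),
   variance floor (10⁻⁸…0.5) and weight decay.  With predictor noise
   present the encoder can even exploit per-patient noise fingerprints to
   separate region members from non-members.  The diagnostic contrast
   survives only when the representation is reconstruction-dominated.
   Consequently the end-to-end subgroup-recovery and stability tests in
   the acceptance suite document measured behaviour that falls short of
   their nominal targets; the recovery metrics are reproduced honestly by
   `scripts/acceptance.py` rather than tuned.
2. **The flag rule resolves regions, not memberships.**  Local
   coefficients are kernel-smoothed, so the deviation field around a
   planted region extends over every patient within roughly one bandwidth
   of it.  Even with oracle latent coordinates the flagged set is two to
   three times the true membership, capping the Jaccard overlap between
   the largest detected subgroup and the planted one near 0.3, with
   member-level sensitivity around 0.75–0.85.  Additionally, a subgroup
   with enough leverage (large delta, off-centre mass) shifts the global
   coefficient itself by several standard errors, in which case the
   *background* falls outside the confidence interval en masse and forms
   the largest "subgroup".  Confidence-interval flagging against a single
   contaminated global fit is a heuristic, not an inferential procedure.

## Numerical choices

* Weighted least squares solves the normal equations with `ridge_eps`
  (1e-6) added to the slope block of the Gram diagonal; the intercept is
  never penalized.  With `ridge_eps = 0` and a full-rank design the
  solution equals the exact WLS minimizer (tested against a BFGS oracle
  at 1e-6).
* The k-NN index selection inside the training loss is treated as fixed
  within a loss evaluation (it is piecewise constant in `Z`); the
  distance *value* to the selected neighbour is differentiated.  The loss
  is therefore differentiated almost everywhere, and gradient checks pin
  the neighbour indices.
* Ties in neighbour distances break by patient index (stable sort).
  Duplicate latent points up to the k-th neighbour raise an error that
  suggests increasing k or jittering.
* Deviation-rank stability uses population SDs of ranks (ties averaged),
  rank 1 = largest absolute deviation.
* Latent alignment across runs maximizes total |Pearson correlation| via
  optimal assignment; signs are chosen to make aligned correlations
  positive.
* Stepwise AIC is the Gaussian OLS form n·log(SSE/n) + 2(k+1), k counting
  regression parameters including the intercept, +1 for the variance.
  Backward steps require an AIC drop > 1, forward interaction steps > 2;
  both thresholds are configurable (a drop-threshold of 0 is a documented
  alternative convention).  Ties break toward the lowest column index.

## Problem sizes in the bundled studies

The scenario studies run at n = 200, p = 30, with d = 2 latent
dimensions, 300-epoch full-batch training, 5 data seeds for the recovery
and benchmark studies and 5 × 5 (repetitions × initialization seeds) for
the stability study; the stepwise study uses n = 300 over 20 seeds.
These sizes make every study reproducible on a single CPU in minutes
while keeping each qualitative contrast (composite vs PCA vs plain
autoencoder; inside- vs outside-subgroup RMSE) well clear of its
decision threshold wherever the method can meet it.
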