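# Methods

## The decomposition model

Each mRNA-capture spot on a spatial transcriptomics slide mixes transcripts
from several cells, so its expression profile is modeled as a weighted sum
of cell-type signatures, `Y ≈ W H`.  `Y` is the m-genes × n-spots
expression matrix (normalized), `W` the m × p signature matrix of mean
normalized reference expression per cell type (collapsed from a paired
single-cell dataset), and `H` the p × n matrix of per-spot cell-type
proportions with columns on the open probability simplex.

Per spot *j* the likelihood is a Student-t regression,

    y_ij | H, ν_j, β0_j, σ_j  ~  t(ν_j, β0_j + (W H^(j))_i, σ_j),

with priors

* `H^(j) ~ Dirichlet(1, …, 1)` — flat on the simplex, enforcing
  `h_kj > 0`, `Σ_k h_kj = 1`;
* `ν_j − 3 ~ Gamma(2, 0.1)` — heavy tails allowed, but degrees of freedom
  kept above 3 so the likelihood variance is finite;
* `β0_j` flat (an intercept absorbing additive offsets);
* `σ_j` non-informative: half-Cauchy(0, 5·sd(y_j)) by default, with a
  `flat` option.

The t-likelihood is the load-bearing robustness choice: single-cell-derived
signatures mis-state the brightest genes' means by large absolute amounts,
and a Gaussian fit lets those few genes dominate.  The t model downweights
them adaptively (this is visible in the simulation benchmark, where the
same data defeat ordinary least squares by a factor ~2 in MAE).

### Image guidance

A paired tissue image (an immunofluorescence channel, or a patch-level
probability map from a tile classifier applied to an H&E stain) supplies a
per-spot prior mean `τ_j ∈ (0,1)` for one target cell type *a* (or for the
summed proportion of a group of types, e.g. total lymphocyte content).  The
guided model multiplies the flat Dirichlet by a Beta factor on `h_aj` with
mean `τ_j` and total-count (concentration) `λ`, implemented as the kernel

    λ · [ τ_j · log h_aj + (1 − τ_j) · log(1 − h_aj) ].

This is the Beta(τλ+1, (1−τ)λ+1) density, i.e. the mean/total-count prior
written so that its weight vanishes exactly as λ → 0 (recovering the base
model) and its mode sits exactly at τ_j, pinning `h_aj → τ_j` as λ → ∞.
For the working range λ ≳ 10 it is numerically indistinguishable from
Beta(τλ, (1−τ)λ); the exponent shift is what makes both limits exact.
`beta_shapes()` still reports the plain (τλ, (1−τ)λ) parameterization.
For a grouped target the factor applies to the group's summed proportion,
leaving the within-group split to the expression data.

### Fitting

No-U-turn-free Hamiltonian Monte Carlo with analytic gradients
(`gist/_hmc.py`): 12 leapfrog steps per iteration with ±20% per-iteration
step-size jitter, dual-averaging adaptation to acceptance 0.8 during
burn-in, and a diagonal mass matrix estimated from the first warmup
window.  Defaults are 2000 iterations with the first 1000 discarded as
burn-in; posterior means over the retained draws are the point estimates,
with `H` columns renormalized (drift ≤ 1e-6).

Unconstrained parameterization per spot: additive-logistic (softmax with
fixed last coordinate) for the simplex with the exact log-Jacobian
`Σ log h_k`; `log(ν − 3)`; `log σ` with a small additive floor
(`σ = 10⁻⁶·scale + e^v`) and a wide Normal(v₀, 5²) containment on `log σ`.
The floor and containment are numerical guards: on exactly-noiseless input
the scale otherwise collapses and the flat-prior posterior is improper.
Five log-units of containment sd is vacuous for any realistic posterior.

Spots share no parameters, so all n per-spot posteriors are sampled
simultaneously with spot-major (n × m) array arithmetic.  Every spot draws
its momenta, acceptance uniforms and jitter from its own seeded stream
(`derive_spot_seeds`), and all per-spot reductions run over contiguous
per-spot rows, so a joint fit and a single-spot fit with the same per-spot
seed are bit-identical.  Divergent transitions (energy error > 1000) are
counted and a warning is issued above 10%.

Cell-type exchangeability holds in distribution, not bit-wise: the fixed
reference coordinate of the softmax and the coordinate-indexed momenta mean
a permuted-type fit is a different (identically distributed) chain; the
test asserts agreement of posterior means at Monte Carlo tolerance.

### Choosing λ

`sweep_lambda` refits the guided model along an increasing λ grid and
tracks Spearman agreement of (i) the targeted type with its prior-side
reference and (ii) a held-out type with an independent reference.  The
selected λ is the first grid point at which the held-out agreement has
dropped from its predecessor and continues to drop at every later point —
the onset of sustained over-reliance on the image.  If no sustained decline
exists the maximum of the grid is returned with a warning flag.  λ = 50 is
the package default for applied runs, carried over from that stopping rule
on an independent dataset; at this value the Beta prior concentrates most
of its mass within roughly ±10% of τ.

## Prior construction from images

* `cap_and_rescale`: intensities are capped at the empirical 99th
  percentile, values below the 1st percentile zeroed, then divided by the
  maximum.  Percentiles are order statistics (not interpolated), which
  makes the operation exactly idempotent.
* `spot_mean_intensity`: a pixel belongs to a spot when its center lies
  within the capture radius (default 70 px; exposed because it will not
  generalize across magnifications) of the spot center; border disks are
  clipped.  The disk average gives one value per spot.
* `patch_map_to_spots`: patch probabilities are combined per spot with
  weights proportional to patch∕disk pixel overlap and normalized by the
  total overlap, so the result stays on the probability scale.
* `quantile_map`: raw spot values are mapped onto the empirical quantiles
  of the target type's proportions from a first-round base-model fit
  (average ranks on ties, linear interpolation between order statistics).
  This puts image values on the scale of plausible proportions while
  keeping their ranks — the key step that makes IF intensities or
  classifier scores usable as Beta means.
* τ values are clamped to [10⁻⁴, 1−10⁻⁴] before use.

## Preprocessing

Spatial counts are sparser than single-cell references, so spots may be
imputed by kNN smoothing (stepwise-doubling aggregation schedule: 1, 2, 4,
… up to k neighbors, re-deriving the neighbor graph each step from a
d-component PCA of Freeman–Tukey-stabilized, depth-scaled counts; defaults
k=5, d=10; pooling spots across slides before smoothing is supported by
concatenation).  Normalization offers `depth` (linear scaling to the
median library — what model fitting consumes, since the mixing model is
linear and `Y` and `W` must share a scale), `log1p` (variance-stabilized,
used for dispersion ranking and distances; note log1p retains a small
Jensen-bias trend with depth), and analytic Pearson residuals.  Gene
restriction takes the intersection of each dataset's 2000 most variable
genes, dispersion ranked by the variance of log1p CP10K values; alignment
between `Y` and `W` is by gene id with unmatched ids dropped and logged.

## The synthetic benchmark

`simulation.SimConfig` emulates a Splatter-style mixture benchmark of six
transcriptionally close cell types (PBMC-like):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | simulated gene panel |
| `n_cell_types` | 6 | mixture components |
| `n_spots` | 100 | mixture samples; truth ~ Dirichlet(1,…,1) |
| `cells_per_spot` | 100 | cells per type averaged into each spot |
| `cells_per_type` | 100 | reference cells per type |
| `baseline_sdlog` | 2.9 | log-normal baseline means, ~5 decades |
| `library_size` | 10⁴ | per-cell depth over the panel |
| `outlier_prob` / `facloc` / `facscale` | 0.05 / 4 / 0.5 | bright outlier genes shared across types |
| `de_prob` | 0.1 | per-gene-per-type DE indicator |
| `lfc_df` / `lfc_scale` / `lfc_truncation` | 3 / 0.35 / 5 | truncated-t log-fold-changes on DE genes |
| `nb_dispersion` | 0.5 | NB dispersion φ (variance w + w²/φ) |

Counts are NB(w, φ); the average over c i.i.d. cells is drawn directly as
NB(c·w, c·φ)/c (an exact identity for i.i.d. NB sums).  Mixture cells are
drawn independently of the reference; per-type mean vectors are rescaled to
a common library so proportions are comparable across types.  The
fold-change scale, dispersion and baseline spread are the three knobs the
benchmark's published difficulty pins down jointly: close cell types
(lfc scale 0.35 ≈ 1.4× typical fold change, as between closely related
immune subsets), shallow-capture overdispersion (BCV ≈ 1.4) and a heavy
bright-gene tail.  At these defaults the base model's MAE is ≈ 0.095 and
clipped OLS ≈ 0.17 (10-seed means; the tests assert the bands 0.05–0.12 and
0.15–0.27).

`simulate_image_prior` builds a guiding-image channel of tunable fidelity
ρ: a logit-space convex combination of the true proportions and matched
Gaussian noise, so ρ=1 is a strictly monotone transform of truth and ρ=0 is
truth-independent (the misleading prior used for the λ-sweep scenario).

What the generator does **not** emulate: spatial autocorrelation of
proportions (spots are exchangeable), segmentation/registration error
between image and spot coordinates, platform-specific per-gene capture
biases between the spatial and single-cell assays, dropout beyond NB
sparsity, and mean–dispersion trends.  Passing benchmarks here therefore
demonstrate correctness of the inference and the prior machinery under the
model's own assumptions, not performance on any real tissue.

## Scenario scales used in tests and the acceptance script

Chosen as the package's desk-scale study conditions:

* Mixture benchmark: 500 genes, 100 spots, 1000/500 MCMC iterations,
  averaged over 3 replicates in `scripts/acceptance.py`, 10 replicates in
  the test suite.
* λ-sweep scenario: 3 cell types, 250 genes, 80 spots — a two-dominant-type
  system where pinning the target corrupts the held-out type through the
  simplex constraint; holdout curves are averaged over 3 replicates before
  applying the stopping rule.
* Prior-benefit scenario: 6 types, 120 genes, 40 spots, φ=0.25 — a
  weak-expression regime, which is the setting image guidance exists for;
  with a sharp likelihood a λ=50 prior moves the posterior very little.
* Permutation calibration: 200 null replicates at 2000 permutations.

## Evaluation statistics

`Q` is the ratio of median estimated proportions inside vs outside an
annotated region; `Δ = Q_guided − Q_base`.  The permutation test redraws
the annotation uniformly among masks with the same number of positives
(seeded, bit-reproducible), recomputes Δ per draw, and reports the
one-sided exceedance fraction; when no permuted value reaches the observed
Δ the upper tail of a Normal fitted to the null's mean and sd is reported
instead (`used_normal_approx=True`).  A two-sided option exists.  MAE is
the mean of |predicted − true| over all p × n proportions.  Rank agreement
is Spearman's correlation with average ranks.  A small ordinal helper
encodes low/middle/high grades as 1/2/3 for rank-sum comparisons of
pathologist re-annotations.

## Known limitations

* One image-derived prior (single type or one group) per fit; λ is global
  across spots — per-region adaptivity is out of scope.
* The sampler is plain HMC with a diagonal metric; strongly correlated
  posteriors (e.g. near-duplicate signatures) mix more slowly than a
  dense-metric or NUTS sampler would.
* SCTransform parity is not attempted; any consistent variance-stabilizing
  normalization satisfying the module contract may be plugged in.
* `normalize("pearson")` uses a fixed θ=100 analytic residual, not a
  per-gene fitted θ.
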