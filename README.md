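# gist

**Image-guided Bayesian cell-type decomposition for spatial transcriptomics.**

Spot-based spatial transcriptomics measures mixed transcriptomes: each
mRNA-capture spot covers several cells, and a central analysis task is
estimating the proportion of each cell type at each spot.  Expression-only
deconvolution discards a second signal that is almost always collected with
the assay — the paired tissue image.  An immunofluorescence stain or a deep
learning model applied to the H&E slide carries direct information about
where particular cell types sit.  `gist` is for analysts who want to fold
that image signal into the decomposition rather than inspect it by eye.

## Model

With `Y` the m-genes × n-spots normalized expression matrix and `W` an
m × p signature matrix of mean reference expression per cell type
(collapsed from paired single-cell RNA-seq), the model estimates the p × n
proportions matrix `H` (columns on the simplex) per spot j:

    y_ij ~ t(ν_j,  β₀_j + (W H⁽ʲ⁾)_i,  σ_j)
    H⁽ʲ⁾ ~ Dirichlet(1, …, 1),   ν_j − 3 ~ Gamma(2, 0.1),   σ_j non-informative

The Student-t likelihood makes the fit robust to the bright, badly
mis-specified genes that break least-squares deconvolution.  The
*image-guided* variant adds a Beta prior with per-spot mean τ_j
(image-derived) and global concentration λ on the target cell type's
proportion h_aj (or on a group's summed proportion).  λ → 0 recovers the
expression-only base model; λ → ∞ pins h_aj at τ_j; λ = 50 is the default
operating point, selected by sweeping λ and stopping where a held-out cell
type's agreement with independent ground truth begins a sustained decline.

Image-derived prior means are built by capping/rescaling intensities (or
overlap-weighting patch classifier probabilities), averaging over each
spot's capture disk, and quantile-mapping the spot values onto the
distribution of a first-round base-model fit.  Sampling is Hamiltonian
Monte Carlo with analytic gradients, all spots in parallel (spots share no
parameters); posterior means are the point estimates.

See `docs/methods.md` for the full model, numerical choices, and what the
synthetic benchmark does and does not emulate.

## Worked example

Simulate a weak-expression dataset (120 genes, 40 spots, 6 cell types,
heavy overdispersion — the regime image guidance is designed for), fit the
base model, then add a high-fidelity synthetic image prior on one type:

```python
import numpy as np
from gist import (
    SimConfig, McmcConfig, PriorSpec, simulate_reference, simulate_mixtures,
    normalize, build_signature, fit_base_model, fit_gist_model,
    simulate_image_prior, quantile_map, mean_absolute_error, rank_agreement,
)

cfg = SimConfig(n_genes=120, n_spots=40, nb_dispersion=0.25, seed=7)
ref, truth_ref = simulate_reference(cfg)
mixtures, truth = simulate_mixtures(truth_ref.W_true, cfg)
Y = normalize(mixtures, method="depth")
W = build_signature(ref)

mcmc = McmcConfig(iterations=600, burn_in=300, seed=7)
base = fit_base_model(Y, W, mcmc)
print(f"base-model MAE:   {mean_absolute_error(base.H_mean, truth.H_true):.4f}")

image = simulate_image_prior(truth.H_true.row("type0"), fidelity=0.9, seed=7)
tau = np.clip(quantile_map(image.values, base.H_mean.row("type0")), 1e-4, 1 - 1e-4)
guided = fit_gist_model(Y, W, PriorSpec("type0", tau, lam=50.0), mcmc)
print(f"guided-model MAE: {mean_absolute_error(guided.H_mean, truth.H_true):.4f}")
print(f"target-type rank agreement with truth: "
      f"base {rank_agreement(base.H_mean.row('type0'), truth.H_true.row('type0')):.2f}, "
      f"guided {rank_agreement(guided.H_mean.row('type0'), truth.H_true.row('type0')):.2f}")
```

Output:

```
base-model MAE:   0.1360
guided-model MAE: 0.1250
target-type rank agreement with truth: base -0.12, guided 0.70
```

Expression alone fails to resolve the target type at this depth (rank
agreement -0.12); the quantile-mapped image prior at λ = 50 recovers its
spatial pattern (0.70) and pulls the overall error down.  The evaluation
module adds the annotation-based statistics (the `Q` median ratio, the
improvement `Δ`, and its label-shuffling permutation test with a normal
tail approximation) for benchmarking against e.g. pathologist annotations.

A thin CLI mirrors the pipeline stages: `gist simulate`, `gist preprocess`,
`gist make-prior`, `gist fit-base`, `gist fit-gist`, `gist evaluate`
(see `--help` on each).

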