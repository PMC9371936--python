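"""Synthetic-data generators matching the model's assumed data structure.

The generator emulates a Splatter-style design: per-gene baseline means are
log-normal, each cell type multiplies them by exp(lfc) with log-fold-changes
drawn from a truncated Student-t (heavy-tailed, as fitted to real PBMC
data), and single-cell counts are negative binomial around the type means.
Mixture spots are Dirichlet-weighted averages over freshly drawn cells per
type, independent of the reference used to build the signature matrix.  A
guiding-image channel of tunable fidelity rho interpolates in logit space
between the true proportions of one cell type (rho = 1) and pure noise
(rho = 0, a deliberately misleading prior).

Two non-Bayesian baselines for benchmarking are included: per-spot ordinary
least squares projected onto the simplex, and non-negative sum-to-one
constrained least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .datamodel import (
    ExpressionMatrix,
    ProportionsMatrix,
    SignatureMatrix,
    SingleCellReference,
    ValidationError,
    proportions_from_values,
)
from .image_priors import SpotPriorValues

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference",
    "simulate_mixtures",
    "simulate_image_prior",
    "baseline_linear_regression",
    "baseline_constrained_ls",
]


@dataclass
class SimConfig:
    """Synthetic benchmark configuration.

    Defaults describe the standard mixture benchmark: 6 transcriptionally
    close cell types (think PBMC subsets), 100 mixture spots with
    flat-Dirichlet ground truth, 100 cells per type averaged into each spot,
    and a 100-cell-per-type paired reference.  Gene structure follows the
    Splatter recipe: log-normal baseline means spanning ~5 decades
    (sdlog 2.9) rescaled to a 10^4 library, a 5% fraction of bright
    expression-outlier genes shared across types, per-gene-per-type DE
    indicators at probability 0.1, truncated-t log-fold-changes (df 3,
    scale 0.35 natural log, truncated at +/-5) on DE genes, and NB counts
    with dispersion phi = 0.5 (biological CV ~ 1.4, shallow-capture
    regime).
    """

    n_genes: int = 500
    n_cell_types: int = 6
    cells_per_type: int = 100
    n_spots: int = 100
    cells_per_spot: int = 100
    dirichlet_alpha: Union[float, np.ndarray] = 1.0
    nb_dispersion: Union[float, np.ndarray] = 0.5
    lfc_df: float = 3.0
    lfc_scale: float = 0.35
    lfc_truncation: float = 5.0
    de_prob: float = 0.1
    outlier_prob: float = 0.05
    outlier_facloc: float = 4.0
    outlier_facscale: float = 0.5
    library_size: float = 1e4
    baseline_sdlog: float = 2.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types", "cells_per_type", "n_spots", "cells_per_spot"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValidationError("dirichlet_alpha must be positive")
        phi = np.asarray(self.nb_dispersion, dtype=float)
        if np.any(phi <= 0):
            raise ValidationError("nb_dispersion must be positive")
        if self.lfc_df <= 0 or self.lfc_scale < 0 or self.lfc_truncation <= 0:
            raise ValidationError("invalid log-fold-change parameters")
        if not (0.0 <= self.de_prob <= 1.0):
            raise ValidationError("de_prob must lie in [0, 1]")
        if not (0.0 <= self.outlier_prob <= 1.0):
            raise ValidationError("outlier_prob must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i}" for i in range(self.n_genes)]

    @property
    def cell_type_ids(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_cell_types)]

    def alpha_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.dirichlet_alpha, dtype=float), (self.n_cell_types,)
        ).copy()

    def dispersion_matrix(self) -> np.ndarray:
        """phi_{i,k} broadcast to genes x types."""
        phi = np.asarray(self.nb_dispersion, dtype=float)
        if phi.ndim == 0:
            phi = np.full(self.n_genes, float(phi))
        return np.broadcast_to(phi[:, None], (self.n_genes, self.n_cell_types)).copy()


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    W_true: Optional[SignatureMatrix] = None
    H_true: Optional[ProportionsMatrix] = None
    prior_fidelity: Optional[float] = None
    extras: dict = field(default_factory=dict)


def _truncated_t(rng: np.random.Generator, df: float, scale: float, trunc: float, size) -> np.ndarray:
    """Student-t draws rescaled by ``scale``, redrawn until within +/-trunc."""
    if scale == 0:
        return np.zeros(size)
    out = scale * rng.standard_t(df, size=size)
    bad = np.abs(out) > trunc
    while bad.any():
        out[bad] = scale * rng.standard_t(df, size=int(bad.sum()))
        bad = np.abs(out) > trunc
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + mean^2/phi."""
    mean = np.maximum(mean, 1e-12)
    p = phi / (phi + mean)
    return rng.negative_binomial(phi, p).astype(float)


def _type_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Generative per-type mean profiles (genes x types), equal library sizes."""
    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sdlog, size=cfg.n_genes)
    # Splatter-style expression outliers: a small fraction of genes is
    # replaced by a very bright version (median ~e^facloc times the median
    # gene), identically in every cell type — loud but uninformative.
    is_outlier = rng.random(cfg.n_genes) < cfg.outlier_prob
    factors = rng.lognormal(cfg.outlier_facloc, cfg.outlier_facscale, size=cfg.n_genes)
    baseline = np.where(is_outlier, np.median(baseline) * factors, baseline)
    lfc = _truncated_t(
        rng, cfg.lfc_df, cfg.lfc_scale, cfg.lfc_truncation,
        size=(cfg.n_genes, cfg.n_cell_types),
    )
    # Splatter-style: each gene is differentially expressed in a given type
    # only with probability de_prob; the rest keep the shared baseline.
    de_mask = rng.random((cfg.n_genes, cfg.n_cell_types)) < cfg.de_prob
    means = baseline[:, None] * np.exp(lfc * de_mask)
    return means * (cfg.library_size / means.sum(axis=0, keepdims=True))


def simulate_reference(cfg: SimConfig) -> tuple[SingleCellReference, SimTruth]:
    """Simulate an NB single-cell reference with ``cells_per_type`` cells per type.

    Returns the reference and a partial :class:`SimTruth` whose ``W_true``
    holds the generative mean profiles (the signatures any estimator is
    trying to recover).
    """
    rng = np.random.default_rng(cfg.seed)
    means = _type_means(cfg, rng)
    phi = cfg.dispersion_matrix()
    blocks, labels = [], []
    for k, ct in enumerate(cfg.cell_type_ids):
        mk = np.broadcast_to(means[:, k][:, None], (cfg.n_genes, cfg.cells_per_type))
        pk = np.broadcast_to(phi[:, k][:, None], mk.shape)
        blocks.append(_nb_draw(rng, mk, pk))
        labels += [ct] * cfg.cells_per_type
    ref = SingleCellReference(
        np.concatenate(blocks, axis=1),
        labels,
        cfg.gene_ids,
        cell_types=cfg.cell_type_ids,
    )
    truth = SimTruth(
        W_true=SignatureMatrix(means, cfg.gene_ids, cfg.cell_type_ids)
    )
    return ref, truth


def simulate_mixtures(
    means: Union[SignatureMatrix, np.ndarray],
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate mixture spots from generative type means.

    For each spot a ground-truth column is drawn from a flat Dirichlet;
    ``cells_per_spot`` cells per type are then drawn (independently of the
    reference dataset) and the spot profile is the proportion-weighted
    average of the per-type cell means.  The per-type average over c iid
    NB(w, phi) cells is drawn directly as NB(c*w, c*phi)/c, an exact
    identity for sums of iid negative binomials.
    """
    if isinstance(means, SignatureMatrix):
        mean_values = means.values
    else:
        mean_values = np.asarray(means, dtype=float)
    if mean_values.shape != (cfg.n_genes, cfg.n_cell_types):
        raise ValidationError("means shape does not match the configuration")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    phi = cfg.dispersion_matrix()
    c = cfg.cells_per_spot

    H = rng.dirichlet(cfg.alpha_vector(), size=cfg.n_spots).T  # (p, n)
    Y = np.empty((cfg.n_genes, cfg.n_spots))
    for j in range(cfg.n_spots):
        type_avg = _nb_draw(rng, c * mean_values, c * phi) / c  # (m, p)
        Y[:, j] = type_avg @ H[:, j]

    spot_ids = [f"spot{j}" for j in range(cfg.n_spots)]
    expr = ExpressionMatrix(Y, cfg.gene_ids, spot_ids, layer="counts")
    truth = SimTruth(
        W_true=SignatureMatrix(mean_values.copy(), cfg.gene_ids, cfg.cell_type_ids),
        H_true=proportions_from_values(H, cfg.cell_type_ids, spot_ids),
    )
    return expr, truth


def simulate_image_prior(
    h_true: np.ndarray,
    fidelity: float,
    seed: int = 0,
    spot_ids: Optional[list[str]] = None,
) -> SpotPriorValues:
    """A synthetic guiding-image channel correlated with one type's truth.

    Values are a logit-space convex combination rho * logit(h_true) +
    (1 - rho) * noise mapped back through the logistic function, with the
    noise matched to the truth's logit location and spread.  rho = 1 yields
    a strictly monotone transform of the truth (Spearman correlation 1);
    rho = 0 yields truth-independent noise — a misleading prior.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ValidationError("fidelity must lie in [0, 1]")
    h = np.clip(np.asarray(h_true, dtype=float).ravel(), 1e-6, 1 - 1e-6)
    lh = logit(h)
    rng = np.random.default_rng(seed)
    spread = float(np.std(lh))
    spread = spread if spread > 0 else 1.0
    noise = rng.normal(loc=float(np.mean(lh)), scale=spread, size=len(h))
    mixed = fidelity * lh + (1.0 - fidelity) * noise
    values = np.clip(expit(mixed), 1e-4, 1.0 - 1e-4)
    ids = spot_ids if spot_ids is not None else [f"spot{j}" for j in range(len(h))]
    return SpotPriorValues(ids, values, source="if_channel")


def baseline_linear_regression(
    Y: ExpressionMatrix, W: SignatureMatrix
) -> ProportionsMatrix:
    """Per-spot OLS on the signature columns, clipped to zero and renormalized.

    The simplest conceivable estimator: unconstrained least-squares
    coefficients, negatives set to zero, then rescaled to sum to one.
    """
    _check_aligned(Y, W)
    wv = W.values
    if np.linalg.matrix_rank(wv) < wv.shape[1]:
        raise ValidationError("signature matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(wv, Y.values, rcond=None)  # (p, n)
    clipped = np.maximum(coef, 0.0)
    sums = clipped.sum(axis=0)
    uniform = np.full(wv.shape[1], 1.0 / wv.shape[1])
    clipped[:, sums <= 0] = uniform[:, None]
    return proportions_from_values(clipped, W.cell_type_ids, Y.spot_ids)


def baseline_constrained_ls(
    Y: ExpressionMatrix, W: SignatureMatrix
) -> ProportionsMatrix:
    """Per-spot least squares constrained to the simplex (h >= 0, sum h = 1)."""
    _check_aligned(Y, W)
    wv = W.values
    p = wv.shape[1]
    gram = wv.T @ wv
    # scale the quadratic program to O(1) for the solver's tolerances
    qp_scale = float(np.abs(gram).max())
    if qp_scale <= 0:
        raise ValidationError("signature matrix is identically zero")
    gram_s = gram / qp_scale
    H = np.empty((p, Y.n_spots))
    x0 = np.full(p, 1.0 / p)
    for j in range(Y.n_spots):
        wty_s = (wv.T @ Y.values[:, j]) / qp_scale

        def objective(h):
            return float(h @ gram_s @ h - 2.0 * wty_s @ h)

        def gradient(h):
            return 2.0 * (gram_s @ h - wty_s)

        res = minimize(
            objective,
            x0,
            jac=gradient,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * p,
            constraints=[{"type": "eq", "fun": lambda h: h.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success:  # SLSQP occasionally stalls; retry with trust-constr
            from scipy.optimize import LinearConstraint

            res = minimize(
                objective,
                x0,
                jac=gradient,
                method="trust-constr",
                bounds=[(0.0, 1.0)] * p,
                constraints=[LinearConstraint(np.ones((1, p)), 1.0, 1.0)],
                options={"maxiter": 2000, "gtol": 1e-12},
            )
        if not res.success:
            raise ValidationError(
                f"constrained solver failed for spot {Y.spot_ids[j]!r}: {res.message}"
            )
        H[:, j] = res.x
    return proportions_from_values(H, W.cell_type_ids, Y.spot_ids)


def _check_aligned(Y: ExpressionMatrix, W: SignatureMatrix) -> None:
    if Y.gene_ids != W.gene_ids:
        raise ValidationError(
            "Y and W gene ids are not aligned; use preprocessing.align_genes"
        )
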