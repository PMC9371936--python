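"""Performance statistics for decomposition results.

The headline statistic for annotated slides is the ratio Q of median
estimated proportions inside versus outside an annotated region, the
improvement Delta = Q_guided - Q_base between the image-guided and the
expression-only model, and a label-shuffling permutation test for Delta
(with a normal approximation of the null when the observed statistic
exceeds every permuted value).  Simulation benchmarks are summarized by the
mean absolute error against ground-truth proportions, and agreement with an
independent reference by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, norm, spearmanr

from .datamodel import ProportionsMatrix, SpotAnnotation, ValidationError

__all__ = [
    "PermutationResult",
    "q_statistic",
    "delta",
    "permutation_test",
    "mean_absolute_error",
    "rank_agreement",
    "encode_ordinal",
    "ordinal_rank_sum",
]


@dataclass
class PermutationResult:
    """Observed improvement, its permutation null, and the resulting p-value."""

    observed_delta: float
    null_deltas: np.ndarray
    p_value: float
    used_normal_approx: bool
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.null_deltas = np.asarray(self.null_deltas, dtype=float).ravel()
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p_value must lie in (0, 1]")
        if len(self.null_deltas) != self.n_perm:
            raise ValidationError("null_deltas length must equal n_perm")


def _as_values(h) -> np.ndarray:
    v = np.asarray(h, dtype=float).ravel()
    if np.any(~np.isfinite(v)):
        raise ValidationError("proportions must be finite")
    return v


def q_statistic(h, mask) -> float:
    """Ratio of median proportions in annotated vs other spots.

    ``h`` holds the evaluated cell type's (or group's) per-spot proportions,
    strictly positive; ``mask`` is boolean (or a SpotAnnotation) with at
    least one spot on each side.
    """
    if isinstance(mask, SpotAnnotation):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool).ravel()
    h = _as_values(h)
    if len(h) != len(mask):
        raise ValidationError("h and mask lengths differ")
    if not (mask.any() and (~mask).any()):
        raise ValidationError("mask needs positives and negatives")
    if np.any(h <= 0):
        raise ValidationError("proportions must be strictly positive")
    med_out = float(np.median(h[~mask]))
    if med_out == 0:
        raise ValidationError("median of non-annotated spots is zero")
    return float(np.median(h[mask])) / med_out


def delta(q_guided: float, q_base: float) -> float:
    """Improvement of the image-guided model over the base model: Q_g - Q_b."""
    q_guided, q_base = float(q_guided), float(q_base)
    if not (np.isfinite(q_guided) and np.isfinite(q_base)):
        raise ValidationError("Q statistics must be finite")
    return q_guided - q_base


def permutation_test(
    h_guided,
    h_base,
    mask,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Label-shuffling permutation test for the improvement Delta.

    Each permutation redraws the annotation uniformly at random among masks
    with the same number of positive spots and recomputes
    Delta_perm = Q_guided(perm) - Q_base(perm).  The one-sided p-value is
    the fraction of Delta_perm at least as extreme as the observed Delta;
    when that count is zero the upper tail of a normal distribution matched
    to the null's mean and standard deviation is used instead.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if isinstance(mask, SpotAnnotation):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool).ravel()
    hg = _as_values(h_guided)
    hb = _as_values(h_base)
    if not (len(hg) == len(hb) == len(mask)):
        raise ValidationError("h vectors and mask must be aligned")
    n = len(mask)
    n_pos = int(mask.sum())

    observed = delta(q_statistic(hg, mask), q_statistic(hb, mask))

    rng = np.random.default_rng(seed)
    # permuted masks: first n_pos entries of a random permutation are positive
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    pos = order[:, :n_pos]  # (n_perm, n_pos) indices
    neg = order[:, n_pos:]

    def med(values, idx):
        return np.median(values[idx], axis=1)

    q_g = med(hg, pos) / med(hg, neg)
    q_b = med(hb, pos) / med(hb, neg)
    null = q_g - q_b

    if alternative == "greater":
        count = int(np.sum(null >= observed))
    else:
        count = int(np.sum(np.abs(null) >= abs(observed)))

    if count > 0:
        p = count / n_perm
        approx = False
    else:
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        sd = max(sd, 1e-300)
        if alternative == "greater":
            p = float(norm.sf(observed, loc=mu, scale=sd))
        else:
            p = float(2 * norm.sf(abs(observed), loc=mu, scale=sd))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        approx = True
    return PermutationResult(
        observed_delta=observed,
        null_deltas=null,
        p_value=p,
        used_normal_approx=approx,
        n_perm=n_perm,
        seed=seed,
    )


def mean_absolute_error(pred: ProportionsMatrix, truth: ProportionsMatrix) -> float:
    """Mean over all cell-type x spot entries of |predicted - true| proportion."""
    if pred.values.shape != truth.values.shape:
        raise ValidationError("prediction and truth shapes differ")
    if pred.cell_type_ids != truth.cell_type_ids or pred.spot_ids != truth.spot_ids:
        raise ValidationError("prediction and truth orderings differ")
    return float(np.abs(pred.values - truth.values).mean())


def rank_agreement(pred, reference) -> float:
    """Spearman rank correlation (average ranks on ties) between two vectors."""
    pred = _as_values(pred)
    reference = _as_values(reference)
    if len(pred) != len(reference):
        raise ValidationError("vectors must have equal length")
    if len(pred) < 3:
        raise ValidationError("need at least 3 spots for a rank correlation")
    if np.ptp(pred) == 0 or np.ptp(reference) == 0:
        raise ValidationError("rank correlation undefined for a constant vector")
    return float(spearmanr(pred, reference).statistic)


def encode_ordinal(scores, order=("low", "middle", "high")) -> np.ndarray:
    """Encode ordinal category labels as 1, 2, 3, ... following ``order``."""
    lookup = {str(lab): i + 1 for i, lab in enumerate(order)}
    out = []
    for s in scores:
        key = str(s).strip().lower()
        if key not in lookup:
            raise ValidationError(f"unknown ordinal label {s!r}")
        out.append(lookup[key])
    return np.asarray(out, dtype=float)


def ordinal_rank_sum(scores_a, scores_b, order=("low", "middle", "high")) -> float:
    """One-sided rank-sum p-value that group A's ordinal scores exceed group B's."""
    a = encode_ordinal(scores_a, order)
    b = encode_ordinal(scores_b, order)
    return float(mannwhitneyu(a, b, alternative="greater").pvalue)
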