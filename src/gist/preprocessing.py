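"""Reference signature construction, smoothing, normalization, HVG selection.

Spatial counts are typically far sparser than the single-cell reference, so
spots are optionally imputed by k-nearest-neighbor smoothing (stepwise
doubling aggregation in a PCA-reduced, variance-stabilized space) before
normalization.  Model fitting then operates on the intersection of the two
datasets' most highly variable genes, with the spatial matrix and the
reference brought onto a common normalized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import (
    ExpressionMatrix,
    SignatureMatrix,
    SingleCellReference,
    ValidationError,
)

__all__ = [
    "SmoothingConfig",
    "build_signature",
    "knn_smooth",
    "select_shared_hvgs",
    "normalize",
    "depth_scale",
    "align_genes",
]

logger = logging.getLogger(__name__)


@dataclass
class SmoothingConfig:
    """kNN smoothing parameters: neighbors aggregated (k) and PCA dims (d)."""

    k_neighbors: int = 5
    n_components: int = 10

    def __post_init__(self) -> None:
        if self.k_neighbors < 0:
            raise ValidationError("k_neighbors must be >= 0")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


def depth_scale(values: np.ndarray, target: Optional[float] = None) -> np.ndarray:
    """Scale each column to a common library size (default: the median depth)."""
    depths = values.sum(axis=0)
    if np.any(depths <= 0):
        raise ValidationError(f"all-zero column at index {int(np.argmax(depths <= 0))}")
    if target is None:
        target = float(np.median(depths))
    return values * (target / depths)


def build_signature(
    ref: SingleCellReference,
    normalizer: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> SignatureMatrix:
    """Collapse a single-cell reference to per-type mean normalized expression.

    ``normalizer`` maps the genes x cells count matrix to normalized values
    comparable across cells; the default scales every cell to the median
    library size.  Column order follows the reference's declared type order.
    """
    if normalizer is None:
        normalizer = depth_scale
    norm = np.asarray(normalizer(ref.values), dtype=float)
    if norm.shape != ref.values.shape:
        raise ValidationError("normalizer changed the matrix shape")
    labels = np.asarray(ref.cell_type_labels)
    cols = []
    for ct in ref.cell_types:
        mask = labels == ct
        if not mask.any():  # unreachable for a valid reference; keep the guard
            raise ValidationError(f"no cells for type {ct!r}")
        cols.append(norm[:, mask].mean(axis=1))
    return SignatureMatrix(np.column_stack(cols), list(ref.gene_ids), list(ref.cell_types))


def _freeman_tukey(values: np.ndarray) -> np.ndarray:
    # variance-stabilizing transform for (approximately) Poisson counts
    return np.sqrt(values) + np.sqrt(values + 1.0)


def _reduce(values: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    """Spots x components embedding of variance-stabilized, depth-scaled counts."""
    x = _freeman_tukey(depth_scale(values)).T  # spots x genes
    d = min(n_components, min(x.shape) - 1)
    if d < 1 or np.allclose(x, x.mean(axis=0), atol=1e-12):
        return x  # degenerate: identical spots need no reduction
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    return pca.fit_transform(x)


def knn_smooth(
    counts: ExpressionMatrix,
    cfg: SmoothingConfig,
    seed: int = 0,
    return_neighbors: bool = False,
):
    """Impute spot counts by aggregating each spot with its k nearest neighbors.

    Follows the stepwise-doubling schedule of the kNN-smoothing algorithm:
    neighbors are aggregated with k_step = 1, 2, 4, ... up to ``k``, and the
    reduced space (PCA of Freeman-Tukey-stabilized, depth-scaled values) is
    recomputed from the current aggregate at every step.  Raw counts are
    re-aggregated at each step, so each output profile is an exact sum of
    ``k+1`` input profiles.  ``k_neighbors=0`` is an identity pass-through.
    """
    if counts.layer != "counts":
        raise ValidationError("knn_smooth expects a counts-layer matrix")
    k = int(cfg.k_neighbors)
    n = counts.n_spots
    if k >= n:
        raise ValidationError(f"k_neighbors={k} must be smaller than n_spots={n}")
    raw = counts.values
    neighbors = np.arange(n)[:, None]  # (n, 1): each spot alone
    smoothed = raw.copy()
    k_step = 1
    while k > 0:
        k_step = min(k_step, k)
        emb = _reduce(smoothed, cfg.n_components, seed)
        nn = NearestNeighbors(n_neighbors=k_step + 1).fit(emb)
        neighbors = nn.kneighbors(emb, return_distance=False)  # includes self
        # aggregate the ORIGINAL counts over the neighborhood
        smoothed = raw[:, neighbors].sum(axis=2)
        if k_step == k:
            break
        k_step *= 2
    out = ExpressionMatrix(
        smoothed, list(counts.gene_ids), list(counts.spot_ids), layer="smoothed"
    )
    if return_neighbors:
        return out, neighbors
    return out


def _dispersion(values: np.ndarray) -> np.ndarray:
    """Per-gene variability: variance of log1p depth-scaled (CP10K) values."""
    scaled = values * (1e4 / np.maximum(values.sum(axis=0), 1e-12))
    return np.log1p(scaled).var(axis=1)


def select_shared_hvgs(
    st: ExpressionMatrix,
    ref: SingleCellReference,
    top_n: int = 2000,
) -> list[str]:
    """Intersect the two datasets' ``top_n`` most highly variable genes.

    Variability is ranked within each dataset by the variance of its
    variance-stabilized (log1p CP10K) values.  The result is ordered by the
    spatial matrix's gene order.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    shared_universe = set(st.gene_ids) & set(ref.gene_ids)
    if not shared_universe:
        raise ValidationError("the two datasets share no gene ids")

    def top_set(values, gene_ids):
        disp = _dispersion(values)
        order = np.argsort(-disp, kind="stable")[: min(top_n, len(gene_ids))]
        return {gene_ids[i] for i in order}

    chosen = top_set(st.values, st.gene_ids) & top_set(ref.values, ref.gene_ids)
    if not chosen:
        raise ValidationError("empty intersection of highly variable genes")
    return [g for g in st.gene_ids if g in chosen]


def normalize(counts: ExpressionMatrix, method: str = "log1p") -> ExpressionMatrix:
    """Normalize counts, removing library-size effects.

    Methods: ``depth`` scales each spot to the median library size (linear
    scale, appropriate for fitting the linear mixing model); ``log1p`` is
    log1p of depth-scaled counts (variance-stabilized, for HVG selection and
    distance computations); ``pearson`` gives analytic NB Pearson residuals
    (theta=100), clipped at sqrt(n_spots).
    """
    depths = counts.values.sum(axis=0)
    if np.any(depths <= 0):
        j = int(np.argmax(depths <= 0))
        raise ValidationError(f"all-zero spot {counts.spot_ids[j]!r}")
    if method == "depth":
        out = depth_scale(counts.values)
    elif method == "log1p":
        out = np.log1p(depth_scale(counts.values))
    elif method == "pearson":
        x = counts.values
        total = x.sum()
        mu = np.outer(x.sum(axis=1) / total, depths)
        theta = 100.0
        resid = (x - mu) / np.sqrt(mu + mu**2 / theta + 1e-12)
        clip = np.sqrt(x.shape[1])
        out = np.clip(resid, -clip, clip)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionMatrix(
        out, list(counts.gene_ids), list(counts.spot_ids), layer="normalized"
    )


def align_genes(
    Y: ExpressionMatrix, W: SignatureMatrix
) -> tuple[ExpressionMatrix, SignatureMatrix]:
    """Restrict Y and W to their shared genes, in Y's gene order.

    Alignment is by gene id, never by position; unmatched ids are dropped
    with a logged count.
    """
    shared = [g for g in Y.gene_ids if g in set(W.gene_ids)]
    dropped = (len(Y.gene_ids) - len(shared)) + (len(W.gene_ids) - len(shared))
    if dropped:
        logger.info("align_genes: dropped %d unmatched gene ids", dropped)
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} shared genes after alignment; need at least 2"
        )
    yi = [Y.gene_ids.index(g) for g in shared]
    wi = [W.gene_ids.index(g) for g in shared]
    Y2 = ExpressionMatrix(Y.values[yi, :], shared, list(Y.spot_ids), layer=Y.layer)
    W2 = SignatureMatrix(W.values[wi, :], shared, list(W.cell_type_ids))
    return Y2, W2
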