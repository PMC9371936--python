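"""Core domain types for spot deconvolution.

The central objects mirror the matrix decomposition ``Y ~ W @ H``: an
m-genes x n-spots expression matrix ``Y``, an m x p signature matrix ``W``
of mean reference expression per cell type, and a p x n proportions matrix
``H`` whose columns live on the open probability simplex.  Image-derived
prior information enters as a per-spot Beta prior mean ``tau`` with a global
concentration ``lam`` for one target cell type (or group of cell types).

All containers validate their invariants at construction time so that any
malformed input fails before a downstream computation consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "SingleCellReference",
    "SignatureMatrix",
    "ProportionsMatrix",
    "SpotGeometry",
    "ImageRaster",
    "PatchProbabilityMap",
    "PriorSpec",
    "SpotAnnotation",
    "PosteriorFit",
    "DEFAULT_SPOT_RADIUS_PX",
]

#: Default spot radius, in image pixels, used when a geometry table carries
#: no explicit radius column.
DEFAULT_SPOT_RADIUS_PX = 70.0


class ValidationError(ValueError):
    """An object violated one of its declared invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for x in ids:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValidationError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x spots matrix of counts or normalized expression values."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    layer: str = "counts"

    _LAYERS = ("counts", "smoothed", "normalized")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.spot_ids = _check_unique(self.spot_ids, "spot")
        m, n = self.values.shape
        if len(self.gene_ids) != m or len(self.spot_ids) != n:
            raise ValidationError(
                f"id lengths ({len(self.gene_ids)} genes, {len(self.spot_ids)} "
                f"spots) do not match value shape {self.values.shape}"
            )
        if self.layer not in self._LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.layer != "normalized" and np.any(self.values < 0):
            raise ValidationError("negative entries in expression matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]


@dataclass
class SingleCellReference:
    """Single-cell reference counts with one cell-type label per cell."""

    values: np.ndarray
    cell_type_labels: list[str]
    gene_ids: list[str]
    cell_types: Optional[list[str]] = None  # declared order; defaults to sorted

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("reference values must be a 2-D matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_type_labels = [str(x) for x in self.cell_type_labels]
        m, c = self.values.shape
        if len(self.gene_ids) != m or len(self.cell_type_labels) != c:
            raise ValidationError("gene/label lengths do not match value shape")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("reference counts must be finite and non-negative")
        if self.cell_types is None:
            self.cell_types = sorted(set(self.cell_type_labels))
        else:
            self.cell_types = _check_unique(self.cell_types, "cell type")
        declared = set(self.cell_types)
        for lab in self.cell_type_labels:
            if lab not in declared:
                raise ValidationError(f"label {lab!r} not in declared cell types")
        for ct in self.cell_types:
            if self.cell_type_labels.count(ct) < 1:
                raise ValidationError(f"no cells for type {ct!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class SignatureMatrix:
    """Genes x cell-types matrix of mean reference expression (``W``)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_type_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("signature values must be a 2-D matrix")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_type_ids = _check_unique(self.cell_type_ids, "cell type")
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValidationError("id lengths do not match signature shape")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("signature entries must be finite and non-negative")
        if np.any(self.values.sum(axis=0) == 0):
            k = int(np.argmax(self.values.sum(axis=0) == 0))
            raise ValidationError(
                f"all-zero signature column for type {self.cell_type_ids[k]!r}"
            )


#: Column sums of a proportions matrix must equal 1 within this tolerance.
SIMPLEX_TOL = 1e-6


@dataclass
class ProportionsMatrix:
    """Cell types x spots matrix ``H``; every column is an open-simplex point."""

    values: np.ndarray
    cell_type_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("proportions must be a 2-D matrix")
        self.cell_type_ids = _check_unique(self.cell_type_ids, "cell type")
        self.spot_ids = _check_unique(self.spot_ids, "spot")
        if self.values.shape != (len(self.cell_type_ids), len(self.spot_ids)):
            raise ValidationError("id lengths do not match proportions shape")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("proportions must be finite")
        if self.values.size and np.any(self.values <= 0):
            raise ValidationError("proportions must be strictly positive")
        col_sums = self.values.sum(axis=0)
        if self.values.size and np.any(np.abs(col_sums - 1.0) > SIMPLEX_TOL):
            j = int(np.argmax(np.abs(col_sums - 1.0)))
            raise ValidationError(
                f"column {self.spot_ids[j]!r} sums to {col_sums[j]:.8f}, not 1"
            )

    def row(self, cell_type: Union[str, Sequence[str]]) -> np.ndarray:
        """Per-spot proportions for one cell type, or the sum over a group."""
        if isinstance(cell_type, str):
            cell_type = [cell_type]
        idx = [self.cell_type_ids.index(ct) for ct in cell_type]
        return self.values[idx, :].sum(axis=0)


def proportions_from_values(
    values: np.ndarray, cell_type_ids: Sequence[str], spot_ids: Sequence[str]
) -> ProportionsMatrix:
    """Build a valid :class:`ProportionsMatrix` from approximate proportions.

    Applies a 1e-12 floor (the simplex support is open) and renormalizes each
    column, correcting e.g. the <=1e-6 drift of averaged posterior samples.
    """
    v = np.maximum(np.asarray(values, dtype=float), 1e-12)
    s = v.sum(axis=0)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValidationError("cannot normalize a non-positive column")
    return ProportionsMatrix(v / s, list(cell_type_ids), list(spot_ids))


@dataclass
class SpotGeometry:
    """Spot centers and capture radius in 0-based (row, col) pixel coordinates."""

    spot_ids: list[str]
    centers: np.ndarray  # (n, 2) of (row_px, col_px)
    radius_px: Union[float, np.ndarray] = DEFAULT_SPOT_RADIUS_PX

    def __post_init__(self) -> None:
        self.spot_ids = _check_unique(self.spot_ids, "spot")
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape != (len(self.spot_ids), 2):
            raise ValidationError("centers must be (n_spots, 2)")
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("spot centers must be finite")
        self.radius_px = np.broadcast_to(
            np.asarray(self.radius_px, dtype=float), (len(self.spot_ids),)
        ).copy()
        if np.any(~np.isfinite(self.radius_px)) or np.any(self.radius_px <= 0):
            raise ValidationError("radius_px must be positive and finite")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class ImageRaster:
    """A 2-D grayscale raster (one IF channel, or a probability heat map)."""

    pixels: np.ndarray
    microns_per_pixel: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("image must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("image pixels must be non-negative")
        if self.microns_per_pixel is not None and self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be positive")


@dataclass
class PatchProbabilityMap:
    """Axis-aligned rectangular patches with a probability each.

    Each patch is ``(row0_px, col0_px, height_px, width_px, probability)``;
    the natural source is a patch classifier run over a whole-slide image
    (e.g. a tumor-infiltrating-lymphocyte detector scoring 50x50 micron tiles).
    """

    patches: list[tuple[float, float, float, float, float]]

    def __post_init__(self) -> None:
        cleaned = []
        for p in self.patches:
            r0, c0, h, w, prob = (float(x) for x in p)
            if h <= 0 or w <= 0:
                raise ValidationError("patch height/width must be positive")
            if not (0.0 <= prob <= 1.0):
                raise ValidationError(f"patch probability {prob} outside [0, 1]")
            cleaned.append((r0, c0, h, w, prob))
        self.patches = cleaned


@dataclass
class PriorSpec:
    """Beta prior specification for one target cell type (or group).

    ``tau`` holds the per-spot prior means in (0, 1); ``lam`` is the global
    total-count (concentration) hyperparameter weighting the image against
    the transcriptome.  ``target_cell_type`` may name a single type or a
    group of types, in which case the prior constrains the group's summed
    proportion.
    """

    target_cell_type: Union[str, tuple[str, ...]]
    tau: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        if not isinstance(self.target_cell_type, str):
            self.target_cell_type = tuple(str(x) for x in self.target_cell_type)
            if len(self.target_cell_type) == 0:
                raise ValidationError("empty target cell-type group")
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        if np.any(~np.isfinite(self.tau)) or np.any((self.tau <= 0) | (self.tau >= 1)):
            raise ValidationError("tau values must lie strictly inside (0, 1)")
        self.lam = float(self.lam)
        if not self.lam > 0:
            raise ValidationError("lam must be positive")

    @property
    def target_types(self) -> tuple[str, ...]:
        if isinstance(self.target_cell_type, str):
            return (self.target_cell_type,)
        return self.target_cell_type


@dataclass
class SpotAnnotation:
    """Boolean per-spot annotation (True = annotated positive, e.g. immune)."""

    spot_ids: list[str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = _check_unique(self.spot_ids, "spot")
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if len(self.mask) != len(self.spot_ids):
            raise ValidationError("mask length does not match spot ids")
        if not (self.mask.any() and (~self.mask).any()):
            raise ValidationError(
                "annotation needs at least one positive and one negative spot"
            )


@dataclass
class PosteriorFit:
    """Posterior summary of a fitted decomposition model.

    Point estimates are posterior means over post-burn-in samples.  ``nu_mean``
    (t-distribution degrees of freedom, always > 3), ``beta0_mean`` (per-spot
    intercept) and ``sigma_mean`` (per-spot scale) are reported per spot.
    """

    H_mean: ProportionsMatrix
    nu_mean: np.ndarray
    beta0_mean: np.ndarray
    sigma_mean: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    mcmc_config: Optional[object] = None
    h_samples: Optional[np.ndarray] = None  # (draws, p, n), post-burn-in

    def __post_init__(self) -> None:
        self.nu_mean = np.asarray(self.nu_mean, dtype=float).ravel()
        self.beta0_mean = np.asarray(self.beta0_mean, dtype=float).ravel()
        self.sigma_mean = np.asarray(self.sigma_mean, dtype=float).ravel()
        n = self.H_mean.values.shape[1]
        if not (len(self.nu_mean) == len(self.beta0_mean) == len(self.sigma_mean) == n):
            raise ValidationError("per-spot parameter lengths do not match H")
        if np.any(self.nu_mean <= 3):
            raise ValidationError("posterior mean of nu must exceed 3")
        if np.any(self.sigma_mean <= 0):
            raise ValidationError("posterior mean of sigma must be positive")
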