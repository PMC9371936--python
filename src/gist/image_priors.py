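"""Turn guiding images into per-spot Beta prior means.

Two image sources are supported: a grayscale immunofluorescence channel
(pixel intensities aggregated over each spot's capture disk) and a
patch-level probability map from a tile classifier (patch probabilities
combined by pixel-overlap weighting).  Raw spot values are then mapped onto
the quantiles of a first-round expression-only fit, which places them on the
scale of cell-type proportions, and finally converted to Beta(alpha, beta)
shape parameters through the mean/total-count parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.stats import rankdata

from .datamodel import (
    ImageRaster,
    PatchProbabilityMap,
    PriorSpec,
    SpotGeometry,
    ValidationError,
)

__all__ = [
    "SpotPriorValues",
    "cap_and_rescale",
    "spot_mean_intensity",
    "patch_map_to_spots",
    "quantile_map",
    "beta_shapes",
    "prior_from_values",
    "TAU_CLAMP",
]

logger = logging.getLogger(__name__)

#: Prior means are clamped to [TAU_CLAMP, 1 - TAU_CLAMP]; the Beta mean must
#: be interior to (0, 1).
TAU_CLAMP = 1e-4


@dataclass
class SpotPriorValues:
    """Per-spot values in [0, 1] derived from a guiding image."""

    spot_ids: list[str]
    values: np.ndarray
    source: str = "if_channel"  # or "dl_map"

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.spot_ids):
            raise ValidationError("value length does not match spot ids")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("spot prior values must be finite")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValidationError("spot prior values must lie in [0, 1]")


def cap_and_rescale(
    image: ImageRaster, low_pct: float = 1.0, high_pct: float = 99.0
) -> ImageRaster:
    """Cap intensity outliers and rescale to [0, 1].

    Values above the ``high_pct`` percentile are set to that percentile,
    values below the ``low_pct`` percentile are set to zero, and the result
    is divided by its maximum, so the output maximum is exactly 1 (an
    all-zero image is returned unchanged with a warning).
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValidationError("need 0 <= low_pct < high_pct <= 100")
    px = image.pixels
    if px.size == 0:
        raise ValidationError("empty image")
    if not np.any(px > 0):
        logger.warning("cap_and_rescale: constant-zero image returned unchanged")
        return ImageRaster(px.copy(), image.microns_per_pixel)
    # empirical (order-statistic) percentiles: k_hi pixels count as upper
    # outliers and are capped at the largest non-outlier value; pixels below
    # the low order statistic are zeroed.  Unlike interpolated percentiles
    # this rule is exactly idempotent: re-applying it changes nothing.
    flat = np.sort(px, axis=None)
    n = flat.size
    k_hi = int(np.floor(n * (100.0 - high_pct) / 100.0))
    hi = flat[n - 1 - k_hi]
    idx_lo = int(np.floor(n * low_pct / 100.0))
    lo = flat[idx_lo]
    out = np.minimum(px, hi)
    out[out < lo] = 0.0
    out = out / out.max()
    return ImageRaster(out, image.microns_per_pixel)


def _disk_pixel_coords(
    center: np.ndarray, radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pixels whose centers fall within ``radius`` of ``center``.

    Pixel (r, c) has its center at coordinate (r, c); disks are clipped at
    image borders rather than dropped.
    """
    r0, c0 = center
    rows = np.arange(max(0, int(np.ceil(r0 - radius))), min(shape[0], int(np.floor(r0 + radius)) + 1))
    cols = np.arange(max(0, int(np.ceil(c0 - radius))), min(shape[1], int(np.floor(c0 + radius)) + 1))
    if rows.size == 0 or cols.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[inside], cc[inside]


def spot_mean_intensity(image: ImageRaster, geom: SpotGeometry) -> SpotPriorValues:
    """Mean pixel intensity over each spot's capture disk.

    A pixel belongs to a spot when its center lies within ``radius_px`` of
    the spot center (Euclidean disk).  Spots whose disk contains no pixel
    (fully outside the image) get value 0 with a warning.
    """
    vals = np.zeros(geom.n_spots)
    for j in range(geom.n_spots):
        rr, cc = _disk_pixel_coords(geom.centers[j], float(geom.radius_px[j]), image.pixels.shape)
        if rr.size == 0:
            logger.warning(
                "spot %r lies fully outside the image; value set to 0",
                geom.spot_ids[j],
            )
            continue
        vals[j] = image.pixels[rr, cc].mean()
    peak = vals.max() if vals.size else 0.0
    if peak > 1:  # tolerate un-rescaled images but keep the [0, 1] contract
        logger.warning(
            "spot_mean_intensity: image not on [0, 1]; rescaling spot values "
            "by their maximum (consider cap_and_rescale first)"
        )
        vals = vals / peak
    return SpotPriorValues(list(geom.spot_ids), vals, source="if_channel")


def patch_map_to_spots(
    patch_map: PatchProbabilityMap, geom: SpotGeometry
) -> SpotPriorValues:
    """Overlap-weighted average of patch probabilities for each spot.

    Each spot's value is sum_patch p * overlap / sum_patch overlap, where
    overlap counts the pixels (by center) inside both the patch rectangle
    and the spot disk.  Spots overlapping no patch get 0 with a warning.
    """
    vals = np.zeros(geom.n_spots)
    # extent of the pixel grid: cover all patches and all spot disks
    max_r = max([r0 + h for r0, c0, h, w, _ in patch_map.patches] or [0.0])
    max_c = max([c0 + w for r0, c0, h, w, _ in patch_map.patches] or [0.0])
    shape = (
        int(np.ceil(max(max_r, (geom.centers[:, 0] + geom.radius_px).max()))) + 1,
        int(np.ceil(max(max_c, (geom.centers[:, 1] + geom.radius_px).max()))) + 1,
    )
    for j in range(geom.n_spots):
        rr, cc = _disk_pixel_coords(geom.centers[j], float(geom.radius_px[j]), shape)
        if rr.size == 0:
            logger.warning("spot %r has an empty pixel disk", geom.spot_ids[j])
            continue
        weights = 0.0
        total = 0.0
        for r0, c0, h, w, prob in patch_map.patches:
            # pixel centers inside the half-open rectangle [r0, r0+h) x [c0, c0+w)
            overlap = int(np.sum((rr >= r0) & (rr < r0 + h) & (cc >= c0) & (cc < c0 + w)))
            weights += overlap
            total += overlap * prob
        if weights == 0:
            logger.warning(
                "spot %r overlaps no patch; value set to 0", geom.spot_ids[j]
            )
            continue
        vals[j] = total / weights
    return SpotPriorValues(list(geom.spot_ids), vals, source="dl_map")


def quantile_map(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map ``source`` values onto the empirical quantiles of ``target``.

    Each output value is the linearly interpolated order statistic of
    ``target`` at the fractional rank of the corresponding source value
    (average ranks for ties).  The mapping is monotone and the output's
    empirical distribution equals the target's (up to interpolation at
    tied ranks).
    """
    source = np.asarray(source, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if source.shape != target.shape:
        raise ValidationError("source and target must have the same length")
    n = len(source)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return target.copy()
    ranks = rankdata(source, method="average")
    q = (ranks - 1.0) / (n - 1.0)
    return np.quantile(target, q, method="linear")


def beta_shapes(tau: float, lam: float) -> tuple[float, float]:
    """Convert a (mean, total-count) Beta parameterization to shapes.

    Returns ``(tau * lam, (1 - tau) * lam)``: a Beta with mean ``tau`` and
    concentration (prior sample size) ``lam``.
    """
    tau = float(tau)
    lam = float(lam)
    if not (0.0 < tau < 1.0):
        raise ValidationError(f"tau={tau} must lie strictly inside (0, 1)")
    if not lam > 0:
        raise ValidationError(f"lam={lam} must be positive")
    return tau * lam, (1.0 - tau) * lam


def prior_from_values(
    values: Union[SpotPriorValues, np.ndarray],
    target_cell_type: Union[str, Sequence[str]],
    lam: float,
) -> PriorSpec:
    """Build a :class:`PriorSpec` from mapped per-spot values.

    Values are clamped to [1e-4, 1 - 1e-4] so every Beta mean is interior.
    """
    v = values.values if isinstance(values, SpotPriorValues) else np.asarray(values, float)
    tau = np.clip(v, TAU_CLAMP, 1.0 - TAU_CLAMP)
    if isinstance(target_cell_type, str):
        target = target_cell_type
    else:
        target = tuple(target_cell_type)
    return PriorSpec(target_cell_type=target, tau=tau, lam=lam)
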