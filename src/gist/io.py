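"""Readers and writers for counts, geometry, images, patch maps and results.

Counts are accepted either as MatrixMarket coordinate files (with gene/spot
id sidecar files, one id per line) or as delimited text with a header row of
spot ids and a first column of gene ids.  All delimited outputs are UTF-8
with enough digits to round-trip.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    DEFAULT_SPOT_RADIUS_PX,
    ExpressionMatrix,
    ImageRaster,
    PatchProbabilityMap,
    ProportionsMatrix,
    SpotAnnotation,
    SpotGeometry,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_counts",
    "read_spot_geometry",
    "write_proportions",
    "read_proportions",
    "read_image",
    "read_patch_map",
    "read_annotation",
    "read_id_list",
]


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


def read_id_list(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def _read_delimited(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pandas names the offending line in its message
        raise ParseError(f"{path}: {exc}") from exc


def read_counts(
    path: str,
    format: str = "delimited",
    gene_ids_path: Optional[str] = None,
    spot_ids_path: Optional[str] = None,
) -> ExpressionMatrix:
    """Read a genes x spots counts matrix.

    ``format="mtx"`` expects a MatrixMarket coordinate file plus id sidecars
    (defaults: ``<stem>.genes.txt`` and ``<stem>.spots.txt`` next to it);
    ``format="delimited"`` expects a header row of spot ids and a first
    column of gene ids, comma- or tab-separated.
    """
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        stem = os.path.splitext(path)[0]
        gene_ids = read_id_list(gene_ids_path or stem + ".genes.txt")
        spot_ids = read_id_list(spot_ids_path or stem + ".spots.txt")
    elif format == "delimited":
        df = _read_delimited(path)
        width = len(df.columns)
        bad = df.apply(lambda row: row.isna().any(), axis=1)
        if width and bad.any():
            raise ParseError(
                f"{path}: row {df.index[int(np.argmax(bad.values))]!r} does not "
                f"have {width} values"
            )
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        spot_ids = [str(s) for s in df.columns]
    else:
        raise ValueError(f"unknown counts format {format!r}")
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative entries in counts matrix")
    return ExpressionMatrix(values, gene_ids, spot_ids, layer="counts")


def read_spot_geometry(path: str) -> SpotGeometry:
    """Read a spot geometry table: spot_id, row_px, col_px [, radius_px].

    A platform-neutral dialect: any delimited file with those columns (header
    optional column names ``spot_id,row_px,col_px,radius_px``).  A missing
    radius column defaults to the 70-pixel capture radius.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if "spot_id" not in cols:
        # headerless file: assume positional spot_id,row_px,col_px[,radius_px]
        names = ["spot_id", "row_px", "col_px", "radius_px"][: df.shape[1]]
        try:
            df = pd.read_csv(path, sep=None, engine="python", header=None, names=names)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    else:
        df.columns = cols
    for required in ("spot_id", "row_px", "col_px"):
        if required not in df.columns:
            raise ParseError(f"{path}: missing column {required!r}")
    spot_ids = [str(s) for s in df["spot_id"]]
    centers = df[["row_px", "col_px"]].to_numpy(dtype=float)
    if "radius_px" in df.columns and not df["radius_px"].isna().all():
        radius = df["radius_px"].to_numpy(dtype=float)
    else:
        radius = DEFAULT_SPOT_RADIUS_PX
    return SpotGeometry(spot_ids, centers, radius)


def write_proportions(H: ProportionsMatrix, path: str) -> None:
    """Write ``H`` as a delimited table (rows = cell types, cols = spots).

    Values are written with 12 significant digits so that a read round-trip
    recovers them well within 1e-9.  ``H`` is validated before any bytes are
    written.
    """
    if not isinstance(H, ProportionsMatrix):
        raise TypeError("write_proportions expects a ProportionsMatrix")
    # re-run invariant checks in case values were mutated after construction
    ProportionsMatrix(H.values, H.cell_type_ids, H.spot_ids)
    df = pd.DataFrame(H.values, index=H.cell_type_ids, columns=H.spot_ids)
    df.index.name = "cell_type"
    df.to_csv(path, float_format="%.12g")


def read_proportions(path: str) -> ProportionsMatrix:
    df = _read_delimited(path)
    return ProportionsMatrix(
        df.to_numpy(dtype=float),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )


def read_image(path: str, microns_per_pixel: Optional[float] = None) -> ImageRaster:
    """Read a grayscale TIFF/PNG image; RGB(A) inputs are averaged to gray."""
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:
        pixels = pixels[..., :3].mean(axis=-1)
    return ImageRaster(pixels, microns_per_pixel)


def read_patch_map(path: str) -> PatchProbabilityMap:
    """Read a patch probability table: row0_px, col0_px, height_px, width_px, probability."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    needed = ["row0_px", "col0_px", "height_px", "width_px", "probability"]
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return PatchProbabilityMap([tuple(row) for row in df[needed].to_numpy(dtype=float)])


def read_annotation(path: str) -> SpotAnnotation:
    """Read a binary spot annotation: columns spot_id, annotated (0/1 or bool)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("spot_id", "annotated"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return SpotAnnotation(
        [str(s) for s in df["spot_id"]],
        df["annotated"].astype(bool).to_numpy(),
    )
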