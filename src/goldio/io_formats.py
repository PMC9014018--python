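"""Read/write every on-disk artifact the pipeline touches.

Inputs are a TIFF ROI mask (plus an optional replica image for overlays), a
gold-particle CSV with mandatory ``"X"``/``"Y"`` columns, and an optional
landmark CSV in the same convention. Results go out as plain UTF-8,
comma-separated CSVs with ``.`` decimals; lengths and areas are converted per
:class:`~goldio.data_model.ScaleSpec` at write time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .data_model import ParticlePointSet, RoiMask, ScaleSpec
from .errors import (
    AmbiguousInputError,
    FormatError,
    InvalidMaskError,
    MissingInputError,
)


@dataclass
class InputBundle:
    """The files of one analysis run; mask and gold CSV are mandatory."""

    mask_path: Path
    gold_csv_path: Path
    image_path: Optional[Path] = None
    landmark_csv_path: Optional[Path] = None


def read_points_csv(path, label: str = "gold") -> ParticlePointSet:
    """Load a coordinate CSV into a :class:`ParticlePointSet`.

    The header must contain columns named ``X`` and ``Y`` (exact match first,
    case-insensitive fallback); any extra columns are ignored. Ids are
    assigned 0..n-1 in row order. Both integer and fractional coordinates are
    accepted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # unreadable / not CSV
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc

    cols = {}
    for wanted in ("X", "Y"):
        if wanted in df.columns:
            cols[wanted] = wanted
            continue
        lowered = [c for c in df.columns if c.strip().lower() == wanted.lower()]
        if lowered:
            cols[wanted] = lowered[0]
        else:
            raise FormatError(f"{path}: missing required column {wanted!r}")

    n = len(df)
    xy = np.empty((n, 2), dtype=float)
    for j, wanted in enumerate(("X", "Y")):
        raw = df[cols[wanted]]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() | raw.isna()
        if bad.any():
            # +2: one for the header line, one for 1-based row numbering
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: non-numeric value in column {cols[wanted]!r} at row {row}"
            )
        xy[:, j] = parsed.to_numpy(dtype=float)
    return ParticlePointSet(xy=xy, label=label)


def read_mask_tiff(path) -> RoiMask:
    """Load a single-plane TIFF mask; any nonzero pixel is inside the ROI.

    RGB(A) images are collapsed by any-channel-nonzero. Multi-page files and
    an all-zero mask are errors.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise FormatError(
                    f"{path}: expected a single-plane TIFF, got {len(tif.pages)} pages"
                )
            arr = tif.pages[0].asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    if arr.ndim == 3:  # RGB(A): nonzero in any channel
        grid = np.any(arr != 0, axis=-1)
    elif arr.ndim == 2:
        grid = arr != 0
    else:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    if not grid.any():
        raise InvalidMaskError(f"{path}: mask has no nonzero pixels")
    return RoiMask(grid=grid)


def read_image_tiff(path) -> np.ndarray:
    """Load the replica image (grayscale or RGB) for overlay rendering."""
    path = Path(path)
    try:
        return tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc


def write_mask_tiff(mask: RoiMask, path) -> None:
    tifffile.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


_CSV_EXT = {".csv"}
_TIFF_EXT = {".tif", ".tiff"}


def discover_inputs(folder) -> InputBundle:
    """Identify input files in ``folder`` by filename keyword.

    Keywords are matched case-insensitively as substrings: ``landmark`` and
    ``gold`` against CSV files, ``mask`` and ``image`` against TIFFs (the
    extension split keeps e.g. ``mask_landmark.csv`` out of the mask slot, and
    ``landmark`` is matched before ``mask`` since it contains "mark" but never
    "mask"). A keyword matching two or more files is an ambiguity error;
    missing mask or gold CSV is a missing-input error. The result does not
    depend on directory listing order.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise MissingInputError(f"input folder {folder} does not exist")
    files = sorted(p for p in folder.iterdir() if p.is_file())

    def match(keyword: str, exts, pool):
        hits = [
            p for p in pool if p.suffix.lower() in exts and keyword in p.name.lower()
        ]
        if len(hits) > 1:
            raise AmbiguousInputError(keyword, hits)
        return hits[0] if hits else None

    remaining = list(files)
    landmark = match("landmark", _CSV_EXT, remaining)
    if landmark is not None:
        remaining.remove(landmark)
    gold = match("gold", _CSV_EXT, remaining)
    mask = match("mask", _TIFF_EXT, remaining)
    image = match("image", _TIFF_EXT, remaining)

    if mask is None:
        raise MissingInputError(f"no file matching keyword 'mask' (TIFF) in {folder}")
    if gold is None:
        raise MissingInputError(f"no file matching keyword 'gold' (CSV) in {folder}")
    return InputBundle(
        mask_path=mask,
        gold_csv_path=gold,
        image_path=image,
        landmark_csv_path=landmark,
    )


#: per-workflow result schemas: column -> kind ("length", "area", or "raw")
RESULT_SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "nnd": {
        "id": "raw",
        "x": "length",
        "y": "length",
        "neighbor_id": "raw",
        "neighbor_x": "length",
        "neighbor_y": "length",
        "distance": "length",
    },
    "cluster_summary": {
        "cluster_id": "raw",
        "size": "raw",
        "area": "area",
        "density": "inv_area",
    },
    "cluster_membership": {
        "id": "raw",
        "x": "length",
        "y": "length",
        "cluster_id": "raw",
    },
    "separation": {
        "cluster_id": "raw",
        "centroid_x": "length",
        "centroid_y": "length",
        "neighbor_cluster_id": "raw",
        "distance": "length",
    },
    "rippler": {
        "radius": "length",
        "particle_pct": "raw",
        "area_pct": "raw",
        "lcpi": "raw",
        "n_total": "raw",
    },
}


def write_results_csv(
    records: Sequence[Mapping],
    path,
    scale: ScaleSpec = ScaleSpec(),
    schema: Optional[Mapping[str, str]] = None,
) -> Path:
    """Write workflow records to CSV, converting units per ``scale``.

    ``schema`` maps each column to ``"length"``, ``"area"``, ``"inv_area"``
    or ``"raw"``; columns absent from the schema pass through unchanged. An
    empty record list with a schema yields a header-only file. Row order is
    the caller's (workflows emit deterministic id order).
    """
    path = Path(path)
    if records:
        df = pd.DataFrame(list(records))
    elif schema is not None:
        df = pd.DataFrame(columns=list(schema))
    else:
        raise ValueError("empty records require an explicit schema for the header")
    if schema is not None:
        for col, kind in schema.items():
            if col not in df.columns or kind == "raw":
                continue
            if kind == "length":
                df[col] = scale.length(df[col].to_numpy(dtype=float))
            elif kind == "area":
                df[col] = scale.area(df[col].to_numpy(dtype=float))
            elif kind == "inv_area":
                df[col] = df[col].to_numpy(dtype=float) / scale.area_factor
            else:
                raise ValueError(f"unknown column kind {kind!r}")
    try:
        df.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def write_points_csv(points: ParticlePointSet, path) -> Path:
    """Write a point set back to the ``X``/``Y`` CSV convention."""
    path = Path(path)
    pd.DataFrame({"X": points.x, "Y": points.y}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def result_filename(workflow: str, input_stem: str, random: bool = False) -> str:
    """``<workflow>_<stem>.csv`` / ``<workflow>_random_<stem>.csv``."""
    middle = "random_" if random else ""
    return f"{workflow}_{middle}{input_stem}.csv"
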