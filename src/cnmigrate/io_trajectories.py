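"""Reading, validation and serialization of coupled cell/nucleus centroid tracks.

A *track table* is a tidy :class:`pandas.DataFrame` with one row per frame per
cell and the columns

``movie_id, cell_id, frame, time_min, cell_x, cell_y, nuc_x, nuc_y``

where coordinates are micrometres and ``time_min`` is the acquisition time in
minutes.  Tables are sorted by ``(movie_id, cell_id, frame)``;
``(movie_id, cell_id, frame)`` is unique and time is strictly increasing
within a cell.  The nominal frame spacing is one minute; other spacings are
allowed but flagged by :func:`validate_tracks`.

Coordinate convention for masks: ``x`` is the column index, ``y`` the row
index, origin at the image top-left, pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACK_COLUMNS = (
    "movie_id",
    "cell_id",
    "frame",
    "time_min",
    "cell_x",
    "cell_y",
    "nuc_x",
    "nuc_y",
)
COORD_COLUMNS = ("cell_x", "cell_y", "nuc_x", "nuc_y")
KEY_COLUMNS = ("movie_id", "cell_id", "frame")


class SchemaError(ValueError):
    """A required column is missing or has an unusable type."""


class TrackValidationError(ValueError):
    """The table violates a hard track-table invariant."""


@dataclass
class ValidationReport:
    """Summary counts and soft warnings for a track table.

    ``n_intervals`` is the number of consecutive-frame displacement
    intervals, i.e. ``sum(frames_per_cell - 1)`` over all cells.
    """

    n_movies: int = 0
    n_cells: int = 0
    n_intervals: int = 0
    warnings: list = field(default_factory=list)

    def add(self, code: str, message: str, location: str = "") -> None:
        self.warnings.append((code, message, location))

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)

    def to_dict(self) -> dict:
        return {
            "n_movies": self.n_movies,
            "n_cells": self.n_cells,
            "n_intervals": self.n_intervals,
            "warnings": [list(w) for w in self.warnings],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_tracks(
    path,
    *,
    delimiter: str | None = None,
    pixel_size: float | None = None,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read a coupled-centroid track table from CSV/TSV.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    delimiter : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.tsv``/``.tab`` -> tab, otherwise comma).
    pixel_size : float, optional
        If the file stores coordinates in pixels, the pixel edge length in
        µm/px; coordinates are multiplied by it.  Omit when coordinates are
        already in µm.
    column_map : dict, optional
        Mapping from file column names to the canonical names in
        :data:`TRACK_COLUMNS`, so exports from external trackers can be
        adapted without editing files.

    Returns
    -------
    pandas.DataFrame
        Canonical track table in µm, sorted by ``(movie_id, cell_id, frame)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    if column_map:
        df = df.rename(columns={src: dst for src, dst in column_map.items()})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(TRACK_COLUMNS)].copy()
    df["frame"] = df["frame"].astype(np.int64)
    if (df["frame"] < 0).any():
        raise TrackValidationError("negative frame indices present")
    df["time_min"] = df["time_min"].astype(float)
    for c in COORD_COLUMNS:
        df[c] = df[c].astype(float)
    if pixel_size is not None:
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for c in COORD_COLUMNS:
            df[c] = df[c] * float(pixel_size)
    if not np.isfinite(df[list(COORD_COLUMNS) + ["time_min"]].to_numpy()).all():
        raise TrackValidationError("non-finite coordinate or time values present")
    df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(list(KEY_COLUMNS))
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].drop_duplicates().head(5)
        listing = "; ".join(
            f"({r.movie_id}, {r.cell_id}, frame {r.frame})" for r in keys.itertuples()
        )
        raise TrackValidationError(f"duplicated (movie_id, cell_id, frame) keys: {listing}")
    dt = df.groupby(["movie_id", "cell_id"], sort=False)["time_min"].diff()
    bad = dt.notna() & (dt <= 0)
    if bad.any():
        row = df.loc[bad.idxmax()]
        raise TrackValidationError(
            f"time_min not strictly increasing within cell "
            f"({row.movie_id}, {row.cell_id}) at frame {row.frame}"
        )
    return df


def write_tracks(tracks: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    """Write a track table as delimited text (full float precision)."""
    tracks.loc[:, list(TRACK_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def validate_tracks(
    tracks: pd.DataFrame, *, dt_min: float = 1.0, spacing_tol: float = 0.01
) -> ValidationReport:
    """Count movies/cells/intervals and flag soft anomalies.

    Warnings (never exceptions): single-frame cells, non-consecutive frame
    numbers, and frame spacings deviating from ``dt_min`` by more than
    ``spacing_tol`` (relative).  The input is not modified.
    """
    report = ValidationReport()
    report.n_movies = tracks["movie_id"].nunique()
    grouped = tracks.groupby(["movie_id", "cell_id"], sort=False)
    report.n_cells = grouped.ngroups
    for (movie, cell), g in grouped:
        loc = f"movie={movie} cell={cell}"
        n = len(g)
        report.n_intervals += max(n - 1, 0)
        if n < 2:
            report.add("single_frame", "cell has a single frame; no intervals", loc)
            continue
        frames = g["frame"].to_numpy()
        gaps = np.flatnonzero(np.diff(frames) != 1)
        for i in gaps:
            report.add(
                "frame_gap",
                f"non-consecutive frames {frames[i]} -> {frames[i + 1]}",
                loc,
            )
        dts = np.diff(g["time_min"].to_numpy())
        off = np.flatnonzero(np.abs(dts - dt_min) > spacing_tol * dt_min)
        for i in off:
            report.add(
                "time_spacing",
                f"frame spacing {dts[i]:g} min deviates from nominal {dt_min:g} min "
                f"between frames {frames[i]} and {frames[i + 1]}",
                loc,
            )
    return report


def centroid_from_mask(mask, origin=(0.0, 0.0), pixel_size: float = 1.0):
    """Geometric (unweighted) centroid of a binary mask, in µm.

    ``origin`` is the (x, y) pixel offset of the mask's top-left pixel within
    the full image; ``pixel_size`` is µm/px.  Returns ``(x, y)`` with x along
    columns and y along rows.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask has no foreground pixels")
    x = (cols.mean() + origin[0]) * pixel_size
    y = (rows.mean() + origin[1]) * pixel_size
    return float(x), float(y)


def read_mask(path) -> np.ndarray:
    """Read a single-page binary mask from a TIFF file."""
    import tifffile

    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    return arr != 0


def write_profile(profile, path) -> None:
    """Serialize a :class:`~cnmigrate.cn_core.CNProfile` to JSON."""
    payload = {
        "label": profile.label,
        "source": list(profile.source),
        "pairs": {c: profile.pairs[c].tolist() for c in profile.pairs.columns},
    }
    Path(path).write_text(json.dumps(payload))


def read_profile(path):
    """Load a :class:`~cnmigrate.cn_core.CNProfile` written by :func:`write_profile`."""
    from .cn_core import CNProfile

    payload = json.loads(Path(path).read_text())
    pairs = pd.DataFrame(payload["pairs"])
    return CNProfile(label=payload["label"], pairs=pairs, source=tuple(payload["source"]))
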