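"""Per-tumour cell-coordinate tables.

A tumour section is reduced to a table of typed cell positions: every row is
one nucleus with coordinates in micrometres and a class label in
``{cancer, lymphocyte, stromal}``.  Coordinates follow the image convention
(origin top-left, x rightward, y downward); all geometry downstream is
convention-agnostic, so this matters only for plotting.

The on-disk format is a comma-separated, UTF-8 table with a header row and
required columns ``x,y,class`` plus optional ``cell_id`` and ``section``
(multi-section tumours placed on one slide are pooled into a single map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_CLASSES = ("cancer", "lymphocyte", "stromal")

_REQUIRED_COLUMNS = ("x", "y", "class")
_OPTIONAL_COLUMNS = ("cell_id", "section")


class CellTableError(ValueError):
    """Raised when a cell table violates the format contract."""


@dataclass
class CellMap:
    """One tumour's typed cell coordinates.

    Parameters
    ----------
    tumour_id
        Sample identifier.
    cells
        DataFrame with columns ``x``, ``y`` (μm, float) and ``class``
        (one of :data:`CELL_CLASSES`); optional ``cell_id``/``section``.
    window
        Bounding rectangle ``(xmin, ymin, xmax, ymax)`` in μm.  Defaults to
        the data bounding box.
    """

    tumour_id: str
    cells: pd.DataFrame
    window: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.cells.reset_index(drop=True)
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CellTableError(f"cell table is missing required column {col!r}")
        bad = ~df["class"].isin(CELL_CLASSES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellTableError(
                f"unknown cell class {df['class'].iloc[row]!r} in row {row} "
                f"(allowed: {', '.join(CELL_CLASSES)})"
            )
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            row = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise CellTableError(f"non-finite coordinate in row {row}")
        df["x"] = xy[:, 0]
        df["y"] = xy[:, 1]
        if self.window is None:
            if len(df):
                self.window = (
                    float(xy[:, 0].min()),
                    float(xy[:, 1].min()),
                    float(xy[:, 0].max()),
                    float(xy[:, 1].max()),
                )
            else:
                self.window = (0.0, 0.0, 0.0, 0.0)
        xmin, ymin, xmax, ymax = self.window
        if xmin > xmax or ymin > ymax:
            raise CellTableError(f"invalid window {self.window}")
        if len(df):
            eps = 1e-9
            inside = (
                (xy[:, 0] >= xmin - eps)
                & (xy[:, 0] <= xmax + eps)
                & (xy[:, 1] >= ymin - eps)
                & (xy[:, 1] <= ymax + eps)
            )
            if not inside.all():
                row = int(np.flatnonzero(~inside)[0])
                raise CellTableError(f"coordinate outside window in row {row}")
        self.cells = df

    # -- convenience accessors -------------------------------------------------
    def positions(self, cell_class: str) -> np.ndarray:
        """(k, 2) array of coordinates for one cell class, in table order."""
        sel = self.cells["class"] == cell_class
        return self.cells.loc[sel, ["x", "y"]].to_numpy(dtype=float)

    @property
    def cancer_xy(self) -> np.ndarray:
        return self.positions("cancer")

    @property
    def lymphocyte_xy(self) -> np.ndarray:
        return self.positions("lymphocyte")

    @property
    def lymphocyte_index(self) -> np.ndarray:
        """Row indices (into ``cells``) of the lymphocytes, in table order."""
        return np.flatnonzero((self.cells["class"] == "lymphocyte").to_numpy())

    @property
    def n_cancer(self) -> int:
        return int((self.cells["class"] == "cancer").sum())

    @property
    def n_lymphocyte(self) -> int:
        return int((self.cells["class"] == "lymphocyte").sum())

    @property
    def n_stromal(self) -> int:
        return int((self.cells["class"] == "stromal").sum())

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    def translated(self, dx: float, dy: float) -> "CellMap":
        df = self.cells.copy()
        df["x"] += dx
        df["y"] += dy
        xmin, ymin, xmax, ymax = self.window
        return CellMap(self.tumour_id, df, (xmin + dx, ymin + dy, xmax + dx, ymax + dy))

    def scaled(self, c: float) -> "CellMap":
        """Rescale all coordinates by a positive factor ``c``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        df = self.cells.copy()
        df["x"] *= c
        df["y"] *= c
        xmin, ymin, xmax, ymax = self.window
        return CellMap(self.tumour_id, df, (xmin * c, ymin * c, xmax * c, ymax * c))


def read_cell_map(
    path,
    units: str = "um",
    px_size: float | None = None,
    tumour_id: str | None = None,
    window: tuple[float, float, float, float] | None = None,
) -> CellMap:
    """Read and validate a cell table from CSV.

    ``units='px'`` requires ``px_size`` (μm per pixel); coordinates are
    converted to μm on ingest.  Unknown class tokens and non-numeric
    coordinates are rejected with the offending row number (0-based data
    row, i.e. the row after the header).
    """
    if units not in ("um", "px"):
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    if units == "px" and (px_size is None or px_size <= 0):
        raise ValueError("units='px' requires a positive px_size (μm/pixel)")
    df = pd.read_csv(path, dtype={"class": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"{path}: missing required column {col!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CellTableError(f"{path}: non-numeric coordinate {df[col].iloc[row]!r} in row {row}")
        df[col] = vals.astype(float)
    if units == "px":
        df["x"] *= px_size
        df["y"] *= px_size
    keep = [c for c in (*_REQUIRED_COLUMNS, *_OPTIONAL_COLUMNS) if c in df.columns]
    if tumour_id is None:
        import os

        tumour_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CellMap(tumour_id, df[keep], window)


def write_cell_map(cell_map: CellMap, path) -> None:
    """Write a CellMap back to CSV (full float precision; exact roundtrip)."""
    cell_map.cells.to_csv(path, index=False)


def summarize_cell_map(cell_map: CellMap) -> dict:
    """Per-class counts, window area and per-class intensity (cells/μm²).

    An empty map yields an all-zero summary with a warning rather than an
    error.  Counts always partition the total.
    """
    counts = {c: int((cell_map.cells["class"] == c).sum()) for c in CELL_CLASSES}
    total = int(len(cell_map.cells))
    if total == 0:
        warnings.warn(f"cell map {cell_map.tumour_id!r} is empty", stacklevel=2)
    area = cell_map.area
    intensity = {c: (counts[c] / area if area > 0 else float("nan")) for c in CELL_CLASSES}
    return {
        "tumour_id": cell_map.tumour_id,
        "n_total": total,
        "n_cancer": counts["cancer"],
        "n_lymphocyte": counts["lymphocyte"],
        "n_stromal": counts["stromal"],
        "area_um2": area,
        "intensity": intensity,
    }
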