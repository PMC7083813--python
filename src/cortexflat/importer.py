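"""Reading and validating lesion measurement files.

A measurement file is a CSV or Excel sheet whose first four columns hold,
in order, one coronal slice per row:

* **MB** — bregma-relative anteroposterior coordinate of the slice (mm,
  anterior positive);
* **M1** — along-surface distance from the medial reference point to the
  medial lesion edge (mm, >= 0);
* **M2** — medial lesion edge to lateral lesion edge (mm, > 0);
* **M3** — lateral lesion edge to the rhinal fissure (mm). When the lesion
  extends lateral to the fissure, M2 is measured medial edge → fissure and
  M3 carries a *negative* value (fissure → lateral edge).

A single non-numeric first row is treated as a header and skipped; fully
empty rows are ignored. An optional fifth column tags each row with a
measurement day for time-series input. Decimal points only — the comma is
strictly a field separator.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ImporterError",
    "SliceMeasurement",
    "MeasurementSet",
    "read_measurements",
    "read_measurement_series",
    "apply_mri_shift",
    "write_measurements",
]

MODALITIES = ("histology", "mri")


class ImporterError(ValueError):
    """Invalid measurement file or measurement metadata."""


@dataclass(frozen=True)
class SliceMeasurement:
    """One coronal slice's MB / M1 / M2 / M3 record (all mm)."""

    mb: float
    m1: float
    m2: float
    m3: float

    def __post_init__(self):
        for name in ("mb", "m1", "m2", "m3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ImporterError(f"{name} must be finite, got {v}")
        if self.m1 < 0:
            raise ImporterError(f"m1 must be >= 0, got {self.m1}")
        if self.m2 <= 0:
            raise ImporterError(f"m2 must be > 0, got {self.m2}")

    @property
    def crosses_fissure(self) -> bool:
        """True when the lesion extends lateral to the rhinal fissure."""
        return self.m3 < 0


@dataclass(frozen=True)
class MeasurementSet:
    """Ordered slices for one animal and measurement day.

    Slices are stored sorted by ascending MB; duplicate MB values are
    rejected because the contour construction assumes a single medial /
    lateral edge pair per anteroposterior level. ``slice_depth`` (mm) is
    required for MRI sets and is the voxel size along the AP axis.
    """

    slices: tuple[SliceMeasurement, ...]
    day: int = 1
    modality: str = "histology"
    slice_depth: float | None = None
    ap_shift_applied: bool = field(default=False)

    def __post_init__(self):
        if not self.slices:
            raise ImporterError("measurement set must contain at least one slice")
        if self.day < 1:
            raise ImporterError(f"day must be >= 1, got {self.day}")
        if self.modality not in MODALITIES:
            raise ImporterError(f"modality must be one of {MODALITIES}")
        if self.modality == "mri":
            if self.slice_depth is None or self.slice_depth <= 0:
                raise ImporterError("MRI sets require slice_depth > 0")
        ordered = tuple(sorted(self.slices, key=lambda s: s.mb))
        mbs = [s.mb for s in ordered]
        if len(set(mbs)) != len(mbs):
            dup = next(v for v in mbs if mbs.count(v) > 1)
            raise ImporterError(
                f"duplicate MB value {dup} mm: one edge pair per AP level required")
        object.__setattr__(self, "slices", ordered)

    @property
    def mb_values(self) -> np.ndarray:
        return np.array([s.mb for s in self.slices])


# ---------------------------------------------------------------------------
# file reading

def _load_table(source, fmt: str | None) -> pd.DataFrame:
    """Load the raw table (no header interpretation) from path/bytes/str."""
    is_text = isinstance(source, str) and (
        "\n" in source or ("," in source and not Path(source).exists()))
    if isinstance(source, (str, Path)) and not is_text and fmt is None:
        fmt = Path(source).suffix.lstrip(".").lower() or "csv"
    fmt = (fmt or "csv").lower()
    if fmt == "xls":
        raise ImporterError(
            "legacy .xls workbooks are not supported; save as .xlsx or CSV")
    if fmt not in ("csv", "xlsx"):
        raise ImporterError(f"unsupported format {fmt!r} (use csv or xlsx)")

    if isinstance(source, bytes):
        buf: io.IOBase = io.BytesIO(source)
    elif is_text:
        buf = io.StringIO(source)
    else:
        buf = source  # path-like or open file
    try:
        if fmt == "csv":
            df = pd.read_csv(buf, header=None, dtype=str, sep=",",
                             skip_blank_lines=True, engine="python")
        else:
            df = pd.read_excel(buf, header=None, dtype=str, sheet_name=0,
                               engine="openpyxl")
    except ImporterError:
        raise
    except Exception as exc:
        raise ImporterError(f"could not parse measurement file: {exc}") from exc
    return df


def _is_number(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    try:
        float(str(cell).strip())
        return True
    except ValueError:
        return False


def _parse_rows(df: pd.DataFrame) -> list[tuple[int, list[float]]]:
    """Interpret the raw table: header autodetect, empty-row skip, numeric
    coercion. Returns (1-based source row number, [values...]) pairs."""
    if df.shape[1] < 4:
        raise ImporterError(
            f"measurement file must have at least 4 columns (MB, M1, M2, M3), "
            f"found {df.shape[1]}")
    rows: list[tuple[int, list[float]]] = []
    start = 0
    first = df.iloc[0, :4].tolist() if len(df) else []
    if first and any(not _is_number(c) for c in first):
        start = 1  # header row
    for idx in range(start, len(df)):
        cells = df.iloc[idx].tolist()
        if all(c is None or (isinstance(c, float) and math.isnan(c))
               or str(c).strip() == "" for c in cells):
            continue
        values = []
        for col in range(df.shape[1]):
            cell = cells[col] if col < len(cells) else None
            if col < 4 and not _is_number(cell):
                raise ImporterError(
                    f"row {idx + 1}: non-numeric value {cell!r} in column {col + 1}")
            values.append(float(str(cell).strip()) if _is_number(cell) else math.nan)
        rows.append((idx + 1, values))
    if not rows:
        raise ImporterError("measurement file contains no data rows")
    return rows


def _slice_from_row(rownum: int, values: list[float]) -> SliceMeasurement:
    try:
        return SliceMeasurement(mb=values[0], m1=values[1], m2=values[2],
                                m3=values[3])
    except ImporterError as exc:
        raise ImporterError(f"row {rownum}: {exc}") from exc


def read_measurements(source, fmt: str | None = None, day: int = 1,
                      modality: str = "histology",
                      slice_depth: float | None = None) -> MeasurementSet:
    """Read one measurement file into a single MeasurementSet.

    ``source`` may be a path, raw bytes, CSV text, or an open file;
    ``fmt`` ('csv' or 'xlsx') is inferred from a path suffix when omitted.
    """
    rows = _parse_rows(_load_table(source, fmt))
    slices = tuple(_slice_from_row(n, v) for n, v in rows)
    return MeasurementSet(slices=slices, day=day, modality=modality,
                          slice_depth=slice_depth)


def read_measurement_series(source, fmt: str | None = None, day: int = 1,
                            modality: str = "histology",
                            slice_depth: float | None = None
                            ) -> dict[int, MeasurementSet]:
    """Read a file whose optional fifth column tags rows with a measurement
    day, returning one MeasurementSet per day (``{day: set}``, days sorted).

    Files without a day column yield a single entry under ``day``.
    """
    rows = _parse_rows(_load_table(source, fmt))
    has_day = all(len(v) >= 5 and math.isfinite(v[4]) for _, v in rows)
    groups: dict[int, list] = {}
    for rownum, values in rows:
        d = int(values[4]) if has_day else day
        groups.setdefault(d, []).append(_slice_from_row(rownum, values))
    return {
        d: MeasurementSet(slices=tuple(sls), day=d, modality=modality,
                          slice_depth=slice_depth)
        for d, sls in sorted(groups.items())
    }


# ---------------------------------------------------------------------------
# MRI half-voxel shift

def apply_mri_shift(ms: MeasurementSet, direction: int = +1) -> MeasurementSet:
    """Shift MB by half the AP voxel size for MRI measurement sets.

    MRI slice coordinates refer to the slice centre, so measurements are
    shifted along the AP axis by ``slice_depth / 2``. The anatomical
    direction is configurable: ``direction=+1`` (default) shifts anterior,
    ``-1`` posterior. Histology sets are returned unchanged with a logged
    notice. The shift is recorded and a second application is refused.
    """
    if ms.modality != "mri":
        log.info("apply_mri_shift: histology set left unchanged")
        return ms
    if ms.ap_shift_applied:
        raise ImporterError("half-voxel AP shift already applied to this set")
    if direction not in (-1, +1):
        raise ValueError("direction must be +1 (anterior) or -1 (posterior)")
    delta = direction * ms.slice_depth / 2.0
    shifted = tuple(replace(s, mb=s.mb + delta) for s in ms.slices)
    return replace(ms, slices=shifted, ap_shift_applied=True)


def write_measurements(ms: MeasurementSet, include_day: bool = False) -> str:
    """Serialize a MeasurementSet back to CSV text at full float precision."""
    lines = ["MB,M1,M2,M3" + (",day" if include_day else "")]
    for s in ms.slices:
        row = f"{s.mb!r},{s.m1!r},{s.m2!r},{s.m3!r}"
        if include_day:
            row += f",{ms.day}"
        lines.append(row)
    return "\n".join(lines) + "\n"
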