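"""Fixation-event tables and mapped-fixation output.

Fixation events are consumed as exported by eye-tracking analysis
software (one row per fixation: start, duration, end, gaze x, gaze y);
fixation detection itself happens upstream. Column names, delimiter and
time unit vary between vendors, so the reader takes a dialect
configuration instead of hard-coding a header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "RecordingMeta",
    "FixationEvent",
    "MappedFixation",
    "DialectConfig",
    "FixationTableError",
    "read_fixation_table",
    "write_mapped_fixations",
    "read_mapped_fixations",
]

BACKGROUND_LABEL = "BG"


class FixationTableError(ValueError):
    """A fixation table violates the declared dialect or its invariants."""


@dataclass(frozen=True)
class RecordingMeta:
    """Scene-camera recording parameters.

    Attributes
    ----------
    width, height : int
        Scene-video resolution in pixels.
    fps : float
        Scene-video frame rate in frames per second.
    gaze_accuracy_deg : float
        Tracker accuracy in degrees of visual angle (informational;
        not used by the mapping itself).
    """

    width: int
    height: int
    fps: float
    gaze_accuracy_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class FixationEvent:
    """One fixation with timing and a single representative gaze point.

    Times are milliseconds from video start; the gaze coordinate is in
    scene-camera pixels with the origin at the top-left corner, x
    rightward and y downward. Coordinates may lie outside the frame;
    they are flagged during mapping, not rejected here.
    """

    fixation_id: int
    start_ms: float
    duration_ms: float
    end_ms: float
    gaze_x: float
    gaze_y: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(
                f"fixation {self.fixation_id}: duration must be positive"
            )
        if abs(self.end_ms - (self.start_ms + self.duration_ms)) > 1.0:
            raise ValueError(
                f"fixation {self.fixation_id}: end != start + duration "
                f"({self.end_ms} vs {self.start_ms + self.duration_ms})"
            )


@dataclass(frozen=True)
class MappedFixation:
    """A fixation with its assigned AOI label and the frame used."""

    fixation_id: int
    start_ms: float
    duration_ms: float
    end_ms: float
    gaze_x: float
    gaze_y: float
    frame_index: int
    aoi_label: str
    in_bounds: bool

    @property
    def event(self) -> FixationEvent:
        return FixationEvent(
            self.fixation_id,
            self.start_ms,
            self.duration_ms,
            self.end_ms,
            self.gaze_x,
            self.gaze_y,
        )


#: default column names understood without any configuration
_DEFAULT_COLUMNS = {
    "start": "start_ms",
    "duration": "duration_ms",
    "end": "end_ms",
    "x": "gaze_x",
    "y": "gaze_y",
}


@dataclass(frozen=True)
class DialectConfig:
    """How to read one vendor's fixation export.

    ``columns`` maps the logical fields ``start``, ``duration``, ``end``,
    ``x``, ``y`` to the column names in the file. ``end`` (or exactly one
    of ``end``/``duration``) may be omitted; the missing one is derived.
    ``time_unit`` is ``"ms"`` or ``"s"``.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    time_unit: str = "ms"

    def __post_init__(self) -> None:
        if self.time_unit not in ("ms", "s"):
            raise ValueError("time_unit must be 'ms' or 's'")


def read_fixation_table(
    path,
    dialect: DialectConfig | None = None,
    meta: RecordingMeta | None = None,
) -> list[FixationEvent]:
    """Read a delimited fixation-event table.

    Events are returned sorted by start time with ``fixation_id``
    assigned 1..N in temporal order. If both end and duration columns
    are present they must agree to within 1 ms per row; if one is
    missing it is computed from the other.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    dialect : DialectConfig, optional
        Column map, delimiter and time unit; defaults to comma-separated
        ``start_ms, duration_ms, end_ms, gaze_x, gaze_y`` in milliseconds.
    meta : RecordingMeta, optional
        Unused by parsing; accepted for pipeline symmetry.

    Raises
    ------
    FixationTableError
        On a missing required column, an unparseable row, or an
        end/duration mismatch greater than 1 ms.
    """
    dialect = dialect or DialectConfig()
    cols = dialect.columns
    try:
        df = pd.read_csv(path, sep=dialect.delimiter)
    except pd.errors.EmptyDataError as exc:
        raise FixationTableError(f"{path}: empty fixation table") from exc

    for logical in ("start", "x", "y"):
        if cols.get(logical) not in df.columns:
            raise FixationTableError(
                f"{path}: required column '{cols.get(logical, logical)}' "
                f"(field '{logical}') not found; header is {list(df.columns)}"
            )
    have_dur = cols.get("duration") in df.columns
    have_end = cols.get("end") in df.columns
    if not (have_dur or have_end):
        raise FixationTableError(
            f"{path}: need a duration column ('{cols.get('duration')}') "
            f"or an end column ('{cols.get('end')}')"
        )

    scale = 1000.0 if dialect.time_unit == "s" else 1.0

    def _num(row_idx, column):
        raw = df.iloc[row_idx][column]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise FixationTableError(
                f"{path}: row {row_idx + 2}: cannot parse '{raw}' in column "
                f"'{column}'"
            ) from None
        if pd.isna(value):
            raise FixationTableError(
                f"{path}: row {row_idx + 2}: missing value in column '{column}'"
            )
        return value

    events = []
    for i in range(len(df)):
        start = _num(i, cols["start"]) * scale
        if have_dur:
            duration = _num(i, cols["duration"]) * scale
        if have_end:
            end = _num(i, cols["end"]) * scale
        if have_dur and have_end:
            if abs(end - (start + duration)) > 1.0:
                raise FixationTableError(
                    f"{path}: row {i + 2}: end {end} inconsistent with "
                    f"start+duration {start + duration} by more than 1 ms"
                )
        elif have_dur:
            end = start + duration
        else:
            duration = end - start
        if duration <= 0:
            raise FixationTableError(
                f"{path}: row {i + 2}: non-positive duration {duration} ms"
            )
        events.append(
            FixationEvent(
                fixation_id=0,
                start_ms=start,
                duration_ms=duration,
                end_ms=start + duration,
                gaze_x=_num(i, cols["x"]),
                gaze_y=_num(i, cols["y"]),
            )
        )

    starts = [e.start_ms for e in events]
    if any(b < a for a, b in zip(starts, starts[1:])):
        warnings.warn(
            f"{path}: fixation start times are not monotone; re-sorting",
            stacklevel=2,
        )
        events.sort(key=lambda e: e.start_ms)
    for a, b in zip(events, events[1:]):
        # 1 µs slack: adjacent events sharing a boundary are not overlaps
        if b.start_ms < a.end_ms - 1e-3:
            warnings.warn(
                f"{path}: fixations overlap in time near {b.start_ms} ms",
                stacklevel=2,
            )
            break
    return [replace(e, fixation_id=i + 1) for i, e in enumerate(events)]


_MAPPED_COLUMNS = [
    "fixation_id",
    "start_ms",
    "duration_ms",
    "end_ms",
    "gaze_x",
    "gaze_y",
    "frame_index",
    "aoi_label",
    "in_bounds",
]


def write_mapped_fixations(mapped: list[MappedFixation], path) -> None:
    """Write mapped fixations as UTF-8 CSV, one row per fixation.

    The output round-trips losslessly through
    :func:`read_mapped_fixations`. An empty list is an error: an empty
    mapping output almost always signals an upstream failure.
    """
    if not mapped:
        raise ValueError("refusing to write an empty mapped-fixation list")
    df = pd.DataFrame(
        [
            {
                "fixation_id": m.fixation_id,
                "start_ms": m.start_ms,
                "duration_ms": m.duration_ms,
                "end_ms": m.end_ms,
                "gaze_x": m.gaze_x,
                "gaze_y": m.gaze_y,
                "frame_index": m.frame_index,
                "aoi_label": m.aoi_label,
                "in_bounds": m.in_bounds,
            }
            for m in mapped
        ],
        columns=_MAPPED_COLUMNS,
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_mapped_fixations(path) -> list[MappedFixation]:
    """Read back a mapped-fixation CSV written by :func:`write_mapped_fixations`."""
    df = pd.read_csv(path)
    missing = [c for c in _MAPPED_COLUMNS if c not in df.columns]
    if missing:
        raise FixationTableError(f"{path}: missing columns {missing}")
    return [
        MappedFixation(
            fixation_id=int(r.fixation_id),
            start_ms=float(r.start_ms),
            duration_ms=float(r.duration_ms),
            end_ms=float(r.end_ms),
            gaze_x=float(r.gaze_x),
            gaze_y=float(r.gaze_y),
            frame_index=int(r.frame_index),
            aoi_label=str(r.aoi_label),
            in_bounds=bool(r.in_bounds),
        )
        for r in df.itertuples()
    ]
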