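"""Typed beat-to-beat series, CSV I/O, and alignment onto a common beat grid.

Physiological inputs are event series, not uniformly sampled signals: each
heartbeat yields one beat-to-beat interval (BBI, ms) and one systolic /
diastolic pressure reading (SBP/DBP, mmHg), while each breath yields one
respiratory cycle length (RESP, s).  BBI, SBP and DBP are beat-synchronous
(they derive from the same pressure wave); RESP lives on its own, slower
breath grid and must be mapped onto beats before any coupling analysis.

The on-disk format is a two-column CSV ``time_s,value`` per signal, with an
optional single header line that is auto-detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "BeatSeries",
    "AlignedRecording",
    "SeriesFormatError",
    "AlignmentError",
    "read_beat_series",
    "write_beat_series",
    "align_signals",
    "write_aligned",
    "read_aligned",
]

log = logging.getLogger(__name__)


class SeriesFormatError(ValueError):
    """Raised for unparseable or invalid per-signal CSV input."""


class AlignmentError(ValueError):
    """Raised when signals cannot be placed on a common beat grid."""


class SignalKind(str, Enum):
    """The four physiological event series handled by the analysis."""

    BBI = "BBI"
    SBP = "SBP"
    DBP = "DBP"
    RESP = "RESP"

    @property
    def units(self) -> str:
        return _UNITS[self]

    @property
    def per_beat(self) -> bool:
        """True for signals with one sample per heartbeat (BBI/SBP/DBP)."""
        return self is not SignalKind.RESP


_UNITS = {
    SignalKind.BBI: "ms",
    SignalKind.SBP: "mmHg",
    SignalKind.DBP: "mmHg",
    SignalKind.RESP: "s",
}


@dataclass(frozen=True)
class BeatSeries:
    """One event series: strictly increasing onset times plus one value each.

    For RESP the value is the length of the breathing cycle starting at the
    onset time (s); for the per-beat kinds it is the interval or pressure
    associated with the beat at that time.
    """

    kind: SignalKind
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "kind", SignalKind(self.kind))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise SeriesFormatError("times and values must be 1-D and equally long")
        if len(times) == 0:
            raise SeriesFormatError("empty series")
        if not (np.isfinite(times).all() and np.isfinite(values).all()):
            raise SeriesFormatError("non-finite entries in series")
        if np.any(np.diff(times) <= 0):
            bad = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 1
            raise SeriesFormatError(
                f"times not strictly increasing at sample {bad} (t={times[bad]!r})"
            )
        if np.any(values <= 0):
            raise SeriesFormatError(f"{self.kind.value} values must be positive")

    def __len__(self) -> int:
        return len(self.times)


def read_beat_series(path: str | Path, kind: SignalKind | str) -> BeatSeries:
    """Read one signal from a two-column CSV ``time_s,value``.

    A single non-numeric first line is treated as a header.  Rows with
    non-finite entries are dropped with a warning; non-monotonic times are a
    hard error naming the first offending file row (1-based, header included).
    """
    kind = SignalKind(kind)
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, skip_blank_lines=True, dtype=str)
    except pd.errors.EmptyDataError:
        raise SeriesFormatError(f"{path}: empty file") from None
    if raw.shape[1] < 2:
        raise SeriesFormatError(f"{path}: expected two columns time_s,value")

    first_row_offset = 1  # 1-based file row of the first data row
    t0 = pd.to_numeric(raw.iloc[0, 0], errors="coerce")
    if pd.isna(t0):  # header line
        raw = raw.iloc[1:]
        first_row_offset = 2
        if raw.empty:
            raise SeriesFormatError(f"{path}: no data rows")

    times = pd.to_numeric(raw.iloc[:, 0], errors="coerce").to_numpy(float)
    values = pd.to_numeric(raw.iloc[:, 1], errors="coerce").to_numpy(float)
    rows = np.arange(len(times)) + first_row_offset

    finite = np.isfinite(times) & np.isfinite(values)
    if not finite.all():
        n_bad = int((~finite).sum())
        log.warning("%s: dropped %d row(s) with non-finite entries", path, n_bad)
        times, values, rows = times[finite], values[finite], rows[finite]
    if len(times) == 0:
        raise SeriesFormatError(f"{path}: no valid data rows")

    non_mono = np.nonzero(np.diff(times) <= 0)[0]
    if non_mono.size:
        bad_row = int(rows[non_mono[0] + 1])
        raise SeriesFormatError(
            f"{path}: time not strictly increasing at row {bad_row}"
        )
    return BeatSeries(kind=kind, times=times, values=values, label=path.stem)


def write_beat_series(series: BeatSeries, path: str | Path) -> None:
    """Write a series as ``time_s,value`` CSV (full float precision)."""
    pd.DataFrame({"time_s": series.times, "value": series.values}).to_csv(
        path, index=False
    )


@dataclass(frozen=True)
class AlignedRecording:
    """2–3 signals resampled onto a common beat grid — the 3D point cloud.

    Axis order is meaningful and preserved downstream: the first signal maps
    to rows (X), the second to columns (Y), the third to depth (Z) of the
    cubic box model.
    """

    signals: tuple[SignalKind, ...]
    points: np.ndarray  # (N, k)
    beat_times: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        beat_times = np.asarray(self.beat_times, dtype=float)
        signals = tuple(SignalKind(s) for s in self.signals)
        object.__setattr__(self, "signals", signals)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "beat_times", beat_times)
        if points.ndim != 2 or points.shape[1] != len(signals):
            raise AlignmentError("points must be N×k with one column per signal")
        if not 2 <= len(signals) <= 3:
            raise AlignmentError("2 or 3 signals required")
        if points.shape[0] < 3:
            raise AlignmentError("fewer than 3 aligned beats")
        if len(beat_times) != points.shape[0]:
            raise AlignmentError("beat_times length mismatch")
        if not np.isfinite(points).all():
            raise AlignmentError("missing entries in aligned points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        """Arithmetic mean per axis — the 'main focus' of the point cloud."""
        return self.points.mean(axis=0)

    def sd(self, ddof: int = 1) -> np.ndarray:
        return self.points.std(axis=0, ddof=ddof)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=[s.value for s in self.signals])
        frame.insert(0, "beat_time", self.beat_times)
        return frame


def align_signals(
    series: list[BeatSeries] | tuple[BeatSeries, ...],
    method: str = "previous_event",
) -> AlignedRecording:
    """Place 2–3 event series onto the common beat grid.

    The beat grid is the onset times of the first per-beat signal listed,
    intersected with those of any further per-beat signals (exact time
    match).  RESP is mapped onto each beat either by ``previous_event``
    (the cycle length of the breath ongoing at the beat — causal step hold)
    or ``linear`` (two-point interpolation of cycle length between breath
    onsets).  Beats preceding the first breath are dropped.
    """
    series = list(series)
    if not 2 <= len(series) <= 3:
        raise AlignmentError("align_signals needs 2 or 3 series")
    kinds = [s.kind for s in series]
    if len(set(kinds)) != len(kinds):
        raise AlignmentError("duplicate signal kinds")
    if method not in ("previous_event", "linear"):
        raise AlignmentError(f"unknown alignment method {method!r}")

    per_beat = [s for s in series if s.kind.per_beat]
    if not per_beat:
        raise AlignmentError("at least one per-beat signal (BBI/SBP/DBP) required")

    grid = per_beat[0].times
    keep = np.ones(len(grid), dtype=bool)
    # exact-time intersection with the other per-beat series
    for s in per_beat[1:]:
        idx = np.searchsorted(s.times, grid)
        idx_c = np.clip(idx, 0, len(s.times) - 1)
        keep &= s.times[idx_c] == grid

    resp = next((s for s in series if s.kind is SignalKind.RESP), None)
    if resp is not None:
        keep &= grid >= resp.times[0]

    if not keep.any():
        raise AlignmentError("no temporal overlap between the signals")
    beat_times = grid[keep]
    if len(beat_times) < 3:
        raise AlignmentError(f"only {len(beat_times)} beats retained after alignment")

    columns = []
    for s in series:
        if s.kind.per_beat:
            idx = np.searchsorted(s.times, beat_times)
            columns.append(s.values[idx])
        elif method == "previous_event":
            idx = np.searchsorted(s.times, beat_times, side="right") - 1
            columns.append(s.values[idx])
        else:  # linear interpolation of cycle length between breath onsets
            columns.append(np.interp(beat_times, s.times, s.values))

    return AlignedRecording(
        signals=tuple(kinds), points=np.column_stack(columns), beat_times=beat_times
    )


def write_aligned(recording: AlignedRecording, path: str | Path) -> None:
    recording.to_frame().to_csv(path, index=False)


def read_aligned(path: str | Path) -> AlignedRecording:
    frame = pd.read_csv(path)
    kinds = tuple(SignalKind(c) for c in frame.columns[1:])
    return AlignedRecording(
        signals=kinds,
        points=frame.iloc[:, 1:].to_numpy(float),
        beat_times=frame["beat_time"].to_numpy(float),
    )
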