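"""Reading, writing and time-aligning activity-monitor files.

Beam-break activity monitors record, for each of up to 32 fly tubes
(channels), the number of infrared-beam interruptions per minute.
Single-beam monitors have one detector per tube; multi-beam monitors have
17 detectors along the tube and distinguish "moves" (transitions between
adjacent beams, i.e. locomotion along the tube) from "counts" (all beam
breaks, including within-beam twitches and grooming).

File dialect (see ``docs/dam_dialect.md`` for the bit-exact layout):
tab-separated, one row per minute, no header.  The first eight columns are
row index, date (``DD Mon YY``), time (``HH:MM:SS``), a status code
(1 = valid), a channel-status mask (one ``0``/``1`` character per channel;
``0`` marks an empty tube as opposed to an inactive fly) and three reserved
columns.  Single-beam files then carry one count column per channel.
Multi-beam files carry, per channel, 17 per-detector break columns followed
by precomputed ``moves`` and ``counts`` columns (19 columns per channel).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LightSchedule",
    "TemperatureEpoch",
    "ActivityRecording",
    "MultibeamChannelData",
    "MonitorFileError",
    "read_monitor_file",
    "write_monitor_file",
    "write_multibeam_file",
    "to_zt",
    "zt_minutes",
    "write_zt_csv",
    "SINGLE",
    "MULTIBEAM_MOVES",
    "MULTIBEAM_COUNTS",
]

SINGLE = "single"
MULTIBEAM_MOVES = "multibeam_moves"
MULTIBEAM_COUNTS = "multibeam_counts"
BEAM_MODES = (SINGLE, MULTIBEAM_MOVES, MULTIBEAM_COUNTS)

_N_HEADER_COLS = 8
_N_BEAMS = 17
_MB_COLS_PER_CHANNEL = _N_BEAMS + 2  # 17 detectors + moves + counts
_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"

MINUTES_PER_DAY = 1440


class MonitorFileError(ValueError):
    """Raised for malformed monitor files (gaps, negatives, bad layout)."""


@dataclass(frozen=True)
class LightSchedule:
    """A light:dark cycle anchored at lights-on.

    Zeitgeber time (ZT) 0 is lights-on; under the default 12 h photoperiod
    day is ZT [0, 12) h and night ZT [12, 24) h (half-open, so the minute at
    exactly ZT 12 belongs to night).
    """

    lights_on: dt.time = dt.time(8, 0)
    photoperiod_hours: float = 12.0
    period_hours: float = 24.0

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_hours < self.period_hours:
            raise ValueError("need 0 < photoperiod_hours < period_hours")
        if self.period_hours != 24.0:
            raise ValueError("only 24 h cycles are supported")

    @property
    def day_minutes(self) -> int:
        return int(round(self.photoperiod_hours * 60))

    def zt_of(self, when: dt.datetime) -> int:
        """ZT in whole minutes, in [0, 1440), of a wall-clock instant."""
        mins = when.hour * 60 + when.minute
        on = self.lights_on.hour * 60 + self.lights_on.minute
        return (mins - on) % MINUTES_PER_DAY


@dataclass(frozen=True)
class TemperatureEpoch:
    """A half-open [start_minute, end_minute) span at a fixed temperature."""

    label: str  # baseline | activation | recovery
    start_minute: int
    end_minute: int
    temperature_C: float

    def __post_init__(self) -> None:
        if self.end_minute <= self.start_minute:
            raise ValueError("empty temperature epoch")


def validate_temperature_schedule(
    epochs: Sequence[TemperatureEpoch], n_minutes: int | None = None
) -> None:
    """Check that epochs are ordered, non-overlapping and tile the recording."""
    for a, b in zip(epochs, epochs[1:]):
        if b.start_minute != a.end_minute:
            raise ValueError("temperature epochs must tile without gaps")
    if epochs and n_minutes is not None:
        if epochs[0].start_minute != 0 or epochs[-1].end_minute != n_minutes:
            raise ValueError("temperature epochs must cover the recording")
    base = [e.temperature_C for e in epochs if e.label == "baseline"]
    act = [e.temperature_C for e in epochs if e.label == "activation"]
    if base and act and min(act) <= max(base):
        raise ValueError("activation temperature must exceed baseline")


@dataclass
class ActivityRecording:
    """One fly's per-minute activity counts plus experimental metadata."""

    fly_id: str
    channel: int
    minutes: np.ndarray
    start_datetime: dt.datetime
    beam_mode: str = SINGLE
    condition: dict = field(default_factory=dict)
    temperature_schedule: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes)
        if self.minutes.ndim != 1:
            raise ValueError("minutes must be a 1-D vector")
        if not np.issubdtype(self.minutes.dtype, np.integer):
            as_int = self.minutes.astype(np.int64)
            if not np.array_equal(as_int, self.minutes):
                raise ValueError("activity counts must be integers")
            self.minutes = as_int
        if (self.minutes < 0).any():
            raise ValueError("activity counts must be nonnegative")
        if self.beam_mode not in BEAM_MODES:
            raise ValueError(f"unknown beam_mode {self.beam_mode!r}")
        if self.temperature_schedule:
            validate_temperature_schedule(
                list(self.temperature_schedule), len(self.minutes)
            )

    def __len__(self) -> int:
        return len(self.minutes)


@dataclass
class MultibeamChannelData:
    """Per-channel payload of a multi-beam monitor file.

    ``moves`` are adjacent-beam transitions per minute; ``counts`` are all
    beam breaks per minute (moves + within-beam events), so
    ``counts >= moves`` minute by minute.  ``beams``, if given, is the
    (17, n_minutes) per-detector break matrix; otherwise zeros are written.
    """

    moves: np.ndarray
    counts: np.ndarray
    beams: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.moves = np.asarray(self.moves, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.moves.shape != self.counts.shape:
            raise ValueError("moves/counts length mismatch")
        if (self.counts < self.moves).any():
            raise ValueError("counts must be >= moves at every minute")
        if self.beams is not None:
            self.beams = np.asarray(self.beams, dtype=np.int64)
            if self.beams.shape != (_N_BEAMS, len(self.moves)):
                raise ValueError("beams must have shape (17, n_minutes)")


# ---------------------------------------------------------------------------
# reading


def _parse_rows(path: Path) -> tuple[list[list[str]], list[dt.datetime]]:
    rows: list[list[str]] = []
    stamps: list[dt.datetime] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) <= _N_HEADER_COLS:
                raise MonitorFileError(
                    f"{path}:{lineno}: expected >= {_N_HEADER_COLS + 1} columns"
                )
            try:
                stamp = dt.datetime.strptime(
                    f"{fields[1]} {fields[2]}", f"{_DATE_FMT} {_TIME_FMT}"
                )
            except ValueError as exc:
                raise MonitorFileError(f"{path}:{lineno}: bad timestamp") from exc
            rows.append(fields)
            stamps.append(stamp)
    if not rows:
        raise MonitorFileError(f"{path}: empty monitor file")
    return rows, stamps


def _check_timeline(stamps: list[dt.datetime], path: Path) -> None:
    one_min = dt.timedelta(minutes=1)
    for i in range(1, len(stamps)):
        delta = stamps[i] - stamps[i - 1]
        if delta <= dt.timedelta(0):
            raise MonitorFileError(
                f"{path}: non-monotonic timestamps at row {i + 1}"
            )
        if delta != one_min:
            missing = stamps[i - 1] + one_min
            raise MonitorFileError(
                f"{path}: gap in timestamps; first missing minute is "
                f"{missing:%d %b %y %H:%M:%S}"
            )


def read_monitor_file(
    path: str | Path,
    beam_mode: str = SINGLE,
    light_schedule: LightSchedule | None = None,
    conditions: Mapping[int, dict] | None = None,
    include_empty: bool = False,
) -> list[ActivityRecording]:
    """Read a monitor file into one :class:`ActivityRecording` per channel.

    ``beam_mode`` selects the column set: ``"single"`` for single-beam
    files, ``"multibeam_moves"`` / ``"multibeam_counts"`` for the moves or
    counts column of multi-beam files.  Channels flagged empty in the
    channel-status mask are skipped unless ``include_empty`` is set.
    ``conditions`` optionally maps channel number to a condition-label dict.
    """
    if beam_mode not in BEAM_MODES:
        raise ValueError(f"unknown beam_mode {beam_mode!r}")
    path = Path(path)
    rows, stamps = _parse_rows(path)
    _check_timeline(stamps, path)

    ncols = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != ncols:
            raise MonitorFileError(f"{path}: ragged row {i + 1}")
    payload = ncols - _N_HEADER_COLS
    if beam_mode == SINGLE:
        n_channels = payload
    else:
        if payload % _MB_COLS_PER_CHANNEL:
            raise MonitorFileError(
                f"{path}: {payload} data columns is not a whole number of "
                f"multi-beam channels ({_MB_COLS_PER_CHANNEL} per channel)"
            )
        n_channels = payload // _MB_COLS_PER_CHANNEL

    mask_field = rows[0][4]
    if len(mask_field) == n_channels and set(mask_field) <= {"0", "1"}:
        active = [c == "1" for c in mask_field]
    else:
        active = [True] * n_channels

    try:
        data = np.array(
            [[int(v) for v in r[_N_HEADER_COLS:]] for r in rows], dtype=np.int64
        )
    except ValueError as exc:
        raise MonitorFileError(f"{path}: non-integer count value") from exc
    if (data < 0).any():
        r, c = np.argwhere(data < 0)[0]
        raise MonitorFileError(
            f"{path}: negative count at row {r + 1}, data column {c + 1}"
        )

    recordings = []
    stem = path.stem
    for ch in range(1, n_channels + 1):
        if not active[ch - 1] and not include_empty:
            continue
        if beam_mode == SINGLE:
            col = ch - 1
        else:
            base = (ch - 1) * _MB_COLS_PER_CHANNEL
            col = base + _N_BEAMS + (0 if beam_mode == MULTIBEAM_MOVES else 1)
        cond = dict(conditions.get(ch, {})) if conditions else {}
        if not active[ch - 1]:
            cond["channel_status"] = "empty"
        recordings.append(
            ActivityRecording(
                fly_id=f"{stem}#{ch:02d}",
                channel=ch,
                minutes=data[:, col],
                start_datetime=stamps[0],
                beam_mode=beam_mode,
                condition=cond,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# writing


def _header_fields(
    idx: int, stamp: dt.datetime, mask: str
) -> list[str]:
    return [
        str(idx),
        stamp.strftime(_DATE_FMT),
        stamp.strftime(_TIME_FMT),
        "1",
        mask,
        "0",
        "0",
        "0",
    ]


def write_monitor_file(
    recordings: Iterable[ActivityRecording],
    path: str | Path,
    n_channels: int = 32,
) -> None:
    """Write single-beam recordings to a monitor file.

    All recordings must share ``start_datetime`` and length.  Channels not
    present are written as all-zero and flagged ``0`` (empty tube) in the
    channel-status mask, which distinguishes them from an inactive fly.
    """
    recs = list(recordings)
    if not recs:
        raise ValueError("no recordings to write")
    n = len(recs[0])
    start = recs[0].start_datetime
    by_channel: dict[int, ActivityRecording] = {}
    for r in recs:
        if len(r) != n:
            raise ValueError("recordings have mixed lengths")
        if r.start_datetime != start:
            raise ValueError("recordings have mixed start times")
        if not 1 <= r.channel <= n_channels:
            raise ValueError(f"channel {r.channel} outside 1..{n_channels}")
        if r.channel in by_channel:
            raise ValueError(f"duplicate channel {r.channel}")
        by_channel[r.channel] = r

    mask = "".join("1" if ch in by_channel else "0" for ch in range(1, n_channels + 1))
    zeros = np.zeros(n, dtype=np.int64)
    cols = [
        by_channel[ch].minutes if ch in by_channel else zeros
        for ch in range(1, n_channels + 1)
    ]
    with open(path, "w") as fh:
        for m in range(n):
            stamp = start + dt.timedelta(minutes=m)
            fields = _header_fields(m + 1, stamp, mask)
            fields.extend(str(int(c[m])) for c in cols)
            fh.write("\t".join(fields) + "\n")


def write_multibeam_file(
    channels: Mapping[int, MultibeamChannelData],
    start_datetime: dt.datetime,
    path: str | Path,
    n_channels: int = 32,
) -> None:
    """Write a multi-beam monitor file (17 beam columns + moves + counts)."""
    if not channels:
        raise ValueError("no channels to write")
    lengths = {len(c.moves) for c in channels.values()}
    if len(lengths) != 1:
        raise ValueError("channels have mixed lengths")
    n = lengths.pop()
    for ch in channels:
        if not 1 <= ch <= n_channels:
            raise ValueError(f"channel {ch} outside 1..{n_channels}")
    mask = "".join("1" if ch in channels else "0" for ch in range(1, n_channels + 1))
    zeros = np.zeros(n, dtype=np.int64)
    zbeams = np.zeros((_N_BEAMS, n), dtype=np.int64)
    with open(path, "w") as fh:
        for m in range(n):
            stamp = start_datetime + dt.timedelta(minutes=m)
            fields = _header_fields(m + 1, stamp, mask)
            for ch in range(1, n_channels + 1):
                c = channels.get(ch)
                beams = zbeams if c is None or c.beams is None else c.beams
                moves = zeros if c is None else c.moves
                counts = zeros if c is None else c.counts
                fields.extend(str(int(beams[b, m])) for b in range(_N_BEAMS))
                fields.append(str(int(moves[m])))
                fields.append(str(int(counts[m])))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Zeitgeber alignment


def zt_minutes(recording: ActivityRecording, schedule: LightSchedule) -> np.ndarray:
    """ZT in minutes, in [0, 1440), for every minute of the recording."""
    zt0 = schedule.zt_of(recording.start_datetime)
    return (zt0 + np.arange(len(recording))) % MINUTES_PER_DAY


def to_zt(recording: ActivityRecording, schedule: LightSchedule) -> pd.DataFrame:
    """Per-minute table with columns ``zt_min``, ``phase``, ``count``.

    Phase follows the half-open convention: day = ZT [0, photoperiod),
    night = the rest, so under 12:12 the minute at ZT 720 is night.
    """
    zt = zt_minutes(recording, schedule)
    phase = np.where(zt < schedule.day_minutes, "day", "night")
    return pd.DataFrame(
        {"zt_min": zt, "phase": phase, "count": recording.minutes}
    )


def write_zt_csv(
    recordings: Iterable[ActivityRecording],
    schedule: LightSchedule,
    path: str | Path,
) -> None:
    """CSV export of per-minute series: header ``fly_id,zt_min,phase,count``."""
    frames = []
    for rec in recordings:
        df = to_zt(rec, schedule)
        df.insert(0, "fly_id", rec.fly_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
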