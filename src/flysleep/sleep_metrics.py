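"""Sleep scoring and summary metrics for per-minute activity data.

Fly sleep is operationally defined as a period of inactivity (zero beam
breaks) lasting at least five consecutive minutes.  A recording is scored
into maximal inactivity runs; runs of >= 5 min become sleep bouts, shorter
runs contribute nothing.  Runs truncated by the recording boundary count if
their *observed* length reaches the threshold (the true extent being
unknowable).

Summaries follow the conventions of the sleep field: day = ZT [0, 720) min,
night = ZT [720, 1440) min under a 12:12 cycle; 30-min sleep profiles; a
bout that spans the day/night boundary contributes its minutes to each
phase by membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dam_io import ActivityRecording, TemperatureEpoch, MINUTES_PER_DAY

__all__ = [
    "SleepBout",
    "SleepSeries",
    "SleepSummary",
    "SleepChange",
    "BoxSummary",
    "MIN_SLEEP_BOUT_MIN",
    "score_sleep",
    "summarize",
    "nightly_sleep",
    "sleep_change",
    "flag_dead",
    "tukey_box_summary",
    "sleep_summary_frame",
]

MIN_SLEEP_BOUT_MIN = 5
DAY_MINUTES = 720
DEFAULT_DEAD_THRESHOLD_MIN = 12 * 60


@dataclass(frozen=True)
class SleepBout:
    start_minute: int
    duration_min: int

    @property
    def end_minute(self) -> int:  # half-open
        return self.start_minute + self.duration_min


@dataclass
class SleepSeries:
    """Boolean per-minute sleep state plus its bout decomposition."""

    fly_id: str
    asleep: np.ndarray
    bouts: list[SleepBout]
    source_beam_mode: str = "single"

    def __len__(self) -> int:
        return len(self.asleep)

    @property
    def total_sleep_min(self) -> int:
        return int(self.asleep.sum())


@dataclass
class SleepSummary:
    daytime_sleep_min: int
    nighttime_sleep_min: int
    total_sleep_min: int
    profile_30min: np.ndarray  # 48 bins over ZT [0, 1440)
    per_night_sleep: np.ndarray  # successive full nights in the series


@dataclass(frozen=True)
class SleepChange:
    """Sleep during a thermogenetic-activation phase minus baseline."""

    phase: str
    activation_sleep_min: int
    baseline_sleep_min: int

    @property
    def delta_min(self) -> int:
        return self.activation_sleep_min - self.baseline_sleep_min


@dataclass(frozen=True)
class BoxSummary:
    """Tukey box-and-whisker summary: whiskers at the most extreme values
    within 1.5 IQR of the quartiles; values beyond are outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def _zero_runs(minutes: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero counts as (start, length) pairs."""
    inactive = np.asarray(minutes) == 0
    if not inactive.any():
        return []
    padded = np.concatenate(([False], inactive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def score_sleep(
    recording: ActivityRecording | np.ndarray,
    min_bout: int = MIN_SLEEP_BOUT_MIN,
) -> SleepSeries:
    """Score per-minute sleep: maximal zero-count runs of >= ``min_bout`` min."""
    if isinstance(recording, ActivityRecording):
        minutes = recording.minutes
        fly_id = recording.fly_id
        mode = recording.beam_mode
    else:
        minutes = np.asarray(recording)
        fly_id = ""
        mode = "single"
    if len(minutes) == 0:
        raise ValueError("empty recording")
    bouts = [
        SleepBout(s, l) for s, l in _zero_runs(minutes) if l >= min_bout
    ]
    asleep = np.zeros(len(minutes), dtype=bool)
    for b in bouts:
        asleep[b.start_minute : b.end_minute] = True
    return SleepSeries(fly_id=fly_id, asleep=asleep, bouts=bouts, source_beam_mode=mode)


def summarize(
    series: SleepSeries,
    zt_min: np.ndarray,
    window: tuple[int, int] | None = None,
) -> SleepSummary:
    """Phase totals and 30-min profile for one 24-h window.

    ``zt_min`` gives each minute's ZT (minutes, [0, 1440)); ``window`` is a
    half-open (start, end) index pair spanning exactly 24 h (default: the
    first 24 h).  ``per_night_sleep`` is computed over the whole series.
    """
    zt_min = np.asarray(zt_min)
    if len(zt_min) != len(series):
        raise ValueError("zt_min and series length mismatch")
    if window is None:
        window = (0, MINUTES_PER_DAY)
    start, end = window
    if end - start != MINUTES_PER_DAY:
        raise ValueError("window must span exactly 24 h (1440 min)")
    if start < 0 or end > len(series):
        raise ValueError("window not fully covered by the series")

    asleep = series.asleep[start:end]
    zt = zt_min[start:end]
    day = zt < DAY_MINUTES
    daytime = int(asleep[day].sum())
    nighttime = int(asleep[~day].sum())
    profile = np.bincount((zt // 30)[asleep], minlength=48)
    return SleepSummary(
        daytime_sleep_min=daytime,
        nighttime_sleep_min=nighttime,
        total_sleep_min=daytime + nighttime,
        profile_30min=profile,
        per_night_sleep=nightly_sleep(series, zt_min),
    )


def _phase_instances(
    zt_min: np.ndarray, phase: str
) -> list[tuple[int, int]]:
    """Index spans of *full* phase instances (720 contiguous min of the phase)."""
    in_phase = (
        zt_min < DAY_MINUTES if phase == "daytime" else zt_min >= DAY_MINUTES
    )
    padded = np.concatenate(([False], in_phase, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [
        (int(s), int(e))
        for s, e in zip(edges[::2], edges[1::2])
        if e - s == DAY_MINUTES
    ]


def nightly_sleep(series: SleepSeries, zt_min: np.ndarray) -> np.ndarray:
    """Sleep minutes in each successive full night of the series."""
    return np.array(
        [
            int(series.asleep[s:e].sum())
            for s, e in _phase_instances(np.asarray(zt_min), "nighttime")
        ]
    )


def sleep_change(
    series: SleepSeries,
    zt_min: np.ndarray,
    schedule: Sequence[TemperatureEpoch],
    phase: str = "nighttime",
    activation_ordinal: int | None = None,
) -> SleepChange:
    """Activation-phase sleep minus baseline-phase sleep.

    Baseline = sleep in the *last* full instance of ``phase`` inside the
    baseline epoch(s); activation = sleep in the ``activation_ordinal``-th
    full instance inside the activation epoch(s) (default: the second when
    two or more exist, else the first).
    """
    if phase not in ("daytime", "nighttime"):
        raise ValueError("phase must be 'daytime' or 'nighttime'")
    zt_min = np.asarray(zt_min)
    instances = _phase_instances(zt_min, phase)

    def inside(label: str) -> list[tuple[int, int]]:
        spans = [
            (e.start_minute, e.end_minute) for e in schedule if e.label == label
        ]
        return [
            (s, t)
            for s, t in instances
            if any(s >= a and t <= b for a, b in spans)
        ]

    base = inside("baseline")
    act = inside("activation")
    if not base:
        raise ValueError(f"no full {phase} instance inside the baseline epoch")
    if not act:
        raise ValueError(f"no full {phase} instance inside the activation epoch")
    if activation_ordinal is None:
        activation_ordinal = 2 if len(act) >= 2 else 1
    if not 1 <= activation_ordinal <= len(act):
        raise ValueError(
            f"activation {phase} instance #{activation_ordinal} absent "
            f"({len(act)} available)"
        )
    b0, b1 = base[-1]
    a0, a1 = act[activation_ordinal - 1]
    return SleepChange(
        phase=phase,
        activation_sleep_min=int(series.asleep[a0:a1].sum()),
        baseline_sleep_min=int(series.asleep[b0:b1].sum()),
    )


def flag_dead(
    recording: ActivityRecording,
    threshold_min: int = DEFAULT_DEAD_THRESHOLD_MIN,
) -> tuple[bool, int | None]:
    """Flag a fly as dead if its final zero-count run is >= ``threshold_min``
    and extends to the end of the recording.  Returns (dead, death_minute)."""
    minutes = recording.minutes
    nz = np.flatnonzero(minutes)
    terminal_start = 0 if len(nz) == 0 else int(nz[-1]) + 1
    run = len(minutes) - terminal_start
    if run >= threshold_min:
        return True, terminal_start
    return False, None


def tukey_box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number Tukey boxplot summary with 1.5 IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers
    sit on the most extreme data values within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    )


def sleep_summary_frame(
    entries: Sequence[tuple[ActivityRecording, SleepSeries, SleepSummary]],
) -> pd.DataFrame:
    """Per-fly summary table: fly_id, condition fields, phase totals,
    n_bouts, mean_bout_len."""
    rows = []
    for rec, series, summary in entries:
        row = {"fly_id": rec.fly_id, **rec.condition}
        row.update(
            daytime_sleep_min=summary.daytime_sleep_min,
            nighttime_sleep_min=summary.nighttime_sleep_min,
            total_sleep_min=summary.total_sleep_min,
            n_bouts=len(series.bouts),
            mean_bout_len=(
                float(np.mean([b.duration_min for b in series.bouts]))
                if series.bouts
                else 0.0
            ),
        )
        rows.append(row)
    return pd.DataFrame(rows)
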