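"""Window scoring of per-second behavior labels (video ethograms).

Night behavior of paired flies is scored from video in the first 5 min of
each hour between ZT 18 and ZT 24.  Each second carries one of three
labels — ``immobile``, ``courting``, ``other_active`` — and the scorer must
decide whether in-window immobility is sleep: an immobile run counts as
sleep only if its *full* extent (followed into up to 5 min of context
before/after the window, mirroring how a human scorer checks the
surrounding video) reaches 5 min; shorter immobility is "wake but not
courting" (brief inactivity, grooming pauses and the like).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMMOBILE",
    "COURTING",
    "OTHER_ACTIVE",
    "LABELS",
    "EthogramTrack",
    "WindowScore",
    "score_window",
    "nightly_score",
    "read_ethogram_csv",
    "write_scores_csv",
    "NIGHT_WINDOW_HOURS",
]

IMMOBILE = "immobile"
COURTING = "courting"
OTHER_ACTIVE = "other_active"
LABELS = (IMMOBILE, COURTING, OTHER_ACTIVE)

WINDOW_LEN_S = 300
SLEEP_MIN_S = 300
CONTEXT_S = 300
NIGHT_WINDOW_HOURS = (18, 19, 20, 21, 22, 23)


@dataclass
class EthogramTrack:
    """Per-second behavior labels starting at ``zt_start`` (s since ZT0)."""

    fly_id: str
    labels: np.ndarray
    zt_start: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size == 0:
            raise ValueError("empty label track")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WindowScore:
    window_start_zt: int  # seconds
    pct_sleep: float
    pct_court: float
    pct_wake_noncourt: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def score_window(
    track: EthogramTrack,
    window_start: int,
    window_len: int = WINDOW_LEN_S,
    sleep_min_s: int = SLEEP_MIN_S,
    context_s: int = CONTEXT_S,
) -> WindowScore:
    """Score one analysis window into sleep / courting / wake-not-courting.

    In-window immobile seconds count as sleep iff their maximal immobile
    run, followed up to ``context_s`` beyond each window edge (runs
    straddling either edge are treated symmetrically), reaches
    ``sleep_min_s``; with the default 300-s horizon the criterion is always
    decidable.  Percentages partition 100.
    """
    i0 = window_start - track.zt_start
    i1 = i0 + window_len
    if i0 < 0 or i1 > len(track):
        raise ValueError("window extends beyond the labeled track")
    c0 = max(0, i0 - context_s)
    c1 = min(len(track), i1 + context_s)
    ctx = track.labels[c0:c1]
    sleep_mask = np.zeros(len(ctx), dtype=bool)
    for s, e in _runs(ctx == IMMOBILE):
        if e - s >= sleep_min_s:
            sleep_mask[s:e] = True
    win = slice(i0 - c0, i1 - c0)
    labels_win = ctx[win]
    sleep_s = int(sleep_mask[win].sum())
    court_s = int((labels_win == COURTING).sum())
    wake_s = window_len - sleep_s - court_s
    to_pct = 100.0 / window_len
    return WindowScore(
        window_start_zt=window_start,
        pct_sleep=sleep_s * to_pct,
        pct_court=court_s * to_pct,
        pct_wake_noncourt=wake_s * to_pct,
    )


def nightly_score(
    track: EthogramTrack,
    hours: Sequence[int] = NIGHT_WINDOW_HOURS,
    window_len: int = WINDOW_LEN_S,
) -> WindowScore:
    """Mean of the per-window percentages over the first 5 min of each hour
    (default ZT 18:00 .. 23:00)."""
    scores = [score_window(track, h * 3600, window_len) for h in hours]
    return WindowScore(
        window_start_zt=hours[0] * 3600,
        pct_sleep=float(np.mean([s.pct_sleep for s in scores])),
        pct_court=float(np.mean([s.pct_court for s in scores])),
        pct_wake_noncourt=float(np.mean([s.pct_wake_noncourt for s in scores])),
    )


def read_ethogram_csv(path: str | Path) -> list[EthogramTrack]:
    """Read per-second label tracks (columns ``fly_id,zt_s,label``)."""
    df = pd.read_csv(path)
    tracks = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        grp = grp.sort_values("zt_s")
        zt = grp["zt_s"].to_numpy()
        if len(zt) > 1 and not (np.diff(zt) == 1).all():
            raise ValueError(f"{fly_id}: labels are not contiguous per-second")
        tracks.append(
            EthogramTrack(
                fly_id=str(fly_id),
                labels=grp["label"].to_numpy(),
                zt_start=int(zt[0]),
            )
        )
    return tracks


def write_scores_csv(
    scores: Sequence[tuple[str, WindowScore]], path: str | Path
) -> None:
    """Per-fly percentage table (``fly_id,window_start_zt_s,pct_*``)."""
    pd.DataFrame(
        [
            {
                "fly_id": fid,
                "window_start_zt_s": s.window_start_zt,
                "pct_sleep": s.pct_sleep,
                "pct_court": s.pct_court,
                "pct_wake_noncourt": s.pct_wake_noncourt,
            }
            for fid, s in scores
        ]
    ).to_csv(path, index=False)
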