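"""Courtship-index and censored-latency analysis of mating trials.

A trial pairs one male with one female and is observed for two hours after
introduction.  The courtship index (CI) is the fraction of time the male
courts during the 10 min following courtship initiation, or until
copulation if that comes first; males that never initiate have no CI
(undefined, distinct from zero).  Latencies to initiation and to copulation
are right-censored at the end of observation and compared between groups
with the log-rank test, implemented here directly from its
observed/expected/variance risk-table formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CourtshipTrial",
    "SurvivalSample",
    "CI_WINDOW_S",
    "OBSERVATION_S",
    "courtship_index",
    "to_survival",
    "logrank",
    "read_trials_csv",
    "write_trials_csv",
    "write_comparison_json",
]

CI_WINDOW_S = 600.0  # 10 min CI denominator cap
OBSERVATION_S = 7200.0  # 2 h observation


@dataclass
class CourtshipTrial:
    """Event times (seconds) for one male; ``None`` marks a censored event."""

    trial_id: str
    group: str
    t_intro: float
    t_court_init: float | None
    t_copulation: float | None
    courting_intervals: list[tuple[float, float]] = field(default_factory=list)
    observation_end: float | None = None

    def __post_init__(self) -> None:
        if self.observation_end is None:
            self.observation_end = self.t_intro + OBSERVATION_S
        if self.t_court_init is not None and self.t_court_init < self.t_intro:
            raise ValueError("courtship initiation before introduction")
        if self.t_copulation is not None:
            if self.t_court_init is None:
                raise ValueError("copulation without courtship initiation")
            if self.t_copulation < self.t_court_init:
                raise ValueError("copulation before courtship initiation")
        ivals = sorted(self.courting_intervals)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError("courting intervals overlap")
        self.courting_intervals = ivals


@dataclass(frozen=True)
class SurvivalSample:
    time: float
    event_observed: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


def courtship_index(trial: CourtshipTrial) -> float | None:
    """Fraction of time courting in the 10 min after initiation (or until
    copulation).  ``None`` if the male never initiated courtship."""
    if trial.t_court_init is None:
        return None
    if trial.t_copulation is not None:
        denom = min(CI_WINDOW_S, trial.t_copulation - trial.t_court_init)
    else:
        denom = CI_WINDOW_S
    if denom <= 0:
        return None
    lo, hi = trial.t_court_init, trial.t_court_init + denom
    courting = sum(
        max(0.0, min(b, hi) - max(a, lo)) for a, b in trial.courting_intervals
    )
    return courting / denom


def to_survival(
    trials: Iterable[CourtshipTrial], endpoint: str
) -> list[SurvivalSample]:
    """Latency samples (time since introduction) for one endpoint,
    right-censored at the end of observation."""
    if endpoint not in ("initiation", "copulation"):
        raise ValueError("endpoint must be 'initiation' or 'copulation'")
    out = []
    for t in trials:
        when = t.t_court_init if endpoint == "initiation" else t.t_copulation
        if when is not None:
            out.append(SurvivalSample(when - t.t_intro, True))
        else:
            out.append(SurvivalSample(t.observation_end - t.t_intro, False))
    return out


def logrank(
    group_a: Sequence[SurvivalSample], group_b: Sequence[SurvivalSample]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2, 1 df).

    At each distinct event time the observed events in group A are compared
    with the expectation under a common hazard (risk-set proportion), with
    the hypergeometric variance for ties; censorings at an event time stay
    in the risk set for that time (events precede censorings).
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    times = np.array([s.time for s in group_a] + [s.time for s in group_b])
    events = np.array(
        [s.event_observed for s in group_a] + [s.event_observed for s in group_b]
    )
    in_a = np.zeros(len(times), dtype=bool)
    in_a[: len(group_a)] = True
    if not events.any():
        raise ValueError("no observed events: log-rank is undefined")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int((events & (times == t)).sum())
        d_a = int((events & (times == t) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
    if var == 0:
        # all events in risk sets with a single arm represented: degenerate
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# CSV / JSON interfaces


def _fmt_intervals(ivals: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{a:.12g}-{b:.12g}" for a, b in ivals)


def _parse_intervals(text: str) -> list[tuple[float, float]]:
    if not text or pd.isna(text):
        return []
    out = []
    for part in str(text).split(";"):
        a, _, b = part.partition("-")
        out.append((float(a), float(b)))
    return out


def write_trials_csv(trials: Iterable[CourtshipTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        ci = courtship_index(t)
        rows.append(
            {
                "trial_id": t.trial_id,
                "group": t.group,
                "t_intro_s": t.t_intro,
                "t_court_init_s": "" if t.t_court_init is None else t.t_court_init,
                "t_copulation_s": "" if t.t_copulation is None else t.t_copulation,
                "courting_intervals": _fmt_intervals(t.courting_intervals),
                "observation_end_s": t.observation_end,
                "courtship_index": "" if ci is None else ci,
                "court_censored": t.t_court_init is None,
                "copulation_censored": t.t_copulation is None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[CourtshipTrial]:
    df = pd.read_csv(path)
    trials = []
    for _, row in df.iterrows():
        def _opt(key: str) -> float | None:
            v = row.get(key)
            return None if pd.isna(v) or v == "" else float(v)

        trials.append(
            CourtshipTrial(
                trial_id=str(row["trial_id"]),
                group=str(row["group"]),
                t_intro=float(row["t_intro_s"]),
                t_court_init=_opt("t_court_init_s"),
                t_copulation=_opt("t_copulation_s"),
                courting_intervals=_parse_intervals(row.get("courting_intervals", "")),
                observation_end=_opt("observation_end_s"),
            )
        )
    return trials


def write_comparison_json(
    statistic: float, p: float, path: str | Path, df: int = 1, **extra
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"test": "logrank", "statistic": statistic, "df": df, "p": p, **extra},
            fh,
            indent=2,
        )
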