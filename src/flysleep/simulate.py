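"""Synthetic data with ground truth for every stage of the pipeline.

The fly model is a two-state (wake/sleep) Markov chain on the 1-min
measurement grid with phase-dependent transition probabilities: from wake a
fly falls asleep with probability ``p_fall`` and from sleep it wakes with
probability ``p_wake``, each taking a day or night value by Zeitgeber
phase.  Sleep-run lengths are therefore geometric with mean 1/p_wake,
which gives closed-form expectations for what the 5-min-rule scorer will
report (see :func:`expected_scored_sleep`).  Awake minutes emit a
zero-truncated Poisson count (>= 1 beam break); asleep minutes emit zero.

Every generator is bit-reproducible: each fly draws from its own RNG stream
seeded from (seed, CRC32(fly_id)), so cohorts are order- and
parallel-independent.
"""

from __future__ import annotations

import datetime as dt
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .calcium import FluorescenceTrace, PerfusionProtocol
from .courtship import CourtshipTrial, OBSERVATION_S
from .dam_io import (
    MINUTES_PER_DAY,
    MULTIBEAM_COUNTS,
    MULTIBEAM_MOVES,
    ActivityRecording,
    LightSchedule,
    TemperatureEpoch,
    write_monitor_file,
)

__all__ = [
    "FlyModel",
    "SimulationTruth",
    "EpochOverride",
    "simulate_fly",
    "simulate_cohort",
    "simulate_multibeam",
    "simulate_latency_trials",
    "simulate_gcamp",
    "GcampTruth",
    "build_experiment",
    "transition_probability_arrays",
    "two_by_two_cells",
    "stationary_sleep_fraction",
    "scored_run_fraction",
    "expected_scored_sleep_stationary",
    "expected_scored_sleep",
    "calibrate_night_p_wake",
    "models_for_targets",
    "DEFAULT_START",
    "SD_BETWEEN_FLIES_MIN",
]

DEFAULT_START = dt.datetime(2021, 1, 1, 8, 0)  # lights-on, ZT0
DAY_MINUTES = 720

# Between-fly SD (min) of target nighttime sleep added on top of the
# within-process variability of the chain (~36-49 min at mid-range means),
# bringing total per-fly SD of scored nighttime sleep to ~120 min.
SD_BETWEEN_FLIES_MIN = 110.0


@dataclass(frozen=True)
class FlyModel:
    """Per-minute transition probabilities and emission rate for one fly."""

    p_fall_asleep_day: float = 0.06
    p_fall_asleep_night: float = 0.10
    p_wake_day: float = 0.12
    p_wake_night: float = 0.02
    wake_activity_rate: float = 2.5  # mean counts per awake minute (ZTP mean)
    condition: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_fall_asleep_day",
            "p_fall_asleep_night",
            "p_wake_day",
            "p_wake_night",
        ):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.wake_activity_rate <= 1:
            raise ValueError("wake_activity_rate must exceed 1 (ZTP mean)")


@dataclass(frozen=True)
class EpochOverride:
    """Replace transition probabilities over [start_minute, end_minute)."""

    start_minute: int
    end_minute: int
    p_fall_asleep_day: float | None = None
    p_fall_asleep_night: float | None = None
    p_wake_day: float | None = None
    p_wake_night: float | None = None


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a synthetic recording."""

    fly_id: str
    states: np.ndarray  # True = sleep state
    params: dict
    seed: int
    true_state_min: dict = field(default_factory=dict)  # per-phase sleep-state minutes


def _fly_rng(seed: int, fly_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(fly_id.encode())])
    )


# ---------------------------------------------------------------------------
# zero-truncated Poisson emissions


def _ztp_lambda(mean: float) -> float:
    """Rate of the Poisson whose >=1-truncated mean equals ``mean``."""
    if mean <= 1:
        raise ValueError("truncated-Poisson mean must exceed 1")
    return brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 10 * mean)


def _ztp_sample(u: np.ndarray, lam: float) -> np.ndarray:
    """Inverse-CDF zero-truncated Poisson draws from uniforms ``u``."""
    q = np.exp(-lam) + u * (1 - np.exp(-lam))
    return stats.poisson.ppf(np.clip(q, 0.0, 1.0 - 1e-15), lam).astype(np.int64)


# ---------------------------------------------------------------------------
# the two-state chain


def _transition_arrays(
    model: FlyModel,
    n_min: int,
    overrides: Sequence[EpochOverride] = (),
    zt0: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    zt = (zt0 + np.arange(n_min)) % MINUTES_PER_DAY
    day = zt < DAY_MINUTES
    p_fall = np.where(day, model.p_fall_asleep_day, model.p_fall_asleep_night)
    p_wake = np.where(day, model.p_wake_day, model.p_wake_night)
    for ov in overrides:
        sl = slice(ov.start_minute, ov.end_minute)
        d, n = day[sl], ~day[sl]
        if ov.p_fall_asleep_day is not None:
            p_fall[sl] = np.where(d, ov.p_fall_asleep_day, p_fall[sl])
        if ov.p_fall_asleep_night is not None:
            p_fall[sl] = np.where(n, ov.p_fall_asleep_night, p_fall[sl])
        if ov.p_wake_day is not None:
            p_wake[sl] = np.where(d, ov.p_wake_day, p_wake[sl])
        if ov.p_wake_night is not None:
            p_wake[sl] = np.where(n, ov.p_wake_night, p_wake[sl])
    return p_fall, p_wake


def _states_batch(
    p_fall: np.ndarray, p_wake: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Run the chain for a batch: arrays are (n_flies, n_min); wake start."""
    n_flies, n_min = u.shape
    states = np.zeros((n_flies, n_min), dtype=bool)  # True = sleep
    cur = np.zeros(n_flies, dtype=bool)
    for t in range(1, n_min):
        fall = u[:, t] < p_fall[:, t]
        stay = u[:, t] >= p_wake[:, t]
        cur = np.where(cur, stay, fall)
        states[:, t] = cur
    return states


def transition_probability_arrays(
    model: FlyModel,
    n_min: int,
    overrides: Sequence[EpochOverride] = (),
    zt0: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (p_fall, p_wake) arrays for a model under a phase schedule
    and optional epoch overrides — the chain :func:`expected_scored_sleep`
    needs for closed-form predictions."""
    return _transition_arrays(model, n_min, overrides, zt0)


def two_by_two_cells(
    base_night_sleep: float = 480.0,
    pairing_deficit: float = 120.0,
    interaction: float = 240.0,
) -> list[tuple[dict, float]]:
    """Target nighttime-sleep means for a sex-pairing x diet 2x2 design.

    Female-paired (MF) males sleep less than male-paired (MM) males; the
    deficit is ``pairing_deficit + interaction/2`` under the fed diet and
    ``pairing_deficit - interaction/2`` under protein deprivation, so
    ``interaction`` is the difference-of-differences of the cell means.
    """
    d_fed = pairing_deficit + interaction / 2
    d_dep = pairing_deficit - interaction / 2
    return [
        ({"sex_pairing": "MM", "diet": "fed"}, base_night_sleep),
        ({"sex_pairing": "MF", "diet": "fed"}, base_night_sleep - d_fed),
        ({"sex_pairing": "MM", "diet": "deprived"}, base_night_sleep),
        ({"sex_pairing": "MF", "diet": "deprived"}, base_night_sleep - d_dep),
    ]


def simulate_cohort(
    models: Sequence[FlyModel],
    n_days: float,
    fly_ids: Sequence[str] | None = None,
    start_datetime: dt.datetime = DEFAULT_START,
    overrides: Sequence[EpochOverride] = (),
    temperature_schedule: Sequence[TemperatureEpoch] = (),
) -> list[tuple[ActivityRecording, SimulationTruth]]:
    """Simulate many flies at once (single minute-loop across the batch).

    Each fly keeps its own RNG stream, so results are identical to calling
    :func:`simulate_fly` one fly at a time.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    n_min = int(round(n_days * MINUTES_PER_DAY))
    if fly_ids is None:
        fly_ids = [f"fly{i:03d}" for i in range(len(models))]
    if len(fly_ids) != len(models):
        raise ValueError("fly_ids and models length mismatch")

    zt0 = LightSchedule().zt_of(start_datetime) if start_datetime else 0
    p_fall = np.empty((len(models), n_min))
    p_wake = np.empty((len(models), n_min))
    u = np.empty((len(models), n_min))
    v = np.empty((len(models), n_min))
    for i, (m, fid) in enumerate(zip(models, fly_ids)):
        p_fall[i], p_wake[i] = _transition_arrays(m, n_min, overrides, zt0)
        rng = _fly_rng(m.seed, fid)
        u[i] = rng.random(n_min)
        v[i] = rng.random(n_min)

    states = _states_batch(p_fall, p_wake, u)
    zt = (zt0 + np.arange(n_min)) % MINUTES_PER_DAY
    night = zt >= DAY_MINUTES

    out = []
    for i, (m, fid) in enumerate(zip(models, fly_ids)):
        counts = np.zeros(n_min, dtype=np.int64)
        awake = ~states[i]
        lam = _ztp_lambda(m.wake_activity_rate)
        counts[awake] = _ztp_sample(v[i][awake], lam)
        rec = ActivityRecording(
            fly_id=fid,
            channel=(i % 32) + 1,
            minutes=counts,
            start_datetime=start_datetime,
            beam_mode="single",
            condition=dict(m.condition),
            temperature_schedule=list(temperature_schedule),
        )
        truth = SimulationTruth(
            fly_id=fid,
            states=states[i],
            params={
                "p_fall_asleep_day": m.p_fall_asleep_day,
                "p_fall_asleep_night": m.p_fall_asleep_night,
                "p_wake_day": m.p_wake_day,
                "p_wake_night": m.p_wake_night,
                "wake_activity_rate": m.wake_activity_rate,
            },
            seed=m.seed,
            true_state_min={
                "daytime": int(states[i][~night].sum()),
                "nighttime": int(states[i][night].sum()),
            },
        )
        out.append((rec, truth))
    return out


def simulate_fly(
    model: FlyModel,
    n_days: float,
    fly_id: str = "fly000",
    start_datetime: dt.datetime = DEFAULT_START,
    overrides: Sequence[EpochOverride] = (),
    temperature_schedule: Sequence[TemperatureEpoch] = (),
) -> tuple[ActivityRecording, SimulationTruth]:
    """Simulate one fly's per-minute activity recording with ground truth."""
    return simulate_cohort(
        [model],
        n_days,
        fly_ids=[fly_id],
        start_datetime=start_datetime,
        overrides=overrides,
        temperature_schedule=temperature_schedule,
    )[0]


def simulate_multibeam(
    model: FlyModel,
    n_days: float,
    fly_id: str = "fly000",
    move_rate: float = 1.5,
    micro_rate: float = 1.3,
    twitch_prob: float = 0.10,
    start_datetime: dt.datetime = DEFAULT_START,
) -> tuple[ActivityRecording, ActivityRecording, SimulationTruth]:
    """Simulate one fly on a 17-beam monitor: (moves rec, counts rec, truth).

    While awake the fly paces the tube (adjacent-beam transitions at
    ``move_rate`` per minute, possibly zero in any one minute) and
    additionally makes within-beam micro-movements (Poisson at
    ``micro_rate``); while asleep it occasionally twitches in place
    (probability ``twitch_prob`` per minute), which registers in the counts
    channel only.  Counts >= moves at every minute by construction, so
    sleep scored from counts can only be shorter than sleep scored from
    moves; with ``micro_rate = twitch_prob = 0`` the two series coincide.
    """
    n_min = int(round(n_days * MINUTES_PER_DAY))
    zt0 = LightSchedule().zt_of(start_datetime)
    p_fall, p_wake = _transition_arrays(model, n_min, zt0=zt0)
    rng = _fly_rng(model.seed, fly_id)
    u = rng.random(n_min)
    states = _states_batch(p_fall[None, :], p_wake[None, :], u[None, :])[0]
    awake = ~states

    steps = rng.poisson(move_rate, n_min)
    micro = rng.poisson(micro_rate, n_min)
    twitch = rng.binomial(1, twitch_prob, n_min)

    moves = np.where(awake, steps, 0).astype(np.int64)
    counts = np.where(awake, steps + micro, twitch).astype(np.int64)
    assert (counts >= moves).all()

    zt = (zt0 + np.arange(n_min)) % MINUTES_PER_DAY
    night = zt >= DAY_MINUTES
    truth = SimulationTruth(
        fly_id=fly_id,
        states=states,
        params={"move_rate": move_rate, "micro_rate": micro_rate,
                "twitch_prob": twitch_prob},
        seed=model.seed,
        true_state_min={
            "daytime": int(states[~night].sum()),
            "nighttime": int(states[night].sum()),
        },
    )
    common = dict(start_datetime=start_datetime, condition=dict(model.condition))
    rec_moves = ActivityRecording(
        fly_id=fly_id, channel=1, minutes=moves, beam_mode=MULTIBEAM_MOVES, **common
    )
    rec_counts = ActivityRecording(
        fly_id=fly_id, channel=1, minutes=counts, beam_mode=MULTIBEAM_COUNTS, **common
    )
    return rec_moves, rec_counts, truth


# ---------------------------------------------------------------------------
# closed-form expectations for the scored-sleep observable


def stationary_sleep_fraction(p_fall: float, p_wake: float) -> float:
    """Long-run fraction of minutes in the sleep state."""
    return p_fall / (p_fall + p_wake)


def scored_run_fraction(p_wake: float, min_bout: int = 5) -> float:
    """Fraction of sleep-state minutes lying in runs of >= ``min_bout`` min.

    Run lengths are geometric with continuation probability q = 1 - p_wake:
    sum_{l>=L} l(1-q)q^{l-1} / E[L] = q^{L-1} (L(1-q) + q).
    """
    q = 1.0 - p_wake
    L = min_bout
    return q ** (L - 1) * (L * (1 - q) + q)


def expected_scored_sleep_stationary(
    p_fall: float, p_wake: float, n_minutes: int, min_bout: int = 5
) -> float:
    """Stationary approximation to E[scored sleep] over ``n_minutes``."""
    return (
        n_minutes
        * stationary_sleep_fraction(p_fall, p_wake)
        * scored_run_fraction(p_wake, min_bout)
    )


def expected_scored_sleep(
    p_fall: np.ndarray,
    p_wake: np.ndarray,
    min_bout: int = 5,
    init_p_sleep: float = 0.0,
    window: tuple[int, int] | None = None,
) -> float:
    """Exact E[scored sleep minutes] of the (inhomogeneous) two-state chain.

    ``p_fall``/``p_wake`` are per-minute transition probabilities indexed by
    the destination minute (index 0 is the initial minute, whose sleep
    probability is ``init_p_sleep``).  A minute is scored asleep iff it lies
    in a maximal sleep run of >= ``min_bout`` minutes, where runs truncated
    by the recording edge count at their observed length — exactly the
    scorer's convention.  Computed as
    P(sleep at m) - P(m in a maximal run shorter than ``min_bout``),
    the latter a finite sum over run placements.
    """
    p_fall = np.asarray(p_fall, dtype=float)
    p_wake = np.asarray(p_wake, dtype=float)
    n = len(p_fall)
    if len(p_wake) != n:
        raise ValueError("p arrays must have equal length")

    # forward marginals P(sleep at t)
    pi = np.empty(n)
    pi[0] = init_p_sleep
    for t in range(1, n):
        pi[t] = (1 - pi[t - 1]) * p_fall[t] + pi[t - 1] * (1 - p_wake[t])

    # P(a maximal run starts at s)
    start = np.empty(n)
    start[0] = init_p_sleep
    start[1:] = (1 - pi[:-1]) * p_fall[1:]

    # log cumulative continuation products: prod_{t=s+1..e} (1 - p_wake[t])
    logc = np.log1p(-p_wake)
    cum = np.concatenate(([0.0], np.cumsum(logc)))  # cum[t+1] = sum_{u<=t}

    short = np.zeros(n)
    m = np.arange(n)
    for ds in range(min_bout - 1):
        s = m - ds
        for de in range(min_bout - 1 - ds):
            e = m + de
            valid = (s >= 0) & (e <= n - 1)
            sv, ev = s[valid], e[valid]
            prob = start[sv] * np.exp(cum[ev + 1] - cum[sv + 1])
            endp = np.where(ev + 1 <= n - 1, p_wake[np.minimum(ev + 1, n - 1)], 1.0)
            short[valid] += prob * endp
    scored = pi - short
    if window is None:
        window = (0, n)
    return float(scored[window[0] : window[1]].sum())


def calibrate_night_p_wake(
    target_night_sleep_min: float,
    p_fall_night: float = 0.10,
    min_bout: int = 5,
    night_minutes: int = 720,
) -> float:
    """Solve for the nighttime waking probability giving a target mean
    scored nighttime sleep (stationary approximation)."""
    if not 0 < target_night_sleep_min < night_minutes:
        raise ValueError("target must lie in (0, night length)")

    def f(pw: float) -> float:
        return (
            expected_scored_sleep_stationary(p_fall_night, pw, night_minutes, min_bout)
            - target_night_sleep_min
        )

    return brentq(f, 1e-5, 0.995)


def models_for_targets(
    cells: Sequence[tuple[dict, float]],
    n_per_cell: int,
    seed: int,
    sd_between: float = SD_BETWEEN_FLIES_MIN,
    base_model: FlyModel | None = None,
) -> tuple[list[FlyModel], list[str]]:
    """Per-fly models whose mean scored nighttime sleep matches cell targets.

    ``cells`` is a sequence of (condition labels, target mean nighttime
    sleep in minutes).  Each fly's personal target is drawn
    N(cell mean, ``sd_between``) and mapped to a nighttime waking
    probability via :func:`calibrate_night_p_wake`, modeling between-fly
    heterogeneity on top of the chain's intrinsic variability.
    """
    base = base_model or FlyModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    models: list[FlyModel] = []
    fly_ids: list[str] = []
    for ci, (cond, mean) in enumerate(cells):
        targets = np.clip(
            rng.normal(mean, sd_between, n_per_cell), 30.0, 700.0
        )
        for fi, tgt in enumerate(targets):
            pw = calibrate_night_p_wake(tgt, base.p_fall_asleep_night)
            models.append(
                replace(base, p_wake_night=pw, condition=dict(cond), seed=seed)
            )
            fly_ids.append(f"cell{ci}_fly{fi:03d}")
    return models, fly_ids


# ---------------------------------------------------------------------------
# courtship latency trials


def simulate_latency_trials(
    rate_court: float,
    rate_cop: float,
    n: int,
    group: str = "G",
    censor_s: float = OBSERVATION_S,
    target_ci: float = 0.55,
    seed: int = 0,
) -> list[CourtshipTrial]:
    """Exponential courtship-initiation and copulation latencies with
    right-censoring at ``censor_s``; courting intervals fill a fraction
    ~``target_ci`` of the CI denominator window."""
    trials = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        tid = f"{group}_{i:03d}"
        lat_court = rng.exponential(1 / rate_court) if rate_court > 0 else np.inf
        if lat_court >= censor_s:
            trials.append(
                CourtshipTrial(tid, group, 0.0, None, None, [], censor_s)
            )
            continue
        t_init = float(lat_court)
        gap = rng.exponential(1 / rate_cop) if rate_cop > 0 else np.inf
        t_cop = t_init + gap
        if t_cop >= censor_s:
            t_cop = None
        denom = min(600.0, (t_cop - t_init) if t_cop is not None else 600.0)
        frac = float(np.clip(rng.normal(target_ci, 0.1), 0.05, 0.95))
        # three equal courting intervals spread across the window
        seg = denom / 3.0
        on = frac * seg
        intervals = [
            (t_init + j * seg, t_init + j * seg + on) for j in range(3)
        ]
        trials.append(
            CourtshipTrial(tid, group, 0.0, t_init, t_cop, intervals, censor_s)
        )
    return trials


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass(frozen=True)
class GcampTruth:
    transient_amplitude: float
    offset_C: float
    amplitude_A: float
    rate_k: float
    noise_sigma: float


def _transient_shape(t: np.ndarray, protocol: PerfusionProtocol) -> np.ndarray:
    """Smooth ramp-plateau-decay, confined to [atp_start, atp_end + 60 s]."""
    up0, up1 = protocol.atp_start_s, protocol.atp_start_s + 20.0
    dn0, dn1 = protocol.atp_end_s + 20.0, protocol.atp_end_s + 60.0
    s = np.zeros_like(t, dtype=float)
    ramp = (t >= up0) & (t < up1)
    s[ramp] = 0.5 * (1 - np.cos(np.pi * (t[ramp] - up0) / (up1 - up0)))
    s[(t >= up1) & (t < dn0)] = 1.0
    decay = (t >= dn0) & (t < dn1)
    s[decay] = 0.5 * (1 + np.cos(np.pi * (t[decay] - dn0) / (dn1 - dn0)))
    return s


def simulate_gcamp(
    protocol: PerfusionProtocol | None = None,
    offset_C: float = 100.0,
    A_over_C: float = 0.5,
    rate_k: float = 0.005,
    transient_amplitude: float = 0.3,
    noise_sigma_over_C: float = 0.01,
    seed: int = 0,
) -> tuple[FluorescenceTrace, GcampTruth]:
    """Synthetic indicator trace: exponential photobleach of the resting
    signal plus an ATP-evoked transient on the stable component.

    raw(t) = A e^{-kt} + C (1 + a s(t)) + eps,  eps ~ N(0, sigma^2),
    with s(t) a smooth ramp-plateau-decay confined to the perfusion window
    plus 60 s.  Under the pipeline's decay-only detrend and F0 = C, the
    noiseless peak dF/F0 equals ``transient_amplitude`` exactly.
    """
    protocol = protocol or PerfusionProtocol()
    n = int(round(protocol.total_duration_s / protocol.sample_interval_s)) + 1
    t = np.arange(n) * protocol.sample_interval_s
    A = A_over_C * offset_C
    sigma = noise_sigma_over_C * offset_C
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA]))
    s = _transient_shape(t, protocol)
    raw = (
        A * np.exp(-rate_k * t)
        + offset_C * (1 + transient_amplitude * s)
        + rng.normal(0.0, sigma, n)
    )
    return (
        FluorescenceTrace(times_s=t, raw_F=raw),
        GcampTruth(transient_amplitude, offset_C, A, rate_k, sigma),
    )


# ---------------------------------------------------------------------------
# experiment presets


FIG1_CELL_MEANS = {
    ("MM", "fed"): 600.0,
    ("MF", "fed"): 200.0,
    ("MM", "deprived"): 620.0,
    ("MF", "deprived"): 480.0,
}

TRPA1_SCHEDULE_DAYS = (1.5, 1.0, 1.0)  # baseline, activation, recovery


def trpa1_temperature_schedule(
    baseline_C: float = 22.0, activation_C: float = 29.0
) -> list[TemperatureEpoch]:
    d0, d1, d2 = TRPA1_SCHEDULE_DAYS
    m0 = int(d0 * MINUTES_PER_DAY)
    m1 = m0 + int(d1 * MINUTES_PER_DAY)
    m2 = m1 + int(d2 * MINUTES_PER_DAY)
    return [
        TemperatureEpoch("baseline", 0, m0, baseline_C),
        TemperatureEpoch("activation", m0, m1, activation_C),
        TemperatureEpoch("recovery", m1, m2, baseline_C),
    ]


def build_experiment(config: Mapping, outdir: str | Path) -> dict:
    """Write a full synthetic experiment (monitor files + truth) to disk.

    ``config`` needs a ``preset`` key — one of ``fig1_nutrition_by_pairing``,
    ``fig6_trpa1_activation``, ``fig7_screen`` — plus ``seed`` and optional
    size overrides (``n_per_cell``/``n_per_group``/``n_per_line``,
    ``n_days``).  Returns a manifest describing every file written; a
    ``truth.json`` records per-fly generating parameters and hidden-state
    phase totals.
    """
    preset = config.get("preset")
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if preset == "fig1_nutrition_by_pairing":
        n = int(config.get("n_per_cell", 32))
        if n < 1:
            raise ValueError("n_per_cell must be >= 1")
        n_days = float(config.get("n_days", 2))
        cells = [
            ({"sex_pairing": sp, "diet": diet}, mean)
            for (sp, diet), mean in FIG1_CELL_MEANS.items()
        ]
        models, fly_ids = models_for_targets(cells, n, seed)
        results = simulate_cohort(models, n_days, fly_ids=fly_ids)
        files = _write_cohort_monitors(results, outdir, per_file=n)
        truth = _truth_records(results, models)
    elif preset == "fig6_trpa1_activation":
        n = int(config.get("n_per_group", 32))
        if n < 1:
            raise ValueError("n_per_group must be >= 1")
        sched = trpa1_temperature_schedule()
        n_days = sum(TRPA1_SCHEDULE_DAYS)
        base = FlyModel(seed=seed, condition={"genotype": "control"})
        exp = FlyModel(
            seed=seed, condition={"genotype": "experimental"}
        )
        act = sched[1]
        override = EpochOverride(
            act.start_minute, act.end_minute, p_wake_night=2 * exp.p_wake_night
        )
        res_exp = simulate_cohort(
            [exp] * n,
            n_days,
            fly_ids=[f"exp_fly{i:03d}" for i in range(n)],
            overrides=[override],
            temperature_schedule=sched,
        )
        res_ctl = simulate_cohort(
            [base] * n,
            n_days,
            fly_ids=[f"ctl_fly{i:03d}" for i in range(n)],
            temperature_schedule=sched,
        )
        results = res_exp + res_ctl
        files = _write_cohort_monitors(results, outdir, per_file=n)
        truth = _truth_records(results, [exp] * n + [base] * n)
        truth["temperature_schedule"] = [
            {"label": e.label, "start": e.start_minute, "end": e.end_minute,
             "temperature_C": e.temperature_C}
            for e in sched
        ]
    elif preset == "fig7_screen":
        n = int(config.get("n_per_line", 30))
        if n < 1:
            raise ValueError("n_per_line must be >= 1")
        n_lines = int(config.get("n_lines", 20))
        hit_lines = tuple(config.get("hit_lines", (3, 11)))
        effect = float(config.get("hit_effect_min", -150.0))
        base_mean = float(config.get("base_night_sleep_min", 480.0))
        cells: list[tuple[dict, float]] = [({"group": "uas_control"}, base_mean)]
        for line in range(1, n_lines + 1):
            mean = base_mean + (effect if line in hit_lines else 0.0)
            cells.append(({"group": "experimental", "line": f"L{line:02d}"}, mean))
            cells.append(({"group": "gal4_control", "line": f"L{line:02d}"}, base_mean))
        models, fly_ids = models_for_targets(cells, n, seed)
        results = simulate_cohort(models, float(config.get("n_days", 1)), fly_ids=fly_ids)
        files = _write_cohort_monitors(results, outdir, per_file=n)
        truth = _truth_records(results, models)
        truth["hit_lines"] = [f"L{line:02d}" for line in hit_lines]
    else:
        raise ValueError(f"unknown preset {preset!r}")

    truth["seed"] = seed
    truth["preset"] = preset
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    manifest = {
        "preset": preset,
        "seed": seed,
        "monitor_files": [str(f) for f in files],
        "truth": str(outdir / "truth.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_cohort_monitors(
    results: Sequence[tuple[ActivityRecording, SimulationTruth]],
    outdir: Path,
    per_file: int = 32,
) -> list[Path]:
    per_file = min(per_file, 32)
    files = []
    for fi in range(0, len(results), per_file):
        chunk = [r for r, _ in results[fi : fi + per_file]]
        for ch, rec in enumerate(chunk, start=1):
            rec.channel = ch
        path = outdir / f"Monitor{fi // per_file + 1}.txt"
        write_monitor_file(chunk, path)
        files.append(path)
    return files


def _truth_records(
    results: Sequence[tuple[ActivityRecording, SimulationTruth]],
    models: Sequence[FlyModel],
) -> dict:
    return {
        "flies": [
            {
                "fly_id": truth.fly_id,
                "condition": dict(rec.condition),
                "params": truth.params,
                "true_state_min": truth.true_state_min,
            }
            for (rec, truth), m in zip(results, models)
        ]
    }
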