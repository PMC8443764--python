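"""Synthetic study generator.

Emulates the study design the analysis assumes: each subject completes two
intertemporal-choice tasks (SV, delays in seconds; LV, delays in days) built
from a full factorial of 5 delays x 5 later rewards against a fixed sooner
option of 4 coins "now", plus two timing tasks (estimation and production)
over the intervals {3, 7, 14, 30, 64} s, three repetitions each.

Ground truth is hierarchical: each subject's pair of log discount factors is
drawn from a bivariate normal with a configurable cross-task correlation, the
softmax noise log(tau) from a normal, and a single latent internal clock speed
(ICS) drives both timing tasks as reciprocal distortions — a fast clock
(ICS > 1) over-estimates durations and under-produces them.  Timing noise is
multiplicative with a constant coefficient of variation (scalar timing /
Weber's law).  An optional coupling parameter lets the latent clock shift the
seconds-task log discount factor, so the downstream inference chain can be
exercised under a known effect; it defaults to zero (no relationship).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SubjectProfile",
    "sample_population",
    "build_task_schedule",
    "simulate_choices",
    "simulate_timing_trials",
    "simulate_dataset",
    "scheduled_stimulus_minutes",
]

TASKS = ("SV", "LV")
TIMING_TASKS = ("estimation", "production")

#: reported durations are truncated at this floor (seconds) so they stay positive
REPORT_FLOOR_S = 0.1


@dataclass
class SimulationConfig:
    """Ground truth and design parameters for one simulated study.

    Defaults reproduce the design constants of the study being emulated
    (25 later options, 200 trials per task, 30 timing observations per
    subject) with a population of 26 subjects whose log discount factors
    correlate 0.6 across tasks, a Weber fraction of 0.2, and no built-in
    relation between clock speed and discounting (``coupling_gamma = 0``).
    """

    n_subjects: int = 26
    mean_logk_sv: float = -3.0   # log(1/s)
    mean_logk_lv: float = -3.0   # log(1/day)
    sd_logk: float = 1.0
    rho_logk: float = 0.6
    mean_logtau: float = 0.0
    sd_logtau: float = 0.3
    alpha_mean: float = 0.9      # geometric-mean latent clock speed
    alpha_sd: float = 0.15       # sd of log(ICS)
    beta: float = 0.95           # power exponent of subjective time
    weber_fraction: float = 0.2  # CV of timing reports
    coupling_gamma: float = 0.0  # shift of logk_SV per unit of (ICS - 1)
    delay_set_s: tuple = (3.0, 7.0, 14.0, 30.0, 64.0)
    delay_set_d: tuple = (3.0, 7.0, 14.0, 30.0, 64.0)
    reward_set: tuple = (1.0, 2.0, 5.0, 8.0, 10.0)
    sooner_reward: float = 4.0
    reps_per_combo: int = 8
    timing_intervals: tuple = (3.0, 7.0, 14.0, 30.0, 64.0)
    timing_reps: int = 3
    group: str = "new"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sd_logk < 0 or self.sd_logtau < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.rho_logk <= 1.0:
            raise ValueError(f"rho_logk must lie in [-1, 1], got {self.rho_logk}")
        if not 0.0 <= self.weber_fraction < 1.0:
            raise ValueError("weber_fraction must lie in [0, 1)")
        if self.alpha_mean <= 0 or self.beta <= 0:
            raise ValueError("alpha_mean and beta must be positive")
        for name in ("delay_set_s", "delay_set_d", "reward_set", "timing_intervals"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be nonempty and strictly positive")
        if self.sooner_reward <= 0:
            raise ValueError("sooner_reward must be positive")
        if self.reps_per_combo < 1 or self.timing_reps < 1:
            raise ValueError("repetition counts must be >= 1")

    def delay_set(self, task: str) -> tuple:
        if task == "SV":
            return tuple(self.delay_set_s)
        if task == "LV":
            return tuple(self.delay_set_d)
        raise ValueError(f"unknown task {task!r}; expected 'SV' or 'LV'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectProfile:
    """Ground-truth parameters for one simulated subject."""

    subject_id: str
    true_logk_sv: float
    true_logk_lv: float
    true_logtau: float
    true_alpha_e: float   # estimation scaling; > 1 for fast clocks
    true_alpha_p: float   # production scaling; < 1 for fast clocks
    true_beta: float
    true_ics: float       # latent internal clock speed
    group: str = "new"

    def __post_init__(self) -> None:
        vals = [self.true_logk_sv, self.true_logk_lv, self.true_logtau,
                self.true_alpha_e, self.true_alpha_p, self.true_beta]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter for subject {self.subject_id}")
        if min(self.true_alpha_e, self.true_alpha_p, self.true_beta) <= 0:
            raise ValueError("alpha and beta must be positive")


def scheduled_stimulus_minutes(intervals: Sequence[float] = (3, 7, 14, 30, 64),
                               reps: int = 3) -> float:
    """Total scheduled stimulus time of one timing task, in minutes.

    Sum of the target intervals times the repetition count; excludes the
    subject's own report latencies and inter-trial intervals.
    """
    return float(sum(intervals)) * reps / 60.0


def sample_population(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw a population of subjects from the hierarchical ground truth.

    (logk_SV, logk_LV) come from a bivariate normal with correlation
    ``rho_logk``; log(tau) from a normal; the latent clock ICS from a
    lognormal with median ``alpha_mean``.  Estimation and production scalings
    are reciprocal views of the one latent clock (alpha_e = ICS,
    alpha_p = 1/ICS).  ``coupling_gamma`` shifts logk_SV by
    gamma * (ICS - 1); logk_LV is never coupled, because only experienced
    delays should be exposed to the internal clock.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cov = (config.sd_logk ** 2) * np.array(
        [[1.0, config.rho_logk], [config.rho_logk, 1.0]]
    )
    means = np.array([config.mean_logk_sv, config.mean_logk_lv])
    # eigh handles the degenerate cases (sd_logk = 0, |rho| = 1) exactly
    logk = rng.multivariate_normal(means, cov, size=n, method="eigh")
    logtau = rng.normal(config.mean_logtau, config.sd_logtau, size=n)
    ics = np.exp(rng.normal(np.log(config.alpha_mean), config.alpha_sd, size=n))
    logk_sv = logk[:, 0] + config.coupling_gamma * (ics - 1.0)

    width = len(str(n))
    return [
        SubjectProfile(
            subject_id=f"s{i + 1:0{width}d}",
            true_logk_sv=float(logk_sv[i]),
            true_logk_lv=float(logk[i, 1]),
            true_logtau=float(logtau[i]),
            true_alpha_e=float(ics[i]),
            true_alpha_p=float(1.0 / ics[i]),
            true_beta=float(config.beta),
            true_ics=float(ics[i]),
            group=config.group,
        )
        for i in range(n)
    ]


def build_task_schedule(config: SimulationConfig, task: str) -> pd.DataFrame:
    """Build the offer list for one intertemporal-choice task.

    Full factorial of delays x later rewards, each combination repeated
    ``reps_per_combo`` times, against the fixed sooner option at delay 0.
    Trial order is shuffled deterministically from the config seed; the
    first half of trials is labelled session 1, the second half session 2.
    """
    delays = config.delay_set(task)
    offers = [
        (d, r)
        for d in delays
        for r in config.reward_set
        for _ in range(config.reps_per_combo)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(TASKS.index(task),)))
    order = rng.permutation(len(offers))
    n = len(offers)
    rows = []
    for trial, idx in enumerate(order, start=1):
        d, r = offers[idx]
        rows.append({
            "task": task,
            "session": 1 if trial <= n / 2 else 2,
            "trial": trial,
            "sooner_reward": config.sooner_reward,
            "later_reward": r,
            "delay": d,
        })
    return pd.DataFrame(rows)


def simulate_choices(
    profiles: Sequence[SubjectProfile],
    schedule: pd.DataFrame,
    task: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every subject's choices over one task schedule.

    Each trial's choice is Bernoulli with the softmax-hyperbolic probability
    at the subject's true (logk, logtau) for the task; delays are in task
    units (seconds for SV, days for LV).
    """
    from tempodisc.discounting import hyperbolic_choice_probability

    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(100 + TASKS.index(task),)))
    sooner = schedule["sooner_reward"].to_numpy(float)
    later = schedule["later_reward"].to_numpy(float)
    delay = schedule["delay"].to_numpy(float)
    out = []
    for prof in profiles:
        logk = prof.true_logk_sv if task == "SV" else prof.true_logk_lv
        p_later = hyperbolic_choice_probability(
            sooner, later, delay, logk, prof.true_logtau
        )
        choice = (rng.random(len(schedule)) < p_later).astype(int)
        df = schedule.copy()
        df.insert(0, "subject_id", prof.subject_id)
        df.insert(1, "group", prof.group)
        df["choice"] = choice
        out.append(df)
    return pd.concat(out, ignore_index=True)


def simulate_timing_trials(
    profiles: Sequence[SubjectProfile],
    intervals: Sequence[float] = (3.0, 7.0, 14.0, 30.0, 64.0),
    reps: int = 3,
    weber_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate estimation and production trials for every subject.

    The mean report for target t is the subjective duration
    ST(t) = alpha * t^beta, with multiplicative normal noise of SD
    ``weber_fraction`` times the mean, so the coefficient of variation is
    constant across intervals (scalar timing).  Estimation reports are typed
    as integer seconds and are rounded to the nearest integer >= 1;
    production reports are positive reals floored at 0.1 s.
    """
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be strictly positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(200,)))
    rows = []
    for prof in profiles:
        for task in TIMING_TASKS:
            alpha = prof.true_alpha_e if task == "estimation" else prof.true_alpha_p
            trial = 0
            # random presentation order over interval x rep, as in the task
            grid = np.repeat(intervals, reps)
            order = rng.permutation(len(grid))
            for t in grid[order]:
                trial += 1
                mean_st = alpha * t ** prof.true_beta
                report = mean_st * (1.0 + rng.normal(0.0, weber_fraction))
                if task == "estimation":
                    report = max(1.0, round(report))
                else:
                    report = max(REPORT_FLOOR_S, report)
                rows.append({
                    "subject_id": prof.subject_id,
                    "group": prof.group,
                    "task": task,
                    "trial": trial,
                    "actual_s": float(t),
                    "reported_s": float(report),
                })
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full generator: population, both choice tasks, timing trials.

    Returns a dict with keys ``profiles`` (list of SubjectProfile),
    ``choices`` and ``timing`` (tidy DataFrames).  If ``out_dir`` is given,
    writes ``choices.csv``, ``timing.csv`` and ``truth.csv`` there.
    """
    profiles = sample_population(config)
    choice_frames = []
    for task in TASKS:
        schedule = build_task_schedule(config, task)
        choice_frames.append(
            simulate_choices(profiles, schedule, task, seed=config.seed)
        )
    choices = pd.concat(choice_frames, ignore_index=True)
    timing = simulate_timing_trials(
        profiles,
        intervals=config.timing_intervals,
        reps=config.timing_reps,
        weber_fraction=config.weber_fraction,
        seed=config.seed,
    )
    result = {"profiles": profiles, "choices": choices, "timing": timing}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        choices.to_csv(out / "choices.csv", index=False)
        timing.to_csv(out / "timing.csv", index=False)
        pd.DataFrame([asdict(p) for p in profiles]).to_csv(
            out / "truth.csv", index=False
        )
    return result
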