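"""Synthetic participants with the statistical structure the analyses assume.

A synthetic participant is a conditioning-model trajectory (RW or SS) wrapped
in the measurement process of a clamped-feedback reaching session:

* iid Gaussian motor noise on the heading angle (default sigma 3.5 deg);
* clockwise/counterclockwise clamp direction: the model works in
  adaptive-positive coordinates and the raw recorded heading is sign-mapped
  per ``clamp_dir`` (cw clamps drive CCW-positive adaptation);
* occasional outlier reaches replacing the heading with a draw outside the
  platform's screening bounds (rates default to the printed per-platform
  exclusion rates: lab 0.03%, web ~1.35%);
* reaction and movement times from truncated Gaussians (RT 293+/-49 ms,
  MT 103+/-31.2 ms), with a configurable fraction of "slow" trials that
  exceed the RT>400 ms / MT>300 ms exclusion thresholds;
* a within-movement feedback-correction: the heading measured 50 ms after
  movement initiation differs from the heading at the target radius by
  Gaussian noise (default mean -0.32 deg, sd 2.92 deg).

Clamp direction and CS+ cue assignment are counterbalanced across a cohort,
and every participant gets a unique schedule seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models
from .schedule import (ACQUISITION, TrialSchedule, make_compound_schedule,
                       make_differential_schedule)

#: design label -> (schedule factory kwargs, platform)
DESIGN_TABLE = {
    "exp1_differential": (dict(kind="differential", n_acq=600, n_probe=200), "lab"),
    "exp2_delay": (dict(kind="differential", n_acq=600, n_probe=200), "web"),
    "exp3_simultaneous": (dict(kind="differential", n_acq=600, n_probe=200), "web"),
    "exp4_compound": (dict(kind="compound", n_acq=600, n_probe_per_cs=100), "lab"),
}

#: printed per-platform outlier rates (fraction of trials)
OUTLIER_RATE = {"lab": 0.0003, "web": 0.0135}

# screening bounds (deg, oriented series) per platform; see preprocess
LAB_ABS_BOUND = 100.0
WEB_LO, WEB_HI = -50.0, 70.0


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions being emulated."""

    model: str = "rw"  # generating model: "rw" or "ss"
    params: dict = field(default_factory=lambda: dict(models.EXP1_RW))
    sigma_motor: float = 3.5  # deg, iid execution noise on heading
    rt_mean: float = 293.0  # ms
    rt_sd: float = 49.0
    rt_bounds: tuple = (100.0, 400.0)
    mt_mean: float = 103.0  # ms
    mt_sd: float = 31.2
    mt_bounds: tuple = (30.0, 300.0)
    slow_prob: float = 0.08  # fraction of trials exceeding RT/MT thresholds
    outlier_prob: float | None = None  # None -> platform default rate
    correction_mean: float = -0.32  # deg, heading(target radius) - heading(50 ms)
    correction_sd: float = 2.92
    salience_jitter_sd: float = 0.0  # log-normal sd on alpha_tone (off by default)
    salience_sum_fixed: bool = True  # jitter trades alpha_tone against alpha_light
    counterbalance: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.model not in ("rw", "ss"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("slow_prob",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.outlier_prob is not None and not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob outside [0, 1]")
        for name in ("sigma_motor", "rt_sd", "mt_sd", "correction_sd",
                     "salience_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ParticipantData:
    """Raw per-trial records of one (synthetic or imported) participant."""

    participant_id: str
    design: str
    platform: str  # "lab" | "web"
    clamp_dir: str  # "cw" | "ccw"
    cs_assignment: str  # physical cue serving as CS+ ("tone" | "light")
    schedule: TrialSchedule
    records: pd.DataFrame  # trial, phase, cs, clamp_deg, hand_angle_deg,
    #                        angle_50ms_deg, rt_ms, mt_ms

    def __post_init__(self):
        if len(self.records) != len(self.schedule):
            raise ValueError("one record per schedule trial required")
        if self.clamp_dir not in ("cw", "ccw"):
            raise ValueError(f"unknown clamp_dir {self.clamp_dir!r}")

    @property
    def orient_sign(self) -> float:
        """Multiplier mapping raw heading to adaptive-positive coordinates."""
        return 1.0 if self.clamp_dir == "cw" else -1.0


def _cs_column(schedule: TrialSchedule) -> list:
    out = []
    for t in schedule.trials:
        if t.cs_set == {"tone", "light"}:
            out.append("compound")
        else:
            (cue,) = t.cs_set
            out.append(cue)
    return out


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws by resampling (bounds are a few sd wide)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _jittered_params(config: SyntheticConfig, rng) -> dict:
    params = dict(config.params)
    if config.model == "rw" and config.salience_jitter_sd > 0:
        total = params["alpha_tone"] + params["alpha_light"]
        a_tone = params["alpha_tone"] * rng.lognormal(0.0, config.salience_jitter_sd)
        if config.salience_sum_fixed:
            a_tone = float(np.clip(a_tone, 0.0, total))
            params["alpha_tone"] = a_tone
            params["alpha_light"] = total - a_tone
        else:
            params["alpha_tone"] = float(min(a_tone, 1.0))
            params["alpha_light"] = float(
                min(params["alpha_light"]
                    * rng.lognormal(0.0, config.salience_jitter_sd), 1.0)
            )
    return params


def _outlier_draw(rng, platform):
    """Heading (oriented coordinates) guaranteed to violate the platform's
    screening bounds."""
    if platform == "lab":
        return rng.uniform(LAB_ABS_BOUND + 1, LAB_ABS_BOUND + 40) * rng.choice([-1, 1])
    if rng.random() < 0.5:
        return rng.uniform(WEB_LO - 30, WEB_LO - 1)
    return rng.uniform(WEB_HI + 1, WEB_HI + 30)


def generate_participant(
    schedule: TrialSchedule,
    config: SyntheticConfig,
    seed: int,
    participant_id: str = "p001",
    platform: str = "lab",
    clamp_dir: str = "cw",
) -> ParticipantData:
    """One synthetic participant over a given schedule; reproducible per seed."""
    rng = np.random.default_rng(seed)
    n = len(schedule)
    params = _jittered_params(config, rng)
    if config.model == "rw":
        traj = models.rw_simulate(schedule, models.RWParams(**params))
    else:
        traj = models.ss_simulate(schedule, models.SSParams(**params))
    oriented = traj.heading + (
        rng.normal(0.0, config.sigma_motor, n) if config.sigma_motor > 0 else 0.0
    )
    p_out = (OUTLIER_RATE[platform] if config.outlier_prob is None
             else config.outlier_prob)
    if p_out > 0:
        hits = np.flatnonzero(rng.random(n) < p_out)
        for i in hits:
            oriented[i] = _outlier_draw(rng, platform)
    sign = 1.0 if clamp_dir == "cw" else -1.0
    hand = oriented * sign

    rt = _truncnorm(rng, config.rt_mean, config.rt_sd, *config.rt_bounds, size=n)
    mt = _truncnorm(rng, config.mt_mean, config.mt_sd, *config.mt_bounds, size=n)
    slow = rng.random(n) < config.slow_prob
    slow_kind = rng.random(n) < 0.5
    rt[slow & slow_kind] = rng.uniform(405.0, 650.0, int((slow & slow_kind).sum()))
    mt[slow & ~slow_kind] = rng.uniform(305.0, 450.0, int((slow & ~slow_kind).sum()))

    # feedback correction lives in raw (unoriented) screen coordinates
    correction = rng.normal(config.correction_mean, config.correction_sd, n)
    angle_50 = hand - correction

    records = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "phase": schedule.phases,
            "cs": _cs_column(schedule),
            "clamp_deg": schedule.us_array,
            "hand_angle_deg": hand,
            "angle_50ms_deg": angle_50,
            "rt_ms": rt,
            "mt_ms": mt,
        }
    )
    return ParticipantData(
        participant_id=participant_id, design=schedule.design,
        platform=platform, clamp_dir=clamp_dir,
        cs_assignment=schedule.cs_plus, schedule=schedule, records=records,
    )


def _make_schedule(design: str, seed: int, cs_plus: str) -> TrialSchedule:
    kwargs, _ = DESIGN_TABLE[design]
    if kwargs["kind"] == "differential":
        return make_differential_schedule(
            kwargs["n_acq"], kwargs["n_probe"], seed=seed, design=design,
            cs_plus=cs_plus,
        )
    return make_compound_schedule(
        kwargs["n_acq"], kwargs["n_probe_per_cs"], seed=seed, cs_plus=cs_plus
    )


def generate_cohort(design: str, n_participants: int,
                    config: SyntheticConfig) -> list:
    """Counterbalanced cohort with unique per-participant schedules.

    Clamp direction alternates every participant and the CS+ cue every two,
    so any multiple of 4 is fully crossed (16 -> 8 cw / 8 ccw and
    8 tone-CS+ / 8 light-CS+).
    """
    if design not in DESIGN_TABLE:
        raise ValueError(f"unknown design {design!r}")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if config.counterbalance and n_participants % 2:
        raise ValueError("counterbalanced cohorts need an even n_participants")
    _, platform = DESIGN_TABLE[design]
    rng = np.random.default_rng(config.master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_participants, 2))
    cohort = []
    for i in range(n_participants):
        if config.counterbalance:
            clamp_dir = "cw" if i % 2 == 0 else "ccw"
            cs_plus = "tone" if (i // 2) % 2 == 0 else "light"
        else:
            clamp_dir = "cw"
            cs_plus = "tone"
        sched = _make_schedule(design, int(seeds[i, 0]), cs_plus)
        cohort.append(
            generate_participant(
                sched, config, seed=int(seeds[i, 1]),
                participant_id=f"p{i + 1:03d}", platform=platform,
                clamp_dir=clamp_dir,
            )
        )
    return cohort


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``config`` with every noise source switched off."""
    return replace(config, sigma_motor=0.0, outlier_prob=0.0, slow_prob=0.0,
                   correction_sd=0.0, correction_mean=0.0)
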