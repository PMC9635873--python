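"""Rescorla-Wagner and state-space simulators of clamped-feedback adaptation.

Both models predict the heading angle (deg, adaptive-positive: away from the
clamped cursor) on every trial of a :class:`~reachcond.schedule.TrialSchedule`.

Rescorla-Wagner (RW). Each conditioned stimulus i carries an associative
strength V_i (deg). The movement plan is itself a CS, present on every trial;
tone and light are present only when scheduled. The predicted heading on
trial n is the summed strength of the CSs present,

    V_total[n] = V_plan[n] + sum_{i in cs_set(n)} V_i[n],

and after the movement every present CS updates from the shared sensory
prediction error,

    V_i[n+1] = V_i[n] + alpha_i * beta * (lambda * US[n] - V_total[n]),

with US = 1 on 15-deg-clamp trials and 0 on 0-deg-clamp and no-feedback
trials. lambda is the asymptotic conditioning level (deg), beta the US
learning rate and alpha_i the salience of CS i. Absent CSs carry their
strengths forward unchanged. The response on trial n uses the pre-update
strengths (response precedes learning).

State space (SS). A single motor state x (deg) with retention A and learning
rate B, driven by the previous trial's error:

    x[n+1] = A * x[n] + B * e[n],  e[n] = 15 on error-clamp trials else 0.

The SS prediction never depends on the cue presented on the current trial,
which is why it cannot produce a Pavlovian (current-CS) effect.

All simulation is done in adaptive-positive coordinates; the 15-deg clamp
error enters with a positive sign (equivalent to the -15/flip convention up
to a global sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import ACQUISITION, CLAMP_ERROR, TrialSchedule

#: parameter sets used for the published-style differential (Experiment 1)
#: and compound (Experiment 4) simulations
EXP1_RW = dict(lam=15.0, beta=0.12, alpha_plan=0.99, alpha_tone=0.002,
               alpha_light=0.002)
EXP4_RW = dict(lam=15.0, beta=0.02, alpha_plan=0.99, alpha_tone=0.1,
               alpha_light=0.1)
DEFAULT_SS = dict(A=0.9, B=0.12)


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters (see module docstring for roles/units)."""

    lam: float
    beta: float
    alpha_plan: float
    alpha_tone: float
    alpha_light: float

    def __post_init__(self):
        for name in ("beta", "alpha_plan", "alpha_tone", "alpha_light"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        # coupled update is a contraction-or-bounded map only below this
        total = (self.alpha_plan + self.alpha_tone + self.alpha_light) * self.beta
        if total >= 2.0:
            raise ValueError(
                f"(alpha_plan+alpha_tone+alpha_light)*beta = {total} >= 2: "
                "unstable update"
            )

    def alpha(self, cue: str) -> float:
        return {"plan": self.alpha_plan, "tone": self.alpha_tone,
                "light": self.alpha_light}[cue]


@dataclass(frozen=True)
class SSParams:
    """State-space parameters: retention A and learning rate B, both in [0, 1]."""

    A: float
    B: float

    def __post_init__(self):
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"A={self.A} outside [0, 1]")
        if not 0.0 <= self.B <= 1.0:
            raise ValueError(f"B={self.B} outside [0, 1]")


@dataclass
class RWTrajectory:
    """Per-trial associative strengths (pre-update, i.e. as expressed on that
    trial) and the predicted heading ``v_total``."""

    v_plan: np.ndarray
    v_tone: np.ndarray
    v_light: np.ndarray
    v_total: np.ndarray  # predicted heading, deg
    spe: np.ndarray  # lambda*US - V_total per trial
    us_indicator: np.ndarray

    @property
    def heading(self) -> np.ndarray:
        return self.v_total

    def heading_if(self, cue: str) -> np.ndarray:
        """Counterfactual predicted heading had ``cue`` (alone) been the
        current-trial CS, holding the learned state fixed."""
        v_cue = {"tone": self.v_tone, "light": self.v_light}[cue]
        return self.v_plan + v_cue


@dataclass
class SSTrajectory:
    """Per-trial motor state ``x`` (= predicted heading) and driving error."""

    x: np.ndarray
    e: np.ndarray

    @property
    def heading(self) -> np.ndarray:
        return self.x

    def heading_if(self, cue: str) -> np.ndarray:
        # the state-space prediction is blind to the current-trial cue
        return self.x


def rw_step(v_present: float, v_i: float, alpha_i: float, beta: float,
            lam: float, us: float) -> float:
    """Single Rescorla-Wagner update of one present CS.

    ``v_present`` is the summed strength of all CSs present on the trial
    (V_total); the returned value is
    ``v_i + alpha_i * beta * (lam * us - v_present)``.
    """
    if not 0.0 <= alpha_i <= 1.0:
        raise ValueError("alpha_i outside [0, 1]")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta outside [0, 1]")
    return v_i + alpha_i * beta * (lam * us - v_present)


def us_indicator(schedule: TrialSchedule) -> np.ndarray:
    """1 on error-clamp (15 deg) trials, 0 on 0-deg-clamp and no-feedback
    trials."""
    return np.array(
        [1.0 if (t.us is not None and t.us == CLAMP_ERROR) else 0.0
         for t in schedule.trials]
    )


def rw_simulate(schedule: TrialSchedule, params: RWParams,
                v0: dict | None = None) -> RWTrajectory:
    """Simulate the Rescorla-Wagner model over a schedule.

    Strengths start at 0 (override via ``v0`` with keys plan/tone/light).
    """
    n = len(schedule)
    us = us_indicator(schedule)
    v = {"plan": 0.0, "tone": 0.0, "light": 0.0}
    if v0:
        v.update(v0)
    v_plan = np.empty(n)
    v_tone = np.empty(n)
    v_light = np.empty(n)
    v_total = np.empty(n)
    for i, trial in enumerate(schedule.trials):
        v_plan[i], v_tone[i], v_light[i] = v["plan"], v["tone"], v["light"]
        present = ("plan",) + tuple(sorted(trial.cs_set))
        v_total[i] = sum(v[c] for c in present)
        err = params.lam * us[i] - v_total[i]
        for c in present:
            v[c] = v[c] + params.alpha(c) * params.beta * err
    spe = params.lam * us - v_total
    return RWTrajectory(v_plan=v_plan, v_tone=v_tone, v_light=v_light,
                        v_total=v_total, spe=spe, us_indicator=us)


def ss_simulate(schedule: TrialSchedule, params: SSParams,
                x0: float = 0.0) -> SSTrajectory:
    """Simulate the state-space model over a schedule (x starts at ``x0``)."""
    n = len(schedule)
    e = CLAMP_ERROR * us_indicator(schedule)
    x = np.empty(n)
    state = x0
    for i in range(n):
        x[i] = state
        state = params.A * state + params.B * e[i]
    return SSTrajectory(x=x, e=e)


# ---------------------------------------------------------------------------
# trajectory-level effects


@dataclass
class TrajectoryEffects:
    """2x2 cell means of the trial-to-trial heading change and the two
    derived contrasts (deg). ``cells[i, j]``: previous-trial CS i x
    current-trial CS j, index 0 = CS+, 1 = CS-."""

    cells: np.ndarray
    pavlovian: float
    adaptation: float
    interaction: float


_CELL_NAMES = [["CS+ after CS+", "CS- after CS+"],
               ["CS+ after CS-", "CS- after CS-"]]


def cells_to_contrasts(cells: np.ndarray) -> tuple[float, float, float]:
    """Equal-weight marginal contrasts of a 2x2 (previous x current) table:
    (pavlovian, adaptation, interaction)."""
    cells = np.asarray(cells, dtype=float)
    pav = cells[:, 0].mean() - cells[:, 1].mean()
    adapt = cells[0, :].mean() - cells[1, :].mean()
    inter = (cells[0, 0] - cells[0, 1]) - (cells[1, 0] - cells[1, 1])
    return float(pav), float(adapt), float(inter)


def trajectory_effects(heading, schedule: TrialSchedule,
                       phase: str = ACQUISITION,
                       statistic: str = "mean") -> TrajectoryEffects:
    """Trial-to-trial change analysis of a (noiseless) heading series.

    Delta[n] = heading[n] - heading[n-1] over consecutive trial pairs within
    ``phase``; cell (i, j) is the mean (or median) Delta over trials with
    CS_i on trial n-1 and CS_j on trial n. The Pavlovian effect is the
    equal-weight current-CS contrast, the adaptation effect the previous-CS
    contrast.
    """
    heading = np.asarray(heading, dtype=float)
    if heading.shape[0] != len(schedule):
        raise ValueError("heading series not aligned to schedule")
    sl = schedule.phase_slice(phase)
    labels = schedule.cs_labels()[sl]
    if sl.stop - sl.start < 2:
        raise ValueError(f"phase {phase!r} has fewer than 2 trials")
    if "compound" in labels:
        raise ValueError(
            "trajectory_effects is defined for differential (CS+/CS-) "
            "phases; use the effects module for compound designs"
        )
    theta = heading[sl]
    delta = np.diff(theta)
    prev_lab, cur_lab = labels[:-1], labels[1:]
    agg = np.mean if statistic == "mean" else np.median
    cells = np.empty((2, 2))
    for i, p in enumerate("+-"):
        for j, c in enumerate("+-"):
            sel = (prev_lab == p) & (cur_lab == c)
            if not sel.any():
                raise ValueError(
                    f"empty cell '{_CELL_NAMES[i][j]}' in phase {phase!r}"
                )
            cells[i, j] = agg(delta[sel])
    pav, adapt, inter = cells_to_contrasts(cells)
    return TrajectoryEffects(cells=cells, pavlovian=pav, adaptation=adapt,
                             interaction=inter)


def pavlovian_contrast(traj, schedule: TrialSchedule,
                       phase: str = ACQUISITION) -> float:
    """Structural Pavlovian effect of a model trajectory.

    Mean over phase trials of the difference in the model's predicted heading
    had the current CS been the CS+ cue vs the CS- cue, with the learned
    state held fixed. This equals the expectation of the Delta-cell Pavlovian
    estimator of :func:`trajectory_effects` (which on any single finite
    schedule additionally carries O(n^-1/2) retention-fluctuation sampling
    error), and it is identically zero for the state-space model, whose
    prediction does not depend on the current cue.
    """
    sl = schedule.phase_slice(phase)
    if sl.stop - sl.start < 1:
        raise ValueError(f"phase {phase!r} is empty")
    cs_plus = schedule.cs_plus
    cs_minus = "light" if cs_plus == "tone" else "tone"
    diff = traj.heading_if(cs_plus)[sl] - traj.heading_if(cs_minus)[sl]
    return float(diff.mean())


# ---------------------------------------------------------------------------
# parameter sweeps


def _simulate(model: str, schedule: TrialSchedule, params: dict):
    if model == "rw":
        return rw_simulate(schedule, RWParams(**params))
    if model == "ss":
        return ss_simulate(schedule, SSParams(**params))
    raise ValueError(f"unknown model {model!r}")


def _expand_rw_axis(name: str, value: float, params: dict) -> None:
    if name == "alpha_cs":  # tone and light constrained to the same salience
        params["alpha_tone"] = value
        params["alpha_light"] = value
    else:
        params[name] = value


def sweep_pavlovian(model: str, grid: dict, schedules,
                    phase: str = ACQUISITION,
                    base_params: dict | None = None,
                    estimator: str = "contrast") -> np.ndarray:
    """Pavlovian effect over a 2-axis parameter grid, averaged over schedules.

    Parameters
    ----------
    model : {"rw", "ss"}
    grid : dict
        Exactly two axes, name -> 1-d array of values. RW axis names:
        ``lam``, ``beta``, ``alpha_plan``, ``alpha_cs`` (sets tone = light);
        SS axis names: ``A``, ``B``.
    schedules : TrialSchedule or sequence of TrialSchedule
        Effects are averaged across schedules (different seeds emulate the
        participant-unique trial orders).
    estimator : {"contrast", "delta"}
        ``"contrast"`` uses :func:`pavlovian_contrast` (exact, no sampling
        error); ``"delta"`` uses the Delta-cell estimator of
        :func:`trajectory_effects`, the same computation applied to data.

    Returns a matrix of shape ``(len(axis0), len(axis1))`` with axes in the
    dict's insertion order.
    """
    if len(grid) != 2:
        raise ValueError("grid must have exactly two axes")
    if isinstance(schedules, TrialSchedule):
        schedules = [schedules]
    (name0, ax0), (name1, ax1) = grid.items()
    base = dict(EXP1_RW if model == "rw" else DEFAULT_SS)
    if base_params:
        base.update(base_params)
    out = np.empty((len(ax0), len(ax1)))
    for i, v0 in enumerate(ax0):
        for j, v1 in enumerate(ax1):
            params = dict(base)
            if model == "rw":
                _expand_rw_axis(name0, v0, params)
                _expand_rw_axis(name1, v1, params)
            else:
                params[name0] = v0
                params[name1] = v1
            vals = []
            for sched in schedules:
                traj = _simulate(model, sched, params)
                if estimator == "contrast":
                    vals.append(pavlovian_contrast(traj, sched, phase))
                elif estimator == "delta":
                    vals.append(
                        trajectory_effects(traj.heading, sched, phase).pavlovian
                    )
                else:
                    raise ValueError(f"unknown estimator {estimator!r}")
            out[i, j] = np.mean(vals)
    return out
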