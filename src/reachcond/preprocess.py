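"""Raw records -> oriented, baseline-subtracted heading series with masks.

Orientation maps every participant into adaptive-positive coordinates: the
sign of the heading angle is flipped for counterclockwise-clamp participants
so that positive values always point away from the clamped cursor. The
heading on the first acquisition trial is then treated as the baseline
reaching angle and subtracted from all trials.

Screening follows the platform-specific printed rules:

* lab: |theta| > 100 deg off target, or a trial-to-trial change > 25 deg;
* web: theta outside (-50, 70) deg, or a trial-to-trial change > 20 deg.

A change-based flag marks the later trial of the pair. Slow trials
(RT > 400 ms and/or MT > 300 ms, strict) are excluded from the
trial-to-trial-change analyses only, never from time-course exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import ACQUISITION, TrialSchedule
from .synthetic import ParticipantData

RT_LIMIT_MS = 400.0
MT_LIMIT_MS = 300.0

OUTLIER_RULES = {
    "lab": dict(abs_bound=100.0, jump=25.0),
    "web": dict(lo=-50.0, hi=70.0, jump=20.0),
}


@dataclass
class PreprocessedSeries:
    """Oriented, baselined heading series of one participant plus masks."""

    theta: np.ndarray  # deg, adaptive-positive, baseline-subtracted
    outlier_mask: np.ndarray  # True = screened out
    slow_mask: np.ndarray
    delta: np.ndarray  # theta[n] - theta[n-1]
    delta_valid: np.ndarray  # pairing rule satisfied and both trials clean
    correction: np.ndarray  # heading(target radius) - heading(50 ms), raw deg
    schedule: TrialSchedule
    baseline: float = 0.0  # first-acquisition-trial heading already removed

    @property
    def mask(self) -> np.ndarray:
        """Combined exclusion mask used for the Delta analyses."""
        return self.outlier_mask | self.slow_mask

    @property
    def theta_unbaselined(self) -> np.ndarray:
        """Oriented heading without the baseline shift; both conditioning
        models pin the initial state at zero, so time-course fits use this
        series (an additive offset lies outside either model class)."""
        return self.theta + self.baseline


def orient_and_baseline(data: ParticipantData) -> np.ndarray:
    """Sign-flip ccw participants and subtract the first-acquisition-trial
    heading (the baseline reach)."""
    hand = data.records["hand_angle_deg"].to_numpy(dtype=float)
    oriented = hand * data.orient_sign
    acq = np.flatnonzero(data.schedule.phases == ACQUISITION)
    if acq.size == 0:
        raise ValueError("no acquisition trials; baseline undefined")
    baseline = oriented[acq[0]]
    if not np.isfinite(baseline):
        raise ValueError("first acquisition trial is missing/non-finite")
    return oriented - baseline


def flag_outliers(theta, platform: str) -> np.ndarray:
    """Outlier mask for an oriented heading series under the platform rule.

    Jump-based flags mark trial n of the (n-1, n) pair.
    """
    theta = np.asarray(theta, dtype=float)
    try:
        rule = OUTLIER_RULES[platform]
    except KeyError:
        raise ValueError(f"unknown platform {platform!r}") from None
    if platform == "lab":
        mask = np.abs(theta) > rule["abs_bound"]
    else:
        mask = (theta < rule["lo"]) | (theta > rule["hi"])
    jump = np.abs(np.diff(theta)) > rule["jump"]
    mask[1:] |= jump
    return mask


def flag_slow_trials(data: ParticipantData) -> np.ndarray:
    """True where RT exceeds 400 ms and/or MT exceeds 300 ms (strict)."""
    rt = data.records["rt_ms"].to_numpy(dtype=float)
    mt = data.records["mt_ms"].to_numpy(dtype=float)
    return (rt > RT_LIMIT_MS) | (mt > MT_LIMIT_MS)


def delta_heading(theta, mask, phases) -> tuple[np.ndarray, np.ndarray]:
    """Trial-to-trial heading change with its validity flags.

    delta[n] = theta[n] - theta[n-1]; valid only where both trials of the
    pair are unmasked and belong to the same phase (the phase-boundary pair
    is never analyzed). delta[0] is undefined (NaN, invalid).
    """
    theta = np.asarray(theta, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    phases = np.asarray(phases)
    if theta.size < 2:
        raise ValueError("series must have length >= 2")
    delta = np.full(theta.size, np.nan)
    delta[1:] = np.diff(theta)
    valid = np.zeros(theta.size, dtype=bool)
    valid[1:] = (~mask[1:]) & (~mask[:-1]) & (phases[1:] == phases[:-1])
    delta[~valid] = np.nan
    return delta, valid


@dataclass
class FeedbackCorrection:
    per_trial: np.ndarray  # deg
    participant_mean: float  # mean over acquisition trials
    cs_plus_mean: float | None  # per-CS means, differential designs only
    cs_minus_mean: float | None


def feedback_correction(data: ParticipantData) -> FeedbackCorrection:
    """Within-movement correction: heading at the target radius minus heading
    50 ms after movement initiation (raw screen coordinates)."""
    hand = data.records["hand_angle_deg"].to_numpy(dtype=float)
    a50 = data.records["angle_50ms_deg"].to_numpy(dtype=float)
    corr = hand - a50
    acq = data.schedule.phases == ACQUISITION
    labels = data.schedule.cs_labels()
    if "compound" in labels[acq]:
        plus_mean = minus_mean = None
    else:
        plus_mean = float(corr[acq & (labels == "+")].mean())
        minus_mean = float(corr[acq & (labels == "-")].mean())
    return FeedbackCorrection(
        per_trial=corr,
        participant_mean=float(corr[acq].mean()),
        cs_plus_mean=plus_mean,
        cs_minus_mean=minus_mean,
    )


def preprocess(data: ParticipantData) -> PreprocessedSeries:
    """Full single-participant preprocessing chain."""
    oriented = data.records["hand_angle_deg"].to_numpy(dtype=float) * data.orient_sign
    theta = orient_and_baseline(data)
    baseline = float(oriented[0] - theta[0]) if len(theta) else 0.0
    outliers = flag_outliers(theta, data.platform)
    slow = flag_slow_trials(data)
    delta, valid = delta_heading(theta, outliers | slow, data.schedule.phases)
    corr = feedback_correction(data)
    return PreprocessedSeries(
        theta=theta, outlier_mask=outliers, slow_mask=slow, delta=delta,
        delta_valid=valid, correction=corr.per_trial, schedule=data.schedule,
        baseline=baseline,
    )
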