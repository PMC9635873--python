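"""Trial schedules for differential and compound conditioning designs.

Each experiment is an ordered sequence of reaching trials. During acquisition
every trial carries clamped cursor feedback (the US): a 15 deg clamp on CS+
trials (error signal) or a 0 deg clamp on CS- trials (no error). During the
probe phase the feedback is withheld entirely (``us=None``). The movement plan
acts as an additional, implicit CS on every trial and is therefore not listed
in ``cs_set``.

Differential designs interleave CS+ and CS- pseudo-randomly under the
constraint that the acquisition CS sequence shows no significant lag-1
autocorrelation, so participants cannot predict the upcoming cue from the
previous one. Sequences are built by shuffling a balanced multiset (exact
50/50 counts) and rejection-sampled until the lag-1 criterion passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ACQUISITION = "acquisition"
PROBE = "probe"

CLAMP_ERROR = 15.0  # deg, the error-bearing clamp (US on CS+ trials)
CLAMP_ZERO = 0.0  # deg, straight-to-target clamp (US on CS- trials)

#: two-sided p-value above which a lag-1 autocorrelation is deemed
#: non-significant and the candidate CS sequence accepted
LAG1_ALPHA = 0.05

DESIGNS = ("exp1_differential", "exp2_delay", "exp3_simultaneous", "exp4_compound")


@dataclass(frozen=True)
class Trial:
    """One reaching trial.

    Parameters
    ----------
    index : int
        1-based trial number within the session.
    phase : str
        ``"acquisition"`` or ``"probe"``.
    cs_set : frozenset of str
        Explicit cues presented, subset of ``{"tone", "light"}``. The
        movement-plan CS is implicitly present on every trial.
    us : float or None
        Clamp angle in degrees (15 or 0) or ``None`` when no feedback is
        shown (probe trials).
    """

    index: int
    phase: str
    cs_set: frozenset
    us: float | None

    def __post_init__(self):
        if self.phase not in (ACQUISITION, PROBE):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.cs_set:
            raise ValueError("cs_set must be non-empty")
        if not self.cs_set <= {"tone", "light"}:
            raise ValueError(f"unknown cues in cs_set: {set(self.cs_set)}")
        if self.phase == PROBE and self.us is not None:
            raise ValueError("probe trials carry no US (us must be None)")


@dataclass
class TrialSchedule:
    """Ordered trial list plus design metadata.

    ``cs_plus`` names the cue paired with the 15 deg clamp in differential
    designs (irrelevant for compound acquisition, where both cues are always
    present). ``lag1_stat``/``lag1_p`` record the lag-1 autocorrelation test
    of the acquisition CS sequence where defined.
    """

    trials: list
    design: str
    seed: int
    cs_plus: str = "tone"
    lag1_stat: float | None = None
    lag1_p: float | None = None
    # imperative-onset jitter is metadata only; no analysis consumes it
    imperative_delay_range_ms: tuple = field(default=(800, 1200), repr=False)

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        for i, t in enumerate(self.trials, start=1):
            if t.index != i:
                raise ValueError("trial indices must be contiguous and 1-based")

    def __len__(self):
        return len(self.trials)

    @property
    def phases(self) -> np.ndarray:
        return np.array([t.phase for t in self.trials])

    @property
    def us_array(self) -> np.ndarray:
        """US per trial with ``nan`` for no-feedback trials."""
        return np.array(
            [np.nan if t.us is None else t.us for t in self.trials], dtype=float
        )

    def cs_labels(self) -> np.ndarray:
        """Per-trial CS label: '+' (CS+ cue alone), '-' (CS- cue alone) or
        'compound' (both cues)."""
        out = []
        for t in self.trials:
            if t.cs_set == {"tone", "light"}:
                out.append("compound")
            elif self.cs_plus in t.cs_set:
                out.append("+")
            else:
                out.append("-")
        return np.array(out)

    def phase_slice(self, phase: str) -> slice:
        idx = np.flatnonzero(self.phases == phase)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


def lag1_autocorrelation(cs_sequence) -> tuple[float, float]:
    """Lag-1 autocorrelation of a +/-1-coded CS sequence.

    Returns the Pearson correlation of ``s[1:]`` with ``s[:-1]`` and a
    two-sided p-value for the null of zero correlation.
    """
    s = np.asarray(cs_sequence, dtype=float)
    if s.size < 3:
        raise ValueError("sequence must have length >= 3")
    if np.ptp(s) == 0:
        raise ValueError("sequence is constant; lag-1 correlation undefined")
    a, b = s[1:], s[:-1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("shifted sequence is constant; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _balanced_shuffle(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random permutation of an exactly balanced +/-1 multiset of size n."""
    seq = np.repeat([1.0, -1.0], n // 2)
    rng.shuffle(seq)
    return seq


def _sample_lag1_ok(rng, n, max_attempts):
    """Balanced +/-1 sequence passing the lag-1 non-significance criterion."""
    if n < 3:  # too short for the test; counts alone constrain the design
        return _balanced_shuffle(rng, n), None, None
    for _ in range(max_attempts):
        seq = _balanced_shuffle(rng, n)
        r, p = lag1_autocorrelation(seq)
        if p > LAG1_ALPHA:
            return seq, r, p
    raise RuntimeError(
        f"no balanced sequence of length {n} passed the lag-1 criterion "
        f"within {max_attempts} attempts (over-constrained design)"
    )


def make_differential_schedule(
    n_acq: int,
    n_probe: int,
    seed: int,
    max_attempts: int = 1000,
    design: str = "exp1_differential",
    cs_plus: str = "tone",
) -> TrialSchedule:
    """Differential-conditioning schedule: 50/50 interleaved CS+/CS-.

    Acquisition has ``n_acq/2`` CS+ (15 deg clamp) and ``n_acq/2`` CS-
    (0 deg clamp) trials; the probe phase has ``n_probe/2`` of each CS with
    no feedback. The acquisition CS sequence is rejection-sampled until it
    shows no significant lag-1 autocorrelation. Deterministic given ``seed``.
    """
    if n_acq < 0 or n_probe < 0:
        raise ValueError("trial counts must be non-negative")
    if n_acq % 2 or n_probe % 2:
        raise ValueError("n_acq and n_probe must be even for a 50/50 design")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if cs_plus not in ("tone", "light"):
        raise ValueError("cs_plus must be 'tone' or 'light'")
    rng = np.random.default_rng(seed)
    acq_seq, r, p = _sample_lag1_ok(rng, n_acq, max_attempts)
    probe_seq = _balanced_shuffle(rng, n_probe)
    cs_minus = "light" if cs_plus == "tone" else "tone"
    trials = []
    for code in acq_seq:
        is_plus = code > 0
        trials.append(
            Trial(
                index=len(trials) + 1,
                phase=ACQUISITION,
                cs_set=frozenset({cs_plus if is_plus else cs_minus}),
                us=CLAMP_ERROR if is_plus else CLAMP_ZERO,
            )
        )
    for code in probe_seq:
        trials.append(
            Trial(
                index=len(trials) + 1,
                phase=PROBE,
                cs_set=frozenset({cs_plus if code > 0 else cs_minus}),
                us=None,
            )
        )
    return TrialSchedule(
        trials=trials, design=design, seed=seed, cs_plus=cs_plus,
        lag1_stat=r, lag1_p=p,
    )


def make_compound_schedule(
    n_acq: int,
    n_probe_per_cs: int,
    seed: int,
    cs_plus: str = "tone",
) -> TrialSchedule:
    """Compound-conditioning schedule (Experiment-4 style).

    Every acquisition trial presents tone+light together with the 15 deg
    clamp. The probe phase contains ``n_probe_per_cs`` no-feedback trials for
    each of compound, tone-alone and light-alone, in random order.
    """
    if n_acq < 0 or n_probe_per_cs < 0:
        raise ValueError("trial counts must be non-negative")
    rng = np.random.default_rng(seed)
    probe_sets = (
        [frozenset({"tone", "light"})] * n_probe_per_cs
        + [frozenset({"tone"})] * n_probe_per_cs
        + [frozenset({"light"})] * n_probe_per_cs
    )
    order = rng.permutation(len(probe_sets))
    trials = [
        Trial(index=i + 1, phase=ACQUISITION,
              cs_set=frozenset({"tone", "light"}), us=CLAMP_ERROR)
        for i in range(n_acq)
    ]
    for k in order:
        trials.append(
            Trial(index=len(trials) + 1, phase=PROBE,
                  cs_set=probe_sets[k], us=None)
        )
    return TrialSchedule(
        trials=trials, design="exp4_compound", seed=seed, cs_plus=cs_plus
    )


def make_constant_schedule(
    n: int,
    cs_set=("tone",),
    us: float | None = CLAMP_ERROR,
    phase: str = ACQUISITION,
    design: str = "exp1_differential",
) -> TrialSchedule:
    """Degenerate schedule repeating one trial type; handy for closed-form
    checks (constant-US acquisition, probe-only extinction, ...)."""
    trials = [
        Trial(index=i + 1, phase=phase, cs_set=frozenset(cs_set),
              us=None if phase == PROBE else us)
        for i in range(n)
    ]
    return TrialSchedule(trials=trials, design=design, seed=0)
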