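"""Trial-by-trial effect statistics for conditioning analyses.

The central quantity is the trial-to-trial change in heading angle
(Delta theta). For differential designs each valid Delta is assigned to one
of four cells by the CS on the previous trial crossed with the CS on the
current trial; a two-way repeated-measures ANOVA on the per-participant cell
means yields the adaptation effect (previous-trial CS), the Pavlovian effect
(current-trial CS) and their interaction. The ANOVA is computed from the
full within-subject sums-of-squares decomposition; for these 1-df factors
each F equals the square of the paired t on the corresponding contrast.

Also provided: the binned multiple-regression view of how the two effects
evolve over acquisition, the compound-probe Friedman analysis, the
overshadowing (tone vs light) correlation, and the pooled
singleton-vs-compound ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import PreprocessedSeries
from .schedule import ACQUISITION, PROBE

_DIFF_LEVELS = ("+", "-")
_POOLED_LEVELS = ("compound", "singleton")


def _participant_labels(pre: PreprocessedSeries, pooled: bool = False):
    labels = pre.schedule.cs_labels()
    if pooled:
        labels = np.where(labels == "compound", "compound", "singleton")
    return labels


def _cells(delta, valid, labels, sl, levels, statistic, who=""):
    """Per-participant (previous x current) cell table of valid Deltas."""
    agg = {"mean": np.mean, "median": np.median}[statistic]
    d = delta[sl]
    v = valid[sl].copy()
    v[0] = False  # the first in-phase trial has no in-phase predecessor
    lab = labels[sl]
    out = np.empty((len(levels), len(levels)))
    for i, p in enumerate(levels):
        for j, c in enumerate(levels):
            sel = np.zeros(len(d), dtype=bool)
            sel[1:] = v[1:] & (lab[:-1] == p) & (lab[1:] == c)
            if not sel.any():
                raise ValueError(
                    f"empty cell (previous={p!r}, current={c!r}){who}"
                )
            out[i, j] = agg(d[sel])
    return out


def cell_stats(pre: PreprocessedSeries, phase: str = ACQUISITION,
               statistic: str = "mean") -> np.ndarray:
    """2x2 cell table (rows: previous CS {+, -}; cols: current CS) of one
    participant's valid Delta theta within ``phase``."""
    sl = pre.schedule.phase_slice(phase)
    labels = _participant_labels(pre)
    if "compound" in labels[sl]:
        raise ValueError("cell_stats requires a differential (CS+/CS-) phase")
    return _cells(pre.delta, pre.delta_valid, labels, sl, _DIFF_LEVELS,
                  statistic)


@dataclass
class EffectTest:
    F: float
    p: float
    eta_p2: float
    df: tuple
    mean_diff: float  # contrast group mean, deg
    ci95: tuple  # 95% CI of the contrast
    cohen_d: float


@dataclass
class EffectsResult:
    cells: np.ndarray  # (n_subjects, 2, 2)
    previous: EffectTest  # adaptation effect (trial n-1 CS)
    current: EffectTest  # Pavlovian effect (trial n CS)
    interaction: EffectTest
    contrasts: dict  # per-participant contrast arrays by effect name
    levels: tuple = _DIFF_LEVELS


def _contrast_test(c, F, eta):
    n = c.size
    m = float(c.mean())
    sd = float(c.std(ddof=1))
    tcrit = stats.t.ppf(0.975, n - 1)
    sem = sd / np.sqrt(n)
    p = float(stats.f.sf(F, 1, n - 1))
    return EffectTest(F=float(F), p=p, eta_p2=float(eta), df=(1, n - 1),
                      mean_diff=m, ci95=(m - tcrit * sem, m + tcrit * sem),
                      cohen_d=m / sd if sd > 0 else np.nan)


def rm_anova_2x2(cells, levels=_DIFF_LEVELS) -> EffectsResult:
    """Two-way repeated-measures ANOVA on (n_subjects, 2, 2) cell means.

    Factors: previous-trial CS x current-trial CS. Partial eta-squared is
    SS_effect / (SS_effect + SS_error) with the effect's own subject-by-
    effect interaction as error.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n_subjects, 2, 2)")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    if not np.isfinite(y).all():
        raise ValueError("incomplete cells (non-finite entries)")

    grand = y.mean()
    m_i = y.mean(axis=(1, 2))  # subject
    m_p = y.mean(axis=(0, 2))  # previous-CS level
    m_c = y.mean(axis=(0, 1))  # current-CS level
    m_pc = y.mean(axis=0)
    m_ip = y.mean(axis=2)
    m_ic = y.mean(axis=1)

    ss_p = 2 * n * ((m_p - grand) ** 2).sum()
    ss_ps = 2 * ((m_ip - m_i[:, None] - m_p[None, :] + grand) ** 2).sum()
    ss_c = 2 * n * ((m_c - grand) ** 2).sum()
    ss_cs = 2 * ((m_ic - m_i[:, None] - m_c[None, :] + grand) ** 2).sum()
    ss_pc = n * ((m_pc - m_p[:, None] - m_c[None, :] + grand) ** 2).sum()
    resid = (y - m_ip[:, :, None] - m_ic[:, None, :] - m_pc[None, :, :]
             + m_i[:, None, None] + m_p[None, :, None] + m_c[None, None, :]
             - grand)
    ss_pcs = (resid ** 2).sum()

    for name, err in (("previous", ss_ps), ("current", ss_cs),
                      ("interaction", ss_pcs)):
        if err <= 0:
            raise ValueError(
                f"zero error variance for the {name} effect (degenerate "
                "cells); F undefined"
            )

    f_p = ss_p / (ss_ps / (n - 1))
    f_c = ss_c / (ss_cs / (n - 1))
    f_pc = ss_pc / (ss_pcs / (n - 1))

    # per-participant contrasts (equal cell weights)
    adapt = y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)
    pav = y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1)
    inter = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])

    return EffectsResult(
        cells=y,
        previous=_contrast_test(adapt, f_p, ss_p / (ss_p + ss_ps)),
        current=_contrast_test(pav, f_c, ss_c / (ss_c + ss_cs)),
        interaction=_contrast_test(inter, f_pc, ss_pc / (ss_pc + ss_pcs)),
        contrasts=dict(previous=adapt, current=pav, interaction=inter),
        levels=tuple(levels),
    )


def differential_effects(pres, phase: str = ACQUISITION,
                         statistic: str = "mean") -> EffectsResult:
    """Cohort-level 2x2 analysis: per-participant cells then the RM ANOVA."""
    cells = np.stack([cell_stats(p, phase, statistic) for p in pres])
    return rm_anova_2x2(cells)


# ---------------------------------------------------------------------------
# binned dynamics (regression of Delta on coded CS predictors)


@dataclass
class DynamicsResult:
    weights: np.ndarray  # (n_subjects, n_bins, 3): previous, current, interaction
    slopes: np.ndarray  # (n_subjects, 3), weight change per bin
    slope_tests: dict  # effect -> (t, p) one-sample test of zero slope
    slope_contrast: tuple  # paired t (current - previous slopes): (t, p)
    bin_width: int


def binned_dynamics_participant(pre: PreprocessedSeries, bin_width: int = 50,
                                phase: str = ACQUISITION) -> np.ndarray:
    """Per-bin OLS weights of Delta theta on coded previous-CS, current-CS
    and their product (CS+ = +1, CS- = -1).

    Rank-deficient bins yield NaN weights. Returns (n_bins, 3).
    """
    sl = pre.schedule.phase_slice(phase)
    n_phase = sl.stop - sl.start
    n_bins = n_phase // bin_width
    if n_bins < 2:
        raise ValueError("phase too short for >= 2 bins")
    labels = _participant_labels(pre)[sl]
    if "compound" in labels:
        raise ValueError("binned dynamics requires a differential phase")
    code = np.where(labels == "+", 1.0, -1.0)
    d = pre.delta[sl]
    v = pre.delta_valid[sl].copy()
    v[0] = False
    out = np.full((n_bins, 3), np.nan)
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        idx = np.arange(max(lo, 1), hi)
        idx = idx[v[idx]]
        if idx.size < 4:
            continue
        X = np.column_stack([
            np.ones(idx.size), code[idx - 1], code[idx],
            code[idx - 1] * code[idx],
        ])
        if np.linalg.matrix_rank(X) < 4:
            continue
        beta, *_ = np.linalg.lstsq(X, d[idx], rcond=None)
        out[b] = beta[1:]
    return out


def _ols_slope(y):
    x = np.arange(y.size, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    xc = x - x.mean()
    return float((xc @ y) / (xc @ xc))


def binned_dynamics(pres, bin_width: int = 50,
                    phase: str = ACQUISITION) -> DynamicsResult:
    """Cohort dynamics: per-participant bin weights, per-participant slopes
    of each weight series, and group tests on the slopes.

    Group inference uses per-participant OLS slopes: a one-sample t test per
    effect and a paired t between the Pavlovian and adaptation slopes (an
    intentionally simple stand-in for a mixed-model type x bin interaction).
    """
    weights = np.stack(
        [binned_dynamics_participant(p, bin_width, phase) for p in pres]
    )
    slopes = np.apply_along_axis(_ols_slope, 1, weights)
    tests = {}
    for k, name in enumerate(("previous", "current", "interaction")):
        t, p = stats.ttest_1samp(slopes[:, k], 0.0)
        tests[name] = (float(t), float(p))
    t, p = stats.ttest_rel(slopes[:, 1], slopes[:, 0])
    return DynamicsResult(weights=weights, slopes=slopes, slope_tests=tests,
                          slope_contrast=(float(t), float(p)),
                          bin_width=bin_width)


# ---------------------------------------------------------------------------
# compound conditioning (probe phase)


@dataclass
class CompoundProbeResult:
    medians: np.ndarray  # (n_subjects, 3): compound, tone, light
    chi2: float
    p: float
    kendall_w: float
    pairwise: dict  # pair -> Bonferroni-corrected Wilcoxon p


def _probe_cs_types(pre: PreprocessedSeries):
    types = []
    for t in pre.schedule.trials:
        if t.cs_set == {"tone", "light"}:
            types.append("compound")
        else:
            (cue,) = t.cs_set
            types.append(cue)
    return np.array(types)


def compound_probe_medians(pre: PreprocessedSeries,
                           statistic: str = "median") -> np.ndarray:
    """Per-participant (compound, tone, light) Delta statistic over probe
    trials, regardless of the previous trial's CS."""
    agg = {"mean": np.mean, "median": np.median}[statistic]
    sl = pre.schedule.phase_slice(PROBE)
    types = _probe_cs_types(pre)[sl]
    d = pre.delta[sl]
    v = pre.delta_valid[sl].copy()
    v[0] = False
    out = np.empty(3)
    for k, name in enumerate(("compound", "tone", "light")):
        sel = v & (types == name)
        if not sel.any():
            raise ValueError(f"no valid probe trials with CS type {name!r}")
        out[k] = agg(d[sel])
    return out


def compound_probe_analysis(pres, statistic: str = "median"):
    """Friedman test over the three probe CS conditions plus Kendall's W and
    Bonferroni-corrected pairwise Wilcoxon signed-rank tests."""
    med = np.stack([compound_probe_medians(p, statistic) for p in pres])
    n, k = med.shape
    if np.all(np.ptp(med, axis=1) == 0):  # fully tied: no rank information
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(med[:, 0], med[:, 1], med[:, 2])
    w = chi2 / (n * (k - 1))
    names = ("compound", "tone", "light")
    pairwise = {}
    for a, b in ((0, 1), (0, 2), (1, 2)):
        diff = med[:, a] - med[:, b]
        if np.all(diff == 0):  # fully tied pair carries no information
            pw = 1.0
        else:
            _, pw = stats.wilcoxon(med[:, a], med[:, b])
        pairwise[f"{names[a]} vs {names[b]}"] = min(1.0, 3.0 * float(pw))
    return CompoundProbeResult(medians=med, chi2=float(chi2), p=float(p),
                               kendall_w=float(w), pairwise=pairwise)


def elemental_probe_means(pre: PreprocessedSeries) -> tuple[float, float]:
    """(tone-alone, light-alone) mean Delta over valid probe trials."""
    sl = pre.schedule.phase_slice(PROBE)
    types = _probe_cs_types(pre)[sl]
    d = pre.delta[sl]
    v = pre.delta_valid[sl].copy()
    v[0] = False
    out = []
    for name in ("tone", "light"):
        sel = v & (types == name)
        if not sel.any():
            raise ValueError(f"no valid probe trials with CS type {name!r}")
        out.append(float(d[sel].mean()))
    return tuple(out)


def overshadow_correlation(tone_means, light_means) -> tuple[float, float]:
    """Pearson correlation (two-sided) between per-participant tone-alone and
    light-alone probe responses: the overshadowing trade-off."""
    x = np.asarray(tone_means, dtype=float)
    y = np.asarray(light_means, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 participants")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pooled_singleton_anova(pres, statistic: str = "mean") -> EffectsResult:
    """Compound-probe 2x2 ANOVA after pooling tone/light into 'singleton':
    (previous CS type) x (current CS type), levels (compound, singleton)."""
    tables = []
    for pre in pres:
        sl = pre.schedule.phase_slice(PROBE)
        labels = _participant_labels(pre, pooled=True)
        tables.append(
            _cells(pre.delta, pre.delta_valid, labels, sl, _POOLED_LEVELS,
                   statistic)
        )
    return rm_anova_2x2(np.stack(tables), levels=_POOLED_LEVELS)
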