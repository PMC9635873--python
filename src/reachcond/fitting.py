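"""Multi-start bounded least-squares fitting of the RW and SS models.

Each model is fit to a participant's oriented, baseline-subtracted heading
series by minimizing the sum of squared residuals (SSR) over valid
(unmasked) trials, while the model state propagates through every trial —
the participant experienced masked trials too. Probe trials enter as US = 0
extinction trials. To escape local minima the bounded local optimizer
(L-BFGS-B) is restarted from many random initial points (200 by default)
drawn uniformly within the bounds: all parameters in (0, 1) except lambda,
bounded at (-30, 60).

Models are compared per participant by SSR and by the residual-based
AIC = n*ln(SSR/n) + 2k, with k = 5 for RW (lambda, beta, alpha_plan,
alpha_tone, alpha_light) and k = 2 for SS (A, B). Only the products
alpha_i*beta are identifiable in the RW model; parameters are nevertheless
counted as written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats
from scipy.optimize import minimize

from . import models
from .schedule import CLAMP_ERROR, TrialSchedule

RW_PARAM_NAMES = ("lam", "beta", "alpha_plan", "alpha_tone", "alpha_light")
RW_BOUNDS = ((-30.0, 60.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0))
SS_PARAM_NAMES = ("A", "B")
SS_BOUNDS = ((0.0, 1.0), (0.0, 1.0))

_BIG = 1e8  # saturation value for diverged parameter combinations


@njit(cache=True)
def _rw_core(us, tone, light, lam, beta, a_plan, a_tone, a_light):  # pragma: no cover
    n = us.shape[0]
    out = np.empty(n)
    vp = 0.0
    vt = 0.0
    vl = 0.0
    for i in range(n):
        tot = vp
        if tone[i]:
            tot += vt
        if light[i]:
            tot += vl
        out[i] = tot
        err = lam * us[i] - tot
        if abs(err) > _BIG:
            for j in range(i, n):
                out[j] = _BIG
            break
        d = beta * err
        vp += a_plan * d
        if tone[i]:
            vt += a_tone * d
        if light[i]:
            vl += a_light * d
    return out


@njit(cache=True)
def _ss_core(e, A, B):  # pragma: no cover
    n = e.shape[0]
    out = np.empty(n)
    x = 0.0
    for i in range(n):
        out[i] = x
        x = A * x + B * e[i]
    return out


def schedule_arrays(schedule: TrialSchedule):
    """(us indicator, tone-present, light-present) arrays for the fast cores."""
    us = models.us_indicator(schedule)
    tone = np.array([1 if "tone" in t.cs_set else 0 for t in schedule.trials],
                    dtype=np.uint8)
    light = np.array([1 if "light" in t.cs_set else 0 for t in schedule.trials],
                     dtype=np.uint8)
    return us, tone, light


def predict_series(model: str, params, schedule: TrialSchedule) -> np.ndarray:
    """Predicted heading series; delegates to the simulators in ``models``."""
    if model == "rw":
        if not isinstance(params, models.RWParams):
            params = models.RWParams(**dict(params))
        return models.rw_simulate(schedule, params).heading
    if model == "ss":
        if not isinstance(params, models.SSParams):
            params = models.SSParams(**dict(params))
        return models.ss_simulate(schedule, params).heading
    raise ValueError(f"unknown model {model!r}")


@dataclass
class FitResult:
    model: str
    params: dict
    ssr: float  # deg^2 over valid trials
    aic: float | None  # None when SSR = 0 (degenerate; compare SSR only)
    n: int  # number of residual points
    k: int  # parameter count as written
    n_starts: int
    best_start: int
    converged: bool


def aic(ssr: float, n: int, k: int) -> float:
    """Residual-based Akaike information criterion: n*ln(ssr/n) + 2k."""
    if n <= 0:
        raise ValueError("n must be positive")
    if ssr <= 0:
        raise ValueError("ssr must be positive (degenerate fit: compare SSR)")
    return n * np.log(ssr / n) + 2 * k


def fit_model(series, valid, schedule: TrialSchedule, model: str,
              n_starts: int = 200, seed: int = 0) -> FitResult:
    """Best-of-``n_starts`` bounded least-squares fit of one model.

    ``series`` is the observed oriented heading (deg) aligned to the
    schedule; residuals are evaluated only where ``valid`` is True.
    """
    series = np.asarray(series, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if series.shape[0] != len(schedule) or valid.shape[0] != len(schedule):
        raise ValueError("series/valid not aligned to schedule")
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid observations")
    obs = series[valid]
    us, tone, light = schedule_arrays(schedule)
    e = CLAMP_ERROR * us

    if model == "rw":
        names, bounds = RW_PARAM_NAMES, RW_BOUNDS

        def predict(x):
            return _rw_core(us, tone, light, x[0], x[1], x[2], x[3], x[4])

    elif model == "ss":
        names, bounds = SS_PARAM_NAMES, SS_BOUNDS

        def predict(x):
            return _ss_core(e, x[0], x[1])

    else:
        raise ValueError(f"unknown model {model!r}")

    def objective(x):
        r = obs - predict(x)[valid]
        ssr = float(r @ r)
        return ssr if np.isfinite(ssr) else 1e300

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    best_start = -1
    any_converged = False
    for s in range(n_starts):
        x0 = rng.uniform(lo, hi)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options=dict(ftol=1e-12, gtol=1e-9, maxiter=500))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
            best_start = s
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {n_starts} starts failed for model {model!r} "
            f"(last status: {getattr(best, 'message', 'n/a')})"
        )
    ssr = float(best.fun)
    n = int(valid.sum())
    k = len(names)
    return FitResult(
        model=model, params=dict(zip(names, (float(v) for v in best.x))),
        ssr=ssr, aic=float(aic(ssr, n, k)) if ssr > 0 else None,
        n=n, k=k, n_starts=n_starts, best_start=best_start,
        converged=any_converged,
    )


@dataclass
class ModelComparison:
    delta_ssr: np.ndarray  # RW - SS per participant
    delta_aic: np.ndarray
    ssr_test: tuple  # (t, p, cohen_d) of the paired comparison
    aic_test: tuple


def _paired(d):
    d = np.asarray(d, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        # identical differences: no evidence against (or for) zero
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        return float(t), 1.0 if t == 0 else 0.0, np.nan
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p), float(d.mean() / sd)


def compare_models(fits_rw, fits_ss) -> ModelComparison:
    """Per-participant RW - SS differences in SSR and AIC plus the paired t
    tests across the cohort (negative differences favour RW)."""
    if len(fits_rw) != len(fits_ss):
        raise ValueError("cohorts differ in size")
    for fr, fs in zip(fits_rw, fits_ss):
        if fr.n != fs.n:
            raise ValueError(
                "fits compare different valid-trial sets "
                f"(n={fr.n} vs {fs.n})"
            )
    d_ssr = np.array([fr.ssr - fs.ssr for fr, fs in zip(fits_rw, fits_ss)])
    if any(fr.aic is None or fs.aic is None
           for fr, fs in zip(fits_rw, fits_ss)):
        raise ValueError("AIC undefined for a degenerate (SSR=0) fit")
    d_aic = np.array([fr.aic - fs.aic for fr, fs in zip(fits_rw, fits_ss)])
    return ModelComparison(delta_ssr=d_ssr, delta_aic=d_aic,
                           ssr_test=_paired(d_ssr), aic_test=_paired(d_aic))


def fit_cohort(pres, n_starts: int = 200, seed: int = 0,
               include_slow: bool = True, baselined: bool = False):
    """Fit both models to every preprocessed participant and compare.

    Residual trials are those passing outlier screening (slow trials are kept
    by default: they exclude Delta pairs, not time-course samples). Fits use
    the oriented series without the baseline shift unless ``baselined`` is
    set: both models pin the initial state at zero, and subtracting the
    (noisy) first-trial heading injects a constant offset outside either
    model class. Returns (rw fits, ss fits, ModelComparison).
    """
    rng = np.random.default_rng(seed)
    fits_rw, fits_ss = [], []
    for pre in pres:
        valid = ~pre.outlier_mask if include_slow else ~pre.mask
        series = pre.theta if baselined else pre.theta_unbaselined
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        fits_rw.append(fit_model(series, valid, pre.schedule, "rw",
                                 n_starts=n_starts, seed=int(s1)))
        fits_ss.append(fit_model(series, valid, pre.schedule, "ss",
                                 n_starts=n_starts, seed=int(s2)))
    return fits_rw, fits_ss, compare_models(fits_rw, fits_ss)
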