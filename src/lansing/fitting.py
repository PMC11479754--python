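"""Maximum-likelihood fitting of one mortality model to one group's lifespans.

Stage 1 of the two-stage survival analysis: each of the four model families
is fitted to a group's integer daily lifespans by maximizing either the
interval-censored log-likelihood (default; matches a daily census in which a
recorded lifespan L means death in [L, L+1)) or the continuous-density
log-likelihood, and the families are compared by AICc and Akaike weights.

Optimization is a derivative-free Nelder-Mead simplex run on log-scale
parameters (positivity enforced by construction), restarted from a log-spaced
grid plus warm starts taken from the fitted next-simpler nested family, so
the fitted log-likelihoods respect the nesting chain
exponential <= Gompertz <= logistic up to optimizer tolerance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    FAMILIES,
    MortalityParams,
    _N_PARAMS,
    _hazard_raw,
    _log_survival_raw,
    hazard,
    interval_death_probability,
    log_survival,
)

__all__ = [
    "FitResult",
    "negative_loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "selection_table",
]

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300  # clamp for underflowing interval probabilities
_LOG_OF_FLOOR = float(np.log(_LOG_FLOOR))

# multi-start grid bounds (log-spaced), per parameter
_GRID = {"a": (1e-4, 0.5), "b": (1e-3, 1.0), "c": (1e-2, 1e2)}


@dataclass(frozen=True)
class FitResult:
    """One maximum-likelihood fit: parameters, log-likelihood, and AICc."""

    params: MortalityParams
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_starts_tried: int
    mode: str = "interval"


def _check_lifespans(lifespans) -> np.ndarray:
    arr = np.asarray(lifespans)
    if arr.size == 0:
        raise ValueError("lifespan vector is empty")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("lifespans must be integer day counts")
    arr = arr.astype(np.int64)
    if np.any(arr < 1):
        raise ValueError("lifespans must be >= 1 day")
    return arr


def _nll_raw(family: str, a: float, b: float, c: float, days: np.ndarray,
             days1: np.ndarray, counts: np.ndarray, mode: str) -> float:
    """Unvalidated likelihood kernel on pre-tabulated (unique day, count) pairs.

    Underflowing or non-finite probabilities are silently clamped at 1e-300:
    optimizer hot loops hit bad parameter regions routinely and only need
    the objective to stay finite and terrible there.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ls0 = _log_survival_raw(family, a, b, c, days)
        if mode == "interval":
            ls1 = _log_survival_raw(family, a, b, c, days1)
            logp = ls0 + np.log(-np.expm1(ls1 - ls0))
        elif mode == "density":
            logp = np.log(_hazard_raw(family, a, b, c, days)) + ls0
        else:
            raise ValueError(f"unknown likelihood mode {mode!r}")
        bad = ~np.isfinite(logp)
        if bad.any():
            logp = np.where(bad, _LOG_OF_FLOOR, logp)
        return float(-(counts * logp).sum())


def negative_loglik(params: MortalityParams, lifespans, mode: str = "interval") -> float:
    """Negative log-likelihood of a lifespan sample under one model.

    interval mode: -sum log[l(L) - l(L+1)] (death during census day L).
    density mode:  -sum log[h(L) l(L)] (continuous density at the integer age).

    Probabilities that underflow to zero are clamped at 1e-300 with a warning
    so a bad parameter region stays finite (and terrible) for the optimizer.
    """
    arr = _check_lifespans(lifespans)
    days, counts = np.unique(arr, return_counts=True)
    if mode == "interval":
        p = interval_death_probability(params, days)
    elif mode == "density":
        p = hazard(params, days) * np.exp(log_survival(params, days))
    else:
        raise ValueError(f"unknown likelihood mode {mode!r}")
    bad = ~((p > 0) & np.isfinite(p))
    if bad.any():
        warnings.warn(
            f"clamping {int(bad.sum())} zero/non-finite likelihood terms for {params}",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(bad, _LOG_FLOOR, p)
    return float(-(counts * np.log(p)).sum())


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Relative likelihoods exp(-delta/2) normalized over the candidate set."""
    v = np.asarray(aicc_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty AICc list")
    if not np.all(np.isfinite(v)):
        raise ValueError("AICc values must be finite")
    rel = np.exp(-0.5 * (v - v.min()))
    return rel / rel.sum()


def _grid_starts(names: tuple[str, ...], n_per_axis: int) -> list[np.ndarray]:
    axes = [
        np.log(np.geomspace(_GRID[name][0], _GRID[name][1], n_per_axis)) for name in names
    ]
    return [np.array(combo) for combo in itertools.product(*axes)]


def _make_params(family: str, theta: np.ndarray) -> MortalityParams:
    vals = np.exp(theta)
    if family == "exponential":
        return MortalityParams(family, vals[0])
    if family in ("gompertz", "weibull"):
        return MortalityParams(family, vals[0], vals[1])
    return MortalityParams(family, vals[0], vals[1], vals[2])


def _closed_form_exponential_a(lifespans: np.ndarray, mode: str) -> float:
    # interval-censored exponential MLE: a_hat = ln((1 + Lbar)/Lbar)
    lbar = float(np.mean(lifespans))
    if mode == "interval":
        return float(np.log((1.0 + lbar) / lbar))
    return 1.0 / lbar


def minimize_family(family: str, lifespans, mode: str, starts: list[np.ndarray]):
    """Run Nelder-Mead from every start; return (best_theta, best_nll, any_converged)."""
    arr = _check_lifespans(lifespans)
    days, counts = np.unique(arr, return_counts=True)
    days = days.astype(float)
    days1 = days + 1.0

    def objective(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 50):  # guard against runaway simplex
            return 1e12
        vals = np.exp(theta)
        a = vals[0]
        b = vals[1] if vals.size > 1 else 0.0
        c = vals[2] if vals.size > 2 else 0.0
        return _nll_raw(family, a, b, c, days, days1, counts, mode)

    best: tuple[np.ndarray, float] | None = None
    any_ok = False
    for theta0 in starts:
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 4000, "maxfev": 6000},
        )
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or bool(res.success)
        if (
            best is None
            or res.fun < best[1] - 1e-10
            or (abs(res.fun - best[1]) <= 1e-10
                and np.linalg.norm(np.exp(res.x)) < np.linalg.norm(np.exp(best[0])))
        ):
            best = (res.x, float(res.fun))
    if best is None:
        raise RuntimeError(f"all {len(starts)} optimizer starts failed for {family}")
    return best[0], best[1], any_ok


def fit_model(
    family: str,
    lifespans,
    mode: str = "interval",
    n_grid_starts: int | None = None,
    extra_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Fit one model family to one group's lifespans by maximum likelihood.

    Multi-start Nelder-Mead on log parameters. Gompertz and Weibull fits are
    warm-started from the closed-form interval-censored exponential MLE, and
    the logistic fit additionally from the fitted Gompertz parameters with a
    vanishing heterogeneity c, which enforces the nesting inequalities
    loglik(logistic) >= loglik(gompertz) >= loglik(exponential).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    arr = _check_lifespans(lifespans)
    n = int(arr.size)
    k = _N_PARAMS[family]
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} lifespans to fit {family}, got {n}")

    names = ("a",) if family == "exponential" else (("a", "b") if family != "logistic" else ("a", "b", "c"))
    if n_grid_starts == 0:
        # light refit mode (e.g. bootstrap replicates near a known optimum):
        # run only from the caller-supplied starts
        if not extra_starts:
            raise ValueError("n_grid_starts=0 requires extra_starts")
        starts = []
    else:
        per_axis = n_grid_starts if n_grid_starts is not None else {1: 8, 2: 3, 3: 2}[len(names)]
        starts = _grid_starts(names, per_axis)
        a_exp = _closed_form_exponential_a(arr, mode)
        if family == "exponential":
            starts.append(np.array([np.log(a_exp)]))
        elif family in ("gompertz", "weibull"):
            starts.append(np.array([np.log(a_exp), np.log(1e-3)]))
            starts.append(np.array([np.log(a_exp), 0.0]))
        else:  # logistic: warm start from the nested Gompertz optimum
            gfit = fit_model("gompertz", arr, mode=mode)
            starts.append(np.array([np.log(gfit.params.a), np.log(gfit.params.b), np.log(1e-5)]))
            starts.append(np.array([np.log(gfit.params.a), np.log(gfit.params.b), 0.0]))
    if extra_starts:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    theta, nll, converged = minimize_family(family, arr, mode, starts)
    params = _make_params(family, theta)
    ll = -nll
    if not converged:
        logger.warning("no optimizer start reported convergence for %s fit (n=%d)", family, n)
    return FitResult(
        params=params,
        loglik=ll,
        k=params.k,
        n=n,
        aicc=aicc(ll, params.k, n),
        converged=converged,
        n_starts_tried=len(starts),
        mode=mode,
    )


def selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AICc model-selection table: delta-AICc and Akaike weights, best first.

    Columns: model, k, AICc, delta_AICc, weight, converged.
    """
    if not fits:
        raise ValueError("no fits to tabulate")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits compare different datasets (n values {sorted(ns)})")
    aiccs = np.array([f.aicc for f in fits])
    weights = akaike_weights(aiccs)
    table = pd.DataFrame(
        {
            "model": [f.params.family for f in fits],
            "k": [f.k for f in fits],
            "AICc": aiccs,
            "delta_AICc": aiccs - aiccs.min(),
            "weight": weights,
            "converged": [f.converged for f in fits],
        }
    )
    return table.sort_values("delta_AICc", kind="stable").reset_index(drop=True)
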