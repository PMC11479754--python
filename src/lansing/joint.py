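"""Joint two-group logistic survival models with common or distinct parameters.

Stage 2 of the analysis: having established that the logistic family fits
each group best on its own, the two groups (e.g. first- and fifth-born
offspring) are fitted *together* under a suite of candidate logistic models
in which each of (a, b, c) is independently either common to both groups or
distinct between them — 2^3 = 8 candidates. A capital letter in the model
name marks a distinct parameter: "Abc" has distinct initial mortality a but
common b and c; "abc" is fully pooled; "ABC" is equivalent to two separate
fits. Candidates are compared by AICc on the combined sample, which
localizes *where* on the mortality trajectory two groups differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fitting import (
    FitResult,
    _check_lifespans,
    _nll_raw,
    aicc,
    akaike_weights,
    fit_model,
)
from .models import MortalityParams

__all__ = [
    "JointModelSpec",
    "JointFitResult",
    "enumerate_candidates",
    "fit_joint",
    "joint_selection",
]

logger = logging.getLogger(__name__)

#: canonical candidate order: number of distinct parameters, then a-b-c priority
CANONICAL_NAMES = ("abc", "Abc", "aBc", "abC", "ABc", "AbC", "aBC", "ABC")


@dataclass(frozen=True)
class JointModelSpec:
    """Which of the logistic parameters differ between the two groups."""

    distinct_a: bool
    distinct_b: bool
    distinct_c: bool

    @property
    def name(self) -> str:
        return (
            ("A" if self.distinct_a else "a")
            + ("B" if self.distinct_b else "b")
            + ("C" if self.distinct_c else "c")
        )

    @property
    def k(self) -> int:
        """3 shared coordinates plus one extra per distinct parameter."""
        return 3 + self.distinct_a + self.distinct_b + self.distinct_c

    @classmethod
    def from_name(cls, name: str) -> "JointModelSpec":
        if len(name) != 3 or name.lower() != "abc":
            raise ValueError(f"joint model name must be a casing of 'abc', got {name!r}")
        return cls(name[0] == "A", name[1] == "B", name[2] == "C")


@dataclass(frozen=True)
class JointFitResult:
    """A fitted joint model: per-group parameters sharing the common values."""

    spec: JointModelSpec
    params_g1: MortalityParams
    params_g2: MortalityParams
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    mode: str = "interval"


def enumerate_candidates() -> list[JointModelSpec]:
    """All eight candidate common/distinct patterns, in canonical order."""
    return [JointModelSpec.from_name(name) for name in CANONICAL_NAMES]


def _theta_layout(spec: JointModelSpec) -> list[bool]:
    return [spec.distinct_a, spec.distinct_b, spec.distinct_c]


def _unpack(spec: JointModelSpec, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the reduced log-parameter vector into per-group (a, b, c) triples."""
    g1, g2, i = [], [], 0
    for distinct in _theta_layout(spec):
        g1.append(theta[i])
        g2.append(theta[i + 1] if distinct else theta[i])
        i += 2 if distinct else 1
    return np.array(g1), np.array(g2)


def _pack(spec: JointModelSpec, log_g1: np.ndarray, log_g2: np.ndarray) -> np.ndarray:
    out = []
    for j, distinct in enumerate(_theta_layout(spec)):
        if distinct:
            out.extend([log_g1[j], log_g2[j]])
        else:
            out.append(0.5 * (log_g1[j] + log_g2[j]))
    return np.array(out)


def fit_joint(
    spec: JointModelSpec,
    lifespans_g1,
    lifespans_g2,
    mode: str = "interval",
    warm_fits: tuple[FitResult, FitResult] | None = None,
    pooled_fit: FitResult | None = None,
    n_grid_starts: int = 2,
) -> JointFitResult:
    """Maximize the summed two-group logistic log-likelihood in reduced space.

    Common parameters are single optimizer coordinates shared by both groups,
    so the fitted common values are bit-identical across groups by
    construction. Starts combine (i) a warm start built from the two separate
    single-group logistic fits (log-mean for common coordinates), (ii) the
    pooled single-group fit, and (iii) a small log-spaced grid.
    """
    arr1 = _check_lifespans(lifespans_g1)
    arr2 = _check_lifespans(lifespans_g2)
    n = int(arr1.size + arr2.size)
    if n <= spec.k + 1:
        raise ValueError(f"need n > k + 1 = {spec.k + 1} individuals, got {n}")
    ud1, uc1 = np.unique(arr1, return_counts=True)
    ud2, uc2 = np.unique(arr2, return_counts=True)
    ud1 = ud1.astype(float)
    ud2 = ud2.astype(float)
    ud1p, ud2p = ud1 + 1.0, ud2 + 1.0

    def objective(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 50):
            return 1e12
        t1, t2 = _unpack(spec, theta)
        v1, v2 = np.exp(t1), np.exp(t2)
        return (_nll_raw("logistic", v1[0], v1[1], v1[2], ud1, ud1p, uc1, mode)
                + _nll_raw("logistic", v2[0], v2[1], v2[2], ud2, ud2p, uc2, mode))

    if warm_fits is None:
        warm_fits = (
            fit_model("logistic", arr1, mode=mode),
            fit_model("logistic", arr2, mode=mode),
        )
    f1, f2 = warm_fits
    log1 = np.log(f1.params.as_array())
    log2 = np.log(f2.params.as_array())
    starts = [_pack(spec, log1, log2)]

    if pooled_fit is None:
        pooled_fit = fit_model("logistic", np.concatenate([arr1, arr2]), mode=mode)
    logp = np.log(pooled_fit.params.as_array())
    starts.append(_pack(spec, logp, logp))

    # small grid in the reduced space, log-spaced around plausible scales
    grid_axes = {"a": (-6.0, -2.0), "b": (-3.0, -0.5), "c": (-1.0, 1.0)}
    base = [grid_axes[p] for p in "abc"]
    for hi_lo in range(n_grid_starts):
        frac = hi_lo / max(n_grid_starts - 1, 1)
        triple = np.array([lo + frac * (hi - lo) for lo, hi in base])
        starts.append(_pack(spec, triple, triple))

    best = None
    converged = False
    for theta0 in starts:
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 6000, "maxfev": 9000},
        )
        if not np.isfinite(res.fun):
            continue
        converged = converged or bool(res.success)
        if best is None or res.fun < best[1] - 1e-10:
            best = (res.x, float(res.fun))
    if best is None:
        raise RuntimeError(f"all starts failed for joint model {spec.name}")

    t1, t2 = _unpack(spec, best[0])
    v1, v2 = np.exp(t1), np.exp(t2)
    # force exact bit-identity of common coordinates (unpack shares them already)
    params_g1 = MortalityParams("logistic", *v1)
    params_g2 = MortalityParams("logistic", *v2)
    ll = -best[1]
    if not converged:
        logger.warning("joint model %s: no start reported convergence", spec.name)
    return JointFitResult(
        spec=spec,
        params_g1=params_g1,
        params_g2=params_g2,
        loglik=ll,
        k=spec.k,
        n=n,
        aicc=aicc(ll, spec.k, n),
        converged=converged,
        mode=mode,
    )


def joint_selection(
    lifespans_g1,
    lifespans_g2,
    mode: str = "interval",
) -> tuple[pd.DataFrame, dict[str, JointFitResult]]:
    """Fit all eight candidates and rank them by AICc on the combined sample.

    Returns the selection table (columns model, a_status, b_status, c_status,
    k, AICc, delta_AICc, weight, converged; best model first) and the fitted
    models keyed by name.
    """
    arr1 = _check_lifespans(lifespans_g1)
    arr2 = _check_lifespans(lifespans_g2)
    warm = (fit_model("logistic", arr1, mode=mode), fit_model("logistic", arr2, mode=mode))
    pooled = fit_model("logistic", np.concatenate([arr1, arr2]), mode=mode)
    fits = {
        spec.name: fit_joint(spec, arr1, arr2, mode=mode, warm_fits=warm, pooled_fit=pooled)
        for spec in enumerate_candidates()
    }
    names = list(fits)
    aiccs = np.array([fits[m].aicc for m in names])
    weights = akaike_weights(aiccs)
    status = lambda distinct: "distinct" if distinct else "common"  # noqa: E731
    table = pd.DataFrame(
        {
            "model": names,
            "a_status": [status(fits[m].spec.distinct_a) for m in names],
            "b_status": [status(fits[m].spec.distinct_b) for m in names],
            "c_status": [status(fits[m].spec.distinct_c) for m in names],
            "k": [fits[m].k for m in names],
            "AICc": aiccs,
            "delta_AICc": aiccs - aiccs.min(),
            "weight": weights,
            "converged": [fits[m].converged for m in names],
        }
    )
    table = table.sort_values("delta_AICc", kind="stable").reset_index(drop=True)
    return table, fits
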