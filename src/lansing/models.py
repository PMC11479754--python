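"""Parametric mortality models: hazard, survival, and daily death probabilities.

Four classical families are supported, all parameterized per day:

========== =========================================== ==========
family     survival l(t)                               parameters
========== =========================================== ==========
exponential exp(-a t)                                  a
gompertz    exp(-(a/b) (e^{bt} - 1))                   a, b
weibull     exp(-(a t)^b)                              a, b
logistic    (1 + (a c / b)(e^{bt} - 1))^{-1/c}         a, b, c
========== =========================================== ==========

``a`` is the initial-mortality (level) parameter: for the exponential,
Gompertz, and logistic families the hazard at age zero equals ``a`` exactly.
``b`` is the mortality-rate parameter governing how fast hazard changes with
age, and ``c`` is the logistic family's heterogeneity (deceleration)
parameter: unobserved frailty variation flattens the population hazard at
late ages, and c -> 0 recovers the Gompertz model.

The Weibull family here uses the scale-inside convention
``l(t) = exp(-(a t)^b)`` so that ``a`` remains the level-like parameter and
``b`` the shape; this is a documented convention of this package, chosen for
consistency with the other families' a-level / b-shape roles.

Lifespans observed by daily census are interval censored: an individual
recorded with lifespan ``L`` died somewhere in ``[L, L+1)`` days, so its
contribution to a discrete likelihood is ``l(L) - l(L+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILIES",
    "MortalityParams",
    "survival",
    "log_survival",
    "hazard",
    "interval_death_probability",
]

FAMILIES = ("exponential", "gompertz", "weibull", "logistic")

_N_PARAMS = {"exponential": 1, "gompertz": 2, "weibull": 2, "logistic": 3}

# Below this, (1 + c*u)^(-1/c) is evaluated through its Gompertz series limit
# to avoid any cancellation in the exponent.
_SMALL_C = 1e-6


@dataclass(frozen=True)
class MortalityParams:
    """A model family tag plus its (a, b, c) parameter values.

    Parameters not used by the family must be left as ``None``; all present
    parameters must be strictly positive.
    """

    family: str
    a: float
    b: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        k = _N_PARAMS[self.family]
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"initial mortality a must be positive and finite, got {self.a}")
        if k >= 2:
            if self.b is None or not (np.isfinite(self.b) and self.b > 0):
                raise ValueError(f"{self.family} requires b > 0, got {self.b}")
        elif self.b is not None:
            raise ValueError(f"{self.family} takes no b parameter")
        if k == 3:
            if self.c is None or not (np.isfinite(self.c) and self.c > 0):
                raise ValueError(f"{self.family} requires c > 0, got {self.c}")
        elif self.c is not None:
            raise ValueError(f"{self.family} takes no c parameter")

    @property
    def k(self) -> int:
        """Number of free parameters (1, 2, or 3)."""
        return _N_PARAMS[self.family]

    def as_array(self) -> np.ndarray:
        """The free parameters as a length-k array in (a, b, c) order."""
        return np.array([v for v in (self.a, self.b, self.c) if v is not None])


def _log_survival_raw(family: str, a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    """Unvalidated log-survival kernel for optimizer hot loops.

    Caller is responsible for parameter positivity and errstate handling.
    """
    if family == "exponential":
        return -a * t
    if family == "gompertz":
        return -(a / b) * np.expm1(b * t)
    if family == "weibull":
        return -((a * t) ** b)
    u = (a / b) * np.expm1(b * t)
    if c < _SMALL_C:
        return -u * (1.0 - 0.5 * c * u)
    return -np.log1p(c * u) / c


def _hazard_raw(family: str, a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    """Unvalidated hazard kernel; see :func:`_log_survival_raw`."""
    if family == "exponential":
        return np.broadcast_to(np.asarray(a, dtype=float), np.shape(t))
    if family == "gompertz":
        return a * np.exp(b * t)
    if family == "weibull":
        return a * b * (a * t) ** (b - 1.0)
    out = a * np.exp(b * t) / (1.0 + (a * c / b) * np.expm1(b * t))
    return np.where(np.isfinite(out), out, b / c)


def _check_age(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    return t


def log_survival(params: MortalityParams, t) -> np.ndarray:
    """Natural log of the survivorship function, vectorized over ``t``.

    Working in log space keeps deep-tail interval probabilities accurate and
    lets l(t) underflow gracefully to 0 at extreme ages.
    """
    t = _check_age(t)
    with np.errstate(over="ignore"):
        # for c below _SMALL_C the logistic branch switches to its Gompertz
        # series limit, avoiding cancellation in the (1 + c u)^(-1/c) exponent
        return _log_survival_raw(params.family, params.a, params.b, params.c, t)


def survival(params: MortalityParams, t) -> np.ndarray:
    """Survivorship l(t): the probability of being alive at age t days.

    Satisfies l(0) = 1 for every family and is non-increasing in t.
    """
    return np.exp(log_survival(params, t))


def hazard(params: MortalityParams, t) -> np.ndarray:
    """Instantaneous mortality rate h(t) = -d ln l(t) / dt, per day."""
    t = _check_age(t)
    with np.errstate(over="ignore", invalid="ignore"):
        # weibull h(0) is 0 for b > 1 and diverges for b < 1; the logistic
        # hazard plateaus at b/c as t -> inf (substituted where exp overflows)
        return _hazard_raw(params.family, params.a, params.b, params.c, t).copy()


def interval_death_probability(params: MortalityParams, day) -> np.ndarray:
    """Probability of death in the daily census interval [day, day+1).

    ``day`` is the recorded integer lifespan (>= 1). Computed as
    ``l(day) * (1 - l(day+1)/l(day))`` in log space, which stays accurate far
    into the survival tail where the naive difference would cancel.
    """
    day = np.asarray(day)
    if np.any(day < 1):
        raise ValueError("recorded lifespans start at day 1")
    ls0 = log_survival(params, day)
    ls1 = log_survival(params, day + 1)
    with np.errstate(invalid="ignore"):
        p = np.exp(ls0) * -np.expm1(ls1 - ls0)
    # survival already underflowed to 0 at this age: no probability mass left
    return np.where(np.isneginf(ls0), 0.0, p)
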