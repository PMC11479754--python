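"""Randomization tests, bootstrap confidence intervals, and survival bands.

Life-history traits from daily cohort censuses (lifespan, age at first
reproduction, total offspring, intrinsic rate of increase) are typically
skewed, so group comparisons use distribution-free resampling:

* a two-sided permutation test on the absolute difference in group means,
  with the add-one correction so a reported p can never be exactly zero;
* stratified (within-group) nonparametric bootstrap percentile intervals for
  mean differences and for fitted mortality-model parameters;
* pointwise percentile confidence bands for fitted survival curves, obtained
  by evaluating l(t) under each bootstrap parameter draw.

Every routine is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .fitting import FitResult, fit_model
from .joint import JointFitResult, JointModelSpec, fit_joint
from .models import MortalityParams, survival

__all__ = [
    "PermutationResult",
    "BootstrapCI",
    "BootstrapParams",
    "permutation_test",
    "bootstrap_mean_diff",
    "bootstrap_model_params",
    "survival_band",
]

logger = logging.getLogger(__name__)

_EXHAUSTIVE_LIMIT = 200_000  # enumerate all label assignments below this count


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float  # group1 mean - group2 mean
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    level: float
    n_reps: int
    seed: int | None


@dataclass
class BootstrapParams:
    """Bootstrap draws of fitted model parameters, one row per replicate."""

    draws: dict[str, np.ndarray]  # group label -> (n_reps, 3) array of (a, b, c)
    ci: dict[str, dict[str, BootstrapCI]]  # group -> parameter -> CI
    n_reps: int
    n_failed: int
    seed: int
    level: float = 0.95
    meta: dict = field(default_factory=dict)


def permutation_test(
    values_g1,
    values_g2,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> PermutationResult:
    """Two-sided randomization test for a difference in group means.

    Pools the two samples, repeatedly reassigns group labels preserving the
    group sizes, and compares |mean difference| of each relabelling to the
    observed one. Sampled mode reports the add-one corrected
    p = (count + 1)/(n_permutations + 1); when the number of distinct label
    assignments is small (or ``exhaustive=True``), all assignments are
    enumerated and p is the exact tail fraction.
    """
    x1 = np.asarray(values_g1, dtype=float)
    x2 = np.asarray(values_g2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 values")
    observed = float(x1.mean() - x2.mean())
    pooled = np.concatenate([x1, x2])
    n1, n = x1.size, pooled.size

    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; permutation p-value is 1", RuntimeWarning)
        return PermutationResult(observed, 1.0, 0, seed, exhaustive=True)

    total = comb(n, n1)
    do_exhaustive = exhaustive is True or (exhaustive == "auto" and total <= _EXHAUSTIVE_LIMIT)
    tol = 1e-12 * max(1.0, abs(observed))
    if do_exhaustive:
        pooled_sum = pooled.sum()
        count = 0
        for idx in combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            diff = s1 / n1 - (pooled_sum - s1) / (n - n1)
            if abs(diff) >= abs(observed) - tol:
                count += 1
        return PermutationResult(observed, count / total, total, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in blocks: argsort of uniform keys gives random label splits
    block = max(1, min(n_permutations, 200_000 // max(n, 1)))
    done = 0
    while done < n_permutations:
        m = min(block, n_permutations - done)
        keys = rng.random((m, n))
        order = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        s1 = pooled[order].sum(axis=1)
        diffs = s1 / n1 - (pooled.sum() - s1) / (n - n1)
        count += int(np.sum(np.abs(diffs) >= abs(observed) - tol))
        done += m
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, seed, exhaustive=False)


def bootstrap_mean_diff(
    values_g1,
    values_g2,
    n_reps: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for the difference in group means (g1 - g2).

    Each group is resampled with replacement independently (stratified
    bootstrap), preserving the two sample sizes.
    """
    x1 = np.asarray(values_g1, dtype=float)
    x2 = np.asarray(values_g2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("groups must be non-empty")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} gives unstable percentile endpoints", RuntimeWarning)
    rng = np.random.default_rng(seed)
    m1 = x1[rng.integers(0, x1.size, size=(n_reps, x1.size))].mean(axis=1)
    m2 = x2[rng.integers(0, x2.size, size=(n_reps, x2.size))].mean(axis=1)
    diffs = m1 - m2
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return BootstrapCI(float(x1.mean() - x2.mean()), float(lo), float(hi), level, n_reps, seed)


def _param_cis(draws: np.ndarray, points: np.ndarray, level: float, n_reps: int, seed: int):
    alpha = (1.0 - level) / 2.0
    out = {}
    for j, name in enumerate(("a", "b", "c")):
        lo, hi = np.quantile(draws[:, j], [alpha, 1.0 - alpha])
        out[name] = BootstrapCI(float(points[j]), float(lo), float(hi), level, n_reps, seed)
    return out


def bootstrap_model_params(
    family_or_spec,
    lifespans_g1,
    lifespans_g2=None,
    n_reps: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    mode: str = "interval",
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> BootstrapParams:
    """Bootstrap CIs for fitted mortality-model parameters.

    Resamples lifespans with replacement within each group, refits the model
    to every replicate (warm-started from the original fit for speed and
    stability), and returns percentile CIs plus the raw parameter draws,
    which downstream code turns into survival confidence bands.

    ``family_or_spec`` is either a single-family name (one group, or two
    groups fitted independently is not supported — pass one group) or a
    :class:`JointModelSpec` with both groups supplied.
    """
    rng = np.random.default_rng(seed)
    joint = isinstance(family_or_spec, JointModelSpec)
    if joint and lifespans_g2 is None:
        raise ValueError("joint bootstrap needs both groups")

    arr1 = np.asarray(lifespans_g1, dtype=np.int64)
    arr2 = np.asarray(lifespans_g2, dtype=np.int64) if lifespans_g2 is not None else None

    if joint:
        pooled = fit_model("logistic", np.concatenate([arr1, arr2]), mode=mode)
        base = fit_joint(family_or_spec, arr1, arr2, mode=mode, pooled_fit=pooled)
        base_params = {group_labels[0]: base.params_g1, group_labels[1]: base.params_g2}
        warm1 = _as_fitresult(base.params_g1, base, arr1.size)
        warm2 = _as_fitresult(base.params_g2, base, arr2.size)
    else:
        base_single = fit_model(family_or_spec, arr1, mode=mode)
        if not base_single.converged:
            logger.warning("base %s fit did not converge before bootstrap", family_or_spec)
        base_params = {group_labels[0]: base_single.params}

    draws = {g: [] for g in base_params}
    n_failed = 0
    for _ in range(n_reps):
        b1 = arr1[rng.integers(0, arr1.size, arr1.size)]
        try:
            if joint:
                b2 = arr2[rng.integers(0, arr2.size, arr2.size)]
                fit = fit_joint(
                    family_or_spec, b1, b2, mode=mode, warm_fits=(warm1, warm2),
                    pooled_fit=pooled, n_grid_starts=0,
                )
                if not fit.converged:
                    n_failed += 1
                draws[group_labels[0]].append(_triple(fit.params_g1))
                draws[group_labels[1]].append(_triple(fit.params_g2))
            else:
                start = np.log(base_single.params.as_array())
                fit = fit_model(family_or_spec, b1, mode=mode, n_grid_starts=0,
                                extra_starts=[start])
                if not fit.converged:
                    n_failed += 1
                draws[group_labels[0]].append(_triple(fit.params))
        except (RuntimeError, ValueError):
            n_failed += 1

    if n_failed > 0.1 * n_reps:
        warnings.warn(
            f"{n_failed}/{n_reps} bootstrap replicates failed to converge; "
            "CIs may be unreliable",
            RuntimeWarning,
        )
    draw_arrays = {g: np.array(v, dtype=float) for g, v in draws.items()}
    cis = {
        g: _param_cis(draw_arrays[g], _triple(base_params[g]), level, n_reps, seed)
        for g in draw_arrays
        if draw_arrays[g].size
    }
    return BootstrapParams(
        draws=draw_arrays,
        ci=cis,
        n_reps=n_reps,
        n_failed=n_failed,
        seed=seed,
        level=level,
        meta={"mode": mode, "model": getattr(family_or_spec, "name", family_or_spec),
              "band_type": "pointwise percentile"},
    )


def _triple(params: MortalityParams) -> np.ndarray:
    return np.array([params.a, params.b if params.b is not None else np.nan,
                     params.c if params.c is not None else np.nan])


def _as_fitresult(params: MortalityParams, base: JointFitResult, n: int) -> FitResult:
    # shim so fit_joint warm starts accept the per-group params of a prior joint fit
    return FitResult(params=params, loglik=base.loglik, k=params.k, n=n,
                     aicc=base.aicc, converged=base.converged, n_starts_tried=0)


def survival_band(
    param_draws,
    ages,
    level: float = 0.95,
    family: str = "logistic",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile confidence band for a fitted survival curve.

    ``param_draws`` is either a sequence of :class:`MortalityParams` or an
    (n_draws, n_params) array of parameter values for ``family``. Each draw's
    l(t) is evaluated on the age grid and the band is the per-age percentile
    envelope. Pointwise, not simultaneous.
    """
    ages = np.asarray(ages, dtype=float)
    if hasattr(param_draws, "ndim"):
        arr = np.asarray(param_draws, dtype=float)
        plist = [MortalityParams(family, *row[~np.isnan(row)]) for row in arr]
    else:
        plist = list(param_draws)
    if len(plist) < 100:
        raise ValueError("need at least 100 parameter draws for a stable band")
    curves = np.stack([survival(p, ages) for p in plist])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    return lower, upper
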