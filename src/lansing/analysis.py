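"""End-to-end two-stage analysis of a two-group cohort of schedules.

Glue between the stages: per-group model selection across the four mortality
families, joint 8-candidate logistic selection, trait comparisons via
randomization tests and stratified bootstrap CIs, and bootstrap survival
bands for the best joint model. Works on any validated list of
:class:`~lansing.demography.ReproductionSchedule`, whether generated
synthetically or read from a cohort file.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .demography import TRAITS, cohort_summaries, compare_groups, trait_vectors
from .fitting import fit_model, selection_table
from .joint import JointModelSpec, joint_selection
from .models import FAMILIES, survival
from .resampling import bootstrap_mean_diff, bootstrap_model_params, permutation_test, survival_band

logger = logging.getLogger(__name__)

__all__ = ["analyze_cohort"]


def analyze_cohort(
    schedules,
    group_names: tuple[str, str],
    n_permutations: int = 10_000,
    n_boot_mean: int = 10_000,
    n_boot_model: int = 200,
    level: float = 0.95,
    mode: str = "interval",
    age_grid=None,
    seed: int = 0,
    cohort=None,
):
    """Run stage-1 and stage-2 model selection, trait tests, and bands.

    Returns a :class:`~lansing.simulate.PipelineResult`. Sub-seeds for the
    stochastic stages are derived deterministically from ``seed``.
    """
    from .simulate import PipelineResult

    g1, g2 = group_names
    summaries = cohort_summaries(schedules)
    lifespans = {
        g: np.array([s.lifespan for s in schedules if s.group == g]) for g in (g1, g2)
    }
    for g in (g1, g2):
        if lifespans[g].size == 0:
            raise ValueError(f"no individuals in group {g!r}")

    # stage 1: four families per group, ranked by AICc
    logger.info("stage 1: fitting %s to each group", ", ".join(FAMILIES))
    stage1_fits = {
        g: {fam: fit_model(fam, lifespans[g], mode=mode) for fam in FAMILIES}
        for g in (g1, g2)
    }
    stage1_tables = {g: selection_table(list(stage1_fits[g].values())) for g in (g1, g2)}

    # stage 2: eight joint logistic candidates
    logger.info("stage 2: joint logistic candidate suite")
    stage2_table, stage2_fits = joint_selection(lifespans[g1], lifespans[g2], mode=mode)
    best_name = stage2_table.iloc[0]["model"]

    # traits: randomization test + stratified bootstrap CI per trait
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(len(TRAITS) * 2 + 1)
    traits = compare_groups(summaries, g1, g2)
    pvals, lowers, uppers = [], [], []
    for i, trait in enumerate(TRAITS):
        v1 = trait_vectors(summaries, g1, trait)
        v2 = trait_vectors(summaries, g2, trait)
        perm = permutation_test(
            v1, v2, n_permutations=n_permutations,
            seed=int(sub[2 * i].generate_state(1)[0] % 2**31), exhaustive=False,
        )
        ci = bootstrap_mean_diff(
            v1, v2, n_reps=n_boot_mean, level=level,
            seed=int(sub[2 * i + 1].generate_state(1)[0] % 2**31),
        )
        pvals.append(perm.p_value)
        lowers.append(ci.lower)
        uppers.append(ci.upper)
    traits["p_value"] = pvals
    traits["ci_lower"] = lowers
    traits["ci_upper"] = uppers

    # survival bands for the best joint model
    logger.info("bootstrap survival bands for best joint model %s", best_name)
    boot_seed = int(sub[-1].generate_state(1)[0] % 2**31)
    boot = bootstrap_model_params(
        JointModelSpec.from_name(best_name),
        lifespans[g1], lifespans[g2],
        n_reps=n_boot_model, level=level, seed=boot_seed, mode=mode,
        group_labels=(g1, g2),
    )
    if age_grid is None:
        age_grid = np.arange(0, int(max(ls.max() for ls in lifespans.values())) + 6)
    best = stage2_fits[best_name]
    rows = []
    for g, params in ((g1, best.params_g1), (g2, best.params_g2)):
        lower, upper = survival_band(boot.draws[g], age_grid, level=level)
        point = survival(params, age_grid)
        rows.append(pd.DataFrame({
            "group": g, "age": age_grid, "survival": point,
            "lower": lower, "upper": upper,
        }))
    bands = pd.concat(rows, ignore_index=True)

    return PipelineResult(
        cohort=cohort,
        stage1_tables=stage1_tables,
        stage1_fits=stage1_fits,
        stage2_table=stage2_table,
        stage2_fits=stage2_fits,
        traits=traits,
        summaries=summaries,
        bands=bands,
        seed=seed,
    )
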