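"""Benchmark scenarios used to validate the pipeline on known ground truth.

These are the package's standard parameter-recovery settings: cohorts where
exactly one variable carries a real association and the rest are correlated
noise, so the stability-selection machinery can be scored against truth.
"""

from __future__ import annotations

import numpy as np

from .preprocess import (
    DesignMatrix,
    apply_llod_policy,
    build_design,
    complete_cases,
    subset_variables,
)
from .simulate import SimConfig, generate_cohort

#: name of the single truly associated analyte in the recovery scenario
RECOVERY_TRUE = "CYT01"


def recovery_config(seed: int) -> SimConfig:
    """One cytokine with standardized log-scale effect 1.25 against 15
    correlated nulls (shared-factor loading 0.55), ~150 pups split evenly."""
    return SimConfig(
        n_dams_exposed=24,
        n_dams_control=24,
        pups_per_litter_mean=(3.125, 3.125),
        cytokine_log_effects={RECOVERY_TRUE: 1.25},
        cytokine_correlation=0.55,
        n_cytokines=16,
        missing_rate=0.0,
        seed=seed,
    )


def recovery_design(seed: int) -> DesignMatrix:
    """Cytokines-only standardized design for the recovery scenario."""
    table, _ = generate_cohort(recovery_config(seed))
    table, _ = apply_llod_policy(table)
    table = complete_cases(table)
    table = subset_variables(table, table.cytokines)
    return build_design(table)


def permute_outcome(design: DesignMatrix, seed: int) -> DesignMatrix:
    """Copy of a design with outcome labels globally permuted (null cohort)."""
    rng = np.random.default_rng(seed)
    return DesignMatrix(
        X=design.X.copy(),
        y=rng.permutation(design.y),
        column_names=list(design.column_names),
        scaling=dict(design.scaling),
        binary_columns=list(design.binary_columns),
        outcome_name=design.outcome_name,
        outcome_coding=dict(design.outcome_coding),
    )
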