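"""Budget-impact projection over a short fixed horizon.

An eligibility funnel (national caseload x access x HER2-positive share x
residual-disease share) sizes the treatable population; a yearly growth
rate projects it forward; year-specific uptake shares split it between the
new drug and the comparator.  Budget impact is the per-patient annual cost
difference times the number switched, undiscounted by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import BiaInputs, ModelConfig, ValidationError
from .synthetic import LifeTable


def eligible_population(
    total: int, access: float, her2: float, residual: float
) -> int:
    """Funnel head count: round(total x access x her2 x residual)."""
    for name, share in (("access", access), ("her2", her2), ("residual", residual)):
        if not 0.0 <= share <= 1.0:
            raise ValidationError(f"{name} share {share!r} outside [0, 1]")
    return int(round(total * access * her2 * residual))


def project_population(base: int, growth: float, year: int) -> int:
    """Population in a given model year (year 1 = base)."""
    if year < 1:
        raise ValidationError(f"year index {year!r} must be >= 1")
    return int(round(base * (1.0 + growth) ** (year - 1)))


@dataclass(frozen=True)
class BiaResult:
    table: pd.DataFrame
    per_patient_delta: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "per_patient_annual_delta_usd": self.per_patient_delta,
            "years": self.table.to_dict(orient="records"),
        }


def first_year_cost(
    strategy: str, config: ModelConfig, life_table: Optional[LifeTable] = None
) -> float:
    """Undiscounted first-year per-patient cost of one arm.

    Runs the cohort engine with discounting switched off and truncates the
    accumulation to the cycles inside the first model year (the budget
    convention: costs in the year they occur, no discounting).
    """
    from . import engine
    from .costing import build_strategy_costing
    from .synthetic import life_table_from_config

    undiscounted = config.model_copy(
        update={
            "settings": config.settings.model_copy(
                update={"discount_cost": 0.0, "discount_utility": 0.0}
            )
        }
    )
    if life_table is None:
        life_table = life_table_from_config(undiscounted)
    seq = engine.build_transition_sequence(strategy, undiscounted, life_table)
    n_year = int(np.ceil(365.25 / undiscounted.settings.cycle_days))
    trace = engine.run_cohort(seq, n_cycles=n_year)
    costing = build_strategy_costing(strategy, undiscounted)
    u, c = engine._state_vectors(strategy, costing, undiscounted, trace.n_cycles)
    cost, _qaly, _ = engine.accumulate_outcomes(
        trace, seq, u, c, costing.packages, undiscounted
    )
    return cost


def budget_impact(
    inputs: BiaInputs,
    per_patient_delta: float,
    horizon_years: int = 3,
) -> BiaResult:
    """Year-by-year and cumulative budget impact.

    Each year's incident eligible population is split by uptake; only the
    switched patients generate the incremental cost (non-switched patients
    stay on the comparator, whose cost cancels in the difference).
    """
    if horizon_years > len(inputs.uptake_by_year):
        raise ValidationError(
            f"horizon {horizon_years} years exceeds the {len(inputs.uptake_by_year)} "
            "configured uptake years"
        )
    base = eligible_population(
        inputs.total_patients,
        inputs.access_share,
        inputs.her2_share,
        inputs.residual_share,
    )
    rows = []
    cumulative = 0.0
    for year in range(1, horizon_years + 1):
        n_eligible = project_population(base, inputs.annual_growth, year)
        uptake = inputs.uptake_by_year[year - 1]
        n_treated = int(round(n_eligible * uptake))
        incremental = n_eligible * uptake * per_patient_delta
        cumulative += incremental
        rows.append(
            {
                "year": year,
                "eligible": n_eligible,
                "uptake": uptake,
                "tdm1_treated": n_treated,
                "incremental_impact_usd": incremental,
                "cumulative_impact_usd": cumulative,
            }
        )
    return BiaResult(table=pd.DataFrame(rows), per_patient_delta=per_patient_delta)


def run_bia(
    config: ModelConfig,
    life_table: Optional[LifeTable] = None,
    horizon_years: int = 3,
) -> BiaResult:
    """Budget impact using the engine's first-year cost difference."""
    delta = first_year_cost("tdm1", config, life_table) - first_year_cost(
        "trastuzumab", config, life_table
    )
    return budget_impact(config.bia, delta, horizon_years)
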