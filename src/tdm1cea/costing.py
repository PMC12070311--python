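"""Per-cycle and transition-triggered costs.

Pricing follows the payer-perspective rules of the analysis: vial-level drug
costs with full-vial wastage (an exact small-menu optimizer picks the
cheapest vial combination covering the dose), generic/brand market-share
blending, an 80/20 government/private tariff blend on service fees, a
metastatic-state cost scaled from a configured reference, and an end-of-life
escalation charged to the MP->Death flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .parameters import (
    CostInputs,
    ModelConfig,
    ModelSettings,
    ValidationError,
    VialOption,
)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


def blended_price(generic: float, brand: float, generic_share: float) -> float:
    """Market-share-weighted price: share*generic + (1-share)*brand."""
    if generic < 0 or brand < 0:
        raise ValidationError("prices must be non-negative")
    if not 0.0 <= generic_share <= 1.0:
        raise ValidationError(f"generic_share={generic_share!r} outside [0, 1]")
    return generic_share * generic + (1.0 - generic_share) * brand


def tariff_blend(gov: float, priv: float, gov_weight: float = 0.8) -> float:
    """Government/private tariff blend for service fees (default 80/20)."""
    if gov < 0 or priv < 0:
        raise ValidationError("tariffs must be non-negative")
    if not 0.0 <= gov_weight <= 1.0:
        raise ValidationError(f"gov_weight={gov_weight!r} outside [0, 1]")
    return gov_weight * gov + (1.0 - gov_weight) * priv


def optimal_vial_combination(
    dose_mg: float, menu: Sequence[VialOption], allow_sharing: bool = False
) -> tuple[dict[float, int], float]:
    """Cheapest integer vial combination covering ``dose_mg``.

    Full-vial wastage: total vial content must reach the dose, no sharing
    between patients.  Exhaustive over count vectors (menus are small), so
    the result is exact.  With ``allow_sharing`` the cost is pro-rata at the
    best per-mg price instead.
    """
    if dose_mg < 0:
        raise ValidationError(f"dose {dose_mg!r} must be non-negative")
    if dose_mg == 0:
        return {}, 0.0
    if not menu:
        raise ValidationError("empty vial menu with a positive dose")
    if allow_sharing:
        best = min(menu, key=lambda v: v.usd / v.mg)
        return {best.mg: dose_mg / best.mg}, dose_mg * best.usd / best.mg
    max_counts = [math.ceil(dose_mg / v.mg) for v in menu]
    best_cost = math.inf
    best_counts: tuple[int, ...] = ()
    for counts in product(*(range(c + 1) for c in max_counts)):
        mg = sum(n * v.mg for n, v in zip(counts, menu))
        if mg < dose_mg:
            continue
        cost = sum(n * v.usd for n, v in zip(counts, menu))
        if cost < best_cost:
            best_cost, best_counts = cost, counts
    return (
        {v.mg: n for n, v in zip(best_counts, menu) if n},
        best_cost,
    )


# ---------------------------------------------------------------------------
# per-cycle state costs
# ---------------------------------------------------------------------------

def treatment_cycle_cost(
    strategy: str, cycle_index: int, settings: ModelSettings, costs: CostInputs
) -> float:
    """Cost of one on-treatment cycle (drug + administration + monitoring)."""
    if not 0 <= cycle_index < settings.treatment_cycles:
        raise ValidationError(
            f"cycle {cycle_index} outside the {settings.treatment_cycles}-cycle "
            "treatment tunnel"
        )
    if strategy == "trastuzumab":
        drug = costs.trastuzumab
        dose = drug.dose_mg_per_kg * settings.body_weight_kg
        _, vial_cost = optimal_vial_combination(
            dose, drug.vials, costs.allow_vial_sharing
        )
    elif strategy == "tdm1":
        drug = costs.tdm1
        vial_cost = drug.vials_per_administration * drug.vial_usd
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")
    return (
        vial_cost * drug.cost_modifier + costs.admin_fee_usd + drug.monitoring_usd
    )


def mpf_cycle_cost(
    settings: ModelSettings, costs: CostInputs, with_docetaxel: bool = True
) -> float:
    """Per-cycle cost of the metastatic progression-free regimen.

    Trastuzumab (if continued until progression) plus administration, plus —
    during the docetaxel phase — the BSA-dosed docetaxel vial cost and its
    monitoring fee.
    """
    total = costs.admin_fee_usd
    if costs.trastuzumab_in_mpf:
        drug = costs.trastuzumab
        dose = drug.dose_mg_per_kg * settings.body_weight_kg
        _, vial_cost = optimal_vial_combination(
            dose, drug.vials, costs.allow_vial_sharing
        )
        total += vial_cost * drug.cost_modifier + drug.monitoring_usd
    if with_docetaxel:
        total += docetaxel_cycle_component(settings, costs)
    return total


def docetaxel_cycle_component(settings: ModelSettings, costs: CostInputs) -> float:
    """Docetaxel drug + monitoring cost for one cycle of the metastatic regimen."""
    doc = costs.docetaxel
    if settings.body_surface_area_m2 <= 0:
        raise ValidationError("body surface area must be configured and positive")
    dose = doc.dose_mg_per_m2 * settings.body_surface_area_m2
    _, vial_cost = optimal_vial_combination(dose, doc.vials, costs.allow_vial_sharing)
    return vial_cost * doc.cost_modifier + doc.monitoring_usd


def mp_cycle_cost(reference: float, scaling: float) -> float:
    """Metastatic-progression state cost: configured reference times scaling."""
    if reference < 0:
        raise ValidationError("reference cost must be non-negative")
    return reference * scaling


def eol_cycles(duration_months: float, cycle_days: float) -> float:
    return duration_months * DAYS_PER_MONTH / cycle_days


def eol_package_cost(
    mp_cost_per_cycle: float,
    multiplier: float,
    duration_months: float,
    cycle_days: float,
) -> float:
    """Incremental end-of-life cost charged once per MP->Death transition.

    Care in the last ``duration_months`` costs ``multiplier`` times the MP
    state cost; the MP cost itself keeps accruing through the trace, so the
    package charges the excess ``(multiplier - 1)`` over the equivalent
    number of cycles.
    """
    if min(mp_cost_per_cycle, multiplier, duration_months, cycle_days) < 0:
        raise ValidationError("end-of-life inputs must be non-negative")
    return (multiplier - 1.0) * mp_cost_per_cycle * eol_cycles(
        duration_months, cycle_days
    )


# ---------------------------------------------------------------------------
# assembled cost structure for the engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionPackage:
    """One-off cost and QALY adjustment triggered by a transition flux."""

    from_state: str
    to_state: str
    cost: float
    qaly: float
    label: str


@dataclass(frozen=True)
class StrategyCosting:
    """Everything the engine needs to cost one strategy arm.

    ``state_cost`` maps state name -> $/cycle while occupying the state;
    the on-treatment drug cost applies only inside the treatment tunnel,
    which the engine knows from ``settings.treatment_cycles``.
    """

    strategy: str
    idfs_on_cost: float
    idfs_off_cost: float
    mpf_cost: float
    mp_cost: float
    packages: tuple[TransitionPackage, ...]


def build_strategy_costing(strategy: str, config: ModelConfig) -> StrategyCosting:
    """Price all states and transition packages for one arm.

    The docetaxel phase (drug, monitoring, neutropenic-fever management and
    the regimen's adverse-event disutilities) is charged as a package on
    entry to MPF, since a cohort trace does not track time-in-state; the
    end-of-life escalation and the EOL utility replacement are charged on
    the MP->Death flux.
    """
    settings, costs, utils = config.settings, config.costs, config.utilities
    cyc_years = settings.cycle_years

    mp_per_cycle = mp_cycle_cost(
        costs.mp_reference_cost_usd_per_cycle, costs.mp_scaling
    )

    doc_component = docetaxel_cycle_component(settings, costs)
    nf = next(
        (
            ae
            for ae in utils.ae_profiles.get("mpf_regimen", ())
            if "febrile" in ae.name or "neutropenic_fever" in ae.name
        ),
        None,
    )
    nf_cost = (nf.incidence if nf else 0.0) * costs.neutropenic_fever_cost_usd
    mpf_ae_qaly = (
        sum(inc * dis for inc, dis in utils.profile_pairs("mpf_regimen"))
        * cyc_years
        * costs.docetaxel.cycles
    )
    mpf_entry = TransitionPackage(
        from_state="IDFS",
        to_state="MPF",
        cost=doc_component * costs.docetaxel.cycles + nf_cost,
        qaly=mpf_ae_qaly,
        label="docetaxel_phase",
    )

    eol_cost = eol_package_cost(
        mp_per_cycle,
        costs.eol_multiplier,
        costs.eol_duration_months,
        settings.cycle_days,
    )
    eol_qaly = (
        (utils.u_eol - utils.u_mp)
        * cyc_years
        * eol_cycles(costs.eol_duration_months, settings.cycle_days)
    )
    eol = TransitionPackage(
        from_state="MP", to_state="DEATH", cost=eol_cost, qaly=eol_qaly,
        label="end_of_life",
    )

    return StrategyCosting(
        strategy=strategy,
        idfs_on_cost=treatment_cycle_cost(strategy, 0, settings, costs),
        idfs_off_cost=0.0,
        mpf_cost=mpf_cycle_cost(settings, costs, with_docetaxel=False),
        mp_cost=mp_per_cycle,
        packages=(mpf_entry, eol),
    )
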