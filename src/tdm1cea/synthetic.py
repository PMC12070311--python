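"""Synthetic stand-ins for the external inputs the model needs.

The published analysis drew on three inputs that are not printed anywhere:
the WHO female life table, the Kaplan–Meier curves behind the annual event
probabilities, and a per-cycle metastatic-state reference cost.  This module
generates each with known ground truth so the whole pipeline is testable
offline:

* a Gompertz–Makeham life table (clearly a stand-in, not WHO data; a CSV
  loader accepts a real table),
* individual-level exponential survival datasets whose Kaplan–Meier-derived
  annual event probabilities recover a chosen ground truth,
* a complete default configuration carrying every printed parameter value
  plus documented stand-ins for the unprinted ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    DAYS_PER_YEAR,
    ModelConfig,
    ValidationError,
    validate_parameters,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual probabilities of all-cause death, ages 0..max."""

    age: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self):
        if len(self.age) != len(self.q_annual):
            raise ValidationError("life table age and q columns differ in length")
        if np.any((self.q_annual < 0) | (self.q_annual > 1)):
            raise ValidationError("life table q outside [0, 1]")

    def annual_q(self, age: float | np.ndarray) -> np.ndarray:
        """Annual death probability at (floored) age; errors on a gap."""
        idx = np.floor(np.asarray(age)).astype(int) - int(self.age[0])
        if np.any(idx < 0) or np.any(idx >= len(self.age)):
            bad = np.asarray(age)[(idx < 0) | (idx >= len(self.age))]
            raise ValidationError(
                f"life table does not cover age(s) {np.unique(bad)!r}"
            )
        return self.q_annual[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "qx": self.q_annual})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy(float))


def make_life_table(
    makeham_a: float = 5.0e-5,
    gompertz_b: float = 2.3e-5,
    gompertz_c: float = 0.099,
    max_age: int = 100,
) -> LifeTable:
    """Gompertz–Makeham synthetic life table.

    ``q(age) = 1 - exp(-(a + b * exp(c * age)))``.  Default parameters give
    q(45) ~ 2e-3 and q(85) ~ 0.1 — the general shape of an adult female
    life table, documented as a non-authoritative stand-in.  Values that
    would exceed 1 are clamped with a warning.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ValidationError("life-table parameters must be non-negative")
    age = np.arange(max_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * age)
    q = 1.0 - np.exp(-hazard)
    if np.any(q > 1.0):  # pragma: no cover - exp() keeps q < 1 mathematically
        logger.warning("life-table q exceeded 1 at some ages; clamped")
        q = np.clip(q, 0.0, 1.0)
    return LifeTable(age=age, q_annual=q)


def life_table_from_config(config: ModelConfig) -> LifeTable:
    """Build (or load) the life table a configuration asks for."""
    lt = config.life_table
    if lt.csv_path is not None:
        return LifeTable.from_csv(lt.csv_path)
    return make_life_table(lt.makeham_a, lt.gompertz_b, lt.gompertz_c)


# ---------------------------------------------------------------------------
# survival datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSurvivalDataset:
    """Individual-level times with the generating annual probability recorded."""

    frame: pd.DataFrame = field(repr=False)  # columns: time_days, event
    annual_p: float
    seed: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def simulate_survival_dataset(
    annual_p: float,
    n: int,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticSurvivalDataset:
    """Exponential event times matching a target annual event probability.

    Event rate is ``-ln(1 - annual_p) / 365.25`` per day; censoring is an
    independent exponential with annual probability ``censor_rate`` (0
    disables it).  Reproducible under a fixed seed.
    """
    if not 0.0 < annual_p < 1.0:
        raise ValidationError(f"annual_p={annual_p!r} outside (0, 1)")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError(f"censor_rate={censor_rate!r} outside [0, 1)")
    rng = np.random.default_rng(seed)
    rate = -np.log1p(-annual_p) / DAYS_PER_YEAR
    t_event = rng.exponential(1.0 / rate, size=n)
    if censor_rate > 0.0:
        c_rate = -np.log1p(-censor_rate) / DAYS_PER_YEAR
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    frame = pd.DataFrame({"time_days": time, "event": event})
    return SyntheticSurvivalDataset(frame=frame, annual_p=annual_p, seed=seed)


def km_annual_probability(dataset: SyntheticSurvivalDataset | pd.DataFrame) -> float:
    """Product-limit estimate of the one-year event probability 1 - S(365.25 d)."""
    from lifelines import KaplanMeierFitter

    frame = dataset.frame if isinstance(dataset, SyntheticSurvivalDataset) else dataset
    if int(frame["event"].sum()) == 0:
        raise ValidationError("all observations censored; KM estimate undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(frame["time_days"], event_observed=frame["event"])
    return float(1.0 - kmf.predict(DAYS_PER_YEAR))


# ---------------------------------------------------------------------------
# default fixture configuration
# ---------------------------------------------------------------------------

def default_config() -> ModelConfig:
    """The packaged base-case configuration.

    Printed parameter values (doses, hazard ratios with CIs, utilities,
    adverse-event incidences and disutilities, vial prices, monitoring and
    administration fees, tariff and market-share weights, the end-of-life
    multiplier, the budget-impact funnel) are carried verbatim.  Quantities
    the source analysis used but never printed are synthetic stand-ins with
    the rationale in the methods note: comparator-arm baseline annual event
    probabilities, the per-cycle metastatic reference cost, body surface
    area, T-DM1 vials per administration, and the neutropenic-fever
    treatment cost.
    """
    raw = {
        "settings": {},  # all defaults: 21-day cycle, ages 45-100, 7%/3%
        "transitions": {
            "idfs_hr": {
                "point": 0.5, "ci_low": 0.39, "ci_high": 0.64,
                "family": "beta", "kind": "hazard_ratio",
                "applies_to": "idfs_event", "arms": ["tdm1"],
            },
            "drfs": {
                "point": 0.6, "ci_low": 0.45, "ci_high": 0.79,
                "family": "beta", "kind": "hazard_ratio",
                "applies_to": None, "arms": ["tdm1"],
            },
            "os_mpf": {
                "point": 0.74, "ci_low": 0.49, "ci_high": 1.120,
                "family": "beta", "kind": "hazard_ratio",
                "applies_to": "mpf_death", "arms": ["trastuzumab", "tdm1"],
            },
            "pfs_mpf": {
                "point": 0.69, "ci_low": 0.48, "ci_high": 0.990,
                "family": "beta", "kind": "hazard_ratio",
                "applies_to": "mpf_progression", "arms": ["trastuzumab", "tdm1"],
            },
            # synthetic stand-ins: annual event probabilities for the
            # comparator arm / untreated metastatic course
            "baseline_annual": {
                "idfs_event": 0.08,
                "mpf_progression": 0.45,
                "mpf_death": 0.10,
                "mp_death": 0.35,
            },
            "idfs_effect_param": "idfs_hr",
        },
        "utilities": {
            "u_idfs_on": 0.814,
            "u_idfs_off": 0.826,
            "u_mpf": 0.702,
            "u_mp": 0.443,
            "u_eol": 0.250,
            "ae_profiles": {
                # grade >=III incidences; events without a published
                # disutility carry 0
                "trastuzumab": [
                    {"name": "platelet_count_decreased", "incidence": 0.003, "disutility": -0.108},
                    {"name": "hypertension", "incidence": 0.012, "disutility": 0.0},
                    {"name": "radiation_skin_injury", "incidence": 0.010, "disutility": 0.0},
                    {"name": "peripheral_sensory_neuropathy", "incidence": 0.0, "disutility": -0.12},
                    {"name": "neutrophil_count_decreased", "incidence": 0.007, "disutility": -0.09},
                    {"name": "hypokalemia", "incidence": 0.001, "disutility": 0.0},
                    {"name": "fatigue", "incidence": 0.001, "disutility": -0.115},
                    {"name": "anemia", "incidence": 0.001, "disutility": -0.12},
                ],
                "tdm1": [
                    {"name": "platelet_count_decreased", "incidence": 0.057, "disutility": -0.108},
                    {"name": "hypertension", "incidence": 0.020, "disutility": 0.0},
                    {"name": "radiation_skin_injury", "incidence": 0.014, "disutility": 0.0},
                    {"name": "peripheral_sensory_neuropathy", "incidence": 0.014, "disutility": -0.12},
                    {"name": "neutrophil_count_decreased", "incidence": 0.012, "disutility": -0.09},
                    {"name": "hypokalemia", "incidence": 0.012, "disutility": 0.0},
                    {"name": "fatigue", "incidence": 0.011, "disutility": -0.115},
                    {"name": "anemia", "incidence": 0.011, "disutility": -0.12},
                ],
                "mpf_regimen": [
                    {"name": "diarrhea", "incidence": 0.042, "disutility": -0.103},
                    {"name": "peripheral_neuropathy", "incidence": 0.280, "disutility": -0.12},
                    {"name": "peripheral_edema", "incidence": 0.278, "disutility": -0.06},
                    {"name": "neutropenia", "incidence": 0.193, "disutility": -0.09},
                    {"name": "febrile_neutropenia", "incidence": 0.065, "disutility": -0.15},
                    {"name": "elevated_alt", "incidence": 0.008, "disutility": 0.0},
                    {"name": "elevated_ast", "incidence": 0.003, "disutility": 0.0},
                    {"name": "elevated_ggt", "incidence": 0.003, "disutility": 0.0},
                    {"name": "anemia", "incidence": 0.050, "disutility": -0.12},
                    {"name": "hypertension", "incidence": 0.047, "disutility": 0.0},
                ],
            },
        },
        "costs": {
            "trastuzumab": {
                "dose_mg_per_kg": 6.0,
                "vials": [{"mg": 150, "usd": 71.0}, {"mg": 440, "usd": 182.0}],
                "monitoring_usd": 13.0,
                "cost_modifier": 1.0,
            },
            "tdm1": {
                "dose_mg_per_kg": 3.6,
                "vial_usd": 180.0,
                "vials_per_administration": 2,  # stand-in: 234 mg via 100+160 mg
                "monitoring_usd": 13.0,
                "cost_modifier": 1.0,
            },
            "docetaxel": {
                "dose_mg_per_m2": 75.0,
                "cycles": 6,
                "vials": [{"mg": 20, "usd": 8.0}, {"mg": 80, "usd": 31.0}],
                "monitoring_usd": 6.0,
                "cost_modifier": 1.0,
            },
            "admin_fee_usd": 4.5,
            "generic_share": 0.95,
            "tariff_gov_weight": 0.8,
            "tariff_priv_weight": 0.2,
            "mp_reference_cost_usd_per_cycle": 450.0,  # synthetic stand-in
            "mp_scaling": 1.0 / 3.0,
            "eol_multiplier": 4.15,
            "eol_duration_months": 6.0,
            "neutropenic_fever_cost_usd": 500.0,  # synthetic stand-in
            "trastuzumab_in_mpf": True,
            "allow_vial_sharing": False,
            "uncertainty_cv": 0.1,
        },
        "bia": {
            "total_patients": 12684,
            "access_share": 0.95,
            "her2_share": 0.243,
            "residual_share": 0.50,
            "residual_share_range": [0.40, 0.60],
            "annual_growth": 0.03,
            "uptake_by_year": [0.05, 0.10, 0.15],
        },
        "life_table": {},
    }
    return validate_parameters(raw)


# kept under the name the rest of the codebase and docs use interchangeably
default_fixture_config = default_config
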