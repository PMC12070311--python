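"""Model parameters: schema, validation, and clinical-scale conversions.

Every quantity the model consumes lives in a :class:`ModelConfig` tree of
frozen pydantic models.  Clinical inputs arrive on an annual scale (annual
event probabilities, hazard ratios with 95% CIs); the Markov engine runs on
a 21-day cycle, so this module owns the annual-to-cycle conversion and the
proportional-hazards transform, plus method-of-moments fitting of the
sampling distributions used in probabilistic sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pydantic
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

ArmName = Literal["trastuzumab", "tdm1"]
TransitionName = Literal["idfs_event", "mpf_progression", "mpf_death", "mp_death"]


class ValidationError(ValueError):
    """Aggregated parameter-validation failure; message names every bad field."""


# ---------------------------------------------------------------------------
# scale conversions
# ---------------------------------------------------------------------------

def annual_prob_to_cycle_prob(p_annual: float, cycle_days: float) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant (exponential) hazard within the year, so
    ``p_cycle = 1 - (1 - p_annual) ** (cycle_days / 365.25)``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValidationError(f"p_annual={p_annual!r} outside [0, 1]")
    if cycle_days <= 0:
        raise ValidationError(f"cycle_days={cycle_days!r} must be positive")
    return 1.0 - (1.0 - p_annual) ** (cycle_days / DAYS_PER_YEAR)


def cycle_prob_to_annual(p_cycle: float, cycle_days: float) -> float:
    """Inverse of :func:`annual_prob_to_cycle_prob`."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValidationError(f"p_cycle={p_cycle!r} outside [0, 1]")
    if cycle_days <= 0:
        raise ValidationError(f"cycle_days={cycle_days!r} must be positive")
    return 1.0 - (1.0 - p_cycle) ** (DAYS_PER_YEAR / cycle_days)


def apply_hazard_ratio(
    p_base: float, hr: float, method: str = "probability"
) -> float:
    """Apply a hazard ratio to a baseline event probability.

    ``1 - (1 - p_base) ** hr`` — the proportional-hazards transform on the
    probability scale.  Under the exponential within-interval hazard used
    throughout (rate ``r = -ln(1 - p)``), the rate-scale route
    ``1 - exp(-hr * r)`` is algebraically the same map, so both ``method``
    names share one code path.
    """
    if method not in ("probability", "rate"):
        raise ValidationError(f"unknown hazard-ratio method {method!r}")
    if not 0.0 <= p_base <= 1.0:
        raise ValidationError(f"p_base={p_base!r} outside [0, 1]")
    if hr <= 0.0:
        raise ValidationError(f"hazard ratio hr={hr!r} must be positive")
    return 1.0 - (1.0 - p_base) ** hr


def effective_state_utility(
    base: float, ae_profile: Sequence[tuple[float, float]]
) -> float:
    """State utility net of adverse-event disutilities.

    ``base + sum(incidence_i * disutility_i)``, floored at 0 (a clamp is
    logged, not fatal).  ``ae_profile`` is an iterable of
    ``(incidence, disutility)`` pairs with incidence in [0, 1] and
    disutility <= 0.
    """
    total = float(base)
    for incidence, disutility in ae_profile:
        if not 0.0 <= incidence <= 1.0:
            raise ValidationError(f"incidence={incidence!r} outside [0, 1]")
        if disutility > 0.0:
            raise ValidationError(f"disutility={disutility!r} must be <= 0")
        total += incidence * disutility
    if total < 0.0:
        logger.warning("effective utility %.4f < 0 clamped to 0", total)
        total = 0.0
    return total


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

DistributionFamily = Literal["beta", "gamma", "normal", "lognormal"]


class ParamSpec(BaseModel, frozen=True):
    """A scalar parameter with its uncertainty specification.

    The 95% CI is read as symmetric-normal for moment fitting
    (sd = width / 3.92).  Parameters published without a CI fall back to a
    coefficient of variation supplied at fit time.
    """

    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    family: DistributionFamily = "beta"

    @model_validator(mode="after")
    def _check_ci(self) -> "ParamSpec":
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not self.ci_low <= self.point <= self.ci_high:
                raise ValueError(
                    f"CI ({self.ci_low}, {self.ci_high}) does not bracket "
                    f"point {self.point}"
                )
        return self


@dataclass(frozen=True)
class FittedDistribution:
    """Method-of-moments fit of a :class:`ParamSpec`, ready for sampling."""

    family: str
    mean: float
    sd: float
    params: tuple[float, ...]
    sign: float = 1.0  # -1 for negative-valued parameters fitted on magnitude

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.sd == 0.0:
            out = np.full(size if size is not None else (), self.mean)
            return float(out) if size is None else out
        if self.family == "beta":
            out = rng.beta(*self.params, size=size)
        elif self.family == "gamma":
            shape, scale = self.params
            out = rng.gamma(shape, scale, size=size)
        elif self.family == "normal":
            out = rng.normal(*self.params, size=size)
        elif self.family == "lognormal":
            out = rng.lognormal(*self.params, size=size)
        else:  # pragma: no cover
            raise ValidationError(f"unknown family {self.family!r}")
        return self.sign * out


def fit_distribution(
    spec: ParamSpec, default_cv: float = 0.1, name: str = ""
) -> FittedDistribution:
    """Fit shape parameters to a point estimate and 95% CI by moments.

    beta: ``alpha + beta = m(1-m)/v - 1``; gamma: ``shape = m^2/v``,
    ``scale = v/m``; normal: ``(m, sd)``.  A beta request whose CI upper
    bound exceeds 1 cannot be a probability-scale quantity and is switched
    to lognormal with a warning.  Negative-valued parameters (disutilities)
    are fitted on their magnitude and sampled with the sign restored.
    """
    m = spec.point
    sign = 1.0
    if m < 0:
        sign = -1.0
        m = -m
    if spec.ci_low is not None:
        lo, hi = sorted((sign * spec.ci_low, sign * spec.ci_high))
        if hi == lo:
            raise ValidationError(
                f"degenerate zero-width CI for {name or 'parameter'}"
            )
        sd = (hi - lo) / (2.0 * 1.96)
    else:
        sd = default_cv * abs(m)
        hi = m + 1.96 * sd
    family = spec.family
    if family == "beta" and hi > 1.0:
        logger.warning(
            "parameter %s: beta requested but CI upper bound %.3f > 1; "
            "switching to lognormal", name or "<unnamed>", hi,
        )
        family = "lognormal"
    if sd == 0.0:
        return FittedDistribution(family, sign * m, 0.0, (m,), sign=1.0)
    v = sd * sd
    if family == "beta":
        if not 0.0 < m < 1.0:
            raise ValidationError(f"beta mean {m} for {name!r} outside (0, 1)")
        if v >= m * (1.0 - m):
            raise ValidationError(
                f"infeasible beta moments for {name!r}: variance {v:.4g} >= "
                f"m(1-m) = {m * (1 - m):.4g}"
            )
        conc = m * (1.0 - m) / v - 1.0
        params = (m * conc, (1.0 - m) * conc)
    elif family == "gamma":
        if m <= 0:
            raise ValidationError(f"gamma mean {m} for {name!r} must be > 0")
        params = (m * m / v, v / m)
    elif family == "normal":
        params = (m, sd)
    elif family == "lognormal":
        sigma2 = math.log1p(v / (m * m))
        params = (math.log(m) - sigma2 / 2.0, math.sqrt(sigma2))
    else:  # pragma: no cover
        raise ValidationError(f"unknown family {family!r}")
    return FittedDistribution(family, m, sd, params, sign=sign)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class ModelSettings(BaseModel, frozen=True):
    """Global model constants (time grid, discounting, cohort, threshold)."""

    cycle_days: float = 21.0
    start_age: float = 45.0
    horizon_age: float = 100.0
    discount_cost: float = 0.07
    discount_utility: float = 0.03
    body_weight_kg: float = 65.0
    body_surface_area_m2: float = 1.7
    wtp_threshold: float = 1085.0
    treatment_cycles: int = 14
    half_cycle_correction: bool = True
    hr_transform: Literal["probability", "rate"] = "probability"

    @model_validator(mode="after")
    def _invariants(self) -> "ModelSettings":
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        for field in ("discount_cost", "discount_utility"):
            r = getattr(self, field)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{field}={r} outside [0, 1)")
        if self.start_age >= self.horizon_age:
            raise ValueError("start_age must be below horizon_age")
        if self.treatment_cycles < 1:
            raise ValueError("treatment_cycles must be >= 1")
        if self.body_weight_kg <= 0 or self.body_surface_area_m2 <= 0:
            raise ValueError("body size parameters must be positive")
        return self

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return math.ceil((self.horizon_age - self.start_age) / self.cycle_years)


class EffectParam(ParamSpec, frozen=True):
    """A clinical effect parameter plus its interpretation wiring.

    ``kind`` says whether the printed value is a hazard ratio (applied
    multiplicatively to a baseline annual probability) or itself an annual
    probability; ``applies_to`` names the transition it modifies, and
    ``arms`` lists the strategies it applies to.  ``applies_to=None``
    leaves the parameter inert (sampled in PSA but not wired into the
    base-case transitions).
    """

    kind: Literal["hazard_ratio", "annual_probability"] = "hazard_ratio"
    applies_to: Optional[TransitionName] = None
    arms: tuple[ArmName, ...] = ("trastuzumab", "tdm1")

    @model_validator(mode="after")
    def _positive(self) -> "EffectParam":
        if self.point <= 0:
            raise ValueError(f"effect point estimate {self.point} must be > 0")
        if self.kind == "annual_probability" and not 0 < self.point < 1:
            raise ValueError("annual_probability value must lie in (0, 1)")
        return self


class BaselineProbs(BaseModel, frozen=True):
    """Comparator-arm annual event probabilities (per transition)."""

    idfs_event: float
    mpf_progression: float
    mpf_death: float
    mp_death: float

    @model_validator(mode="after")
    def _in_unit(self) -> "BaselineProbs":
        for name in ("idfs_event", "mpf_progression", "mpf_death", "mp_death"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline {name}={p} outside (0, 1)")
        return self


class TransitionInputs(BaseModel, frozen=True):
    idfs_hr: EffectParam
    drfs: EffectParam
    os_mpf: EffectParam
    pfs_mpf: EffectParam
    baseline_annual: BaselineProbs
    # selects which arm-effect parameter drives the TDM1 IDFS->MPF difference
    idfs_effect_param: Literal["idfs_hr", "drfs"] = "idfs_hr"

    def effect_params(self) -> dict[str, EffectParam]:
        return {
            "idfs_hr": self.idfs_hr,
            "drfs": self.drfs,
            "os_mpf": self.os_mpf,
            "pfs_mpf": self.pfs_mpf,
        }

    def resolve_annual(
        self, arm: ArmName, hr_method: str = "probability"
    ) -> dict[str, float]:
        """Annual transition probabilities for one strategy arm.

        Starts from the comparator baseline and applies each effect
        parameter according to its interpretation flag and arm wiring.
        """
        annual = {
            "idfs_event": self.baseline_annual.idfs_event,
            "mpf_progression": self.baseline_annual.mpf_progression,
            "mpf_death": self.baseline_annual.mpf_death,
            "mp_death": self.baseline_annual.mp_death,
        }
        for name, par in self.effect_params().items():
            if name in ("idfs_hr", "drfs"):
                # exactly one of the two drives the IDFS->MPF arm effect
                if name != self.idfs_effect_param:
                    continue
                target = par.applies_to or "idfs_event"
            else:
                target = par.applies_to
            if target is None or arm not in par.arms:
                continue
            if par.kind == "annual_probability":
                annual[target] = par.point
            else:
                annual[target] = apply_hazard_ratio(
                    annual[target], par.point, method=hr_method
                )
        return annual


class AdverseEvent(BaseModel, frozen=True):
    name: str
    incidence: float = Field(ge=0.0, le=1.0)
    disutility: float = Field(le=0.0)


class UtilityInputs(BaseModel, frozen=True):
    u_idfs_on: float = Field(ge=0.0, le=1.0)
    u_idfs_off: float = Field(ge=0.0, le=1.0)
    u_mpf: float = Field(ge=0.0, le=1.0)
    u_mp: float = Field(ge=0.0, le=1.0)
    u_eol: float = Field(ge=0.0, le=1.0)
    ae_profiles: dict[str, tuple[AdverseEvent, ...]] = Field(default_factory=dict)

    def profile_pairs(self, key: str) -> list[tuple[float, float]]:
        return [(ae.incidence, ae.disutility) for ae in self.ae_profiles.get(key, ())]


class VialOption(BaseModel, frozen=True):
    mg: float = Field(gt=0.0)
    usd: float = Field(ge=0.0)


class InfusionDrugCost(BaseModel, frozen=True):
    """Weight-dosed drug priced from a vial menu (trastuzumab)."""

    dose_mg_per_kg: float = Field(gt=0.0)
    vials: tuple[VialOption, ...]
    monitoring_usd: float = Field(ge=0.0)
    cost_modifier: float = Field(default=1.0, ge=0.0)


class FixedVialDrugCost(BaseModel, frozen=True):
    """Drug priced per vial with a configured vial count (T-DM1; the single
    published price carries no mg content)."""

    dose_mg_per_kg: float = Field(gt=0.0)
    vial_usd: float = Field(ge=0.0)
    vials_per_administration: int = Field(default=2, ge=1)
    monitoring_usd: float = Field(ge=0.0)
    cost_modifier: float = Field(default=1.0, ge=0.0)


class BsaDrugCost(BaseModel, frozen=True):
    """Body-surface-area-dosed drug (docetaxel in the metastatic regimen)."""

    dose_mg_per_m2: float = Field(gt=0.0)
    cycles: int = Field(ge=0)
    vials: tuple[VialOption, ...]
    monitoring_usd: float = Field(ge=0.0)
    cost_modifier: float = Field(default=1.0, ge=0.0)


class CostInputs(BaseModel, frozen=True):
    trastuzumab: InfusionDrugCost
    tdm1: FixedVialDrugCost
    docetaxel: BsaDrugCost
    admin_fee_usd: float = Field(ge=0.0)
    generic_share: float = Field(ge=0.0, le=1.0)
    tariff_gov_weight: float = Field(ge=0.0, le=1.0)
    tariff_priv_weight: float = Field(ge=0.0, le=1.0)
    mp_reference_cost_usd_per_cycle: float = Field(ge=0.0)
    mp_scaling: float = Field(gt=0.0, le=1.0)
    eol_multiplier: float = Field(ge=1.0)
    eol_duration_months: float = Field(ge=0.0)
    neutropenic_fever_cost_usd: float = Field(ge=0.0)
    trastuzumab_in_mpf: bool = True
    allow_vial_sharing: bool = False
    uncertainty_cv: float = Field(default=0.1, gt=0.0)

    @model_validator(mode="after")
    def _weights(self) -> "CostInputs":
        if abs(self.tariff_gov_weight + self.tariff_priv_weight - 1.0) > 1e-9:
            raise ValueError("tariff weights must sum to 1")
        return self


class BiaInputs(BaseModel, frozen=True):
    total_patients: int = Field(gt=0)
    access_share: float = Field(ge=0.0, le=1.0)
    her2_share: float = Field(ge=0.0, le=1.0)
    residual_share: float = Field(ge=0.0, le=1.0)
    residual_share_range: tuple[float, float] = (0.40, 0.60)
    annual_growth: float = Field(ge=0.0)
    uptake_by_year: tuple[float, ...] = (0.05, 0.10, 0.15)

    @model_validator(mode="after")
    def _uptake(self) -> "BiaInputs":
        for u in self.uptake_by_year:
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"uptake {u} outside [0, 1]")
        if any(
            b < a
            for a, b in zip(self.uptake_by_year, self.uptake_by_year[1:])
        ):
            raise ValueError("uptake_by_year must be non-decreasing")
        return self


class LifeTableParams(BaseModel, frozen=True):
    """Gompertz–Makeham generator parameters, or a CSV path to a real table."""

    makeham_a: float = Field(default=5.0e-5, ge=0.0)
    gompertz_b: float = Field(default=2.3e-5, ge=0.0)
    gompertz_c: float = Field(default=0.099, ge=0.0)
    csv_path: Optional[str] = None


class ModelConfig(BaseModel, frozen=True):
    """Root configuration: every number the pipeline consumes."""

    settings: ModelSettings = ModelSettings()
    transitions: TransitionInputs
    utilities: UtilityInputs
    costs: CostInputs
    bia: BiaInputs
    life_table: LifeTableParams = LifeTableParams()


def validate_parameters(raw: Mapping | ModelConfig) -> ModelConfig:
    """Validate a raw mapping (or re-validate a config) into a ModelConfig.

    Raises :class:`ValidationError` whose message aggregates every violated
    field with its dotted path.
    """
    if isinstance(raw, ModelConfig):
        raw = raw.model_dump()
    try:
        return ModelConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"])
            lines.append(f"{path}: {err['msg']}")
        raise ValidationError(
            "invalid model parameters:\n  " + "\n  ".join(lines)
        ) from exc


def load_config(path) -> ModelConfig:
    """Load and validate a YAML or JSON configuration file."""
    import json
    import yaml

    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return validate_parameters(raw)


def save_config(config: ModelConfig, path) -> None:
    """Write a configuration to YAML (round-trips through load_config)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
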