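"""Markov cohort engine.

Health states: IDFS_on (a 14-cycle on-treatment tunnel), IDFS_off, MPF
(metastatic progression-free), MP (metastatic progression) and Death.
Transitions follow the model structure: IDFS -> {IDFS, MPF, Death},
MPF -> {MPF, MP, Death}, MP -> {MP, Death}; Death is absorbing.  Background
(non-cancer) mortality comes from an age-indexed life table and acts on all
living states; disease events are scaled into the residual survival mass so
that every row stays stochastic.

The engine propagates state occupancy through per-cycle transition matrices,
accumulates discounted costs and QALYs with a half-cycle correction, and
reports the incremental cost-effectiveness ratio.  A patient-level
microsimulation over the same matrices serves as an independent validation
route for the deterministic trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .costing import StrategyCosting, TransitionPackage, build_strategy_costing
from .parameters import (
    ModelConfig,
    ValidationError,
    annual_prob_to_cycle_prob,
)
from .synthetic import LifeTable, life_table_from_config

STATES = ("IDFS_on", "IDFS_off", "MPF", "MP", "DEATH")
IDFS_ON, IDFS_OFF, MPF, MP, DEATH = range(5)

ROW_SUM_TOL = 1e-12
TRACE_SUM_TOL = 1e-10
DEATH_STOP = 1.0 - 1e-6


@dataclass(frozen=True)
class TransitionMatrixSequence:
    """Row-stochastic 5x5 matrices, one per cycle (time-varying mortality)."""

    matrices: np.ndarray  # (n_cycles, 5, 5)
    ages: np.ndarray      # age at the start of each cycle
    strategy: str = ""

    def __post_init__(self):
        m = self.matrices
        if m.ndim != 3 or m.shape[1:] != (5, 5):
            raise ValidationError(f"matrix sequence has shape {m.shape}")
        if np.any(m < -ROW_SUM_TOL) or np.any(m > 1 + ROW_SUM_TOL):
            raise ValidationError("transition probabilities outside [0, 1]")
        if np.max(np.abs(m.sum(axis=2) - 1.0)) > ROW_SUM_TOL:
            raise ValidationError("transition matrix rows do not sum to 1")
        if not np.allclose(m[:, DEATH, :], np.eye(5)[DEATH], atol=ROW_SUM_TOL):
            raise ValidationError("Death row must be the identity row")

    def __len__(self) -> int:
        return self.matrices.shape[0]


def build_transition_sequence(
    strategy: str,
    config: ModelConfig,
    life_table: LifeTable,
) -> TransitionMatrixSequence:
    """Per-cycle transition matrices for one strategy arm.

    Background mortality is applied first; disease-event probabilities act
    on the residual ``1 - p_bg`` mass.  Within MPF, excess death and
    progression are treated as independent competing events with death
    taking precedence: ``P(death) = p_bg + (1-p_bg) q_d`` and
    ``P(progress) = (1-p_bg)(1-q_d) q_p``.  The on-treatment tunnel empties
    into IDFS_off at the end of cycle ``treatment_cycles``.
    """
    if strategy not in ("trastuzumab", "tdm1"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    settings = config.settings
    n = settings.n_cycles
    cyc = settings.cycle_days

    ages = settings.start_age + np.arange(n) * settings.cycle_years
    q_bg_annual = life_table.annual_q(ages)
    p_bg = 1.0 - (1.0 - q_bg_annual) ** (cyc / 365.25)

    annual = config.transitions.resolve_annual(
        strategy, hr_method=settings.hr_transform
    )
    p_rel = annual_prob_to_cycle_prob(annual["idfs_event"], cyc)
    p_prog = annual_prob_to_cycle_prob(annual["mpf_progression"], cyc)
    p_mpf_d = annual_prob_to_cycle_prob(annual["mpf_death"], cyc)
    p_mp_d = annual_prob_to_cycle_prob(annual["mp_death"], cyc)

    live = 1.0 - p_bg  # (n,)
    m = np.zeros((n, 5, 5))

    # IDFS rows (on-treatment tunnel and off-treatment)
    idfs_to_mpf = live * p_rel
    idfs_stay = live * (1.0 - p_rel)
    k = np.arange(n)
    in_tunnel = k < settings.treatment_cycles - 1
    m[:, IDFS_ON, MPF] = idfs_to_mpf
    m[:, IDFS_ON, DEATH] = p_bg
    m[in_tunnel, IDFS_ON, IDFS_ON] = idfs_stay[in_tunnel]
    m[~in_tunnel, IDFS_ON, IDFS_OFF] = idfs_stay[~in_tunnel]
    m[:, IDFS_OFF, IDFS_OFF] = idfs_stay
    m[:, IDFS_OFF, MPF] = idfs_to_mpf
    m[:, IDFS_OFF, DEATH] = p_bg

    # MPF row: competing excess death and progression in the residual mass
    mpf_death = p_bg + live * p_mpf_d
    mpf_prog = live * (1.0 - p_mpf_d) * p_prog
    m[:, MPF, DEATH] = mpf_death
    m[:, MPF, MP] = mpf_prog
    m[:, MPF, MPF] = 1.0 - mpf_death - mpf_prog

    # MP row
    mp_death = p_bg + live * p_mp_d
    m[:, MP, DEATH] = mp_death
    m[:, MP, MP] = 1.0 - mp_death

    m[:, DEATH, DEATH] = 1.0

    return TransitionMatrixSequence(matrices=m, ages=ages, strategy=strategy)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over cycles; row 0 is the starting distribution."""

    occupancy: np.ndarray  # (n_rows, 5), rows sum to 1
    ages: np.ndarray
    strategy: str = ""

    def __post_init__(self):
        occ = self.occupancy
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > TRACE_SUM_TOL:
            raise ValidationError("trace rows do not sum to 1")
        if np.any(np.diff(occ[:, DEATH]) < -TRACE_SUM_TOL):
            raise ValidationError("Death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def life_years(self) -> float:
        """Undiscounted life-years (half-cycle corrected)."""
        alive = 1.0 - self.occupancy[:, DEATH]
        mid = 0.5 * (alive[:-1] + alive[1:])
        return float(mid.sum() * (self.ages[1] - self.ages[0]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages[: len(df)])
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(
    sequence: TransitionMatrixSequence,
    n_cycles: Optional[int] = None,
    start_state: int = IDFS_ON,
) -> CohortTrace:
    """Propagate the cohort: row k+1 = row k @ matrix k.

    Stops early once Death occupancy exceeds ``1 - 1e-6``.
    """
    n = len(sequence) if n_cycles is None else min(n_cycles, len(sequence))
    occ = np.zeros((n + 1, 5))
    occ[0, start_state] = 1.0
    mats = sequence.matrices
    last = n
    for k in range(n):
        occ[k + 1] = occ[k] @ mats[k]
        if occ[k + 1, DEATH] > DEATH_STOP:
            last = k + 1
            break
    cycle_years = float(
        sequence.ages[1] - sequence.ages[0]
    ) if len(sequence.ages) > 1 else 0.0
    ages = sequence.ages[0] + np.arange(last + 1) * cycle_years
    return CohortTrace(
        occupancy=occ[: last + 1], ages=ages, strategy=sequence.strategy
    )


def microsimulate(
    sequence: TransitionMatrixSequence,
    n_patients: int,
    seed: int,
    n_cycles: Optional[int] = None,
    start_state: int = IDFS_ON,
) -> np.ndarray:
    """Patient-level frequencies over the same matrices (validation route).

    Returns an occupancy-frequency array shaped like the cohort trace.
    Individuals transition by inverse-CDF sampling each cycle.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(sequence) if n_cycles is None else min(n_cycles, len(sequence))
    states = np.full(n_patients, start_state, dtype=np.int64)
    freq = np.zeros((n + 1, 5))
    freq[0, start_state] = 1.0
    for k in range(n):
        cum = np.cumsum(sequence.matrices[k][states], axis=1)
        u = rng.random(n_patients)
        states = (u[:, None] > cum).sum(axis=1)
        freq[k + 1] = np.bincount(states, minlength=5) / n_patients
    return freq


# ---------------------------------------------------------------------------
# discounted accumulation
# ---------------------------------------------------------------------------

def discount_factor(elapsed_years: float | np.ndarray, rate: float):
    """Present-value factor ``(1 + rate) ** (-elapsed_years)``."""
    if rate < 0:
        raise ValidationError(f"discount rate {rate!r} must be >= 0")
    elapsed = np.asarray(elapsed_years, dtype=float)
    if np.any(elapsed < 0):
        raise ValidationError("elapsed time must be non-negative")
    out = (1.0 + rate) ** (-elapsed)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StrategyOutcome:
    strategy: str
    cost: float
    qaly: float
    life_years: float
    trace: CohortTrace = field(repr=False)
    cost_components: dict = field(default_factory=dict, repr=False)


def accumulate_outcomes(
    trace: CohortTrace,
    sequence: TransitionMatrixSequence,
    state_utilities: np.ndarray,
    state_costs: np.ndarray,
    packages: tuple[TransitionPackage, ...],
    config: ModelConfig,
) -> tuple[float, float, dict]:
    """Discounted cost and QALY totals from a cohort trace.

    ``state_utilities`` is (5,) or (n_cycles, 5) utility weights;
    ``state_costs`` likewise in $/cycle.  Per-cycle accrual uses the
    half-cycle correction (mean of adjacent occupancy rows) when enabled;
    transition packages are charged against the flux
    ``occ[k, from] * M[k, from, to]`` at the discount factor of cycle k.
    QALYs weight occupancy by utility times the cycle length in years.
    """
    settings = config.settings
    occ = trace.occupancy
    n = trace.n_cycles
    mats = sequence.matrices[:n]
    dt = settings.cycle_years

    u = np.asarray(state_utilities, dtype=float)
    c = np.asarray(state_costs, dtype=float)
    if u.ndim == 1:
        u = np.broadcast_to(u, (n, 5))
    if c.ndim == 1:
        c = np.broadcast_to(c, (n, 5))
    if u.shape != (n, 5) or c.shape != (n, 5):
        raise ValidationError(
            f"utility/cost arrays must align with the trace: got {u.shape}, "
            f"{c.shape}, expected {(n, 5)}"
        )

    if settings.half_cycle_correction:
        occ_mid = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_mid = occ[:-1]
    elapsed = np.arange(n) * dt
    df_u = discount_factor(elapsed, settings.discount_utility)
    df_c = discount_factor(elapsed, settings.discount_cost)

    qaly = float(np.sum(df_u * np.sum(occ_mid * u, axis=1)) * dt)
    cost = float(np.sum(df_c * np.sum(occ_mid * c, axis=1)))
    components = {"state_cost": cost, "state_qaly": qaly}

    state_index = {s: i for i, s in enumerate(STATES)}
    for pkg in packages:
        if pkg.from_state == "IDFS":
            sources = (IDFS_ON, IDFS_OFF)
        else:
            sources = (state_index[pkg.from_state],)
        dest = state_index[pkg.to_state]
        flux = np.zeros(n)
        for s in sources:
            flux += occ[:-1, s] * mats[:, s, dest]
        pkg_cost = float(np.sum(df_c * flux) * pkg.cost)
        pkg_qaly = float(np.sum(df_u * flux) * pkg.qaly)
        cost += pkg_cost
        qaly += pkg_qaly
        components[f"package_{pkg.label}_cost"] = pkg_cost
        components[f"package_{pkg.label}_qaly"] = pkg_qaly
    return cost, qaly, components


def _state_vectors(
    strategy: str, costing: StrategyCosting, config: ModelConfig, n_cycles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (n, 5) utility and cost arrays for one arm."""
    from .parameters import effective_state_utility

    utils = config.utilities
    u_on = effective_state_utility(
        utils.u_idfs_on, utils.profile_pairs(strategy)
    )
    u = np.tile(
        np.array([u_on, utils.u_idfs_off, utils.u_mpf, utils.u_mp, 0.0]),
        (n_cycles, 1),
    )
    c = np.tile(
        np.array(
            [
                costing.idfs_on_cost,
                costing.idfs_off_cost,
                costing.mpf_cost,
                costing.mp_cost,
                0.0,
            ]
        ),
        (n_cycles, 1),
    )
    # drug costs only accrue inside the treatment tunnel; afterwards any
    # residual IDFS_on occupancy (none, by construction) would cost nothing
    tc = config.settings.treatment_cycles
    c[tc:, IDFS_ON] = 0.0
    return u, c


def evaluate_strategy(
    strategy: str,
    config: ModelConfig,
    life_table: Optional[LifeTable] = None,
) -> StrategyOutcome:
    """Run one arm end to end: matrices -> trace -> discounted totals."""
    if life_table is None:
        life_table = life_table_from_config(config)
    seq = build_transition_sequence(strategy, config, life_table)
    trace = run_cohort(seq)
    costing = build_strategy_costing(strategy, config)
    u, c = _state_vectors(strategy, costing, config, trace.n_cycles)
    cost, qaly, components = accumulate_outcomes(
        trace, seq, u, c, costing.packages, config
    )
    return StrategyOutcome(
        strategy=strategy,
        cost=cost,
        qaly=qaly,
        life_years=trace.life_years(),
        trace=trace,
        cost_components=components,
    )


# ---------------------------------------------------------------------------
# incremental results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EconResult:
    """Incremental comparison of intervention vs comparator."""

    comparator: str
    intervention: str
    cost_comparator: float
    cost_intervention: float
    qaly_comparator: float
    qaly_intervention: float
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]          # $/QALY, unrounded; None if undefined
    icer_rounded: Optional[int]    # nearest dollar, for reporting
    verdict: str                   # ICER | dominant | dominated | undefined

    def to_dict(self) -> dict:
        return {
            "comparator": self.comparator,
            "intervention": self.intervention,
            "cost": {
                self.comparator: self.cost_comparator,
                self.intervention: self.cost_intervention,
            },
            "qaly": {
                self.comparator: self.qaly_comparator,
                self.intervention: self.qaly_intervention,
            },
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "icer_rounded": self.icer_rounded,
            "verdict": self.verdict,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_icer(
    comparator: tuple[float, float] | StrategyOutcome,
    intervention: tuple[float, float] | StrategyOutcome,
    labels: tuple[str, str] = ("comparator", "intervention"),
    qaly_tol: float = 1e-12,
) -> EconResult:
    """ICER (or a dominance verdict) from two (cost, QALY) evaluations.

    delta_cost < 0 with delta_qaly > 0 is 'dominant' (intervention cheaper
    and better); the mirror image is 'dominated'; delta_qaly = 0 yields an
    undefined-ICER signal rather than a division.
    """
    if isinstance(comparator, StrategyOutcome):
        labels = (comparator.strategy, labels[1])
        comparator = (comparator.cost, comparator.qaly)
    if isinstance(intervention, StrategyOutcome):
        labels = (labels[0], intervention.strategy)
        intervention = (intervention.cost, intervention.qaly)
    c0, q0 = comparator
    c1, q1 = intervention
    dc, dq = c1 - c0, q1 - q0
    icer = icer_rounded = None
    if abs(dq) <= qaly_tol:
        verdict = "undefined"
    elif dc < 0 and dq > 0:
        verdict = "dominant"
    elif dc > 0 and dq < 0:
        verdict = "dominated"
    else:
        verdict = "ICER"
        icer = dc / dq
        icer_rounded = int(round(icer))
    return EconResult(
        comparator=labels[0],
        intervention=labels[1],
        cost_comparator=c0,
        cost_intervention=c1,
        qaly_comparator=q0,
        qaly_intervention=q1,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        icer_rounded=icer_rounded,
        verdict=verdict,
    )


def run_base_case(
    config: ModelConfig, life_table: Optional[LifeTable] = None
) -> tuple[EconResult, StrategyOutcome, StrategyOutcome]:
    """Evaluate both arms under one configuration and compare them."""
    if life_table is None:
        life_table = life_table_from_config(config)
    comp = evaluate_strategy("trastuzumab", config, life_table)
    intv = evaluate_strategy("tdm1", config, life_table)
    return compute_icer(comp, intv), comp, intv
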