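"""Cohort engine: matrices, propagation, discounting, ICER, microsim oracle."""

import numpy as np
import pytest

from tdm1cea.engine import (
    DEATH,
    IDFS_OFF,
    IDFS_ON,
    MP,
    MPF,
    CohortTrace,
    TransitionMatrixSequence,
    accumulate_outcomes,
    build_transition_sequence,
    compute_icer,
    discount_factor,
    evaluate_strategy,
    microsimulate,
    run_cohort,
)
from tdm1cea.parameters import (
    ValidationError,
    annual_prob_to_cycle_prob,
    apply_hazard_ratio,
)
from tdm1cea.sensitivity import apply_overrides
from tdm1cea.synthetic import LifeTable


def identity_sequence(n, start_age=45.0, cycle_years=21.0 / 365.25):
    mats = np.tile(np.eye(5), (n, 1, 1))
    ages = start_age + np.arange(n) * cycle_years
    return TransitionMatrixSequence(matrices=mats, ages=ages)


class TestTransitionMatrices:
    def test_rows_stochastic_and_death_absorbing(self, config, life_table):
        for arm in ("trastuzumab", "tdm1"):
            seq = build_transition_sequence(arm, config, life_table)
            sums = seq.matrices.sum(axis=2)
            assert np.max(np.abs(sums - 1.0)) < 1e-12
            assert np.allclose(seq.matrices[:, DEATH], np.eye(5)[DEATH])

    def test_no_disease_no_mortality_gives_identity_outside_tunnel_exit(self):
        # a zero life table and (near-)zero disease probabilities leave the
        # cohort where it is, except the deterministic tunnel exit
        lt = LifeTable(np.arange(101), np.zeros(101))
        from tdm1cea import default_config
        from tdm1cea.sensitivity import apply_overrides

        cfg = apply_overrides(
            default_config(),
            {
                "transitions.baseline_annual.idfs_event": 1e-15,
                "transitions.baseline_annual.mpf_progression": 1e-15,
                "transitions.baseline_annual.mpf_death": 1e-15,
                "transitions.baseline_annual.mp_death": 1e-15,
            },
        )
        seq = build_transition_sequence("trastuzumab", cfg, lt)
        k_exit = cfg.settings.treatment_cycles - 1
        assert np.allclose(seq.matrices[0], np.eye(5), atol=1e-12)
        assert seq.matrices[k_exit][IDFS_ON, IDFS_OFF] == pytest.approx(1.0)

    def test_certain_mortality_sends_all_mass_to_death(self, config):
        lt = LifeTable(np.arange(101), np.ones(101))
        seq = build_transition_sequence("trastuzumab", config, lt)
        assert np.allclose(seq.matrices[:, :4, DEATH], 1.0)

    def test_tdm1_exit_probability_is_hazard_ratio_transform(
        self, config, life_table
    ):
        comp = build_transition_sequence("trastuzumab", config, life_table)
        intv = build_transition_sequence("tdm1", config, life_table)
        p_bg = comp.matrices[0, IDFS_OFF, DEATH]
        base_annual = config.transitions.baseline_annual.idfs_event
        hr = config.transitions.idfs_hr.point
        expected = annual_prob_to_cycle_prob(
            apply_hazard_ratio(base_annual, hr), config.settings.cycle_days
        )
        observed = intv.matrices[0, IDFS_ON, MPF] / (1.0 - p_bg)
        assert observed == pytest.approx(expected, rel=1e-12)

    def test_non_stochastic_matrix_refused(self):
        mats = np.tile(np.eye(5), (3, 1, 1))
        mats[1, 0, 0] = 0.5  # row no longer sums to 1
        with pytest.raises(ValidationError, match="sum"):
            TransitionMatrixSequence(matrices=mats, ages=np.arange(3.0))

    def test_unknown_strategy_rejected(self, config, life_table):
        with pytest.raises(ValidationError, match="strategy"):
            build_transition_sequence("pertuzumab", config, life_table)

    def test_life_table_gap_names_missing_age(self, config):
        lt = LifeTable(np.arange(60), np.zeros(60))  # stops at age 59
        with pytest.raises(ValidationError, match="age"):
            build_transition_sequence("trastuzumab", config, lt)


class TestCohortPropagation:
    def test_identity_sequence_constant_trace(self):
        trace = run_cohort(identity_sequence(10))
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_one_step_absorption(self):
        mats = np.zeros((1, 5, 5))
        mats[0, :, DEATH] = 1.0
        seq = TransitionMatrixSequence(matrices=mats, ages=np.array([45.0]))
        trace = run_cohort(seq)
        assert trace.occupancy[0, IDFS_ON] == 1.0
        assert trace.occupancy[1, DEATH] == 1.0

    def test_conservation_and_death_monotone(self, base_outcomes):
        for outcome in base_outcomes:
            occ = outcome.trace.occupancy
            assert np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-10
            assert np.all(np.diff(occ[:, DEATH]) >= -1e-10)

    def test_early_stop_when_cohort_extinct(self, config):
        lt = LifeTable(np.arange(101), np.full(101, 0.9999))
        seq = build_transition_sequence("trastuzumab", config, lt)
        trace = run_cohort(seq)
        assert trace.n_cycles < len(seq)
        assert trace.occupancy[-1, DEATH] > 1 - 1e-6

    def test_tdm1_idfs_occupancy_dominates_comparator(self, base_outcomes):
        comp, intv = base_outcomes
        n = min(len(comp.trace.occupancy), len(intv.trace.occupancy))
        idfs_comp = comp.trace.occupancy[:n, IDFS_ON] + comp.trace.occupancy[:n, IDFS_OFF]
        idfs_intv = intv.trace.occupancy[:n, IDFS_ON] + intv.trace.occupancy[:n, IDFS_OFF]
        assert np.all(idfs_intv >= idfs_comp - 1e-12)

    def test_trace_frame_round_trip(self, base_outcomes):
        df = base_outcomes[0].trace.to_frame()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert len(df) == base_outcomes[0].trace.n_cycles + 1


class TestMicrosimOracle:
    def test_trace_matches_patient_level_frequencies(self, config, life_table):
        """Short-horizon check that the deterministic trace equals
        patient-level simulation frequencies within Monte-Carlo error."""
        seq = build_transition_sequence("tdm1", config, life_table)
        n_pat, n_cyc = 30_000, 80
        trace = run_cohort(seq, n_cycles=n_cyc)
        freq = microsimulate(seq, n_pat, seed=7, n_cycles=n_cyc)
        p = trace.occupancy
        se = np.sqrt(p * (1 - p) / n_pat)
        z = np.abs(freq - p) / np.where(se > 0, se, 1.0)
        exact = se == 0
        assert np.all(freq[exact] == p[exact])
        assert np.max(z) < 5.0
        assert np.mean(z > 3.0) <= 0.005


class TestDiscounting:
    @pytest.mark.parametrize(
        "elapsed, rate, expected",
        [(5.0, 0.0, 1.0), (1.0, 0.07, 1.0 / 1.07), (2.0, 0.03, 1.03**-2)],
    )
    def test_examples(self, elapsed, rate, expected):
        assert discount_factor(elapsed, rate) == pytest.approx(expected, abs=1e-12)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-1.0, 0.03)

    def test_annuity_closed_form(self, config):
        """Constant utility 1, no death: discounted QALYs equal the
        geometric-series annuity formula to 1e-9."""
        n = 400
        seq = identity_sequence(n)
        trace = run_cohort(seq, n_cycles=n)
        u = np.zeros(5)
        u[IDFS_ON] = 1.0
        cost, qaly, _ = accumulate_outcomes(
            trace, seq, u, np.zeros(5), (), config
        )
        dt = config.settings.cycle_years
        v = (1.0 + config.settings.discount_utility) ** (-dt)
        expected = dt * (1.0 - v**n) / (1.0 - v)
        assert qaly == pytest.approx(expected, abs=1e-9)
        assert cost == 0.0

    def test_zero_rate_qalys_equal_life_years(self, config, life_table):
        cfg = apply_overrides(
            config,
            {"settings.discount_cost": 0.0, "settings.discount_utility": 0.0},
        )
        seq = build_transition_sequence("trastuzumab", cfg, life_table)
        trace = run_cohort(seq)
        u = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
        _, qaly, _ = accumulate_outcomes(trace, seq, u, np.zeros(5), (), cfg)
        assert qaly == pytest.approx(trace.life_years(), abs=1e-9)


class TestOutcomeMonotonicity:
    def test_raising_state_utility_never_decreases_qalys(self, config, life_table):
        base = evaluate_strategy("trastuzumab", config, life_table)
        bumped = evaluate_strategy(
            "trastuzumab",
            apply_overrides(config, {"utilities.u_mpf": 0.80}),
            life_table,
        )
        assert bumped.qaly >= base.qaly

    def test_raising_cost_never_decreases_total_cost(self, config, life_table):
        base = evaluate_strategy("tdm1", config, life_table)
        bumped = evaluate_strategy(
            "tdm1",
            apply_overrides(config, {"costs.tdm1.vial_usd": 250.0}),
            life_table,
        )
        assert bumped.cost >= base.cost


class TestIcer:
    def test_printed_base_case_arithmetic(self):
        res = compute_icer((9968.0, 3.99), (11376.0, 5.58))
        assert res.delta_cost == pytest.approx(1408.0)
        assert res.delta_qaly == pytest.approx(1.59)
        assert res.icer_rounded == 886
        assert res.verdict == "ICER"

    def test_identical_strategies_undefined(self):
        res = compute_icer((100.0, 2.0), (100.0, 2.0))
        assert res.verdict == "undefined"
        assert res.icer is None

    def test_cheaper_and_better_dominant(self):
        assert compute_icer((100.0, 2.0), (90.0, 2.5)).verdict == "dominant"

    def test_dearer_and_worse_dominated(self):
        assert compute_icer((100.0, 2.0), (150.0, 1.5)).verdict == "dominated"
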