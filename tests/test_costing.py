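"""Vial pricing, blends, state and transition cost packages."""

import itertools
import math

import numpy as np
import pytest

from tdm1cea.costing import (
    blended_price,
    build_strategy_costing,
    docetaxel_cycle_component,
    eol_package_cost,
    mp_cycle_cost,
    mpf_cycle_cost,
    optimal_vial_combination,
    tariff_blend,
    treatment_cycle_cost,
)
from tdm1cea.parameters import ValidationError, VialOption
from tdm1cea.sensitivity import apply_overrides


def brute_force_vial_cost(dose, menu):
    """Independent oracle: enumerate every count vector up to
    ceil(dose/min_content) per vial and take the cheapest covering one."""
    cap = math.ceil(dose / min(v.mg for v in menu))
    best = math.inf
    for counts in itertools.product(range(cap + 1), repeat=len(menu)):
        if sum(n * v.mg for n, v in zip(counts, menu)) >= dose:
            best = min(best, sum(n * v.usd for n, v in zip(counts, menu)))
    return best


class TestBlends:
    @pytest.mark.parametrize(
        "generic, brand, share, expected",
        [(100, 200, 1.0, 100), (100, 200, 0.0, 200), (100, 200, 0.95, 105)],
    )
    def test_market_share_blend(self, generic, brand, share, expected):
        assert blended_price(generic, brand, share) == pytest.approx(expected)

    def test_negative_price_rejected(self):
        with pytest.raises(ValidationError):
            blended_price(-1, 100, 0.5)

    @pytest.mark.parametrize(
        "gov, priv, expected", [(100, 100, 100), (0, 0, 0), (100, 200, 120)]
    )
    def test_tariff_blend(self, gov, priv, expected):
        assert tariff_blend(gov, priv) == pytest.approx(expected)


class TestVialOptimizer:
    TRAST_MENU = (VialOption(mg=150, usd=71), VialOption(mg=440, usd=182))
    DOC_MENU = (VialOption(mg=20, usd=8), VialOption(mg=80, usd=31))

    def test_zero_dose_costs_nothing(self):
        counts, cost = optimal_vial_combination(0.0, self.TRAST_MENU)
        assert counts == {} and cost == 0.0

    def test_trastuzumab_full_dose_prefers_large_vial(self):
        # 390 mg: one 440 mg vial (182$) beats 3 x 150 mg (213$)
        counts, cost = optimal_vial_combination(390, self.TRAST_MENU)
        assert counts == {440: 1} and cost == 182

    def test_docetaxel_dose_mixes_vials(self):
        # 127.5 mg: 1x80 + 3x20 (55$) beats 2x80 (62$) and 7x20 (56$)
        counts, cost = optimal_vial_combination(127.5, self.DOC_MENU)
        assert counts == {80: 1, 20: 3} and cost == 55

    def test_empty_menu_rejected(self):
        with pytest.raises(ValidationError, match="menu"):
            optimal_vial_combination(100, [])

    def test_vial_sharing_pro_rata(self):
        _, cost = optimal_vial_combination(220, self.TRAST_MENU, allow_sharing=True)
        # cheapest per-mg vial is 440 mg at 182$
        assert cost == pytest.approx(220 * 182 / 440)

    def test_matches_exhaustive_enumeration_on_random_menus(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_vials = rng.integers(1, 4)
            menu = tuple(
                VialOption(
                    mg=float(rng.integers(1, 40) * 10),
                    usd=float(rng.integers(1, 300)),
                )
                for _ in range(n_vials)
            )
            dose = float(rng.uniform(1, 600))
            _, cost = optimal_vial_combination(dose, menu)
            assert cost == pytest.approx(brute_force_vial_cost(dose, menu))


class TestStateCosts:
    def test_trastuzumab_cycle_cost(self, config):
        # 6 mg/kg x 65 kg = 390 mg -> 182$ vial + 4.5$ admin + 13$ monitoring
        cost = treatment_cycle_cost(
            "trastuzumab", 0, config.settings, config.costs
        )
        assert cost == pytest.approx(199.5)

    def test_tdm1_cycle_cost_parametric_in_vial_count(self, config):
        cost = treatment_cycle_cost("tdm1", 0, config.settings, config.costs)
        v = config.costs.tdm1.vials_per_administration
        assert cost == pytest.approx(v * 180 + 4.5 + 13)

    def test_zero_priced_vials_leave_fees_only(self, config):
        cfg = apply_overrides(
            config,
            {
                "costs.trastuzumab.vials.0.usd": 0.0,
                "costs.trastuzumab.vials.1.usd": 0.0,
            },
        )
        cost = treatment_cycle_cost("trastuzumab", 0, cfg.settings, cfg.costs)
        assert cost == pytest.approx(4.5 + 13)

    def test_unknown_strategy_rejected(self, config):
        with pytest.raises(ValidationError):
            treatment_cycle_cost("nivolumab", 0, config.settings, config.costs)

    def test_cycle_outside_tunnel_rejected(self, config):
        with pytest.raises(ValidationError, match="tunnel"):
            treatment_cycle_cost(
                "tdm1", config.settings.treatment_cycles, config.settings, config.costs
            )

    def test_docetaxel_component_at_default_bsa(self, config):
        # 75 mg/m2 x 1.7 m2 = 127.5 mg -> 55$ vials + 6$ monitoring
        assert docetaxel_cycle_component(
            config.settings, config.costs
        ) == pytest.approx(55 + 6)

    def test_mpf_cost_without_docetaxel_is_trastuzumab_only(self, config):
        cost = mpf_cycle_cost(config.settings, config.costs, with_docetaxel=False)
        assert cost == pytest.approx(182 + 4.5 + 13)

    def test_mp_cost_scaling(self):
        assert mp_cycle_cost(0, 1 / 3) == 0
        assert mp_cycle_cost(300, 1 / 3) == pytest.approx(100)
        assert mp_cycle_cost(123.4, 1.0) == pytest.approx(123.4)

    def test_eol_package(self):
        assert eol_package_cost(0, 4.15, 6, 21) == 0
        assert eol_package_cost(100, 1.0, 6, 21) == 0
        # (4.15 - 1) x 100$ x (6 x 30.4375 / 21 = 8.696...) cycles
        assert eol_package_cost(100, 4.15, 6, 21) == pytest.approx(
            3.15 * 100 * 6 * 30.4375 / 21
        )


class TestCostStructure:
    def test_non_drug_costs_identical_across_arms(self, config):
        # administration and monitoring fees are strategy-independent
        t = treatment_cycle_cost("trastuzumab", 0, config.settings, config.costs)
        k = treatment_cycle_cost("tdm1", 0, config.settings, config.costs)
        assert t - 182 == pytest.approx(k - 2 * 180)

    def test_costs_homogeneous_degree_one_in_prices(self, config):
        """Doubling every price doubles both arms' total discounted cost."""
        from tdm1cea.engine import evaluate_strategy
        from tdm1cea.synthetic import life_table_from_config

        lt = life_table_from_config(config)
        price_paths = {
            "costs.trastuzumab.vials.0.usd": 2 * 71.0,
            "costs.trastuzumab.vials.1.usd": 2 * 182.0,
            "costs.tdm1.vial_usd": 2 * 180.0,
            "costs.docetaxel.vials.0.usd": 2 * 8.0,
            "costs.docetaxel.vials.1.usd": 2 * 31.0,
            "costs.trastuzumab.monitoring_usd": 2 * 13.0,
            "costs.tdm1.monitoring_usd": 2 * 13.0,
            "costs.docetaxel.monitoring_usd": 2 * 6.0,
            "costs.admin_fee_usd": 2 * 4.5,
            "costs.mp_reference_cost_usd_per_cycle": 2 * 450.0,
            "costs.neutropenic_fever_cost_usd": 2 * 500.0,
        }
        doubled = apply_overrides(config, price_paths)
        for arm in ("trastuzumab", "tdm1"):
            base = evaluate_strategy(arm, config, lt)
            twice = evaluate_strategy(arm, doubled, lt)
            assert twice.cost == pytest.approx(2 * base.cost, rel=1e-12)
            assert twice.qaly == pytest.approx(base.qaly, rel=1e-12)

    def test_strategy_costing_packages_present(self, config):
        costing = build_strategy_costing("tdm1", config)
        labels = {p.label for p in costing.packages}
        assert labels == {"docetaxel_phase", "end_of_life"}
        eol = next(p for p in costing.packages if p.label == "end_of_life")
        assert eol.cost > 0 and eol.qaly < 0
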