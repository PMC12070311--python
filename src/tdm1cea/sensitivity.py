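"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA re-evaluates the incremental result at the low and high end of
each parameter's range (±20% for costs, 95% CI bounds for clinical effects,
enumerated alternatives for discount rates).  PSA fits each uncertain
parameter's sampling distribution by method of moments, draws all
parameters independently per iteration with one master seed and per-draw
substreams, re-runs both strategy arms on the shared draw, and summarises
the cost-effectiveness plane (quadrant fractions, below-threshold fraction,
acceptability curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import compute_icer, evaluate_strategy
from .parameters import (
    FittedDistribution,
    ModelConfig,
    ParamSpec,
    ValidationError,
    fit_distribution,
    validate_parameters,
)
from .synthetic import LifeTable, life_table_from_config


# ---------------------------------------------------------------------------
# dotted-path overrides on the configuration tree
# ---------------------------------------------------------------------------

def _set_path(tree: dict, path: str, value) -> None:
    """Set a dotted path (list indices as integers) in a dumped config.

    Writing an effect parameter's ``point`` clears its CI bounds: a sampled
    or range value need not be bracketed by the published interval.
    """
    parts = path.split(".")
    node = tree
    for part in parts[:-1]:
        node = node[int(part)] if isinstance(node, list) else node[part]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value
        if last == "point" and "ci_low" in node:
            node["ci_low"] = None
            node["ci_high"] = None


def apply_overrides(config: ModelConfig, overrides: dict[str, float]) -> ModelConfig:
    """Return a validated copy of ``config`` with dotted-path overrides set."""
    # json mode turns tuples into plain lists so paths can index-assign
    tree = config.model_dump(mode="json")
    for path, value in overrides.items():
        _set_path(tree, path, float(value))
    return validate_parameters(tree)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DsaRange:
    """Low/high values for one parameter path."""

    parameter: str
    low: float
    high: float


def default_dsa_ranges(config: ModelConfig) -> list[DsaRange]:
    """The standard one-way set: ±20% on costs, CI bounds on effects,
    enumerated discount-rate alternatives."""
    c = config.costs
    t = config.transitions
    ranges = [
        DsaRange("costs.tdm1.vial_usd", 0.8 * c.tdm1.vial_usd, 1.2 * c.tdm1.vial_usd),
        DsaRange(
            "costs.trastuzumab.vials.1.usd",
            0.8 * c.trastuzumab.vials[1].usd,
            1.2 * c.trastuzumab.vials[1].usd,
        ),
        DsaRange(
            "costs.mp_reference_cost_usd_per_cycle",
            0.8 * c.mp_reference_cost_usd_per_cycle,
            1.2 * c.mp_reference_cost_usd_per_cycle,
        ),
        DsaRange("costs.admin_fee_usd", 0.8 * c.admin_fee_usd, 1.2 * c.admin_fee_usd),
        DsaRange(
            "costs.trastuzumab.monitoring_usd",
            0.8 * c.trastuzumab.monitoring_usd,
            1.2 * c.trastuzumab.monitoring_usd,
        ),
        DsaRange("settings.discount_utility", config.settings.discount_utility, 0.06),
        DsaRange("settings.discount_cost", 0.0, 0.10),
        DsaRange("transitions.idfs_hr.point", t.idfs_hr.ci_low, t.idfs_hr.ci_high),
        DsaRange("transitions.os_mpf.point", t.os_mpf.ci_low, t.os_mpf.ci_high),
        DsaRange("transitions.pfs_mpf.point", t.pfs_mpf.ci_low, t.pfs_mpf.ci_high),
        DsaRange("transitions.drfs.point", t.drfs.ci_low, t.drfs.ci_high),
    ]
    return ranges


def one_way_dsa(
    config: ModelConfig,
    ranges: Sequence[DsaRange],
    life_table: Optional[LifeTable] = None,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high value.

    Sorted by |ICER_high - ICER_low| descending; an end whose incremental
    QALYs vanish is flagged undefined (NaN ICER), not dropped.
    """
    if life_table is None:
        life_table = life_table_from_config(config)

    def icer_at(overrides: dict[str, float]) -> tuple[Optional[float], str]:
        cfg = apply_overrides(config, overrides)
        res = compute_icer(
            evaluate_strategy("trastuzumab", cfg, life_table),
            evaluate_strategy("tdm1", cfg, life_table),
        )
        return res.icer, res.verdict

    base_icer, base_verdict = icer_at({})
    rows = []
    for r in ranges:
        icer_lo, v_lo = icer_at({r.parameter: r.low})
        icer_hi, v_hi = icer_at({r.parameter: r.high})
        spread = (
            abs(icer_hi - icer_lo)
            if icer_lo is not None and icer_hi is not None
            else np.nan
        )
        rows.append(
            {
                "parameter": r.parameter,
                "low_value": r.low,
                "high_value": r.high,
                "icer_low": np.nan if icer_lo is None else icer_lo,
                "icer_high": np.nan if icer_hi is None else icer_hi,
                "verdict_low": v_lo,
                "verdict_high": v_hi,
                "icer_base": np.nan if base_icer is None else base_icer,
                "spread": spread,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "parameter", "low_value", "high_value", "icer_low", "icer_high",
            "verdict_low", "verdict_high", "icer_base", "spread",
        ],
    )
    if len(table):
        table = table.sort_values(
            "spread", ascending=False, kind="mergesort", na_position="last"
        ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def build_psa_distributions(
    config: ModelConfig,
    cv: Optional[float] = None,
    include_doses: bool = False,
    collapse: bool = False,
) -> dict[str, FittedDistribution]:
    """Fit a sampling distribution for every uncertain parameter.

    Families follow the parameter class: beta for probabilities, utilities
    and adverse-event quantities (disutilities on their magnitude), gamma
    for costs, normal for doses (off by default).  Parameters without a
    published CI use a coefficient of variation (``cv``, default from
    config).  ``collapse=True`` degenerates every distribution to its point
    estimate (the PSA then reproduces the deterministic base case).
    """
    if cv is None:
        cv = config.costs.uncertainty_cv
    t, u, c = config.transitions, config.utilities, config.costs
    specs: dict[str, ParamSpec] = {}

    for name, par in t.effect_params().items():
        specs[f"transitions.{name}.point"] = par
    for trans in ("idfs_event", "mpf_progression", "mpf_death", "mp_death"):
        specs[f"transitions.baseline_annual.{trans}"] = ParamSpec(
            point=getattr(t.baseline_annual, trans), family="beta"
        )
    for uname in ("u_idfs_on", "u_idfs_off", "u_mpf", "u_mp", "u_eol"):
        specs[f"utilities.{uname}"] = ParamSpec(
            point=getattr(u, uname), family="beta"
        )
    for profile, events in u.ae_profiles.items():
        for i, ae in enumerate(events):
            base = f"utilities.ae_profiles.{profile}.{i}"
            if ae.incidence > 0:
                specs[f"{base}.incidence"] = ParamSpec(
                    point=ae.incidence, family="beta"
                )
            if ae.disutility < 0:
                specs[f"{base}.disutility"] = ParamSpec(
                    point=ae.disutility, family="beta"
                )
    for i, vial in enumerate(c.trastuzumab.vials):
        specs[f"costs.trastuzumab.vials.{i}.usd"] = ParamSpec(
            point=vial.usd, family="gamma"
        )
    for i, vial in enumerate(c.docetaxel.vials):
        specs[f"costs.docetaxel.vials.{i}.usd"] = ParamSpec(
            point=vial.usd, family="gamma"
        )
    specs["costs.tdm1.vial_usd"] = ParamSpec(point=c.tdm1.vial_usd, family="gamma")
    specs["costs.trastuzumab.monitoring_usd"] = ParamSpec(
        point=c.trastuzumab.monitoring_usd, family="gamma"
    )
    specs["costs.docetaxel.monitoring_usd"] = ParamSpec(
        point=c.docetaxel.monitoring_usd, family="gamma"
    )
    specs["costs.admin_fee_usd"] = ParamSpec(point=c.admin_fee_usd, family="gamma")
    specs["costs.mp_reference_cost_usd_per_cycle"] = ParamSpec(
        point=c.mp_reference_cost_usd_per_cycle, family="gamma"
    )
    specs["costs.neutropenic_fever_cost_usd"] = ParamSpec(
        point=c.neutropenic_fever_cost_usd, family="gamma"
    )
    if include_doses:
        specs["costs.trastuzumab.dose_mg_per_kg"] = ParamSpec(
            point=c.trastuzumab.dose_mg_per_kg, family="normal"
        )
        specs["costs.tdm1.dose_mg_per_kg"] = ParamSpec(
            point=c.tdm1.dose_mg_per_kg, family="normal"
        )
        specs["costs.docetaxel.dose_mg_per_m2"] = ParamSpec(
            point=c.docetaxel.dose_mg_per_m2, family="normal"
        )

    fitted: dict[str, FittedDistribution] = {}
    for path, spec in specs.items():
        fitted[path] = fit_distribution(
            spec, default_cv=0.0 if collapse else cv, name=path
        )
        if collapse and fitted[path].sd != 0.0:
            point = spec.point
            fitted[path] = FittedDistribution(
                fitted[path].family, point, 0.0, (point,), sign=1.0
            )
    return fitted


def sample_psa_draw(
    fitted: dict[str, FittedDistribution], rng: np.random.Generator
) -> dict[str, float]:
    """One independent draw per parameter, with domain clipping.

    Probabilities, utilities and incidences stay in [0, 1]; disutilities
    stay <= 0; costs and ratios stay positive.
    """
    draw: dict[str, float] = {}
    for path, dist in fitted.items():
        x = float(dist.sample(rng))
        if dist.sign < 0 or path.endswith(".disutility"):
            x = min(x, 0.0)
        elif "baseline_annual" in path:
            # baseline probabilities are required to be strictly inside (0, 1)
            x = float(np.clip(x, 1e-9, 1.0 - 1e-9))
        elif "utilities" in path or path.endswith(".incidence"):
            x = float(np.clip(x, 0.0, 1.0))
        else:
            x = max(x, 1e-12)
        draw[path] = x
    return draw


@dataclass(frozen=True)
class PsaResult:
    samples: pd.DataFrame = field(repr=False)
    summary: dict
    seed: int
    wtp: float

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def _quadrant(dc: float, dq: float) -> str:
    if dq > 0:
        return "NE" if dc > 0 else "SE"
    return "NW" if dc > 0 else "SW"


def run_psa(
    config: ModelConfig,
    n_iter: int,
    seed: int,
    wtp: Optional[float] = None,
    life_table: Optional[LifeTable] = None,
    fitted: Optional[dict[str, FittedDistribution]] = None,
) -> PsaResult:
    """Monte-Carlo PSA: shared parameter draws, both arms per iteration.

    The summary reports cost-effectiveness-plane quadrant fractions and two
    below-threshold tallies at the willingness-to-pay ``wtp``:

    * ``below_threshold`` — net-monetary-benefit rule, fraction of draws
      with ``wtp * delta_qaly - delta_cost >= 0`` (the CEAC definition);
    * ``below_threshold_gaining`` — draws that also gain QALYs
      (ICER <= wtp in the NE quadrant, plus dominant SE draws).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if wtp is None:
        wtp = config.settings.wtp_threshold
    if life_table is None:
        life_table = life_table_from_config(config)
    if fitted is None:
        fitted = build_psa_distributions(config)

    children = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        draw = sample_psa_draw(fitted, rng)
        cfg = apply_overrides(config, draw)
        comp = evaluate_strategy("trastuzumab", cfg, life_table)
        intv = evaluate_strategy("tdm1", cfg, life_table)
        dc, dq = intv.cost - comp.cost, intv.qaly - comp.qaly
        rows.append(
            {
                "draw": i,
                "cost_trastuzumab": comp.cost,
                "cost_tdm1": intv.cost,
                "qaly_trastuzumab": comp.qaly,
                "qaly_tdm1": intv.qaly,
                "delta_cost": dc,
                "delta_qaly": dq,
                "quadrant": _quadrant(dc, dq),
                "nmb": wtp * dq - dc,
                "below_threshold": wtp * dq - dc >= 0,
            }
        )
    samples = pd.DataFrame(rows)
    quad = samples["quadrant"].value_counts(normalize=True)
    gaining = (samples["delta_qaly"] > 0) & (
        samples["delta_cost"] <= wtp * samples["delta_qaly"]
    )
    summary = {
        "n_iter": n_iter,
        "seed": seed,
        "wtp": wtp,
        "quadrant_fractions": {
            q: float(quad.get(q, 0.0)) for q in ("NE", "SE", "NW", "SW")
        },
        "below_threshold": float(samples["below_threshold"].mean()),
        "below_threshold_gaining": float(gaining.mean()),
        "undefined_icer": int((samples["delta_qaly"] == 0).sum()),
        "mean_delta_cost": float(samples["delta_cost"].mean()),
        "mean_delta_qaly": float(samples["delta_qaly"].mean()),
    }
    dq_mean = summary["mean_delta_qaly"]
    summary["icer_of_means"] = (
        summary["mean_delta_cost"] / dq_mean if dq_mean != 0 else None
    )
    return PsaResult(samples=samples, summary=summary, seed=seed, wtp=wtp)


def ceac(
    samples: pd.DataFrame, wtp_grid: Iterable[float]
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value, the probability cost-effective is the
    fraction of draws with non-negative net monetary benefit.
    """
    if len(samples) == 0:
        raise ValidationError("CEAC needs at least one PSA sample")
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    rows = [
        {"wtp": float(lam), "prob_cost_effective": float(np.mean(lam * dq - dc >= 0))}
        for lam in wtp_grid
    ]
    return pd.DataFrame(rows, columns=["wtp", "prob_cost_effective"])
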