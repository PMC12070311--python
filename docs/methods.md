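# Methods

This note documents the model implemented in `tdm1cea`: its structure and
assumptions, the parameters that matter and their defaults, what the
synthetic input generators do and do not emulate, the numerical choices,
and the known limitations.

## Cohort model

**States and permitted transitions.** Five states: `IDFS_on` (on-treatment
invasive disease-free, a tunnel of `treatment_cycles` = 14 cycles),
`IDFS_off`, `MPF` (metastatic progression-free), `MP` (metastatic
progression), `Death`. Permitted moves are IDFS → {IDFS, MPF, Death},
MPF → {MPF, MP, Death}, MP → {MP, Death}; Death is absorbing. The tunnel
exit IDFS_on → IDFS_off is deterministic at the end of cycle 14 and needs
no extra tunnel bookkeeping because the whole cohort enters IDFS_on at
cycle 0 and no path re-enters it.

**Time grid.** Cycle length 21 days (one treatment administration
interval); horizon from age 45 to age 100 (957 cycles), with an early stop
once Death occupancy exceeds 1 − 10⁻⁶.

**Mortality composition.** Background all-cause mortality `q(age)` (from
the life table, floored integer age, converted to cycle scale) is applied
first in every living state; disease events act on the residual `1 − p_bg`
mass, which keeps rows stochastic by construction. Within MPF, excess
death and progression compete: death is applied first and progression
among cycle survivors, i.e. `P(death) = p_bg + (1−p_bg)q_d` and
`P(progress) = (1−p_bg)(1−q_d)q_p`. This matches independent event times
with death taking precedence when both fall in one cycle; the ordering
matters only at O(q_d·q_p) per cycle (~10⁻⁵ here).

**Scale conversions.** Annual probability to cycle:
`p_c = 1 − (1−p_a)^(21/365.25)` (constant hazard within the year). Hazard
ratios: `p' = 1 − (1−p)^HR`. Under the exponential within-interval hazard
these are the probability-scale and rate-scale transforms at once — the
two named methods (`hr_transform` setting) are algebraically the same map,
which is why one code path serves both.

**Effect wiring.** The published effect parameters are ambiguous about
scale (a "probabilities (annual)" table block whose first row is labelled
a hazard ratio and whose OS row has a CI crossing 1). Each parameter
therefore carries an interpretation flag (`hazard_ratio` or
`annual_probability`), a target transition and the arms it applies to,
all configuration-driven. Defaults: the IDFS hazard ratio 0.5 (0.39–0.64)
multiplies the comparator's annual metastasis probability for the T-DM1
arm only; the OS 0.74 and PFS 0.69 ratios multiply the baseline MPF death
and progression probabilities in both arms (the metastatic regimen is
arm-independent); the distant-recurrence ratio 0.6 is an alternative arm
effect selectable via `idfs_effect_param` and inert by default, since the
model has a single IDFS→MPF arrow.

**Discounting and accumulation.** Discount factors `(1+r)^(−t_k)` with
`t_k = k·21/365.25` years, r = 7% for costs and 3% for utilities. Per-cycle
accrual uses the half-cycle correction (mean of adjacent occupancy rows);
it is toggleable (`half_cycle_correction`) for sensitivity work. QALYs
weight occupancy by state utility times the cycle length in years; costs
use $/cycle state costs plus transition-triggered packages (below)
discounted at the flux cycle.

## Costing rules

* **Vial costs with wastage.** Doses are weight-based (65 kg; 6 mg/kg
  trastuzumab → 390 mg) or BSA-based (1.7 m²; 75 mg/m² docetaxel →
  127.5 mg). The optimizer enumerates integer vial combinations covering
  the dose and takes the cheapest (exact for the ≤3-vial menus used);
  `allow_vial_sharing` switches to pro-rata pricing. The T-DM1 price is
  published per vial without mg content, so vials per administration is a
  config integer (default 2, consistent with covering 234 mg from the
  commercial 100+160 mg sizes); it is exposed to sensitivity analysis.
* **Fees.** Administration 4.5 $/session and monitoring 13 $ (trastuzumab
  / T-DM1) or 6 $ (docetaxel) per cycle. The 80/20 government/private
  tariff blend applies to service fees via `tariff_blend`; vial prices are
  treated as final (already blended), and the 95/5 generic/brand share is
  available through `blended_price` for configurations that price the two
  versions separately.
* **Docetaxel phase as an entry package.** A cohort trace cannot condition
  on time-in-state, so the first-6-cycles docetaxel component (drug +
  monitoring), the neutropenic-fever management cost (incidence 6.5% ×
  configured 500 $) and the metastatic regimen's adverse-event disutility
  are charged once on the IDFS→MPF flux. Mean MPF dwell (~1.5 y ≈ 26
  cycles) well exceeds the 6-cycle phase, and MPF entry hazard is flat, so
  the approximation error is the discounting within ~4 months of entry.
* **Metastatic state.** MP costs `mp_reference_cost × 1/3` per cycle (the
  one-third scaling mirrors the ratio observed between locally computed
  early-state costs and the reference metastatic costing study; the
  reference value itself is a configured stand-in, default 450 $/cycle →
  150 $/cycle).
* **End of life.** Care in the last six months costs 4.15× the MP level
  and is lived at utility 0.250. Modelled as a package on the MP→Death
  flux: incremental cost `(4.15−1) × mp_cost × (6×30.4375/21 ≈ 8.70
  cycles)` and QALY adjustment `(0.250 − 0.443) × Δt × 8.70`, charged at
  the death cycle. This charges retrospectively at death rather than
  prospectively over the true final six months — the standard cohort-model
  approximation, logged as such.
* **Dose-reduction modifiers** scale expected drug cost per strategy;
  default 1.0 (no published reduction fractions), exposed in config and
  DSA.

**Utilities.** On-treatment IDFS utility is the base 0.814 plus
Σ incidence × disutility over the strategy's grade ≥III adverse-event
profile (T-DM1: 0.8025; trastuzumab: 0.8129 effective). Events without a
published disutility carry 0. The comparator's peripheral-sensory-
neuropathy incidence is not legible in the source table and is set to 0.

## Sensitivity analysis

**DSA.** Default ranges: ±20% on cost parameters, 95% CI bounds on effect
parameters, utility discount {3%, 6%} and cost discount {0%, 10%} (the
intermediate printed rates are reachable by editing the range). Each range
end re-evaluates both arms; ends where T-DM1 becomes dominant are reported
with an undefined ICER and a verdict label rather than dropped.

**PSA.** Distributions by parameter class — beta for probabilities,
utilities, incidences (and disutility magnitudes, sign restored on
sampling), gamma for costs and fees, normal for doses (excluded by
default; doses are never varied in the reported analyses). Method-of-
moments fits treat the 95% CI as symmetric normal (`sd = width/3.92`);
parameters printed without a CI get a 10% coefficient of variation
(`uncertainty_cv`, configurable). A beta request whose CI upper bound
exceeds 1 (the OS-MPF row, 0.74, 0.49–1.120) cannot be a probability and
is refitted on the lognormal with a logged warning. Draws are independent
across parameters (no correlation information is published; noted as a
limitation), shared between arms within a draw, clipped to their domains,
and generated from per-draw substreams of one master `SeedSequence`, so
any prefix of a run is reproducible independently of `n_iter`.
"Cost-effective at λ" is reported two ways: the net-monetary-benefit rule
`λ·ΔQALY − ΔCost ≥ 0` (identical to the CEAC definition, the primary
tally) and the stricter QALY-gaining tally (ICER ≤ λ with ΔQALY > 0, plus
dominant draws).

## Budget impact

Eligible population = round(12,684 × 0.95 × 0.243 × residual share), with
residual share 0.50 (range 0.40–0.60) → 1,464 patients, grown at 3%/year
(1,508, 1,553). Uptake 5%/10%/15% over years 1–3. The per-patient figure
is the first-year undiscounted cost difference from the cohort engine
(budget convention: no discounting, costs in the year incurred); patients
not switched stay on trastuzumab, whose cost cancels in the difference.
Yearly incremental and cumulative totals are both reported; each year is
treated as an incident cohort (prior-year patients' later-year costs are
not carried, flagged as a simplification).

## Synthetic input generators

Three inputs of the original analysis are not published and are replaced
by generators with known ground truth:

* **Life table** — Gompertz–Makeham, `q(age) = 1 − exp(−(a + b·e^{c·age}))`
  with a = 5×10⁻⁵, b = 2.3×10⁻⁵, c = 0.099, giving q(45) ≈ 2×10⁻³ and
  q(85) ≈ 0.1 — the shape of an adult female life table, explicitly
  non-authoritative. A CSV loader (`age,qx`) accepts a real table.
* **Survival datasets** — exponential event times at rate
  `−ln(1−p_annual)/365.25` per day with optional independent exponential
  censoring; the Kaplan–Meier one-year estimate (via lifelines) recovers
  the generating probability, which is the property the tests check at
  n = 50,000.
* **Baseline annual event probabilities** (comparator arm / metastatic
  course), chosen once as clinically plausible for this population and
  regimen: IDFS→MPF 0.08 (≈ the recurrence tempo of trastuzumab-treated
  residual disease), MPF→MP 0.45 and MPF death 0.10 (first-line metastatic
  HER2+ therapy), MP death 0.35 (post-progression survival of roughly
  2–3 years). The MP reference cost (450 $/cycle) and neutropenic-fever
  cost (500 $) are stand-ins on the same footing.

Because these stand-ins determine absolute totals, passing tests show that
the machinery is correct (arithmetic, conservation, convergence, recovery,
reproducibility, direction of effect) — not that the absolute cost and
QALY totals match any particular published figure, which would require the
unpublished inputs. The synthetic data also omit features of real data:
non-exponential hazards within a year, covariate-dependent mortality,
correlated parameters, and real tariff structure.

## Numerical choices

* Row-stochasticity enforced at 10⁻¹² on matrices and 10⁻¹⁰ on trace rows.
* Effective utilities are floored at 0 with a logged warning (not fatal).
* ICERs are reported unrounded and rounded to the nearest dollar;
  ΔQALY within 10⁻¹² of 0 yields an undefined-ICER signal, never a
  division.
* The microsimulation validator compares every state-by-cycle cell at the
  binomial 3-SE level with the standard multiplicity allowance for ~4,800
  correlated comparisons: zero-probability cells must match exactly, no
  cell may deviate beyond 5 SE, and at most 0.5% of cells may fall between
  3 and 5 SE (the chance-expected 3σ exceedances; a systematic error of
  fixed size ε produces z ≈ ε√n ≫ 5 at n = 10⁵, so power is unaffected).
* Validation problem sizes: 10⁵ patients for the microsimulation check,
  10⁴ PSA draws, 10⁵ draws per distribution-recovery check, 5×10⁴
  subjects per Kaplan–Meier recovery, 10³ random menus for the vial
  optimizer.

## Limitations

* Absolute cost/QALY levels inherit the synthetic stand-ins; only
  relative structure and machinery are validated.
* The end-of-life and docetaxel-phase packages are flux-triggered
  approximations to time-in-state conditioning.
* Parameters are sampled independently in PSA.
* Exponential hazards within each year; no patient-level heterogeneity
  outside the validation microsimulation.
* Each budget-impact year is an incident cohort; continuing costs of
  earlier cohorts are not accumulated.
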