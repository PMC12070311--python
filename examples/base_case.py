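"""Base-case cost-utility analysis: both treatment arms through the Markov
cohort engine, lifetime horizon, discounted at 7% (costs) / 3% (utilities).

The printed ICER is the extra cost per quality-adjusted life year gained by
adjuvant T-DM1 over trastuzumab; it is compared with the willingness-to-pay
threshold carried in the configuration (1,085 $/QALY).
"""

from tdm1cea import default_config, run_base_case

config = default_config()
result, comp, intv = run_base_case(config)

for outcome in (comp, intv):
    print(
        f"{outcome.strategy:>12}: cost {outcome.cost:9.2f} $, "
        f"QALYs {outcome.qaly:6.3f}, life-years {outcome.life_years:6.2f}"
    )
print(f"incremental cost  : {result.delta_cost:9.2f} $")
print(f"incremental QALYs : {result.delta_qaly:9.3f}")
print(f"ICER              : {result.icer_rounded} $/QALY ({result.verdict})")
wtp = config.settings.wtp_threshold
print(
    f"at a threshold of {wtp:.0f} $/QALY the intervention is "
    f"{'cost-effective' if result.icer is not None and result.icer <= wtp else 'not cost-effective'}"
)
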