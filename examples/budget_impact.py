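"""Three-year budget-impact projection.

The eligibility funnel (12,684 breast-cancer patients x 95% access x 24.3%
HER2-positive x 50% with residual disease) sizes the treatable population;
3% annual growth and 5%/10%/15% uptake shares split it between the arms.
The per-patient figure is the undiscounted first-year cost difference from
the cohort engine; yearly and cumulative impacts are the payer's extra
spend if T-DM1 replaces trastuzumab for the uptake share.
"""

from tdm1cea import default_config
from tdm1cea.budget_impact import run_bia

config = default_config()
result = run_bia(config)

print(f"per-patient first-year cost difference: {result.per_patient_delta:.2f} $")
print(result.table.round(2).to_string(index=False))
print(
    "\ncumulative_impact_usd is the total extra budget required through "
    "each horizon year"
)
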