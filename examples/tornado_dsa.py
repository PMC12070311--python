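"""One-way deterministic sensitivity analysis (tornado).

Each uncertain parameter is pushed to the low and high end of its range
(±20% for costs, 95% CI bounds for clinical effects, alternative discount
rates) while everything else stays at base case; the table is sorted by the
width of the resulting ICER interval.  A NaN ICER means that end of the
range made the intervention dominant (cheaper and more effective), so no
ratio is defined — the verdict columns say which.
"""

from tdm1cea import default_config, default_dsa_ranges, one_way_dsa

config = default_config()
table = one_way_dsa(config, default_dsa_ranges(config))
cols = ["parameter", "low_value", "high_value", "icer_low", "icer_high",
        "verdict_low", "verdict_high", "spread"]
print(table[cols].round(2).to_string(index=False))
print(
    "\nwidest bars are the parameters the cost-effectiveness conclusion "
    "is most sensitive to"
)
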