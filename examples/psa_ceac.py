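"""Probabilistic sensitivity analysis and acceptability curve.

Every uncertain parameter is drawn from its fitted distribution (beta for
probabilities/utilities, gamma for costs, lognormal where a ratio's CI
crosses 1); both arms are re-evaluated on each shared draw.  Quadrant
fractions describe the cost-effectiveness plane (NE: dearer & better;
SE: cheaper & better, i.e. dominant); the below-threshold fraction is the
probability the intervention is cost-effective at the configured
willingness to pay.
"""

import numpy as np

from tdm1cea import ceac, default_config, run_psa

config = default_config()
result = run_psa(config, n_iter=2000, seed=7)

s = result.summary
print(f"draws: {s['n_iter']}  (seed {s['seed']}, WTP {s['wtp']:.0f} $/QALY)")
print("quadrant fractions:", {k: round(v, 4) for k, v in s["quadrant_fractions"].items()})
print(f"P(cost-effective at WTP)      : {s['below_threshold']:.4f}")
print(f"  ... restricted to QALY gains: {s['below_threshold_gaining']:.4f}")
print(f"mean incremental cost/QALYs   : {s['mean_delta_cost']:.1f} $ / {s['mean_delta_qaly']:.3f}")

grid = np.linspace(0.0, 2.0 * s["wtp"], 9)
curve = ceac(result.samples, grid)
print("\nacceptability curve (P cost-effective vs willingness to pay):")
print(curve.round(4).to_string(index=False))
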