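"""Predict bud behavior for strigolactone-insensitive PIN1 backgrounds.

A PIN1 variant that strigolactone cannot remove from the membrane changes
two things in the model: bulk transport efficiency is lower (S reduced by
20%) and the decay rate mu stays at the strigolactone-receptor-mutant
level for every background. Each SIP1 line keeps its background's basal
efflux v0, so strigolactone acts on these lines only through BRC1 / v0.
The prediction: progressively lower v0 across SIP1, SIP1+GR24 and
SIP1-smxl678 increases one-bud dominance and lengthens the lag, with
little change in maximum growth rate.
"""

import numpy as np

from twobud import DEFAULT_PARAMS
from twobud.genotypes import (
    ConstraintSet,
    DEFAULT_GENOTYPE_POSITIONS,
    Placement,
    predict_metrics,
    sip1_slice,
)

background = Placement(
    positions=dict(DEFAULT_GENOTYPE_POSITIONS),
    indices={l: (0, 0) for l in DEFAULT_GENOTYPE_POSITIONS},
    scores={},
    constraints=ConstraintSet(),
)
d14_mu = DEFAULT_GENOTYPE_POSITIONS["d14"][1]
sip_params, sip_positions = sip1_slice(DEFAULT_PARAMS, background, d14_mu=d14_mu)
print(f"reduced-transport slice: S = {sip_params.S} (background S = {DEFAULT_PARAMS.S})")
for label, (v0, mu) in sip_positions.items():
    print(f"{label:>16}: v0={v0:.3f}, mu={mu:.2f}")

placement = Placement(
    positions=sip_positions,
    indices={l: (0, 0) for l in sip_positions},
    scores={},
    constraints=ConstraintSet(),
)
predictions = predict_metrics(placement, sip_params, n_sims=100, t_end=120, base_seed=9)
print(f"\n{'line':>16} {'p_both':>6} {'p_one':>6} {'p_none':>7} {'lag_med':>8} {'rate_med':>9}")
for label in ("SIP1pin1", "SIP1pin1+GR24", "SIP1pin1smxl678"):
    p = predictions[label]
    lag = np.median(p.lags) if len(p.lags) else float("nan")
    rate = np.median(p.max_rates) if len(p.max_rates) else float("nan")
    print(f"{label:>16} {p.fractions.p_both:6.2f} {p.fractions.p_one:6.2f} "
          f"{p.fractions.p_none:7.2f} {lag:8.1f} {rate:9.2f}")
print("\nDown the series, one-bud dominance and lag rise while the maximum")
print("growth rate stays near-constant: strigolactone acting through BRC1")
print("alone delays activation without weakening growth of the winning bud.")
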