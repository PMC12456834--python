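"""Generate a synthetic bud-length dataset and extract its trace metrics.

The generator draws 40 explants from a wild-type-like archetype (45% both
buds grow, 45% one, 10% neither; lag ~3 days; max rate ~6 mm/day) and the
extractor reads back activity, lag, maximum growth rate, RGI and the
outcome split. With measurement noise of 0.2 mm the recovered summaries
sit close to the generating values.
"""

import numpy as np

from twobud.synthetic import Archetype, generate_explants
from twobud.traces import compute_metrics, outcome_summary

archetype = Archetype()
traces, truth = generate_explants(archetype, n=40, seed=7)

fractions, active_pct = outcome_summary(traces)
print(f"archetype: p=({archetype.p_both}, {archetype.p_one}, {archetype.p_none}), "
      f"lag {archetype.lag_mean} d, rate {archetype.max_rate_mean} mm/d")
print(f"extracted outcome fractions: both={fractions.p_both:.2f} "
      f"one={fractions.p_one:.2f} none={fractions.p_none:.2f}; "
      f"{active_pct:.0f}% of explants active")

lags, rates, rgis = [], [], []
for trace in traces:
    m = compute_metrics(trace)
    if m.rgi is not None:
        rgis.append(m.rgi)
    for bud in (m.top, m.bottom):
        if bud.active:
            lags.append(bud.lag)
            rates.append(bud.max_rate)
print(f"active buds: {len(lags)}; median lag {np.median(lags):.1f} d "
      f"(truth {archetype.lag_mean}); median max rate {np.median(rates):.1f} mm/d "
      f"(daily sampling slightly underestimates the true {archetype.max_rate_mean})")
print(f"mean RGI of active explants: {np.mean(rgis):.2f} "
      "(0.5 = both buds equal, 1.0 = complete dominance)")
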