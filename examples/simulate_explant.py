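"""Simulate a small ensemble of 2-node explants and summarize the outcomes.

Ten stochastic runs at the calibrated wild-type-like cell: each explant's
two buds compete to canalize auxin export. The printed table shows, per
run, the final efflux and length of each bud and the growth outcome by the
3x dominance rule — "one" means one bud ended more than three times longer
than the other, "both" that both activated to comparable lengths.
"""

import numpy as np

from twobud import DEFAULT_PARAMS, ensemble
from twobud.traces import compute_metrics, trajectory_to_trace

runs = ensemble(DEFAULT_PARAMS, n_sims=10, t_end=120.0, base_seed=42)

print(f"cell: v0={DEFAULT_PARAMS.v0}, mu={DEFAULT_PARAMS.mu}, eta={DEFAULT_PARAMS.eta}")
print(f"{'run':>3} {'E_end':>7} {'F_end':>7} {'N_end':>7} {'M_end':>7} outcome")
outcomes = []
for i, traj in enumerate(runs):
    trace = trajectory_to_trace(traj, f"run-{i}", "wt")
    metrics = compute_metrics(
        type(trace)(trace.explant_id, trace.label, trace.times[::10],
                    trace.top[::10], trace.bottom[::10], "simulated")
    )
    outcomes.append(metrics.outcome)
    E, F, N, M = traj.values[-1]
    print(f"{i:>3} {E:7.3f} {F:7.3f} {N:7.1f} {M:7.1f} {metrics.outcome}")

vals, counts = np.unique(outcomes, return_counts=True)
print("outcome counts:", dict(zip(vals.tolist(), counts.tolist())))
print(
    "A high-efflux bud (E or F near 1.4) has canalized its auxin export and\n"
    "grown; a suppressed bud sits near 0.1 with almost no growth."
)
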