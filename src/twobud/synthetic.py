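"""Synthetic experimental-format bud-length datasets with known ground truth.

Real 2-node explant assays measure both bud lengths daily (in mm) for
10-19 days. Activated buds show a slow lag phase followed by a switch to
rapid, near-logistic outgrowth toward a plateau; inhibited buds creep along
at a small residual rate; occasionally a dominant bud stops early and the
other bud then activates. This module emulates those features from explicit
archetype parameters so every downstream stage (trace metrics, outcome
summaries, genotype placement) can be tested against known truth without
any measured data.

Latent curve of an activated bud with switch day ``s``, maximum rate ``g``
and plateau ``P`` (initial length ``L0``):

* constant at ``L0`` for ``t < s``;
* for ``t >= s`` a logistic segment ``L0 + A * (sigma(k (t - t0)) - q)``
  with ``q = 0.20``, ``A = (P - L0) / (1 - q)`` and ``k = 4 g / A``, where
  ``t0`` places the curve at 20% of its rise on the switch day so that the
  curve leaves ``L0`` continuously at ``s`` and its maximum slope is ``g``.

The switch day and maximum slope are the identifiable ground truths; i.i.d.
Gaussian measurement noise is added on top of the monotone latent curve and
lengths are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExplantState, ModelParameters
from .simulate import DEFAULT_DT, ensemble
from .traces import BudTrace

__all__ = ["Archetype", "generate_explants", "generate_from_model"]

#: Fraction of the logistic rise already completed on the switch day.
_SWITCH_FRACTION = 0.20


@dataclass(frozen=True)
class Archetype:
    """Generator parameters describing one genotype/treatment's behavior."""

    label: str = "wildtype-like"
    p_both: float = 0.45
    p_one: float = 0.45
    p_none: float = 0.10
    lag_mean: float = 3.0  # days
    lag_sd: float = 1.0
    max_rate_mean: float = 6.0  # mm/day
    max_rate_sd: float = 1.5
    plateau: float = 25.0  # mm
    initial_length: float = 1.0  # mm
    residual_rate: float = 0.1  # mm/day for inhibited buds
    noise_sd: float = 0.2  # mm, i.i.d. per observation
    days_measured: int = 10
    stop_and_switch_prob: float = 0.05

    def __post_init__(self):
        total = self.p_both + self.p_one + self.p_none
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"outcome probabilities must sum to 1, got {total}")
        if self.days_measured < 3:
            raise ValueError("days_measured must be >= 3")
        for name in ("lag_mean", "max_rate_mean", "plateau", "initial_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lag_sd", "max_rate_sd", "residual_rate", "noise_sd",
                     "stop_and_switch_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.stop_and_switch_prob <= 1:
            raise ValueError("stop_and_switch_prob must be a probability")


def _logistic_curve(times, L0, switch_day, max_rate, plateau):
    """Latent active-bud curve: flat until switch, then logistic to plateau."""
    A = (plateau - L0) / (1.0 - _SWITCH_FRACTION)
    k = 4.0 * max_rate / A
    # sigma(k (s - t0)) = q  =>  t0 = s + ln((1-q)/q)/k
    t0 = switch_day + np.log((1 - _SWITCH_FRACTION) / _SWITCH_FRACTION) / k
    out = np.full_like(times, L0, dtype=float)
    after = times >= switch_day
    sig = 1.0 / (1.0 + np.exp(-k * (times[after] - t0)))
    out[after] = L0 + A * (sig - _SWITCH_FRACTION)
    return out


def _draw_positive(rng, mean, sd, minimum):
    """Normal draw truncated below (redraw-free: clip)."""
    return max(float(rng.normal(mean, sd)), minimum)


def generate_explants(
    archetype: Archetype, n: int, seed: int
) -> tuple[list[BudTrace], pd.DataFrame]:
    """Draw ``n`` synthetic explants plus their ground-truth table.

    Each explant's outcome is drawn from the archetype probabilities; bud
    curves follow the lag-then-logistic model with per-bud lag and rate
    draws. The ground-truth table is keyed by explant id and records the
    drawn outcome and, per bud, the activity flag, switch day (true lag) and
    maximum rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a = archetype
    times = np.arange(a.days_measured + 1, dtype=float)
    traces: list[BudTrace] = []
    records = []

    for idx in range(n):
        outcome = rng.choice(["both", "one", "none"], p=[a.p_both, a.p_one, a.p_none])
        winner_is_top = bool(rng.random() < 0.5)
        stop_switch = outcome == "one" and rng.random() < a.stop_and_switch_prob
        buds = {}
        truth = {}
        roles = {"top": None, "bottom": None}
        if outcome == "both":
            roles = {"top": "active", "bottom": "active"}
        elif outcome == "one":
            roles["top" if winner_is_top else "bottom"] = "active"
            roles["bottom" if winner_is_top else "top"] = "inhibited"
        else:
            roles = {"top": "inhibited", "bottom": "inhibited"}

        # Draws happen in a fixed order (top first) for reproducibility.
        for bud in ("top", "bottom"):
            role = roles[bud]
            if role == "active":
                s = _draw_positive(rng, a.lag_mean, a.lag_sd, 0.0)
                g = _draw_positive(rng, a.max_rate_mean, a.max_rate_sd, 0.1 * a.max_rate_mean)
                latent = _logistic_curve(times, a.initial_length, s, g, a.plateau)
                truth[bud] = {"active": True, "lag": s, "max_rate": g}
            else:
                latent = a.initial_length + a.residual_rate * times
                truth[bud] = {"active": False, "lag": np.nan, "max_rate": a.residual_rate}
            buds[bud] = latent

        if stop_switch:
            # Dominant bud plateaus early; the other bud then activates.
            dom = "top" if winner_is_top else "bottom"
            sub = "bottom" if winner_is_top else "top"
            stop_len = a.initial_length + 0.4 * (a.plateau - a.initial_length)
            buds[dom] = np.minimum(buds[dom], stop_len)
            s2 = truth[dom]["lag"] + _draw_positive(rng, 3.0, 1.0, 1.0)
            g2 = _draw_positive(rng, a.max_rate_mean, a.max_rate_sd, 0.1 * a.max_rate_mean)
            buds[sub] = _logistic_curve(times, a.initial_length, s2, g2, a.plateau)
            truth[sub] = {"active": True, "lag": s2, "max_rate": g2}

        observed = {}
        for bud in ("top", "bottom"):
            noisy = buds[bud] + rng.normal(0.0, a.noise_sd, size=times.shape)
            observed[bud] = np.clip(noisy, 0.0, None)

        explant_id = f"{a.label}-{idx:04d}"
        traces.append(
            BudTrace(
                explant_id=explant_id,
                label=a.label,
                times=times,
                top=observed["top"],
                bottom=observed["bottom"],
                source="experimental",
            )
        )
        records.append(
            {
                "explant_id": explant_id,
                "label": a.label,
                "outcome": outcome,
                "stop_and_switch": stop_switch,
                "top_active": truth["top"]["active"],
                "top_lag": truth["top"]["lag"],
                "top_max_rate": truth["top"]["max_rate"],
                "bottom_active": truth["bottom"]["active"],
                "bottom_lag": truth["bottom"]["lag"],
                "bottom_max_rate": truth["bottom"]["max_rate"],
            }
        )
    return traces, pd.DataFrame.from_records(records)


def generate_from_model(
    placement,
    base_params: ModelParameters,
    n: int,
    t_end: float = 120.0,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    init: ExplantState | None = None,
) -> list[BudTrace]:
    """Simulated-source BudTraces from model ensembles at placed positions.

    ``placement`` is a mapping label -> (v0, mu) or an object with a
    ``positions`` attribute of that form (e.g. a genotype Placement). Member
    ``i`` of label ``l`` uses seed ``seed + l_index * n + i``.
    """
    positions = getattr(placement, "positions", placement)
    init = init or ExplantState()
    traces: list[BudTrace] = []
    for l_index, (label, (v0, mu)) in enumerate(sorted(positions.items())):
        params = base_params.with_updates(v0=float(v0), mu=float(mu))
        runs = ensemble(
            params, init, n_sims=n, t_end=t_end, dt=dt, base_seed=seed + l_index * n
        )
        for i, traj in enumerate(runs):
            traces.append(
                BudTrace(
                    explant_id=f"{label}-{i:04d}",
                    label=label,
                    times=traj.times,
                    top=traj.N,
                    bottom=traj.M,
                    source="simulated",
                )
            )
    return traces
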