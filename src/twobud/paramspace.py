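"""Maps of model behavior across the (v0, mu) parameter plane.

The published analysis characterizes the model on a lattice of (v0, mu)
combinations with all other parameters held at the calibrated slice values:

* a deterministic *behavior map* assigning each cell one of the six behavior
  classes from its steady-state configuration;
* a stochastic *outcome-fraction map*: in mono/bistable cells the outcome is
  forced (class 1 -> both, class 3 -> one, class 6 -> none) and no simulation
  is run; in tri/quadrastable cells (classes 2, 4, 5) the fractions of
  both / one / neither outcomes are estimated from an ensemble of stochastic
  simulations, with the per-run outcome read from final bud lengths by the
  3x dominance rule;
* *lag* and *maximum growth rate* heatmaps averaging trace metrics over the
  activated buds of an ensemble per cell;
* black *boundary* pixels wherever more than one of a cell's neighbors has
  a different number of stable steady states;
* *pixel repair* for cells whose steady-state search failed, filled from
  their neighbors;
* a *sensitivity scan* recomputing any of the above with each non-swept
  parameter perturbed by a fixed fraction (default +-5%).

Cell (i, j) covers ``v0_values[i]``, ``mu_values[j]``; payload lattices are
indexed [i, j]. Stochastic replicate r of cell (i, j) uses seed
``base_seed + r + n_sims * (j + i * n_cols)`` so every pixel is individually
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ExplantState, ModelParameters
from .simulate import DEFAULT_DT, integrate_batch
from .steadystate import (
    BEHAVIOR_CLASSES,
    EmptySteadyStateSetError,
    SteadyStateOptions,
    UnclassifiableBehaviorError,
    classify_behavior,
    find_steady_states,
)
from .traces import OutcomeFractions

__all__ = [
    "GridMap",
    "OutcomeFractions",
    "DEFAULT_V0_RANGE",
    "DEFAULT_MU_RANGE",
    "behavior_map",
    "outcome_fraction_map",
    "mark_boundaries",
    "repair_pixels",
    "metric_heatmaps",
    "sensitivity_scan",
    "render_rgb",
    "cell_seed",
]

#: Calibrated slice axes (see docs/methods.md).
DEFAULT_V0_RANGE = (0.005, 0.14)
DEFAULT_MU_RANGE = (0.2, 6.0)

#: Classes whose outcome is decided by stochasticity (tri/quadrastable).
_STOCHASTIC_CLASSES = (2, 4, 5)
#: Forced fractions in the mono/bistable classes.
_DEGENERATE_FRACTIONS = {1: (1.0, 0.0, 0.0), 3: (0.0, 1.0, 0.0), 6: (0.0, 0.0, 1.0)}

_RGB = {
    "both": np.array([1.0, 0.85, 0.1]),  # yellow
    "one": np.array([0.1, 0.3, 0.85]),  # blue
    "none": np.array([0.85, 0.1, 0.1]),  # red
}
_CLASS_RGB = {
    1: np.array([1.0, 0.85, 0.1]),  # yellow
    2: np.array([0.2, 0.7, 0.3]),  # green
    3: np.array([0.05, 0.1, 0.45]),  # navy
    4: np.array([0.55, 0.8, 0.95]),  # light blue
    5: np.array([1.0, 1.0, 1.0]),  # white
    6: np.array([0.85, 0.1, 0.1]),  # red
}


def cell_seed(base_seed: int, i: int, j: int, r: int, n_sims: int, n_cols: int) -> int:
    """Seed for replicate r of cell (i, j) on an n_cols-wide grid."""
    return int(base_seed + r + n_sims * (j + i * n_cols))


@dataclass
class GridMap:
    """A (v0, mu) lattice carrying one payload kind.

    ``cells`` maps channel name -> array of shape (len(v0), len(mu)).
    Channels by payload kind:

    * behavior: ``class_id`` (int, 0 where failed), ``n_stable``
    * outcome: those plus ``p_both``, ``p_one``, ``p_none``
    * lag / max_rate: those plus ``value`` (NaN = no bud ever activated)
    """

    v0_values: np.ndarray
    mu_values: np.ndarray
    payload: str  # "behavior" | "outcome" | "lag" | "max_rate"
    cells: dict[str, np.ndarray]
    boundary_mask: np.ndarray | None = None
    failure_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v0_values = np.asarray(self.v0_values, dtype=float)
        self.mu_values = np.asarray(self.mu_values, dtype=float)
        shape = (len(self.v0_values), len(self.mu_values))
        for name, arr in self.cells.items():
            if arr.shape != shape:
                raise ValueError(f"channel {name!r} has shape {arr.shape}, expected {shape}")
        if self.failure_mask is None:
            self.failure_mask = np.zeros(shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.v0_values), len(self.mu_values))

    def fractions_at(self, i: int, j: int) -> OutcomeFractions:
        return OutcomeFractions(
            p_both=float(self.cells["p_both"][i, j]),
            p_one=float(self.cells["p_one"][i, j]),
            p_none=float(self.cells["p_none"][i, j]),
        )


def _neighbor_offsets(connectivity: int):
    if connectivity == 8:
        return [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    if connectivity == 4:
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    raise ValueError("connectivity must be 4 or 8")


def behavior_map(
    v0_values: np.ndarray,
    mu_values: np.ndarray,
    base_params: ModelParameters,
    options: SteadyStateOptions | None = None,
    connectivity: int = 8,
    repair: bool = True,
) -> GridMap:
    """Deterministic behavior-class map over the (v0, mu) lattice."""
    v0_values = np.asarray(v0_values, dtype=float)
    mu_values = np.asarray(mu_values, dtype=float)
    if np.any(v0_values <= 0) or np.any(mu_values <= 0):
        raise ValueError("axis values must be positive")
    if np.any(np.diff(v0_values) <= 0) or np.any(np.diff(mu_values) <= 0):
        raise ValueError("axis values must be sorted ascending")
    shape = (len(v0_values), len(mu_values))
    class_id = np.zeros(shape, dtype=int)
    n_stable = np.zeros(shape, dtype=int)
    failed = np.zeros(shape, dtype=bool)
    for i, v0 in enumerate(v0_values):
        for j, mu in enumerate(mu_values):
            params = base_params.with_updates(v0=float(v0), mu=float(mu))
            try:
                sset = find_steady_states(params, options)
                n_stable[i, j] = sset.n_stable
                class_id[i, j] = classify_behavior(sset).class_id
            except (EmptySteadyStateSetError, UnclassifiableBehaviorError):
                failed[i, j] = True
    gmap = GridMap(
        v0_values,
        mu_values,
        "behavior",
        {"class_id": class_id, "n_stable": n_stable},
        failure_mask=failed,
        provenance={
            "base_params": base_params.to_dict(),
            "connectivity": connectivity,
        },
    )
    if repair:
        gmap = repair_pixels(gmap, connectivity=connectivity)
    return mark_boundaries(gmap, connectivity=connectivity)


def mark_boundaries(gmap: GridMap, connectivity: int = 8) -> GridMap:
    """Mark cells with >1 neighbor differing in stable-state count."""
    counts = gmap.cells["n_stable"]
    diff = np.zeros(gmap.shape, dtype=int)
    for di, dj in _neighbor_offsets(connectivity):
        shifted = np.full(gmap.shape, -1)
        src = counts[
            max(0, -di) : counts.shape[0] - max(0, di),
            max(0, -dj) : counts.shape[1] - max(0, dj),
        ]
        shifted[
            max(0, di) : counts.shape[0] - max(0, -di),
            max(0, dj) : counts.shape[1] - max(0, -dj),
        ] = src
        diff += (shifted >= 0) & (shifted != counts)
    gmap.boundary_mask = diff > 1
    return gmap


def repair_pixels(gmap: GridMap, connectivity: int = 8) -> GridMap:
    """Fill failed cells from their neighbors.

    If all non-failed neighbors agree, the cell takes that value; otherwise
    continuous channels take the neighbor mean and the class id takes the
    neighbor value nearest the mean (a class id must remain a class id).
    Failed cells with no non-failed neighbor stay failed, with a warning.
    """
    failed = gmap.failure_mask
    if not failed.any():
        return gmap
    offsets = _neighbor_offsets(connectivity)
    repaired_cells = []
    still_failed = failed.copy()
    for i, j in zip(*np.nonzero(failed)):
        neighbors = [
            (i + di, j + dj)
            for di, dj in offsets
            if 0 <= i + di < gmap.shape[0]
            and 0 <= j + dj < gmap.shape[1]
            and not failed[i + di, j + dj]
        ]
        if not neighbors:
            warnings.warn(f"cell ({i}, {j}) has no repairable neighbors; left failed")
            continue
        for name, arr in gmap.cells.items():
            vals = np.array([arr[ni, nj] for ni, nj in neighbors], dtype=float)
            if np.all(vals == vals[0]):
                fill = vals[0]
            elif name in ("class_id", "n_stable"):
                fill = vals[np.argmin(np.abs(vals - vals.mean()))]
            else:
                fill = vals.mean()
            arr[i, j] = fill if arr.dtype != int else int(round(fill))
        repaired_cells.append((int(i), int(j)))
        still_failed[i, j] = False
    gmap.failure_mask = still_failed
    gmap.provenance.setdefault("repaired_cells", []).extend(repaired_cells)
    return gmap


def _simulated_outcomes(finals: np.ndarray, init: ExplantState, activation_factor: float = 10.0):
    """Outcome codes 0=both, 1=one, 2=none from final (E, F, N, M) rows."""
    N, M = finals[:, 2], finals[:, 3]
    hi = np.maximum(N, M)
    lo = np.minimum(N, M)
    one = hi > 3.0 * lo
    act = (N > init.N * (1 + activation_factor)) & (M > init.M * (1 + activation_factor))
    both = ~one & act
    out = np.full(len(finals), 2, dtype=int)
    out[one] = 1
    out[both] = 0
    return out


def outcome_fraction_map(
    v0_values: np.ndarray,
    mu_values: np.ndarray,
    base_params: ModelParameters,
    n_sims: int = 100,
    t_end: float = 120.0,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
    init: ExplantState | None = None,
    options: SteadyStateOptions | None = None,
    connectivity: int = 8,
    chunk_rows: int = 4096,
) -> GridMap:
    """Stochastic outcome-fraction map over the (v0, mu) lattice.

    Mono/bistable cells get their forced fractions with no simulation;
    tri/quadrastable cells get empirical fractions from ``n_sims``
    stochastic runs each.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    init = init or ExplantState()
    base = behavior_map(
        v0_values, mu_values, base_params, options=options, connectivity=connectivity
    )
    shape = base.shape
    p = {k: np.full(shape, np.nan) for k in ("p_both", "p_one", "p_none")}
    for cid, (pb, po, pn) in _DEGENERATE_FRACTIONS.items():
        mask = base.cells["class_id"] == cid
        p["p_both"][mask], p["p_one"][mask], p["p_none"][mask] = pb, po, pn

    stoch = np.isin(base.cells["class_id"], _STOCHASTIC_CLASSES) & ~base.failure_mask
    cells = list(zip(*np.nonzero(stoch)))
    n_cols = len(mu_values)
    cells_per_chunk = max(1, chunk_rows // n_sims)
    sim_failed = np.zeros(shape, dtype=bool)
    for start in range(0, len(cells), cells_per_chunk):
        chunk = cells[start : start + cells_per_chunk]
        rows_v0 = np.repeat([v0_values[i] for i, _ in chunk], n_sims)
        rows_mu = np.repeat([mu_values[j] for _, j in chunk], n_sims)
        seeds = np.concatenate(
            [
                [cell_seed(base_seed, i, j, r, n_sims, n_cols) for r in range(n_sims)]
                for i, j in chunk
            ]
        )
        _, finals, _ = integrate_batch(
            base_params, init, t_end, dt, seeds=seeds, v0=rows_v0, mu=rows_mu, record=False
        )
        codes = _simulated_outcomes(finals, init)
        for k, (i, j) in enumerate(chunk):
            cell_codes = codes[k * n_sims : (k + 1) * n_sims]
            p["p_both"][i, j] = np.mean(cell_codes == 0)
            p["p_one"][i, j] = np.mean(cell_codes == 1)
            p["p_none"][i, j] = np.mean(cell_codes == 2)

    gmap = GridMap(
        base.v0_values,
        base.mu_values,
        "outcome",
        {
            "class_id": base.cells["class_id"],
            "n_stable": base.cells["n_stable"],
            **p,
        },
        failure_mask=base.failure_mask | sim_failed,
        provenance={
            "base_params": base_params.to_dict(),
            "n_sims": n_sims,
            "t_end": t_end,
            "dt": dt,
            "base_seed": base_seed,
            "seed_policy": "base_seed + r + n_sims * (j + i * n_cols)",
            "connectivity": connectivity,
        },
    )
    gmap = repair_pixels(gmap, connectivity=connectivity)
    return mark_boundaries(gmap, connectivity=connectivity)


def _rolling_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows
    (matches the trace extractor's pandas rolling semantics; odd windows)."""
    if window <= 1:
        return arr
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    T = arr.shape[1]
    cs = np.zeros((arr.shape[0], T + 1))
    np.cumsum(arr, axis=1, out=cs[:, 1:])
    idx = np.arange(T)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, T - 1)
    return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


def _gradient_axis1(arr: np.ndarray, times: np.ndarray) -> np.ndarray:
    out = np.empty_like(arr)
    out[:, 1:-1] = (arr[:, 2:] - arr[:, :-2]) / (times[2:] - times[:-2])
    out[:, 0] = (arr[:, 1] - arr[:, 0]) / (times[1] - times[0])
    out[:, -1] = (arr[:, -1] - arr[:, -2]) / (times[-1] - times[-2])
    return out


def metric_heatmaps(
    v0_values: np.ndarray,
    mu_values: np.ndarray,
    base_params: ModelParameters,
    n_sims: int = 100,
    t_end: float = 120.0,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
    init: ExplantState | None = None,
    activity_threshold: float = 0.02,
    smoothing_window: int = 3,
    connectivity: int = 8,
    chunk_rows: int = 2048,
    statistic: str = "mean",
) -> tuple[GridMap, GridMap]:
    """Mean-lag and mean-max-growth-rate heatmaps over the (v0, mu) lattice.

    Every cell runs ``n_sims`` stochastic simulations. Bud-length traces are
    sampled at unit time steps, smoothed, and differentiated exactly as in
    the trace extractor; a bud is activated if its rate exceeds the activity
    threshold. Cell summaries are over activated buds only; cells where no
    bud ever activates carry NaN. ``statistic`` is "mean" (the published
    convention) or "median" (robust to the heavy right tail of the lag
    distribution; used by the placement search).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    init = init or ExplantState()
    v0_values = np.asarray(v0_values, dtype=float)
    mu_values = np.asarray(mu_values, dtype=float)
    shape = (len(v0_values), len(mu_values))
    lag_map = np.full(shape, np.nan)
    rate_map = np.full(shape, np.nan)
    lag_se = np.full(shape, np.nan)
    rate_se = np.full(shape, np.nan)
    n_buds = np.zeros(shape, dtype=int)
    se_factor = 1.0 if statistic == "mean" else 1.2533  # median is ~25% noisier
    n_cols = len(mu_values)
    cells = [(i, j) for i in range(shape[0]) for j in range(shape[1])]
    cells_per_chunk = max(1, chunk_rows // n_sims)
    stride = max(1, int(round(1.0 / dt)))
    for start in range(0, len(cells), cells_per_chunk):
        chunk = cells[start : start + cells_per_chunk]
        rows_v0 = np.repeat([v0_values[i] for i, _ in chunk], n_sims)
        rows_mu = np.repeat([mu_values[j] for _, j in chunk], n_sims)
        seeds = np.concatenate(
            [
                [cell_seed(base_seed, i, j, r, n_sims, n_cols) for r in range(n_sims)]
                for i, j in chunk
            ]
        )
        times, values, _ = integrate_batch(
            base_params, init, t_end, dt, seeds=seeds, v0=rows_v0, mu=rows_mu, record=True
        )
        sub_t = times[::stride]
        lengths = np.concatenate(
            [values[:, ::stride, 2], values[:, ::stride, 3]], axis=0
        )  # both buds stacked
        rates = _gradient_axis1(_rolling_mean(lengths, smoothing_window), sub_t)
        active = np.any(rates > activity_threshold, axis=1)
        first = np.argmax(rates > activity_threshold, axis=1)
        lag = sub_t[first] - sub_t[0]
        max_rate = rates.max(axis=1)
        n_rows = len(chunk) * n_sims
        for k, (i, j) in enumerate(chunk):
            sel = np.zeros(2 * n_rows, dtype=bool)
            sel[k * n_sims : (k + 1) * n_sims] = True
            sel[n_rows + k * n_sims : n_rows + (k + 1) * n_sims] = True
            act = active & sel
            if act.any():
                lag_map[i, j] = agg(lag[act])
                rate_map[i, j] = agg(max_rate[act])
                count = int(act.sum())
                n_buds[i, j] = count
                lag_se[i, j] = se_factor * np.std(lag[act]) / np.sqrt(count)
                rate_se[i, j] = se_factor * np.std(max_rate[act]) / np.sqrt(count)

    prov = {
        "base_params": base_params.to_dict(),
        "n_sims": n_sims,
        "t_end": t_end,
        "dt": dt,
        "base_seed": base_seed,
        "activity_threshold": activity_threshold,
        "smoothing_window": smoothing_window,
        "statistic": statistic,
        "seed_policy": "base_seed + r + n_sims * (j + i * n_cols)",
    }
    lag_gmap = GridMap(
        v0_values, mu_values, "lag",
        {"value": lag_map, "se": lag_se, "n_buds": n_buds},
        provenance=dict(prov),
    )
    rate_gmap = GridMap(
        v0_values, mu_values, "max_rate",
        {"value": rate_map, "se": rate_se, "n_buds": n_buds.copy()},
        provenance=dict(prov),
    )
    return lag_gmap, rate_gmap


_SENSITIVITY_PARAMS = ("S", "D", "v", "K", "Q", "n", "eta")


def sensitivity_scan(
    op,
    base_params: ModelParameters,
    fraction: float = 0.05,
    parameters: tuple[str, ...] = _SENSITIVITY_PARAMS,
    **op_kwargs,
):
    """Recompute a map operation with each parameter perturbed by +-fraction.

    ``op`` is a map builder taking ``(v0_values, mu_values, base_params,
    ...)`` — e.g. :func:`behavior_map`, :func:`outcome_fraction_map`, or
    :func:`metric_heatmaps` — or the name of one of those. Returns a dict
    keyed by ``(parameter, "+"|"-")``. Perturbations that would violate a
    parameter invariant are skipped with a warning. The swept axes (v0, mu)
    are never perturbed.
    """
    if isinstance(op, str):
        op = {
            "behavior": behavior_map,
            "outcome": outcome_fraction_map,
            "metrics": metric_heatmaps,
        }[op]
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    results = {}
    for name in parameters:
        if name in ("v0", "mu"):
            warnings.warn(f"{name} is a swept axis; skipping its perturbation")
            continue
        for sign, factor in (("+", 1 + fraction), ("-", 1 - fraction)):
            try:
                perturbed = base_params.with_updates(**{name: getattr(base_params, name) * factor})
            except Exception as err:
                warnings.warn(f"skipping {name}{sign}: {err}")
                continue
            results[(name, sign)] = op(base_params=perturbed, **op_kwargs)
    return results


def render_rgb(gmap: GridMap) -> np.ndarray:
    """RGB image of a map using the published color convention.

    Outcome maps blend linearly: RGB = p_both * yellow + p_one * blue +
    p_none * red. Behavior maps use the per-class colors. Boundary cells are
    black.
    """
    shape = gmap.shape
    img = np.ones(shape + (3,))
    if gmap.payload == "outcome":
        img = (
            gmap.cells["p_both"][..., None] * _RGB["both"]
            + gmap.cells["p_one"][..., None] * _RGB["one"]
            + gmap.cells["p_none"][..., None] * _RGB["none"]
        )
    elif gmap.payload == "behavior":
        for cid, color in _CLASS_RGB.items():
            img[gmap.cells["class_id"] == cid] = color
    else:
        vals = gmap.cells["value"]
        finite = np.isfinite(vals)
        lo = np.nanmin(vals) if finite.any() else 0.0
        hi = np.nanmax(vals) if finite.any() else 1.0
        scale = np.where(finite, (vals - lo) / (hi - lo + 1e-300), 0.0)
        img = scale[..., None] * np.array([0.1, 0.2, 0.6]) + (1 - scale[..., None])
    if gmap.boundary_mask is not None:
        img[gmap.boundary_mask] = 0.0
    return np.clip(img, 0.0, 1.0)
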