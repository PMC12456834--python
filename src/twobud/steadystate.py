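"""Fixed points of the two-bud efflux subsystem and their qualitative taxonomy.

The efflux subsystem (E, F) decides everything qualitative about an explant:
which combinations of buds can end up canalized. This module locates all its
fixed points, labels their linear stability, and maps the stable-point
configuration onto one of six behavior classes:

==== ===================== ===========
id   description           color role
==== ===================== ===========
1    both activate         yellow
2    both-or-one           green
3    only one              navy
4    one-or-neither        light blue
5    all four outcomes     white
6    neither activates     red
==== ===================== ===========

Classification uses two efflux thresholds: a symmetric steady state counts
as "both activate" at or above 0.4 when it is the only attractor, and as an
active (rather than inactive) coexisting state at or above 0.24 when an
asymmetric pair is also present.

Root finding exploits the model's structure: every fixed point coordinate
solves the same univariate polynomial once the shared stem-sink threshold
``T = D (E + F) + K`` is fixed, so candidates are enumerated from polynomial
roots along the symmetric line and along a scan of ``T`` values, then
polished with a damped Newton iteration on the full 2-D system. A lattice of
extra starts covers non-integer Hill exponents, where the polynomial form is
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .model import (
    ModelParameters,
    efflux_jacobian_arrays,
    efflux_rates_arrays,
    efflux_upper_bound,
)

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "SteadyStateOptions",
    "BehaviorClass",
    "BEHAVIOR_CLASSES",
    "UnclassifiableBehaviorError",
    "EmptySteadyStateSetError",
    "find_steady_states",
    "classify_stability",
    "classify_behavior",
    "nullclines",
]

#: Symmetric steady state at/above this efflux means "both buds activate"
#: when it is the only stable state (class 1 vs 6 threshold).
ACTIVATION_THRESHOLD = 0.4
#: Symmetric steady state at/above this efflux counts as active when it
#: coexists with an asymmetric pair (class 2 vs 4 threshold).
COEXISTENCE_THRESHOLD = 0.24


class UnclassifiableBehaviorError(RuntimeError):
    """Stable-point configuration outside the six-class table."""


class EmptySteadyStateSetError(RuntimeError):
    """Root search failed to locate any fixed point."""


@dataclass(frozen=True)
class SteadyState:
    E: float
    F: float
    stable: bool
    eigenvalues: tuple[complex, complex]

    @property
    def symmetric(self) -> bool:
        return abs(self.E - self.F) <= 1e-5

    @property
    def value(self) -> float:
        """Symmetric-state efflux value (mean of the two coordinates)."""
        return 0.5 * (self.E + self.F)


@dataclass(frozen=True)
class SteadyStateOptions:
    """Search configuration for :func:`find_steady_states`."""

    box_max: float | None = None  # defaults to (v0 + v) / mu
    lattice_density: int = 10  # lattice_density^2 Newton starts
    t_scan: int = 48  # number of stem-sink threshold values scanned
    dedup_radius: float = 1e-6
    residual_tol: float = 1e-10
    eps_margin: float = 1e-8
    max_newton_iter: int = 80


@dataclass(frozen=True)
class SteadyStateSet:
    points: tuple[SteadyState, ...]
    params: ModelParameters
    tolerance: float

    @property
    def stable_points(self) -> tuple[SteadyState, ...]:
        return tuple(p for p in self.points if p.stable)

    @property
    def n_stable(self) -> int:
        return len(self.stable_points)

    def to_records(self) -> list[dict]:
        return [
            {
                "E": p.E,
                "F": p.F,
                "stability": "stable" if p.stable else "unstable",
                "eig_real_1": p.eigenvalues[0].real,
                "eig_real_2": p.eigenvalues[1].real,
            }
            for p in self.points
        ]


@dataclass(frozen=True)
class BehaviorClass:
    class_id: int
    description: str
    color_role: str


BEHAVIOR_CLASSES: dict[int, BehaviorClass] = {
    1: BehaviorClass(1, "both activate", "yellow"),
    2: BehaviorClass(2, "both-or-one", "green"),
    3: BehaviorClass(3, "only one", "navy"),
    4: BehaviorClass(4, "one-or-neither", "light blue"),
    5: BehaviorClass(5, "all four outcomes", "white"),
    6: BehaviorClass(6, "neither activates", "red"),
}


def _binom_poly(a: float, b: float, n: int) -> np.ndarray:
    """Coefficients (highest degree first) of (a x + b)^n."""
    return np.array([comb(n, k) * a**k * b ** (n - k) for k in range(n, -1, -1)])


def _roots_batch(coeff_rows: np.ndarray) -> list[np.ndarray]:
    """Real nonnegative roots for each row of polynomial coefficients.

    Rows share a common degree (highest-first). Uses stacked companion
    matrices so the whole batch is one eigenvalue call.
    """
    coeff_rows = np.atleast_2d(np.asarray(coeff_rows, dtype=float))
    deg = coeff_rows.shape[1] - 1
    lead = coeff_rows[:, :1]
    # all our polynomials have leading coefficient -mu * (S^n ...) != 0
    monic = coeff_rows / lead
    n_rows = coeff_rows.shape[0]
    companion = np.zeros((n_rows, deg, deg))
    idx = np.arange(deg - 1)
    companion[:, idx + 1, idx] = 1.0
    companion[:, 0, :] = -monic[:, 1:]
    eig = np.linalg.eigvals(companion)
    out = []
    for row in eig:
        real = row[np.abs(row.imag) < 1e-9].real
        out.append(real[real >= -1e-12])
    return out


def _candidate_seeds(params: ModelParameters, opts: SteadyStateOptions) -> np.ndarray:
    """Newton starting points: polynomial-enumerated + lattice."""
    box = opts.box_max if opts.box_max is not None else efflux_upper_bound(params)
    p = params
    seeds = []

    n_int = int(round(p.n))
    if abs(p.n - n_int) < 1e-12 and n_int >= 1:
        Sn = p.S**n_int
        hill_num = np.zeros(n_int + 1)
        hill_num[0] = Sn  # (S x)^n, highest-first over degree n
        # Symmetric line: (v0 - mu x)((Sx)^n + (2D x + K)^n) + v (Sx)^n = 0
        sym_den = hill_num + _binom_poly(2 * p.D, p.K, n_int)
        sym_poly = np.convolve([-p.mu, p.v0], sym_den)
        sym_poly[1:] += p.v * hill_num
        for r in _roots_batch(sym_poly[None, :])[0]:
            seeds.append((r, r))
        # T-scan: for fixed stem-sink threshold T both coordinates solve
        # (v0 - mu x)((Sx)^n + T^n) + v (Sx)^n = 0; pair up distinct roots.
        T_values = np.linspace(p.K, p.K + 2 * p.D * box, opts.t_scan)
        rows = np.empty((opts.t_scan, n_int + 2))
        base = np.zeros(n_int + 1)
        base[0] = Sn
        for i, T in enumerate(T_values):
            den = base.copy()
            den[-1] += T**n_int
            poly = np.convolve([-p.mu, p.v0], den)
            poly[1:] += p.v * base
            rows[i] = poly
        for roots in _roots_batch(rows):
            roots = np.sort(roots)
            for i in range(len(roots)):
                for j in range(i + 1, len(roots)):
                    seeds.append((roots[i], roots[j]))

    grid = np.linspace(0.0, box, opts.lattice_density)
    gE, gF = np.meshgrid(grid, grid)
    upper = gE <= gF  # swap closure restores the lower triangle
    seeds.extend(zip(gE[upper].ravel(), gF[upper].ravel()))
    return np.asarray(seeds, dtype=float)


def _newton_polish(
    seeds: np.ndarray, params: ModelParameters, opts: SteadyStateOptions
) -> np.ndarray:
    """Damped Newton on the 2-D efflux system from every seed; returns
    converged points (residual below tolerance)."""
    box = opts.box_max if opts.box_max is not None else efflux_upper_bound(params)
    X = np.clip(seeds.copy(), 0.0, 1.5 * box)
    active = np.ones(len(X), dtype=bool)
    max_step = 0.25 * max(box, 1e-6)
    for _ in range(opts.max_newton_iter):
        if not active.any():
            break
        E, F = X[active, 0], X[active, 1]
        rE, rF = efflux_rates_arrays(E, F, params)
        res = np.hypot(rE, rF)
        J = efflux_jacobian_arrays(E, F, params)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        ok = np.abs(det) > 1e-14
        dE = np.where(ok, -(rE * J[:, 1, 1] - rF * J[:, 0, 1]) / np.where(ok, det, 1.0), 0.0)
        dF = np.where(ok, -(J[:, 0, 0] * rF - J[:, 1, 0] * rE) / np.where(ok, det, 1.0), 0.0)
        norm = np.hypot(dE, dF)
        scale = np.where(norm > max_step, max_step / np.where(norm > 0, norm, 1.0), 1.0)
        Xa = X[active]
        Xa[:, 0] = np.clip(Xa[:, 0] + scale * dE, 0.0, 1.5 * box)
        Xa[:, 1] = np.clip(Xa[:, 1] + scale * dF, 0.0, 1.5 * box)
        X[active] = Xa
        still = (res > 0.01 * opts.residual_tol) & ok
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    rE, rF = efflux_rates_arrays(X[:, 0], X[:, 1], params)
    res = np.hypot(rE, rF)
    keep = (res <= opts.residual_tol) & (X[:, 0] >= -1e-9) & (X[:, 1] >= -1e-9)
    return np.clip(X[keep], 0.0, None)


def _dedup(points: np.ndarray, radius: float) -> np.ndarray:
    out: list[np.ndarray] = []
    for pt in points:
        if not any(np.hypot(pt[0] - q[0], pt[1] - q[1]) <= radius for q in out):
            out.append(pt)
    return np.asarray(out) if out else np.empty((0, 2))


def classify_stability(
    point: tuple[float, float],
    params: ModelParameters,
    eps_margin: float = 1e-8,
) -> str:
    """'stable' iff all Jacobian eigenvalue real parts are below -eps_margin.

    Marginal points (real part within eps_margin of 0) and saddles are
    labeled 'unstable', preserving the binary labeling.
    """
    J = efflux_jacobian_arrays(
        np.asarray(point[0], dtype=float), np.asarray(point[1], dtype=float), params
    )
    eig = np.linalg.eigvals(J)
    return "stable" if np.max(eig.real) < -eps_margin else "unstable"


def find_steady_states(
    params: ModelParameters, options: SteadyStateOptions | None = None
) -> SteadyStateSet:
    """Locate all fixed points of the efflux subsystem and label stability.

    Raises
    ------
    EmptySteadyStateSetError
        If no Newton start converges (callers building maps may treat the
        cell as failed and later repair it from its neighbors).
    """
    opts = options or SteadyStateOptions()
    seeds = _candidate_seeds(params, opts)
    converged = _newton_polish(seeds, params, opts)
    if len(converged) == 0:
        raise EmptySteadyStateSetError(
            f"no fixed point found for v0={params.v0}, mu={params.mu}"
        )
    # swap closure, then dedup
    swapped = converged[:, ::-1]
    pts = _dedup(np.vstack([converged, swapped]), opts.dedup_radius)
    J = efflux_jacobian_arrays(pts[:, 0], pts[:, 1], params)
    eig = np.linalg.eigvals(J)
    states = []
    for (E, F), ev in zip(pts, eig):
        stable = bool(np.max(ev.real) < -opts.eps_margin)
        states.append(SteadyState(float(E), float(F), stable, (complex(ev[0]), complex(ev[1]))))
    states.sort(key=lambda s: (s.E + s.F, s.E))
    return SteadyStateSet(tuple(states), params, opts.residual_tol)


def classify_behavior(sset: SteadyStateSet, sym_tol: float = 1e-5) -> BehaviorClass:
    """Map a steady-state set onto one of the six behavior classes.

    Only stable points matter. Symmetric states (E* = F*) are read as "both
    buds reach this efflux"; asymmetric swap-pairs as "one bud wins".
    """
    stable = sset.stable_points
    sym = [p for p in stable if abs(p.E - p.F) <= sym_tol]
    asym = [p for p in stable if abs(p.E - p.F) > sym_tol]
    n_pairs, seen = 0, []
    for p in asym:
        if any(abs(p.E - q.F) <= sym_tol and abs(p.F - q.E) <= sym_tol for q in seen):
            continue
        seen.append(p)
        n_pairs += 1

    if len(sym) == 1 and n_pairs == 0:
        return BEHAVIOR_CLASSES[1 if sym[0].value >= ACTIVATION_THRESHOLD else 6]
    if len(sym) == 1 and n_pairs >= 1:
        return BEHAVIOR_CLASSES[2 if sym[0].value >= COEXISTENCE_THRESHOLD else 4]
    if len(sym) == 0 and n_pairs >= 1:
        return BEHAVIOR_CLASSES[3]
    if len(sym) == 2 and n_pairs >= 1:
        values = sorted(p.value for p in sym)
        if values[1] >= ACTIVATION_THRESHOLD and values[0] < ACTIVATION_THRESHOLD:
            return BEHAVIOR_CLASSES[5]
    raise UnclassifiableBehaviorError(
        f"stable configuration outside the six-class table: "
        f"{len(sym)} symmetric state(s) at {[round(p.value, 4) for p in sym]}, "
        f"{n_pairs} asymmetric pair(s)"
    )


def nullclines(
    params: ModelParameters,
    E_range: tuple[float, float] | None = None,
    F_range: tuple[float, float] | None = None,
    resolution: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Point sets tracing dE/dt = 0 and dF/dt = 0 in the (E, F) plane.

    For each value of the partner coordinate the rate equation is a
    univariate polynomial (integer Hill exponent) whose real nonnegative
    roots give the nullcline's branches; non-integer exponents fall back to
    sign-change bracketing with bisection.

    Returns two arrays of (E, F) points.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    box = efflux_upper_bound(params)
    E_range = E_range or (0.0, box)
    F_range = F_range or (0.0, box)
    p = params
    n_int = int(round(p.n))
    is_poly = abs(p.n - n_int) < 1e-12 and n_int >= 1

    def branch(partner_vals: np.ndarray, own_range: tuple[float, float]):
        pts = []
        if is_poly:
            Sn = p.S**n_int
            base = np.zeros(n_int + 1)
            base[0] = Sn
            rows = np.empty((len(partner_vals), n_int + 2))
            for i, y in enumerate(partner_vals):
                # (v0 - mu x)((Sx)^n + (D x + (D y + K))^n) + v (Sx)^n = 0
                den = base + _binom_poly(p.D, p.D * y + p.K, n_int)
                poly = np.convolve([-p.mu, p.v0], den)
                poly[1:] += p.v * base
                rows[i] = poly
            for y, roots in zip(partner_vals, _roots_batch(rows)):
                for x in roots:
                    if own_range[0] - 1e-12 <= x <= own_range[1] + 1e-12:
                        pts.append((x, y))
        else:
            from scipy.optimize import brentq

            xs = np.linspace(own_range[0], own_range[1], 4 * resolution)
            for y in partner_vals:
                vals = efflux_rates_arrays(xs, np.full_like(xs, y), p)[0]
                sign = np.sign(vals)
                for i in np.flatnonzero(np.diff(sign) != 0):
                    root = brentq(
                        lambda x: float(
                            efflux_rates_arrays(
                                np.asarray(x), np.asarray(y), p
                            )[0]
                        ),
                        xs[i],
                        xs[i + 1],
                    )
                    pts.append((root, y))
        return np.asarray(pts) if pts else np.empty((0, 2))

    F_vals = np.linspace(F_range[0], F_range[1], resolution)
    E_vals = np.linspace(E_range[0], E_range[1], resolution)
    de_zero = branch(F_vals, E_range)  # points (E, F) with dE/dt = 0
    fe = branch(E_vals, F_range)  # solved for F given E, returned as (F, E)
    df_zero = fe[:, ::-1] if len(fe) else fe
    return de_zero, df_zero
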