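"""Steady-state finder, stability labels, behavior classes, nullclines."""

import numpy as np
import pytest

from twobud import (
    BEHAVIOR_CLASSES,
    ModelParameters,
    SteadyState,
    SteadyStateOptions,
    SteadyStateSet,
    UnclassifiableBehaviorError,
    classify_behavior,
    classify_stability,
    find_steady_states,
    nullclines,
    simulate,
)
from twobud.model import ExplantState, efflux_rates_arrays, efflux_upper_bound
from twobud.steadystate import EmptySteadyStateSetError

from conftest import random_params


def bisect_symmetric_roots(params, box, n_grid=4000, tol=1e-12):
    """Brute-force oracle: sign-change bracketing + bisection on E = F."""
    xs = np.linspace(0.0, box, n_grid)
    vals = efflux_rates_arrays(xs, xs, params)[0]
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
        lo, hi = xs[i], xs[i + 1]
        flo = vals[i]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fmid = float(efflux_rates_arrays(np.asarray(mid), np.asarray(mid), params)[0])
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
            if hi - lo < tol:
                break
        roots.append(0.5 * (lo + hi))
    return roots


class TestFindSteadyStates:
    def test_linear_model_single_point(self):
        p = ModelParameters(v0=0.08, v=0.0, mu=0.4, K=0.2)
        sset = find_steady_states(p)
        assert len(sset.points) == 1
        pt = sset.points[0]
        assert pt.E == pytest.approx(0.2, abs=1e-9)
        assert pt.F == pytest.approx(0.2, abs=1e-9)
        assert pt.stable

    def test_residuals_below_tolerance(self, params):
        sset = find_steady_states(params)
        for pt in sset.points:
            dE, dF = efflux_rates_arrays(np.asarray(pt.E), np.asarray(pt.F), params)
            assert np.hypot(dE, dF) <= sset.tolerance

    def test_swap_closure(self, params):
        sset = find_steady_states(params)
        for pt in sset.points:
            if abs(pt.E - pt.F) > 1e-6:
                partner = [
                    q
                    for q in sset.points
                    if abs(q.E - pt.F) < 1e-6 and abs(q.F - pt.E) < 1e-6
                ]
                assert len(partner) == 1
                assert partner[0].stable == pt.stable

    def test_symmetric_roots_match_bisection_oracle(self, rng):
        """Diagonal fixed points agree with bracketing-bisection to 1e-8
        on 25 random parameter sets."""
        for _ in range(25):
            p = random_params(rng)
            sset = find_steady_states(p)
            found = sorted(pt.E for pt in sset.points if abs(pt.E - pt.F) <= 1e-6)
            oracle = bisect_symmetric_roots(p, efflux_upper_bound(p))
            assert len(found) == len(oracle)
            for a, b in zip(found, sorted(oracle)):
                assert a == pytest.approx(b, abs=1e-8)

    def test_attractors_of_random_starts_are_found(self, rng):
        """Endpoints of long simulations from random starts land within
        1e-4 of a returned stable point."""
        from twobud.simulate import integrate_batch

        for _ in range(5):
            p = random_params(rng)
            sset = find_steady_states(p)
            stable = np.array([(q.E, q.F) for q in sset.stable_points])
            assert len(stable) > 0
            box = efflux_upper_bound(p)
            starts = rng.uniform(0, box, size=(40, 2))
            init_rows = np.hstack([starts, np.zeros_like(starts)])
            _, finals, _ = integrate_batch(
                p, None, 400, 0.1, record=False, init_states=init_rows
            )
            for end in finals[:, :2]:
                dists = np.hypot(stable[:, 0] - end[0], stable[:, 1] - end[1])
                assert dists.min() < 1e-4

    def test_search_density_robustness(self, params):
        dense = SteadyStateOptions(lattice_density=20, t_scan=96)
        a = find_steady_states(params)
        b = find_steady_states(params, dense)
        assert len(a.points) == len(b.points)


class TestStability:
    def test_linear_model_stable(self):
        p = ModelParameters(v=0.0, mu=0.9, K=0.2)
        assert classify_stability((p.v0 / p.mu, p.v0 / p.mu), p) == "stable"

    def test_stable_point_attracts_perturbation(self, params):
        sset = find_steady_states(params)
        pt = sset.stable_points[0]
        start = ExplantState(E=pt.E + 1e-3, F=max(pt.F - 1e-3, 0.0), N=0, M=0)
        traj = simulate(params.with_updates(eta=0.0), start, t_end=300, dt=0.1)
        end = traj.values[-1, :2]
        assert np.hypot(end[0] - pt.E, end[1] - pt.F) < 1e-4

    def test_unstable_point_repels_along_eigenvector(self, params):
        sset = find_steady_states(params)
        unstable = [
            q for q in sset.points
            if not q.stable and max(ev.real for ev in q.eigenvalues) > 1e-3
        ]
        assert unstable, "calibrated cell should have a saddle"
        pt = unstable[0]
        from twobud.model import efflux_jacobian

        J = efflux_jacobian(pt.E, pt.F, params)
        w, vecs = np.linalg.eig(J)
        direction = np.real(vecs[:, np.argmax(w.real)])
        start = np.clip(np.array([pt.E, pt.F]) + 1e-3 * direction, 0, None)
        traj = simulate(
            params.with_updates(eta=0.0),
            ExplantState(E=start[0], F=start[1], N=0, M=0),
            t_end=120,
            dt=0.1,
        )
        end = traj.values[-1, :2]
        assert np.hypot(end[0] - pt.E, end[1] - pt.F) > 1e-2


def sym(value, stable=True):
    return SteadyState(value, value, stable, (-1 + 0j, -1 + 0j))


def pair(a, b, stable=True):
    return [
        SteadyState(a, b, stable, (-1 + 0j, -1 + 0j)),
        SteadyState(b, a, stable, (-1 + 0j, -1 + 0j)),
    ]


def sset_of(points, params):
    return SteadyStateSet(tuple(points), params, 1e-10)


class TestClassifyBehavior:
    """The six-class table driven by the 0.4 / 0.24 thresholds."""

    @pytest.mark.parametrize(
        "points,expected",
        [
            ([sym(0.6)], 1),
            ([sym(0.39)], 6),
            ([sym(0.10)], 6),
            ([sym(0.30)] + pair(0.7, 0.05), 2),
            ([sym(0.24)] + pair(0.7, 0.05), 2),
            ([sym(0.10)] + pair(0.7, 0.05), 4),
            (pair(0.8, 0.03), 3),
            ([sym(0.05), sym(0.7)] + pair(0.8, 0.02), 5),
        ],
    )
    def test_classification_table(self, points, expected, params):
        assert classify_behavior(sset_of(points, params)).class_id == expected

    def test_unstable_points_ignored(self, params):
        points = [sym(0.6), sym(0.3, stable=False)]
        assert classify_behavior(sset_of(points, params)).class_id == 1

    def test_outside_table_raises(self, params):
        points = [sym(0.1), sym(0.2)] + pair(0.8, 0.02)  # two low symmetric
        with pytest.raises(UnclassifiableBehaviorError):
            classify_behavior(sset_of(points, params))

    def test_class_metadata(self):
        assert BEHAVIOR_CLASSES[1].color_role == "yellow"
        assert BEHAVIOR_CLASSES[6].color_role == "red"
        assert BEHAVIOR_CLASSES[5].description == "all four outcomes"


class TestNullclines:
    def test_linear_model_vertical_line(self):
        p = ModelParameters(v0=0.08, v=0.0, mu=0.4, K=0.2)
        de_zero, _ = nullclines(p, (0.0, 1.0), (0.0, 1.0), resolution=50)
        assert np.allclose(de_zero[:, 0], 0.2, atol=1e-9)

    def test_points_satisfy_rate_residual(self, params):
        de_zero, df_zero = nullclines(params, resolution=60)
        dE = efflux_rates_arrays(de_zero[:, 0], de_zero[:, 1], params)[0]
        assert np.max(np.abs(dE)) < 1e-8
        dF = efflux_rates_arrays(df_zero[:, 0], df_zero[:, 1], params)[1]
        assert np.max(np.abs(dF)) < 1e-8

    def test_intersections_near_fixed_points(self, params):
        """Every fixed point has nearby points on both nullclines."""
        res = 150
        box = efflux_upper_bound(params)
        cell = box / (res - 1)
        de_zero, df_zero = nullclines(params, (0, box), (0, box), resolution=res)
        sset = find_steady_states(params)
        for pt in sset.points:
            for branch in (de_zero, df_zero):
                d = np.hypot(branch[:, 0] - pt.E, branch[:, 1] - pt.F)
                assert d.min() < 2 * cell

    def test_rejects_degenerate_resolution(self, params):
        with pytest.raises(ValueError):
            nullclines(params, resolution=1)


def test_empty_set_error_message():
    with pytest.raises(EmptySteadyStateSetError):
        raise EmptySteadyStateSetError("no fixed point found for v0=1, mu=1")
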