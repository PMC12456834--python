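"""Parameter-space maps: behavior classes, outcome fractions, boundaries,
pixel repair, heatmaps, sensitivity scans."""

import warnings

import numpy as np
import pytest

from twobud import DEFAULT_PARAMS, ModelParameters
from twobud.paramspace import (
    GridMap,
    behavior_map,
    cell_seed,
    mark_boundaries,
    metric_heatmaps,
    outcome_fraction_map,
    render_rgb,
    repair_pixels,
    sensitivity_scan,
)


def tiny_map(counts, class_id=None, payload="behavior", **channels):
    counts = np.asarray(counts)
    cells = {"n_stable": counts, "class_id": np.ones_like(counts) if class_id is None else np.asarray(class_id)}
    cells.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return GridMap(
        np.linspace(0.01, 0.1, counts.shape[0]),
        np.linspace(0.3, 1.0, counts.shape[1]),
        payload,
        cells,
    )


class TestBehaviorMap:
    def test_single_cell_monostable_low_is_class6(self):
        p = ModelParameters(v0=0.05, v=0.0, mu=0.5, K=0.2, eta=0)  # v0/mu = 0.1 < 0.4
        gmap = behavior_map(np.array([0.05]), np.array([0.5]), p)
        assert gmap.cells["class_id"][0, 0] == 6
        assert gmap.cells["n_stable"][0, 0] == 1

    def test_uniform_region_has_no_boundaries(self, params):
        v0 = np.linspace(0.08, 0.10, 3)
        mu = np.linspace(0.55, 0.65, 3)  # deep region 2
        gmap = behavior_map(v0, mu, params)
        assert np.all(gmap.cells["class_id"] == gmap.cells["class_id"][0, 0])
        assert not gmap.boundary_mask.any()

    def test_rejects_unsorted_axes(self, params):
        with pytest.raises(ValueError):
            behavior_map(np.array([0.1, 0.05]), np.array([0.5]), params)

    def test_region_sequence_along_mu(self, params):
        """At mid v0 the class sequence along rising mu is 2 -> (3/4) -> 6."""
        mu = np.array([0.4, 2.8, 4.0, 5.8])
        gmap = behavior_map(np.array([0.09]), mu, params)
        assert list(gmap.cells["class_id"][0]) == [2, 3, 4, 6]


class TestMarkBoundaries:
    def test_uniform_field_empty_mask(self):
        gmap = mark_boundaries(tiny_map(np.ones((4, 4), dtype=int)))
        assert not gmap.boundary_mask.any()

    def test_vertical_interface_marks_interior_cells(self):
        counts = np.ones((4, 4), dtype=int)
        counts[:, 2:] = 3
        gmap = mark_boundaries(tiny_map(counts))
        # every cell in columns 1 and 2 sees >= 2 differing 8-neighbors
        assert gmap.boundary_mask[:, 1].all()
        assert gmap.boundary_mask[:, 2].all()
        assert not gmap.boundary_mask[:, 0].any()
        assert not gmap.boundary_mask[:, 3].any()

    def test_single_differing_neighbor_not_marked(self):
        counts = np.ones((3, 3), dtype=int)
        counts[0, 0] = 3  # corner differs; its neighbors see only 1 difference
        gmap = mark_boundaries(tiny_map(counts))
        assert not gmap.boundary_mask[0, 1]
        assert not gmap.boundary_mask[1, 0]
        # the corner itself sees 3 differing neighbors
        assert gmap.boundary_mask[0, 0]


class TestRepairPixels:
    def test_identical_neighbors_copy_value(self):
        gmap = tiny_map(np.full((3, 3), 1, dtype=int))
        gmap.cells["class_id"][:] = 1
        gmap.failure_mask = np.zeros((3, 3), dtype=bool)
        gmap.failure_mask[1, 1] = True
        repaired = repair_pixels(gmap)
        assert repaired.cells["class_id"][1, 1] == 1
        assert not repaired.failure_mask.any()
        assert (1, 1) in repaired.provenance["repaired_cells"]

    def test_fraction_cell_takes_neighbor_mean(self):
        p_both = np.array([[1.0, 0.5, 0.0]])
        p_one = np.array([[0.0, 0.5, 1.0]])
        p_none = np.zeros((1, 3))
        gmap = tiny_map(
            np.ones((1, 3), dtype=int), payload="outcome",
            p_both=p_both, p_one=p_one, p_none=p_none,
        )
        gmap.failure_mask = np.array([[False, True, False]])
        repaired = repair_pixels(gmap)
        assert repaired.cells["p_both"][0, 1] == pytest.approx(0.5)
        assert repaired.cells["p_one"][0, 1] == pytest.approx(0.5)
        assert repaired.cells["p_none"][0, 1] == pytest.approx(0.0)

    def test_no_failures_is_identity(self):
        gmap = tiny_map(np.ones((2, 2), dtype=int))
        before = {k: v.copy() for k, v in gmap.cells.items()}
        repaired = repair_pixels(gmap)
        for k in before:
            assert np.array_equal(repaired.cells[k], before[k])

    def test_isolated_failure_stays_failed_with_warning(self):
        gmap = tiny_map(np.ones((1, 1), dtype=int))
        gmap.failure_mask = np.array([[True]])
        with pytest.warns(UserWarning):
            repaired = repair_pixels(gmap)
        assert repaired.failure_mask[0, 0]


class TestOutcomeFractionMap:
    @pytest.fixture(scope="class")
    def small_map(self, params=DEFAULT_PARAMS):
        v0 = np.linspace(0.02, 0.14, 6)
        mu = np.linspace(0.3, 5.5, 6)
        return outcome_fraction_map(v0, mu, params, n_sims=25, t_end=120, base_seed=3)

    def test_fractions_sum_to_one(self, small_map):
        total = (
            small_map.cells["p_both"]
            + small_map.cells["p_one"]
            + small_map.cells["p_none"]
        )
        assert np.allclose(total[~small_map.failure_mask], 1.0)

    def test_degenerate_classes_forced_without_simulation(self, small_map):
        cid = small_map.cells["class_id"]
        for mono, key in ((3, "p_one"), (6, "p_none")):
            cells = cid == mono
            if cells.any():
                assert np.all(small_map.cells[key][cells] == 1.0)

    def test_outcome_gradient_polarity(self, small_map):
        """p_both is highest toward high v0 / low mu, p_none toward the
        opposite corner."""
        assert small_map.cells["p_both"][-1, 0] > small_map.cells["p_both"][0, -1]
        assert small_map.cells["p_none"][0, -1] > small_map.cells["p_none"][-1, 0]

    def test_seed_policy_reproducible(self, params):
        v0 = np.linspace(0.06, 0.1, 2)
        mu = np.linspace(0.5, 0.8, 2)
        a = outcome_fraction_map(v0, mu, params, n_sims=10, t_end=60, base_seed=5)
        b = outcome_fraction_map(v0, mu, params, n_sims=10, t_end=60, base_seed=5)
        for key in ("p_both", "p_one", "p_none"):
            assert np.array_equal(a.cells[key], b.cells[key])

    def test_independent_seeds_agree_within_binomial_ci(self, params):
        """Two independent maps of one deep region-2 cell agree on p_both
        within the 99% binomial interval (n=200 each)."""
        v0, mu = np.array([0.09]), np.array([0.6])
        a = outcome_fraction_map(v0, mu, params, n_sims=200, t_end=120, base_seed=1)
        b = outcome_fraction_map(v0, mu, params, n_sims=200, t_end=120, base_seed=10**6)
        pa, pb = a.cells["p_both"][0, 0], b.cells["p_both"][0, 0]
        pool = 0.5 * (pa + pb)
        half = 2.576 * np.sqrt(2 * pool * (1 - pool) / 200)
        assert abs(pa - pb) <= half + 1e-12

    def test_cell_seed_formula(self):
        assert cell_seed(7, i=2, j=3, r=5, n_sims=100, n_cols=10) == 7 + 5 + 100 * (3 + 20)


class TestMetricHeatmaps:
    def test_lag_gradient_and_missing_cells(self, params):
        v0 = np.array([0.01, 0.09])
        mu = np.array([0.6, 5.5])
        lag_map, rate_map = metric_heatmaps(v0, mu, params, n_sims=10, t_end=120, base_seed=2)
        # low-v0 cells switch later than high-v0 cells at the same mu
        assert lag_map.cells["value"][0, 0] > lag_map.cells["value"][1, 0]
        # nothing activates deep in the neither-region: explicit missing value
        assert np.isnan(lag_map.cells["value"][1, 1])
        assert np.isnan(rate_map.cells["value"][1, 1])

    def test_max_rate_bounded_by_growth_hill(self, params):
        _, rate_map = metric_heatmaps(
            np.array([0.09]), np.array([0.6]), params, n_sims=10, t_end=120, base_seed=4
        )
        vals = rate_map.cells["value"]
        assert np.all(vals[np.isfinite(vals)] <= 1.0 + 1e-9)

    def test_zero_noise_collapses_to_deterministic_lag(self, det_params):
        from twobud import canalization_switch_time, simulate

        lag_map, _ = metric_heatmaps(
            np.array([det_params.v0]), np.array([det_params.mu]), det_params,
            n_sims=3, t_end=120, base_seed=0,
        )
        traj = simulate(det_params, t_end=120, dt=0.1)
        t_det = canalization_switch_time(traj)
        # unit-step sampled extraction matches the deterministic switch to
        # within the 1-step sampling resolution
        assert lag_map.cells["value"][0, 0] == pytest.approx(t_det, abs=1.0)


class TestSensitivityScan:
    def test_zero_fraction_is_identity(self, params):
        v0 = np.linspace(0.07, 0.1, 2)
        mu = np.linspace(0.5, 0.7, 2)
        base = behavior_map(v0, mu, params)
        scan = sensitivity_scan(
            behavior_map, params, fraction=0.0, parameters=("S", "D"),
            v0_values=v0, mu_values=mu,
        )
        for gmap in scan.values():
            assert np.array_equal(gmap.cells["class_id"], base.cells["class_id"])

    def test_swept_axes_are_skipped(self, params):
        with pytest.warns(UserWarning):
            scan = sensitivity_scan(
                behavior_map, params, parameters=("mu",),
                v0_values=np.array([0.09]), mu_values=np.array([0.6]),
            )
        assert scan == {}

    def test_small_perturbation_keeps_deep_interior_classes(self, params):
        """At a 0.1% perturbation, deep-interior cells keep their class."""
        v0 = np.linspace(0.06, 0.12, 5)
        mu = np.linspace(0.4, 0.8, 5)  # deep region 2
        base = behavior_map(v0, mu, params)
        scan = sensitivity_scan(
            behavior_map, params, fraction=0.001, parameters=("S", "v"),
            v0_values=v0, mu_values=mu,
        )
        interior = ~base.boundary_mask
        for gmap in scan.values():
            same = gmap.cells["class_id"][interior] == base.cells["class_id"][interior]
            assert same.mean() >= 0.99


def test_render_rgb_blends_and_marks_boundaries():
    p_both = np.array([[0.7, 1.0]])
    p_one = np.array([[0.3, 0.0]])
    p_none = np.zeros((1, 2))
    gmap = tiny_map(
        np.array([[3, 1]]), payload="outcome",
        p_both=p_both, p_one=p_one, p_none=p_none,
    )
    gmap.boundary_mask = np.array([[False, True]])
    img = render_rgb(gmap)
    from twobud.paramspace import _RGB

    expected = 0.7 * _RGB["both"] + 0.3 * _RGB["one"]
    assert np.allclose(img[0, 0], expected)
    assert np.allclose(img[0, 1], 0.0)  # boundary painted black
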