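"""Genotype placement: matching, constraints, predictions, SIP1 slice."""

import numpy as np
import pytest

from twobud import DEFAULT_PARAMS
from twobud.genotypes import (
    ConstraintSet,
    GenotypeObservation,
    InfeasiblePlacementError,
    Placement,
    default_constraints,
    match_region,
    match_tolerance,
    place_genotypes,
    predict_metrics,
    sip1_slice,
)
from twobud.paramspace import GridMap
from twobud.traces import OutcomeFractions


def fraction_map(p_both, class_id=None, n_sims=100):
    """A synthetic outcome GridMap from a p_both lattice (p_none = 0)."""
    p_both = np.asarray(p_both, dtype=float)
    cells = {
        "p_both": p_both,
        "p_one": 1.0 - p_both,
        "p_none": np.zeros_like(p_both),
        "class_id": np.full(p_both.shape, 2) if class_id is None else np.asarray(class_id),
        "n_stable": np.full(p_both.shape, 3),
    }
    return GridMap(
        np.linspace(0.01, 0.14, p_both.shape[0]),
        np.linspace(0.3, 2.0, p_both.shape[1]),
        "outcome",
        cells,
        provenance={"n_sims": n_sims},
    )


def obs(label, p_both, n=100, **kw):
    return GenotypeObservation(
        label, OutcomeFractions(p_both, 1.0 - p_both, 0.0), n, **kw
    )


class TestMatchRegion:
    def test_exact_match_at_zero_tolerance(self):
        gmap = fraction_map([[1.0, 0.4], [0.4, 0.0]])
        cells = match_region(obs("x", 1.0), gmap, tolerance=0.0)
        assert cells == {(0, 0)}

    def test_vacuous_tolerance_matches_everything(self):
        gmap = fraction_map([[1.0, 0.4], [0.4, 0.0]])
        assert len(match_region(obs("x", 0.6), gmap, tolerance=1.0)) == 4

    def test_default_tolerance_scales_with_n(self):
        loose = match_tolerance(obs("x", 0.5, n=25))
        tight = match_tolerance(obs("x", 0.5, n=400))
        assert loose == pytest.approx(4 * tight, rel=1e-6)

    def test_rejects_non_outcome_map(self):
        gmap = fraction_map([[0.5]])
        gmap.payload = "behavior"
        with pytest.raises(ValueError):
            match_region(obs("x", 0.5), gmap)


class TestConstraintSet:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(mu_groups=(frozenset({"a", "b"}), frozenset({"b", "c"})))

    def test_cyclic_orderings_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(v0_order=(("a", "b"), ("b", "a")))

    def test_default_panel_is_consistent(self):
        c = default_constraints()
        assert frozenset({"Col-0", "brc1brc2"}) in c.mu_groups
        assert any("d14" in g for g in c.v0_groups)


class TestPlaceGenotypes:
    def test_single_label_single_cell(self):
        gmap = fraction_map(np.linspace(0, 1, 25).reshape(5, 5))
        regions = {"x": {(2, 3)}}
        placement = place_genotypes(regions, ConstraintSet(), gmap)
        assert placement.indices["x"] == (2, 3)
        assert placement.scores["x"] == 0.0

    def test_equality_group_forces_common_column(self):
        gmap = fraction_map(np.tile(np.linspace(1, 0, 6), (6, 1)))
        regions = {"a": {(1, 2)}, "b": {(4, 2)}}
        constraints = ConstraintSet(mu_groups=(frozenset({"a", "b"}),))
        placement = place_genotypes(regions, constraints, gmap)
        assert placement.indices["a"][1] == placement.indices["b"][1]

    def test_ordering_violation_raises(self):
        gmap = fraction_map(np.tile(np.linspace(1, 0, 6), (6, 1)))
        placement = Placement(
            positions={"a": (0.01, 0.3), "b": (0.01, 0.3)},
            indices={"a": (0, 3), "b": (0, 1)},
            scores={"a": 0, "b": 0},
            constraints=ConstraintSet(mu_order=(("a", "b"),)),
        )
        with pytest.raises(InfeasiblePlacementError):
            placement.verify_constraints()

    def test_infeasible_chain_longer_than_axis(self):
        gmap = fraction_map(np.zeros((1, 2)) + 0.5)
        regions = {"a": {(0, 0)}, "b": {(0, 0)}, "c": {(0, 1)}}
        constraints = ConstraintSet(mu_order=(("a", "b"), ("b", "c")))
        with pytest.raises(InfeasiblePlacementError):
            place_genotypes(regions, constraints, gmap)

    def test_manual_positions_respected(self):
        gmap = fraction_map(np.zeros((4, 4)) + 0.5)
        placement = place_genotypes(
            {"x": set()}, ConstraintSet(), gmap, manual_positions={"x": (1, 2)}
        )
        assert placement.indices["x"] == (1, 2)
        assert placement.positions["x"] == (
            pytest.approx(gmap.v0_values[1]),
            pytest.approx(gmap.mu_values[2]),
        )

    def test_likelihood_cost_pins_best_matching_cell(self):
        """With a graded p_both field, the observation lands on the cell
        whose fractions it matches best, not merely inside a region."""
        field = np.tile(np.linspace(0.0, 1.0, 11), (3, 1))
        gmap = fraction_map(field)
        o = obs("x", 0.7, n=400)
        regions = {"x": match_region(o, gmap)}
        placement = place_genotypes(regions, ConstraintSet(), gmap, observations={"x": o})
        assert placement.indices["x"][1] == 7


class TestPredictMetrics:
    def test_deep_both_cell_predicts_p_both(self, params):
        placement = Placement(
            positions={"wt": (0.135, 0.35)}, indices={"wt": (0, 0)},
            scores={"wt": 0.0}, constraints=ConstraintSet(),
        )
        pred = predict_metrics(placement, params, n_sims=60, t_end=120, base_seed=1)
        assert pred["wt"].fractions.p_both >= 0.95
        assert len(pred["wt"].rgis) == 60
        assert np.all(pred["wt"].max_rates <= 1.0 + 1e-9)

    def test_deterministic_replicates_identical(self, det_params):
        placement = Placement(
            positions={"wt": (0.09, 0.6)}, indices={"wt": (0, 0)},
            scores={"wt": 0.0}, constraints=ConstraintSet(),
        )
        pred = predict_metrics(placement, det_params, n_sims=5, t_end=60, base_seed=0)
        assert len(set(np.round(pred["wt"].lags, 12))) == 1
        mit = pred["wt"].mitchison
        finals = mit.groupby("explant_id")["top"].last()
        assert finals.nunique() == 1


class TestSip1Slice:
    def make_placement(self):
        return Placement(
            positions={
                "Col-0": (0.09, 0.6),
                "Col-0+GR24": (0.055, 1.1),
                "smxl678": (0.03, 1.6),
            },
            indices={"Col-0": (0, 0), "Col-0+GR24": (0, 0), "smxl678": (0, 0)},
            scores={},
            constraints=ConstraintSet(),
        )

    def test_s_reduced_by_default_20_percent(self, params):
        new_params, _ = sip1_slice(params, self.make_placement(), d14_mu=0.35)
        assert new_params.S == pytest.approx(0.8 * params.S)

    def test_zero_reduction_is_identity(self, params):
        new_params, _ = sip1_slice(params, self.make_placement(), d14_mu=0.35, s_reduction=0.0)
        assert new_params == params

    def test_sip1_lines_share_d14_mu_with_decreasing_v0(self, params):
        _, positions = sip1_slice(params, self.make_placement(), d14_mu=0.35)
        mus = {mu for _, mu in positions.values()}
        assert mus == {0.35}
        series = ["SIP1pin1", "SIP1pin1+GR24", "SIP1pin1smxl678"]
        v0s = [positions[label][0] for label in series]
        assert v0s[0] > v0s[1] > v0s[2]

    def test_missing_background_raises(self, params):
        placement = Placement(
            positions={"Col-0": (0.09, 0.6)}, indices={}, scores={},
            constraints=ConstraintSet(),
        )
        with pytest.raises(KeyError):
            sip1_slice(params, placement, d14_mu=0.35)
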