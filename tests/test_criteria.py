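"""Gini / CLF criteria, candidate shifts and anchor point selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorpoint import (
    candidate_shifts,
    clf_criterion,
    distances,
    find_local_optima,
    gini_index,
    make_toy,
    search_interval,
    select_anchor_point,
)

from _oracles import criterion_on_grid, gini_pairwise

nonneg_vectors = st.lists(
    st.floats(min_value=0, max_value=50, allow_nan=False), min_size=2, max_size=12
).map(np.array)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_distances_identity_symmetry_and_toy(toy_pair):
    b1, b2 = toy_pair
    assert np.allclose(distances(b1, b1, 0.0).d, 0.0)
    d = distances(b1, b2, 0.0).d
    expected = np.zeros(10)
    expected[3] = 0.75
    assert np.allclose(d, expected)
    assert np.allclose(distances(b1, b2, 0.3).d, distances(b2, b1, -0.3).d)
    with pytest.raises(ValueError):
        distances(b1, b2[:-1], 0.0)


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------


def test_gini_single_nonzero_reaches_maximum():
    d = np.zeros(10)
    d[4] = 0.75
    assert gini_index(d) == pytest.approx(1 - 1 / 10)
    d[4] = 1.5  # independent of magnitude
    assert gini_index(d) == pytest.approx(0.9)


def test_gini_perfect_equality_is_zero():
    assert gini_index(np.full(7, 3.2)) == pytest.approx(0.0)
    assert gini_index(np.zeros(5)) == 0.0


def test_gini_hand_value():
    assert gini_index(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(0.25)


@settings(deadline=None, max_examples=100)
@given(nonneg_vectors)
def test_gini_rank_formula_equals_pairwise_form(d):
    assert gini_index(d) == pytest.approx(gini_pairwise(d), abs=1e-12)


@settings(deadline=None, max_examples=50)
@given(nonneg_vectors, st.floats(min_value=1e-3, max_value=1e3))
def test_gini_scale_invariance_and_bounds(d, k):
    gi = gini_index(d)
    assert gi == pytest.approx(gini_index(k * d), abs=1e-10)
    assert -1e-12 <= gi <= 1 - 1 / d.size + 1e-12


def test_gini_rejects_negative_entries():
    with pytest.raises(ValueError):
        gini_index(np.array([1.0, -0.1]))


# ---------------------------------------------------------------------------
# CLF criterion
# ---------------------------------------------------------------------------


def test_clf_values_and_epsilon():
    assert clf_criterion(np.zeros(6)) == 0.0
    d = np.zeros(10)
    d[3] = 0.75
    assert clf_criterion(d) == pytest.approx(-0.75)
    assert clf_criterion(np.array([1.0, 2, 3, 4])) == pytest.approx(-10.0)
    assert clf_criterion(np.array([3.0, 4.0]), epsilon=0.0) == pytest.approx(-7.0)
    # smoothed form: -sum sqrt(d^2 + eps)
    assert clf_criterion(np.array([0.0]), epsilon=0.25) == pytest.approx(-0.5)
    with pytest.raises(ValueError):
        clf_criterion(np.array([1.0]), epsilon=-1e-6)


# ---------------------------------------------------------------------------
# interval and candidates
# ---------------------------------------------------------------------------


def test_search_interval_formula():
    b1 = np.array([-2.0, 0.0, 2.0])
    b2 = np.array([-1.0, 1.0, 3.0])
    assert search_interval(b1, b2) == (-5.0, 3.0)
    lo, hi = search_interval(b1, b1)
    assert lo == -hi == -4.0
    assert search_interval(np.array([1.3]), np.array([0.2])) == pytest.approx((1.1, 1.1))


def test_candidates_toy_and_duplicates(toy_pair):
    b1, b2 = toy_pair
    assert np.allclose(candidate_shifts(b1, b2), [-0.75, 0.0])
    assert np.allclose(candidate_shifts(b1, b1), [0.0])


def test_candidates_inside_search_interval():
    rng = np.random.default_rng(1)
    b1, b2 = rng.normal(size=8), rng.normal(size=8)
    lo, hi = search_interval(b1, b2)
    c = candidate_shifts(b1, b2)
    assert np.all((c >= lo - 1e-12) & (c <= hi + 1e-12))


# ---------------------------------------------------------------------------
# anchor point selection
# ---------------------------------------------------------------------------


def test_toy_global_optima_agree_at_zero(toy_pair):
    b1, b2 = toy_pair
    curve = select_anchor_point(b1, b2, criterion="gini")
    assert curve.global_opt["gini"][0] == pytest.approx(0.0, abs=1e-12)
    assert curve.global_opt["clf"][0] == pytest.approx(0.0, abs=1e-12)
    assert curve.global_opt["gini"][1] == pytest.approx(0.9)
    assert curve.global_opt["clf"][1] == pytest.approx(-0.75)
    # the optimal shift aligns every DIF-free item exactly
    assert np.array_equal(curve.anchor_items("gini"), np.delete(np.arange(10), 3))


def test_toy_secondary_local_optimum(toy_pair):
    b1, b2 = toy_pair
    curve = select_anchor_point(b1, b2)
    gini_locals = [o for o in curve.local_opts if o.criterion == "gini"]
    assert len(gini_locals) == 1
    assert gini_locals[0].shift == pytest.approx(-0.75)
    assert gini_locals[0].prominence > 0
    # the CLF criterion is concave piecewise linear: no secondary peak
    assert [o for o in curve.local_opts if o.criterion == "clf"] == []


def test_gini_at_optimum_magnitude_independent():
    for size in (0.75, 1.5, 0.1):
        b1, b2 = make_toy(dif_size=size)
        curve = select_anchor_point(b1, b2)
        assert curve.global_opt["gini"][1] == pytest.approx(0.9)


def test_majority_dif_cluster_aligns_to_cluster():
    """With 6 of 10 items sharing DIF +1.0 both criteria align the majority
    cluster (shift -1.0); the minority alignment at 0 is the secondary peak."""
    b1 = np.linspace(-2, 2, 10)
    b2 = b1.copy()
    b2[:6] += 1.0
    curve = select_anchor_point(b1, b2)
    assert curve.global_opt["gini"][0] == pytest.approx(-1.0)
    assert curve.global_opt["clf"][0] == pytest.approx(-1.0)
    assert curve.global_opt["gini"][1] == pytest.approx(0.6)
    gini_vals = dict(zip(curve.candidates.tolist(), curve.candidate_values["gini"]))
    assert gini_vals[0.0] == pytest.approx(0.4)
    assert any(
        o.criterion == "gini" and o.shift == pytest.approx(0.0) for o in curve.local_opts
    )


def test_degenerate_identical_groups():
    b = np.linspace(-1, 1, 6)
    curve = select_anchor_point(b, b)
    assert curve.global_opt["gini"] == (0.0, 0.0)
    assert curve.local_opts == []


def test_sparse_grid_matches_dense_grid():
    """On random instances, maximising over a dense grid (step 1e-3) that
    additionally contains all candidate shifts never beats the candidate-set
    maximum: optima occur only at single-item anchor points."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        m = int(rng.integers(4, 10))
        b1 = rng.normal(scale=1.2, size=m)
        b2 = b1 + rng.normal(scale=0.7, size=m)
        curve = select_anchor_point(b1, b2)
        lo, hi = curve.interval
        grid = np.union1d(np.arange(lo, hi + 1e-3, 1e-3), curve.candidates)
        for crit in ("gini", "clf"):
            v_dense = criterion_on_grid(b1, b2, crit, grid).max()
            v_best = curve.global_opt[crit][1]
            assert v_best == pytest.approx(v_dense, abs=1e-9)


def test_clf_optimum_is_median_of_candidate_differences():
    rng = np.random.default_rng(99)
    for _ in range(50):
        m = int(rng.integers(3, 12))
        b1 = rng.normal(size=m)
        b2 = b1 + rng.normal(scale=0.5, size=m)
        curve = select_anchor_point(b1, b2)
        diffs = b1 - b2
        med = float(np.median(diffs))
        c_opt, v_opt = curve.global_opt["clf"]
        # every median of the differences maximises -sum |diff - c|
        assert v_opt == pytest.approx(-np.abs(diffs - med).sum(), abs=1e-10)


def test_restriction_invariance_of_selection():
    """Shifting one group's scale moves candidates and optimum by the same
    constant and leaves aligned differences untouched."""
    rng = np.random.default_rng(3)
    b1 = rng.normal(size=7)
    b2 = b1 + rng.normal(scale=0.4, size=7)
    k = 1.37
    base = select_anchor_point(b1, b2)
    shifted = select_anchor_point(b1, b2 + k)
    assert np.allclose(shifted.candidates, base.candidates - k, atol=1e-12)
    for crit in ("gini", "clf"):
        assert shifted.global_opt[crit][0] == pytest.approx(
            base.global_opt[crit][0] - k, abs=1e-10
        )
        assert shifted.global_opt[crit][1] == pytest.approx(
            base.global_opt[crit][1], abs=1e-10
        )
    d0 = b1 - b2 - base.global_opt["gini"][0]
    d1 = b1 - (b2 + k) - shifted.global_opt["gini"][0]
    assert np.allclose(d0, d1, atol=1e-10)


def test_local_optima_require_curve_vectors(toy_pair):
    b1, b2 = toy_pair
    curve = select_anchor_point(b1, b2)
    curve2 = curve.__class__(**{**curve.__dict__, "beta1": None})
    with pytest.raises(ValueError):
        find_local_optima(curve2)


def test_select_rejects_single_item():
    with pytest.raises(ValueError):
        select_anchor_point(np.array([0.0]), np.array([0.1]))
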