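"""Hyperbox primitives: membership, expansion, overlap, contraction.

The membership check uses an independent term-by-term oracle that
evaluates the two-penalty sum per dimension in pure Python; the overlap
check uses a brute-force interval-intersection oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytofmm import (
    ContractViolationError,
    Hyperbox,
    InvalidInputError,
    ShapeError,
    can_expand,
    contract,
    expand,
    membership,
    overlap_test,
)
from conftest import random_box_pair


def membership_oracle(v, w, a, gamma):
    """Literal per-dimension evaluation of the two-penalty membership sum."""
    n = len(a)
    s = 0.0
    for i in range(n):
        s += max(0.0, 1.0 - max(0.0, gamma * min(1.0, a[i] - w[i])))
        s += max(0.0, 1.0 - max(0.0, gamma * min(1.0, v[i] - a[i])))
    return s / (2.0 * n)


def interval_overlap_oracle(box_j, box_k):
    """True iff every dimension's interval intersection has positive width."""
    widths = np.minimum(box_j.max_point, box_k.max_point) - np.maximum(
        box_j.min_point, box_k.min_point
    )
    return bool(np.all(widths > 0.0))


class TestHyperbox:
    def test_invalid_corners_rejected(self):
        with pytest.raises(InvalidInputError):
            Hyperbox([0.5], [0.2], 0)
        with pytest.raises(InvalidInputError):
            Hyperbox([-0.1], [0.5], 0)
        with pytest.raises(InvalidInputError):
            Hyperbox([0.1], [1.2], 0)

    def test_point_box(self):
        b = Hyperbox.point([0.3, 0.7], 2)
        np.testing.assert_array_equal(b.min_point, b.max_point)
        assert b.contains([0.3, 0.7])


class TestMembership:
    def test_inside_box_is_one(self):
        b = Hyperbox([0.2, 0.2], [0.4, 0.4], 0)
        assert membership(b, [0.3, 0.3], 1.0) == 1.0
        assert membership(b, [0.2, 0.4], 1.0) == 1.0  # closed boundary

    def test_hand_value_1d(self):
        b = Hyperbox([0.2], [0.4], 0)
        assert membership(b, [0.5], 1.0) == pytest.approx(0.95, abs=1e-12)

    def test_hand_value_2d_gamma2(self):
        b = Hyperbox([0.2, 0.2], [0.4, 0.4], 0)
        assert membership(b, [0.6, 0.3], 2.0) == pytest.approx(0.9, abs=1e-12)

    def test_strictly_below_one_outside(self, rng):
        b = Hyperbox([0.4, 0.4], [0.6, 0.6], 0)
        for _ in range(20):
            p = rng.random(2)
            if not b.contains(p):
                assert membership(b, p, 1.0) < 1.0

    def test_closed_form_single_dimension_offset(self):
        # a point outside in exactly one dimension by d <= 1/gamma scores
        # 1 - gamma*d/(2n)
        n, gamma, d = 3, 2.0, 0.1
        b = Hyperbox([0.2] * n, [0.4] * n, 0)
        p = [0.3, 0.3, 0.4 + d]
        assert membership(b, p, gamma) == pytest.approx(
            1.0 - gamma * d / (2 * n), abs=1e-12
        )

    def test_monotone_decay_along_axis(self):
        b = Hyperbox([0.2], [0.4], 0)
        scores = [membership(b, [0.4 + d], 1.0) for d in (0.0, 0.1, 0.2, 0.3)]
        assert all(a >= b_ for a, b_ in zip(scores, scores[1:]))

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(500):
            d = int(rng.integers(1, 9))
            lo = rng.random(d)
            hi = lo + rng.random(d) * (1.0 - lo)
            a = rng.random(d)
            gamma = float(rng.uniform(0.1, 4.0))
            b = Hyperbox(lo, hi, 0)
            assert membership(b, a, gamma) == pytest.approx(
                membership_oracle(lo, hi, a, gamma), abs=1e-12
            )

    def test_gamma_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            membership(Hyperbox([0.2], [0.4], 0), [0.3], 0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            membership(Hyperbox([0.2], [0.4], 0), [0.3, 0.3], 1.0)


class TestExpansion:
    def test_theta_one_always_allows(self, rng):
        for _ in range(20):
            b, _ = random_box_pair(rng, 3)
            assert can_expand(b, rng.random(3), 1.0)

    def test_theta_zero_only_identical_pattern(self):
        b = Hyperbox.point([0.3, 0.6], 0)
        assert can_expand(b, [0.3, 0.6], 0.0)
        assert not can_expand(b, [0.3, 0.61], 0.0)

    def test_hand_value_edge_sum(self):
        # enclosing box spans 0.3 and 0.2, sum 0.5 <= 2 * 0.3
        b = Hyperbox([0.2, 0.2], [0.4, 0.4], 0)
        assert can_expand(b, [0.5, 0.3], 0.3)
        assert not can_expand(b, [0.5, 0.3], 0.24)

    def test_expand_elementwise_min_max(self):
        b = Hyperbox([0.2, 0.2], [0.4, 0.4], 1)
        out = expand(b, [0.5, 0.3])
        np.testing.assert_allclose(out.min_point, [0.2, 0.2])
        np.testing.assert_allclose(out.max_point, [0.5, 0.4])
        assert out.class_id == 1

    def test_expand_identity_on_contained_pattern(self):
        b = Hyperbox([0.2, 0.2], [0.4, 0.4], 0)
        out = expand(b, [0.3, 0.3])
        np.testing.assert_array_equal(out.min_point, b.min_point)
        np.testing.assert_array_equal(out.max_point, b.max_point)

    def test_expand_guard_raises_when_test_fails(self):
        b = Hyperbox.point([0.3], 0)
        with pytest.raises(ContractViolationError):
            expand(b, [0.9], theta=0.0)

    def test_expand_preserves_invariants(self, rng):
        for _ in range(50):
            b, _ = random_box_pair(rng, 4)
            out = expand(b, rng.random(4))
            assert np.all(out.min_point <= out.max_point)
            assert out.min_point.min() >= 0.0 and out.max_point.max() <= 1.0


class TestOverlapTest:
    def test_disjoint_boxes(self):
        j = Hyperbox([0.0, 0.0], [0.2, 0.2], 0)
        k = Hyperbox([0.5, 0.5], [0.7, 0.7], 1)
        assert not overlap_test(j, k).overlapping

    def test_partial_overlap_case1(self):
        j = Hyperbox([0.1, 0.1], [0.3, 0.3], 0)
        k = Hyperbox([0.2, 0.2], [0.4, 0.4], 1)
        r = overlap_test(j, k)
        assert r.overlapping
        assert r.case_id == 1
        assert r.dim_index == 0  # tie on delta -> lowest dimension
        assert r.delta == pytest.approx(0.1)

    def test_shared_face_is_not_overlap(self):
        j = Hyperbox([0.0, 0.0], [0.2, 1.0], 0)
        k = Hyperbox([0.2, 0.0], [0.4, 1.0], 1)
        assert not overlap_test(j, k).overlapping

    def test_containment_case3(self):
        j = Hyperbox([0.1], [0.9], 0)
        k = Hyperbox([0.4], [0.6], 1)
        r = overlap_test(j, k)
        assert r.overlapping and r.case_id == 3

    def test_containment_case4(self):
        j = Hyperbox([0.4], [0.6], 0)
        k = Hyperbox([0.1], [0.9], 1)
        r = overlap_test(j, k)
        assert r.overlapping and r.case_id == 4

    def test_agrees_with_interval_oracle(self, rng):
        hits = 0
        for _ in range(2000):
            d = int(rng.integers(1, 6))
            j, k = random_box_pair(rng, d)
            r = overlap_test(j, k)
            assert r.overlapping == interval_overlap_oracle(j, k)
            hits += r.overlapping
        assert hits > 50  # the check exercised genuine overlaps

    def test_delta_is_smallest_straddle_width(self, rng):
        # per dimension the overlap measure is min(w_j - v_k, w_k - v_j):
        # the intersection width for partial overlaps, the cheaper cut
        # depth for containments
        for _ in range(300):
            j, k = random_box_pair(rng, 4)
            r = overlap_test(j, k)
            if r.overlapping:
                widths = np.minimum(
                    j.max_point - k.min_point, k.max_point - j.min_point
                )
                assert r.delta == pytest.approx(widths.min())
                assert widths[r.dim_index] == pytest.approx(widths.min())


class TestContraction:
    def test_case1_midpoint(self):
        j = Hyperbox([0.1, 0.1], [0.3, 0.3], 0)
        k = Hyperbox([0.2, 0.2], [0.4, 0.4], 1)
        r = overlap_test(j, k)
        nj, nk = contract(j, k, r)
        assert nj.max_point[0] == pytest.approx(0.25)
        assert nk.min_point[0] == pytest.approx(0.25)
        assert not overlap_test(nj, nk).overlapping

    def test_case3_cuts_cheaper_side(self):
        # inner box nearer j's max: j's max pulled down to inner box's min
        j = Hyperbox([0.0], [1.0], 0)
        k = Hyperbox([0.7], [0.9], 1)
        r = overlap_test(j, k)
        assert r.case_id == 3
        nj, nk = contract(j, k, r)
        assert nj.max_point[0] == pytest.approx(0.7)
        np.testing.assert_array_equal(nk.min_point, k.min_point)
        assert not overlap_test(nj, nk).overlapping

    def test_only_delta_dimension_changes(self, rng):
        changed_total = 0
        for _ in range(500):
            j, k = random_box_pair(rng, 3)
            r = overlap_test(j, k)
            if not r.overlapping:
                continue
            nj, nk = contract(j, k, r)
            for dim in range(3):
                if dim == r.dim_index:
                    continue
                assert nj.min_point[dim] == j.min_point[dim]
                assert nj.max_point[dim] == j.max_point[dim]
                assert nk.min_point[dim] == k.min_point[dim]
                assert nk.max_point[dim] == k.max_point[dim]
            changed_total += 1
        assert changed_total > 20

    def test_contraction_removes_overlap_randomized(self, rng):
        removed = 0
        for _ in range(2000):
            d = int(rng.integers(1, 5))
            j, k = random_box_pair(rng, d)
            r = overlap_test(j, k)
            if not r.overlapping:
                continue
            nj, nk = contract(j, k, r)
            assert not overlap_test(nj, nk).overlapping
            assert np.all(nj.min_point <= nj.max_point)
            assert np.all(nk.min_point <= nk.max_point)
            removed += 1
        assert removed > 100

    def test_identical_boxes_contract_cleanly(self):
        j = Hyperbox([0.2, 0.2], [0.5, 0.5], 0)
        k = Hyperbox([0.2, 0.2], [0.5, 0.5], 1)
        r = overlap_test(j, k)
        assert r.overlapping
        nj, nk = contract(j, k, r)
        assert not overlap_test(nj, nk).overlapping

    def test_rejects_non_overlapping_result(self):
        j = Hyperbox([0.0], [0.1], 0)
        k = Hyperbox([0.5], [0.6], 1)
        with pytest.raises(ContractViolationError):
            contract(j, k, overlap_test(j, k))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n_dims=st.integers(min_value=1, max_value=4),
)
def test_contract_then_no_overlap_property(data, n_dims):
    """For arbitrary valid overlapping pairs, contraction is sound."""
    def corner_pair():
        lo = [data.draw(st.floats(0.0, 0.9)) for _ in range(n_dims)]
        hi = [data.draw(st.floats(lo[i], 1.0)) for i in range(n_dims)]
        return np.array(lo), np.array(hi)

    vj, wj = corner_pair()
    vk, wk = corner_pair()
    j = Hyperbox(vj, wj, 0)
    k = Hyperbox(vk, wk, 1)
    r = overlap_test(j, k)
    if r.overlapping:
        nj, nk = contract(j, k, r)
        assert not overlap_test(nj, nk).overlapping
        assert np.all(nj.min_point <= nj.max_point)
        assert np.all(nk.min_point <= nk.max_point)
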