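"""EMA centroids, interval/rank partitions, plans and pseudo-label assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicc import (
    CentroidState,
    LabeledBatch,
    SubclassPlan,
    assign_pseudo_labels,
    canonical_projection,
    compute_distances,
    derive_subclass_plan,
    partition_equal_rank,
    partition_equal_width,
    update_centroids,
)
from tests._reference import brute_force_assign


class TestCentroids:
    def test_first_update_sets_center_to_batch_mean(self):
        state = CentroidState.initial(2, 3, alpha=0.99)
        batch = LabeledBatch(np.arange(12.0).reshape(4, 3), [0, 0, 1, 1])
        new = update_centroids(state, batch)
        np.testing.assert_allclose(new.centers[0], [1.5, 2.5, 3.5])
        np.testing.assert_allclose(new.centers[1], [7.5, 8.5, 9.5])
        np.testing.assert_array_equal(new.updates_seen, [1, 1])

    def test_ema_weights_current_batch_by_alpha(self):
        # alpha multiplies the *current* batch mean: zero history, ones batch
        state = CentroidState(
            centers=np.zeros((1, 4)), alpha=0.99, updates_seen=np.array([1])
        )
        batch = LabeledBatch(np.ones((2, 4)), [0, 0])
        new = update_centroids(state, batch)
        np.testing.assert_allclose(new.centers[0], 0.99)

    @pytest.mark.parametrize("alpha", [0.99, 0.5, 0.01])
    def test_closed_form_of_the_recurrence(self, alpha):
        rng = np.random.default_rng(5)
        t_max = 100
        means = rng.normal(size=(t_max, 6))
        state = CentroidState.initial(1, 6, alpha=alpha)
        for t in range(t_max):
            # a two-sample batch whose mean is means[t]
            feats = np.stack([means[t] + 0.5, means[t] - 0.5])
            state = update_centroids(state, LabeledBatch(feats, [0, 0]))
            expected = (1 - alpha) ** t * means[0]
            for k in range(1, t + 1):
                expected = expected + alpha * (1 - alpha) ** (t - k) * means[k]
            np.testing.assert_allclose(state.centers[0], expected, atol=1e-10)

    def test_absent_classes_untouched(self):
        state = CentroidState(
            centers=np.arange(8.0).reshape(2, 4),
            alpha=0.9,
            updates_seen=np.array([3, 3]),
        )
        batch = LabeledBatch(np.ones((2, 4)), [0, 0])
        new = update_centroids(state, batch)
        np.testing.assert_array_equal(new.centers[1], state.centers[1])
        assert new.updates_seen[1] == 3

    def test_dimension_mismatch_rejected(self):
        state = CentroidState.initial(2, 3)
        with pytest.raises(ValueError, match="dimension"):
            update_centroids(state, LabeledBatch(np.ones((2, 5)), [0, 1]))

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError, match="alpha"):
            CentroidState.initial(1, 2, alpha=1.0)


class TestDistances:
    def test_identical_points_have_zero_distance(self):
        f = np.ones((3, 4))
        np.testing.assert_array_equal(compute_distances(f, np.ones(4)), 0.0)

    def test_three_four_five(self):
        d = compute_distances(np.array([[3.0, 4.0]]), np.zeros(2))
        assert d[0] == pytest.approx(5.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        f, mu = rng.normal(size=(20, 7)), rng.normal(size=7)
        expected = [sum((f[i, d] - mu[d]) ** 2 for d in range(7)) ** 0.5 for i in range(20)]
        np.testing.assert_allclose(compute_distances(f, mu), expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_distances(np.array([[np.nan, 0.0]]), np.zeros(2))


class TestEqualWidth:
    def test_enumerated_intervals(self):
        idx = partition_equal_width(np.array([0.0, 1.0, 2.0, 3.0, 9.0]), 3)
        np.testing.assert_array_equal(idx, [0, 0, 0, 1, 2])

    def test_single_interval(self):
        idx = partition_equal_width(np.array([0.3, 5.0, 2.0]), 1)
        np.testing.assert_array_equal(idx, 0)

    def test_degenerate_all_zero(self):
        idx = partition_equal_width(np.zeros(4), 3)
        np.testing.assert_array_equal(idx, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            partition_equal_width(np.array([]), 2)

    @settings(deadline=None, derandomize=True)
    @given(
        dists=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        n_sub=st.integers(1, 10),
    )
    def test_index_is_clipped_floor(self, dists, n_sub):
        d = np.asarray(dists, dtype=float)
        idx = partition_equal_width(d, n_sub)
        assert idx.min() >= 0 and idx.max() < n_sub
        dmax = d.max()
        if dmax - d.min() > 1e-9 * dmax:
            width = dmax / n_sub
            expected = np.minimum(np.floor(d / width).astype(int), n_sub - 1)
            np.testing.assert_array_equal(idx, expected)
        else:
            np.testing.assert_array_equal(idx, 0)


class TestEqualRank:
    def test_rank_equals_index_when_sizes_match(self):
        np.testing.assert_array_equal(
            partition_equal_rank(np.array([5.0, 1.0, 3.0]), 3), [2, 0, 1]
        )

    def test_blocks_of_two(self):
        np.testing.assert_array_equal(
            partition_equal_rank(np.array([4.0, 1.0, 2.0, 9.0]), 2), [1, 0, 0, 1]
        )

    def test_ties_keep_input_order(self):
        idx = partition_equal_rank(np.array([1.0, 1.0, 1.0, 1.0]), 2)
        np.testing.assert_array_equal(idx, [0, 0, 1, 1])

    @settings(deadline=None, derandomize=True)
    @given(
        dists=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=60),
        n_sub=st.integers(1, 8),
    )
    def test_occupancy_balanced_within_one(self, dists, n_sub):
        idx = partition_equal_rank(np.asarray(dists, dtype=float), n_sub)
        counts = np.bincount(idx, minlength=n_sub)
        occupied = counts if len(dists) >= n_sub else counts[counts > 0]
        assert counts.max() - occupied.min() <= 1


class TestSubclassPlan:
    def test_manual_plan_offsets_and_total(self):
        plan = derive_subclass_plan([1] * 7, manual_ns=[2, 1, 1, 10, 8, 1, 4])
        assert plan.offsets == (0, 2, 3, 4, 14, 22, 23)
        assert plan.total == 27

    def test_tail_unit_rule(self):
        plan = derive_subclass_plan([100, 10])
        assert plan.ns == (10, 1) and plan.total == 11

    def test_balanced_counts_need_no_splitting(self):
        plan = derive_subclass_plan([50, 50, 50])
        assert plan.ns == (1, 1, 1) and plan.total == 3

    def test_cap_clips_derived_counts(self):
        plan = derive_subclass_plan([1000, 10], cap=8)
        assert plan.ns == (8, 1)

    def test_manual_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            derive_subclass_plan([10, 10], manual_ns=[1, 1, 1])

    def test_ranges_partition_pseudo_space(self, reference_plan):
        covered = np.concatenate(
            [
                np.arange(o, o + n)
                for o, n in zip(reference_plan.offsets, reference_plan.ns)
            ]
        )
        np.testing.assert_array_equal(covered, np.arange(reference_plan.total))

    def test_json_round_trip(self, reference_plan):
        again = SubclassPlan.from_json(reference_plan.to_json())
        assert again == reference_plan


class TestAssignPseudoLabels:
    def test_single_subclass_class_gets_its_offset(self):
        plan = SubclassPlan.from_ns([2, 2, 1])  # class 2 -> offset 4
        state = CentroidState.initial(3, 2)
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(6, 2))
        batch = LabeledBatch(feats, [2] * 6)
        out, _ = assign_pseudo_labels(batch, state, plan)
        np.testing.assert_array_equal(out.pseudo_labels, 4)

    @pytest.mark.parametrize("mode", ["equal_width", "equal_rank"])
    def test_matches_brute_force_reference(self, mode):
        rng = np.random.default_rng(17)
        plan = SubclassPlan.from_ns([2, 1])
        state = CentroidState.initial(2, 3, alpha=0.9)
        centers_ref = [[0.0] * 3, [0.0] * 3]
        seen_ref = [0, 0]
        for t in range(50):
            feats = rng.normal(size=(8, 3))
            labels = rng.integers(0, 2, size=8)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            out, state = assign_pseudo_labels(
                LabeledBatch(feats, labels, batch_index=t + 1), state, plan, mode
            )
            expected, centers_ref, seen_ref = brute_force_assign(
                feats.tolist(), labels.tolist(), centers_ref, seen_ref, 0.9, [2, 1], mode
            )
            np.testing.assert_array_equal(out.pseudo_labels, expected)

    def test_absent_class_centroids_bit_identical(self):
        plan = SubclassPlan.from_ns([2, 3, 1])
        state = CentroidState(
            centers=np.arange(9.0).reshape(3, 3),
            alpha=0.5,
            updates_seen=np.array([2, 2, 2]),
        )
        batch = LabeledBatch(np.random.default_rng(1).normal(size=(5, 3)), [0] * 5)
        _, new_state = assign_pseudo_labels(batch, state, plan)
        np.testing.assert_array_equal(new_state.centers[1:], state.centers[1:])
        np.testing.assert_array_equal(new_state.updates_seen[1:], [2, 2])

    def test_flat_plan_is_identity_relabelling(self):
        rng = np.random.default_rng(4)
        plan = SubclassPlan.from_ns([1, 1, 1, 1])
        state = CentroidState.initial(4, 6)
        labels = rng.integers(0, 4, size=30)
        out, _ = assign_pseudo_labels(
            LabeledBatch(rng.normal(size=(30, 6)), labels), state, plan
        )
        np.testing.assert_array_equal(out.pseudo_labels, labels)

    def test_canonical_recovery_on_random_batches(self, reference_plan):
        rng = np.random.default_rng(99)
        proj = canonical_projection(reference_plan)
        state = CentroidState.initial(7, 5)
        for _ in range(10):
            labels = rng.integers(0, 7, size=40)
            out, state = assign_pseudo_labels(
                LabeledBatch(rng.normal(size=(40, 5)), labels), state, reference_plan
            )
            recovered = proj.pseudo_to_class[out.pseudo_labels]
            np.testing.assert_array_equal(recovered, labels)

    def test_missing_plan_entry_rejected(self):
        plan = SubclassPlan.from_ns([1, 1])
        state = CentroidState.initial(2, 2)
        with pytest.raises(ValueError, match="class"):
            assign_pseudo_labels(LabeledBatch(np.ones((1, 2)), [5]), state, plan)
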