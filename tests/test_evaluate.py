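"""Confusion charts, normalization conventions, margins, merging, subgroups."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoehar import labels as L
from shoehar.evaluate import (
    confusion,
    merge_confusion,
    merge_labels,
    plot_confusion,
    subgroup_eval,
)

from oracles import oracle_confusion

label7 = st.sampled_from(L.SEVEN_CLASSES)


class TestConfusion:
    def test_hand_enumerated_two_class(self):
        cr = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cr.counts, [[1, 1], [0, 1]])
        assert cr.accuracy == pytest.approx(2 / 3)
        np.testing.assert_allclose(cr.sensitivity, [0.5, 1.0])
        np.testing.assert_allclose(cr.specificity_margin, [1.0, 0.5])

    def test_perfect_predictions(self):
        obs = ["a", "b", "c", "a"]
        cr = confusion(obs, obs, ["a", "b", "c"])
        assert cr.accuracy == 1.0
        np.testing.assert_allclose(cr.sensitivity, 1.0)
        np.testing.assert_allclose(cr.specificity_margin, 1.0)
        assert np.all(cr.counts == np.diag(np.diag(cr.counts)))

    def test_row_normalization(self):
        cr = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"], "row")
        np.testing.assert_allclose(cr.matrix, [[0.5, 0.5], [0, 1]])
        rowsums = cr.matrix.sum(axis=1)
        np.testing.assert_allclose(rowsums, 1.0)

    def test_total_normalization_sums_to_one(self):
        cr = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"], "total")
        assert cr.matrix.sum() == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion(["a"], ["a", "b"], ["a", "b"])

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["a", "z"], ["a", "a"], ["a", "b"])

    def test_empty_margins_undefined_not_zero(self):
        cr = confusion(["a", "a"], ["a", "a"], ["a", "b"])
        assert np.isnan(cr.sensitivity[1])  # b never observed
        assert np.isnan(cr.specificity_margin[1])  # b never predicted
        assert cr.accuracy == 1.0  # NaN does not propagate

    def test_margins_blank_in_csv(self, tmp_path):
        cr = confusion(["a", "a"], ["a", "a"], ["a", "b"])
        p = tmp_path / "cm.csv"
        cr.to_csv(p)
        text = p.read_text()
        assert "nan" not in text.lower()

    @given(
        obs=st.lists(label7, min_size=1, max_size=60),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_match_bruteforce_tally(self, obs, data):
        pred = data.draw(st.lists(label7, min_size=len(obs), max_size=len(obs)))
        cr = confusion(obs, pred, L.SEVEN_CLASSES)
        np.testing.assert_array_equal(
            cr.counts, oracle_confusion(obs, pred, L.SEVEN_CLASSES)
        )


class TestMerge:
    def test_sitting_predicted_standing_becomes_correct(self):
        cr7 = confusion(["sitting"], ["standing"], L.SEVEN_CLASSES)
        assert cr7.accuracy == 0.0
        cr5 = confusion(
            merge_labels(["sitting"]), merge_labels(["standing"]), L.FIVE_CLASSES
        )
        assert cr5.accuracy == 1.0

    def test_merged_cells_are_sums_of_constituents(self, rng):
        obs = rng.choice(L.SEVEN_CLASSES, 200).tolist()
        pred = rng.choice(L.SEVEN_CLASSES, 200).tolist()
        cr7 = confusion(obs, pred, L.SEVEN_CLASSES)
        merged = merge_confusion(cr7)
        direct = confusion(merge_labels(obs), merge_labels(pred), L.FIVE_CLASSES)
        np.testing.assert_array_equal(merged.counts, direct.counts)
        i = merged.classes.index("stationary")
        j = merged.classes.index("walking")
        si = cr7.classes.index("sitting")
        st_ = cr7.classes.index("standing")
        w = cr7.classes.index("walking")
        assert merged.counts[i, j] == cr7.counts[si, w] + cr7.counts[st_, w]

    @given(
        obs=st.lists(label7, min_size=1, max_size=80),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_merge_monotonicity(self, obs, data):
        """Merging can only move off-diagonal mass onto the diagonal."""
        pred = data.draw(st.lists(label7, min_size=len(obs), max_size=len(obs)))
        acc7 = confusion(obs, pred, L.SEVEN_CLASSES).accuracy
        acc5 = confusion(
            merge_labels(obs), merge_labels(pred), L.FIVE_CLASSES
        ).accuracy
        assert acc5 >= acc7

    def test_out_of_domain_label_raises(self):
        with pytest.raises(ValueError, match="mapping domain"):
            merge_labels(["stationary"])


class TestSubgroup:
    def test_single_group_equals_pooled(self, rng):
        obs = rng.choice(L.SEVEN_CLASSES, 50)
        pred = rng.choice(L.SEVEN_CLASSES, 50)
        groups = np.array(["production"] * 50, dtype=object)
        sub = subgroup_eval(obs, pred, groups, "production", L.SEVEN_CLASSES)
        pooled = confusion(obs, pred, L.SEVEN_CLASSES)
        np.testing.assert_array_equal(sub.counts, pooled.counts)

    def test_disjoint_groups_sum_to_pooled(self, rng):
        obs = rng.choice(L.SEVEN_CLASSES, 60)
        pred = rng.choice(L.SEVEN_CLASSES, 60)
        groups = np.array(["logistics"] * 25 + ["production"] * 35, dtype=object)
        a = subgroup_eval(obs, pred, groups, "logistics", L.SEVEN_CLASSES)
        b = subgroup_eval(obs, pred, groups, "production", L.SEVEN_CLASSES)
        pooled = confusion(obs, pred, L.SEVEN_CLASSES)
        np.testing.assert_array_equal(a.counts + b.counts, pooled.counts)

    def test_empty_group_raises(self, rng):
        obs = pred = ["sitting"] * 3
        groups = ["production"] * 3
        with pytest.raises(ValueError, match="empty group"):
            subgroup_eval(obs, pred, groups, "office", L.SEVEN_CLASSES)


def test_heatmap_render(tmp_path, rng):
    obs = rng.choice(L.SEVEN_CLASSES, 40)
    pred = rng.choice(L.SEVEN_CLASSES, 40)
    cr = confusion(obs, pred, L.SEVEN_CLASSES, "row")
    out = tmp_path / "cm.png"
    plot_confusion(cr, out, title="demo")
    assert out.stat().st_size > 0
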