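"""Differential splicing indexes: contrasts, dsiT, selection, aggregation.

The brute-force oracle evaluates each contrast longhand, position by
position, independently of the vectorized implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exondsi import (
    ProbesetAnnotation,
    ProbesetMatrix,
    SampleGroups,
    SplicingModel,
    aggregate_as_list,
    default_plan,
    dsiT_per_probeset,
    dsi_window,
    group_delta,
    overlap_with_de,
    select_top_k,
)


def oracle_window(w):
    """Independent longhand evaluation of the three contrasts."""
    step = (w[0] + w[1]) / 2.0 - (w[2] + w[3]) / 2.0
    bump = (w[1] + w[2]) / 2.0 - (w[0] + w[3]) / 2.0
    spike = w[1] - (w[0] + w[2] + w[3]) / 3.0
    return step, bump, spike


def oracle_dsiT(delta):
    out = []
    for n in range(len(delta) - 3):
        s, b, sp = oracle_window(delta[n : n + 4])
        out.append(abs(s) + abs(b) + abs(sp))
    return np.array(out)


finite_delta = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False),
    min_size=4, max_size=8,
)


class TestDsiWindow:
    @pytest.mark.parametrize("c", [0.0, 1.0, -3.5, 100.0])
    def test_constant_window_scores_zero(self, c):
        assert dsi_window([c, c, c, c]) == pytest.approx(
            (0.0, 0.0, 0.0), abs=1e-12
        )

    def test_step_pattern(self):
        # oracle: step=2, bump=0, spike=4/3
        d1, d2, d3 = dsi_window([0.0, 0.0, -2.0, -2.0])
        assert d1 == pytest.approx(2.0)
        assert d2 == pytest.approx(0.0)
        assert d3 == pytest.approx(4.0 / 3.0)

    def test_spike_pattern(self):
        d1, d2, d3 = dsi_window([0.0, 3.0, 0.0, 0.0])
        assert d1 == pytest.approx(1.5)
        assert d2 == pytest.approx(1.5)
        assert d3 == pytest.approx(3.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            dsi_window([0.0, np.nan, 0.0, 0.0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="exactly 4"):
            dsi_window([1.0, 2.0, 3.0])

    @settings(max_examples=200, deadline=None)
    @given(
        w=st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=4)
    )
    def test_matches_longhand_oracle(self, w):
        got = dsi_window(w)
        exp = oracle_window(w)
        assert np.allclose(got, exp)


class TestDsiT:
    def test_zero_delta_scores_zero(self):
        out = dsiT_per_probeset(np.zeros(6))
        assert len(out) == 3  # last three positions unscored
        assert (out["dsiT"] == 0).all()

    def test_cassette_anchor_score(self):
        # anchor 0 of (0,0,-2,-2,0,0): |2| + |0| + |4/3| = 10/3
        out = dsiT_per_probeset(np.array([0.0, 0.0, -2.0, -2.0, 0.0, 0.0]))
        assert out.loc[0, "dsiT"] == pytest.approx(10.0 / 3.0)

    def test_too_short_gene_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            dsiT_per_probeset(np.zeros(3))

    @settings(max_examples=200, deadline=None)
    @given(delta=finite_delta)
    def test_brute_force_oracle_equivalence(self, delta):
        """dsiT per anchor equals the independent per-window evaluation."""
        got = dsiT_per_probeset(np.array(delta))["dsiT"].to_numpy()
        assert np.allclose(got, oracle_dsiT(delta))

    @settings(max_examples=100, deadline=None)
    @given(delta=finite_delta, shift=st.floats(-20, 20, allow_nan=False))
    def test_shift_invariance(self, delta, shift):
        """A whole-gene group shift leaves every dsi and dsiT unchanged."""
        base = dsiT_per_probeset(np.array(delta))
        shifted = dsiT_per_probeset(np.array(delta) + shift)
        pd.testing.assert_frame_equal(base, shifted, atol=1e-9, rtol=0)

    @settings(max_examples=100, deadline=None)
    @given(delta=finite_delta)
    def test_group_swap_antisymmetry(self, delta):
        """Swapping groups negates each dsi and preserves dsiT exactly."""
        base = dsiT_per_probeset(np.array(delta))
        swapped = dsiT_per_probeset(-np.array(delta))
        for col in ("dsi1", "dsi2", "dsi3"):
            assert np.allclose(swapped[col], -base[col])
        assert np.allclose(swapped["dsiT"], base["dsiT"])


def _tiny_dataset():
    """Two genes x two groups of two samples, no noise."""
    samples = ["a1", "a2", "b1", "b2"]
    groups = SampleGroups({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    # gene TC1: cassette at ordinals 2-3 (magnitude -2 in A); TC2: flat
    prof_a = np.array([8, 8, 6, 6, 8, 8], dtype=float)
    prof_b = np.array([8, 8, 8, 8, 8, 8], dtype=float)
    tc1 = np.column_stack([prof_a, prof_a, prof_b, prof_b])
    tc2 = np.full((5, 4), 7.0)
    sig = pd.DataFrame(
        np.vstack([tc1, tc2]),
        index=[f"PS{i}" for i in range(11)], columns=samples,
    )
    rows = [
        {"probeset_id": f"PS{i}", "transcript_cluster_id": "TC1",
         "ordinal": i, "evidence": "core"} for i in range(6)
    ] + [
        {"probeset_id": f"PS{i + 6}", "transcript_cluster_id": "TC2",
         "ordinal": i, "evidence": "core"} for i in range(5)
    ]
    ann = ProbesetAnnotation(pd.DataFrame(rows).set_index("probeset_id"))
    return ProbesetMatrix(sig), ann, groups


class TestGroupDelta:
    def test_identical_groups_give_zero_delta(self):
        matrix, ann, groups = _tiny_dataset()
        sym = ProbesetMatrix(
            matrix.signals[["a1", "a2", "a1", "a2"]].set_axis(
                ["a1", "a2", "b1", "b2"], axis=1
            )
        )
        deltas = group_delta(sym, ann, groups, "A", "B")
        for gd in deltas.values():
            assert np.allclose(gd.delta, 0.0)

    def test_whole_gene_shift_gives_constant_delta(self):
        matrix, ann, groups = _tiny_dataset()
        shifted = ProbesetMatrix(
            matrix.signals.assign(
                a1=matrix.signals["a1"] + 1.0, a2=matrix.signals["a2"] + 1.0
            )[matrix.sample_ids]
        )
        deltas = group_delta(shifted, ann, groups, "A", "B")
        assert np.allclose(deltas["TC2"].delta, 1.0)

    def test_planted_cassette_recovered_in_delta(self):
        matrix, ann, groups = _tiny_dataset()
        deltas = group_delta(matrix, ann, groups, "A", "B")
        assert np.allclose(deltas["TC1"].delta, [0, 0, -2, -2, 0, 0])

    def test_short_clusters_excluded(self):
        matrix, ann, groups = _tiny_dataset()
        mask = pd.Series(True, index=matrix.signals.index)
        mask.loc[["PS7", "PS8"]] = False  # TC2 down to 3 retained
        deltas = group_delta(matrix, ann, groups, "A", "B", mask=mask)
        assert "TC2" not in deltas and "TC1" in deltas

    def test_mask_restricts_scored_probesets(self):
        matrix, ann, groups = _tiny_dataset()
        mask = pd.Series(True, index=matrix.signals.index)
        mask.loc["PS2"] = False
        deltas = group_delta(matrix, ann, groups, "A", "B", mask=mask)
        assert deltas["TC1"].probeset_ids == (
            "PS0", "PS1", "PS3", "PS4", "PS5"
        )


class TestSelection:
    def _table(self, scores, comparison="A_vs_B"):
        return pd.DataFrame(
            {
                "probeset_id": [f"PS{i:04d}" for i in range(len(scores))],
                "transcript_cluster_id": [
                    f"TC{i // 2}" for i in range(len(scores))
                ],
                "comparison": comparison,
                "dsi1": 0.0, "dsi2": 0.0, "dsi3": 0.0,
                "dsiT": scores,
            }
        )

    def test_exactly_k_selected(self):
        table = select_top_k(self._table(np.arange(20.0)), "A_vs_B", k=5)
        assert table["selected"].sum() == 5
        top = table[table["selected"]]["probeset_id"]
        assert set(top) == {"PS0019", "PS0018", "PS0017", "PS0016", "PS0015"}

    def test_clipping_when_fewer_scoreable(self):
        table = select_top_k(self._table(np.arange(3.0)), "A_vs_B", k=100)
        assert table["selected"].sum() == 3

    def test_ties_broken_by_ascending_probeset_id(self):
        table = select_top_k(self._table(np.zeros(10)), "A_vs_B", k=4)
        chosen = sorted(table[table["selected"]]["probeset_id"])
        assert chosen == ["PS0000", "PS0001", "PS0002", "PS0003"]

    def test_aggregate_deduplicates_transcripts(self):
        table = select_top_k(self._table(np.arange(6.0)), "A_vs_B", k=4)
        out = aggregate_as_list(table)
        # PS2..PS5 selected -> clusters TC1, TC2 (two probesets each)
        assert set(out.index) == {"TC1", "TC2"}
        assert (out["n_selections"] == 2).all()

    def test_aggregate_empty_selection(self):
        table = self._table(np.arange(3.0)).assign(rank=0, selected=False)
        assert len(aggregate_as_list(table)) == 0


class TestPlanAndOverlap:
    def test_default_plan_has_21_comparisons(self):
        names = ["blood", "cd34", "breast", "cerebellum", "heart", "kidney",
                 "liver", "muscle", "pancreas", "prostate", "spleen",
                 "testis", "thyroid"]
        plan = default_plan(names)
        assert len(plan) == 21
        assert all("spleen" not in pair for pair in plan.pairs)
        assert ("blood", "cd34") in plan.pairs

    def test_overlap_disjoint(self):
        out = overlap_with_de({"x"}, {"a"}, {"b"})
        assert out["as_in_up"] == 0 and out["as_in_down"] == 0

    def test_overlap_subset(self):
        out = overlap_with_de({"a", "b"}, {"a", "b", "c"}, set())
        assert out["as_in_up"] == 2

    def test_up_union_from_signature_parts(self):
        """Union built from the 839 + 1217 + 506 signature parts is 2562."""
        a_specific = {f"a{i}" for i in range(839)}
        b_specific = {f"b{i}" for i in range(1217)}
        common = {f"c{i}" for i in range(506)}
        union = a_specific | b_specific | common
        out = overlap_with_de(set(), union, set())
        assert out["n_up_union"] == 2562


class TestSplicingModel:
    def test_full_plan_selects_quota(self, small_dataset):
        """21 comparisons at K=100 flag exactly 2,100 selections."""
        matrix, annotation, groups, _ = small_dataset
        res = SplicingModel(matrix, annotation, groups).fit(k=100)
        assert len(res.model.plan) == 21
        assert res.n_selected == 2100
        per_comp = res.table.groupby("comparison")["selected"].sum()
        assert (per_comp == 100).all()

    def test_planted_events_recovered(self, small_dataset):
        """>=80% of planted AS genes appear in the aggregated list."""
        matrix, annotation, groups, truth = small_dataset
        res = SplicingModel(matrix, annotation, groups).fit(k=100)
        planted = truth.as_gene_ids
        recovered = planted & res.as_transcripts
        assert len(recovered) / len(planted) >= 0.8

    def test_whole_gene_shift_leaves_scores_unchanged(self, small_dataset):
        """Adding a constant to one group's signals changes no dsiT."""
        matrix, annotation, groups, _ = small_dataset
        res1 = SplicingModel(matrix, annotation, groups).fit(k=100)
        blood = groups.samples_in("blood")
        sig = matrix.signals.copy()
        sig[blood] = sig[blood] + 5.0
        res2 = SplicingModel(
            ProbesetMatrix(sig, matrix.detection_p), annotation, groups
        ).fit(k=100)
        pd.testing.assert_frame_equal(res1.table, res2.table, atol=1e-9, rtol=0)
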