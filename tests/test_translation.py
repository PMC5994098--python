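"""Stage-increased classification, overlap scaling and mode calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenomics as pk
from pollenomics.clustering import ClusterModel
from pollenomics.translation import dominant_stage

CFG = pk.ModeConfig()
STAGES = list(pk.STAGES)


def make_model(assignment: dict, centroids: list[list[float]]) -> ClusterModel:
    k = len(centroids)
    return ClusterModel(
        k=k,
        assignment=pd.Series(assignment, name="cluster"),
        centroids=pd.DataFrame(
            centroids, columns=STAGES, index=pd.RangeIndex(k, name="cluster")
        ),
        run_variances=np.zeros(1),
        selected_run=0,
        variance=0.0,
    )


class TestClassifyStageIncreased:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ([0.70, 0.20, 0.10], "tetrad"),
            ([0.66, 0.24, 0.10], None),          # 0.66 < 2/3 at default bound
            ([2 / 3, 1 / 6, 1 / 6], "tetrad"),   # inclusive at exactly 2/3
            ([0.50, 0.30, 0.20], None),
            ([0.10, 0.15, 0.75], "mature"),
        ],
    )
    def test_two_thirds_rule(self, centroid, expected):
        s = pd.Series(centroid, index=STAGES)
        assert pk.classify_stage_increased(s, CFG) == expected

    def test_explicit_066_bound(self):
        # with an explicit 0.66 bound the 0.66 centroid qualifies
        cfg = pk.ModeConfig(increase_threshold=0.66)
        s = pd.Series([0.66, 0.24, 0.10], index=STAGES)
        assert pk.classify_stage_increased(s, cfg) == "tetrad"

    @given(st.lists(st.floats(0.01, 1), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_none_when_max_below_half(self, raw):
        total = sum(raw)
        frac = pd.Series([v / total for v in raw], index=STAGES)
        if frac.max() < 0.5:
            assert pk.classify_stage_increased(frac, CFG) is None


class TestImpliedMinFold:
    @pytest.mark.parametrize(
        "t,expected", [(2 / 3, 2.0), (0.5, 1.0), (0.8, 4.0)]
    )
    def test_worst_case_ratio(self, t, expected):
        cfg = pk.ModeConfig(increase_threshold=t)
        assert pk.implied_min_fold(cfg) == pytest.approx(expected)

    def test_below_half_undefined(self):
        with pytest.raises(pk.PipelineError):
            pk.implied_min_fold(pk.ModeConfig(increase_threshold=0.4))

    @given(st.floats(0.51, 0.95), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_guarantee_holds_for_admissible_centroids(self, t, a, b):
        """Any centroid with fraction >= t has fold >= t/(1-t) over others."""
        rest = 1 - t
        others = np.array([a, b])
        if others.sum() > 0:
            others = others / others.sum() * rest
        else:
            others = np.array([rest, 0.0])
        fold = pk.implied_min_fold(pk.ModeConfig(increase_threshold=t))
        assert t >= fold * others.max() - 1e-9


class TestOverlapMatrix:
    def test_single_shared_gene(self):
        tr = make_model({"g1": 0, "g2": 1}, [[1, 0, 0], [0, 1, 0]])
        pr = make_model({"g1": 1, "g2": 0}, [[1, 0, 0], [0, 1, 0]])
        ov = pk.build_overlap_matrix(tr, pr, ["g1"])
        assert ov.loc[0, 1] == 1
        assert ov.to_numpy().sum() == 1

    def test_row_sums_are_cluster_sizes(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        tr = make_model(
            dict(zip(genes, rng.integers(0, 3, 12))),
            [[1, 0, 0]] * 3,
        )
        pr = make_model(
            dict(zip(genes, rng.integers(0, 2, 12))),
            [[1, 0, 0]] * 2,
        )
        ov = pk.build_overlap_matrix(tr, pr, genes)
        for cl in range(3):
            assert ov.loc[cl].sum() == (tr.assignment == cl).sum()

    def test_disjoint_memberships_zero(self):
        tr = make_model({"g1": 0}, [[1, 0, 0]])
        pr = make_model({"g2": 0}, [[1, 0, 0]])
        ov = pk.build_overlap_matrix(tr, pr, ["g1", "g2"])
        assert ov.to_numpy().sum() == 0


class TestScaleOverlapRow:
    def test_examples(self):
        scaled, deg = pk.scale_overlap_row([2, 5, 8])
        assert scaled.tolist() == [0.0, 0.5, 1.0]
        assert not deg

    def test_degenerate_row(self):
        scaled, deg = pk.scale_overlap_row([3, 3, 3])
        assert scaled.tolist() == [0.0, 0.0, 0.0]
        assert deg

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=10),
        st.floats(0.1, 10),
        st.floats(-100, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, counts, a, b):
        x = np.array(counts, dtype=float)
        s1, d1 = pk.scale_overlap_row(x)
        s2, d2 = pk.scale_overlap_row(a * x + b)
        assert d1 == d2
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_max_maps_to_one(self):
        scaled, deg = pk.scale_overlap_row([1, 4, 2])
        assert scaled.max() == 1.0


class TestCallTranslationModes:
    """Toy two-level clusterings with hand-computable overlaps."""

    def _models(self):
        # transcripts: cluster 0 tetrad-increased (g1..g6),
        #              cluster 1 mature-increased (h1..h3), cluster 2 flat
        tr = make_model(
            {**{f"g{i}": 0 for i in range(1, 7)},
             **{f"h{i}": 1 for i in range(1, 4)},
             "f1": 2},
            [[0.8, 0.1, 0.1], [0.1, 0.1, 0.8], [0.34, 0.33, 0.33]],
        )
        # proteins: cluster 0 tetrad-dominant (g1..g4 -> direct),
        #           cluster 1 post-meiotic-dominant (g5, g6 -> delayed),
        #           cluster 2 mature-dominant (h1..h3 -> direct at mature)
        pr = make_model(
            {**{f"g{i}": 0 for i in range(1, 5)},
             "g5": 1, "g6": 1,
             **{f"h{i}": 2 for i in range(1, 4)},
             "f1": 1},
            [[0.7, 0.2, 0.1], [0.2, 0.6, 0.2], [0.1, 0.2, 0.7]],
        )
        genes = [f"g{i}" for i in range(1, 7)] + ["h1", "h2", "h3", "f1"]
        return tr, pr, genes

    def test_direct_and_delayed_calls(self):
        tr, pr, genes = self._models()
        calls = pk.call_translation_modes(tr, pr, genes, CFG)
        by = {(r.gene_id, r.stage): r.mode for r in calls.itertuples()}
        # tetrad set row over protein clusters: (4, 2, 0) -> scaled (1, .5, 0)
        # -> only protein cluster 0 (same stage) called: direct
        for g in ("g1", "g2", "g3", "g4"):
            assert by[(g, "tetrad")] == "direct"
        # g5, g6 overlap scaled 0.5 exactly -> strict rule: no call
        assert ("g5", "tetrad") not in by
        # mature transcripts -> mature-dominant proteins: direct at mature
        for h in ("h1", "h2", "h3"):
            assert by[(h, "mature")] == "direct"

    def test_delayed_called_from_protein_side(self):
        # protein cluster post-meiotic-increased; transcripts tetrad-increased
        tr = make_model(
            {f"g{i}": 0 for i in range(1, 5)}, [[0.8, 0.1, 0.1], ]
        )
        pr = make_model(
            {**{f"g{i}": 0 for i in range(1, 5)}, "x1": 1},
            [[0.1, 0.8, 0.1], [0.4, 0.3, 0.3]],
        )
        calls = pk.call_translation_modes(tr, pr, [f"g{i}" for i in range(1, 5)] + ["x1"], CFG)
        modes = set(zip(calls["gene_id"], calls["stage"], calls["mode"]))
        # protein rises one stage after the transcript: delayed at tetrad
        for g in ("g1", "g2", "g3", "g4"):
            assert (g, "tetrad", "delayed") in modes

    def test_no_delayed_for_final_stage(self):
        # mature-increased transcripts cannot have delayed calls, and a
        # protein cluster "dominant" beyond mature does not exist
        tr = make_model(
            {"m1": 0, "m2": 0, "z": 1},
            [[0.1, 0.1, 0.8], [0.8, 0.1, 0.1]],
        )
        pr = make_model(
            {"m1": 0, "m2": 0, "z": 1},
            [[0.1, 0.1, 0.8], [0.8, 0.1, 0.1]],
        )
        calls = pk.call_translation_modes(tr, pr, ["m1", "m2", "z"], CFG)
        assert not ((calls["stage"] == "mature") & (calls["mode"] == "delayed")).any()

    def test_one_mode_per_gene_and_stage(self, default_recovery):
        _, result, _ = default_recovery
        dup = result.mode_calls.groupby(["gene_id", "stage"]).size()
        assert (dup <= 1).all()

    def test_earlier_stage_partner_gives_no_call(self):
        # transcript mature-increased, protein tetrad-dominant: protein
        # precedes transcript -> unclassified
        tr = make_model({"a": 0, "b": 1}, [[0.1, 0.1, 0.8], [0.5, 0.3, 0.2]])
        pr = make_model({"a": 0, "b": 1}, [[0.8, 0.1, 0.1], [0.3, 0.4, 0.3]])
        calls = pk.call_translation_modes(tr, pr, ["a", "b"], CFG)
        assert calls.empty


def test_dominant_stage_is_argmax():
    s = pd.Series([0.2, 0.5, 0.3], index=STAGES)
    assert dominant_stage(s) == "post_meiotic"
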