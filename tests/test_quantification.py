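"""Tags-per-million normalisation, detection thresholding and averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenomics as pk
from pollenomics.quantification import mask_undetected

from conftest import make_matrix


def counts_matrix(cols, groups):
    return make_matrix(cols, groups, unit="count")


class TestComputeTpm:
    def test_worked_examples(self):
        m = counts_matrix(
            {"L1": [2.0, 0.0]}, {"L1": ("tetrad", "CO", 1)}
        )
        tpm = pk.compute_tpm(m, {"L1": 400_000})
        assert tpm.values.loc[:, "L1"].tolist() == [5.0, 0.0]
        assert tpm.unit == "TPM"

    def test_column_sum_bounded_by_one_million(self):
        m = counts_matrix(
            {"L1": [100.0, 250.0, 30.0]}, {"L1": ("tetrad", "CO", 1)}
        )
        tpm = pk.compute_tpm(m, {"L1": 380.0})
        assert tpm.values["L1"].sum() == pytest.approx(1e6)

    def test_scale_equivariance(self):
        m = counts_matrix(
            {"L1": [3.0, 7.0], "L2": [1.0, 9.0]},
            {"L1": ("tetrad", "CO", 1), "L2": ("tetrad", "CO", 2)},
        )
        doubled = counts_matrix(
            {"L1": [6.0, 14.0], "L2": [2.0, 18.0]},
            {"L1": ("tetrad", "CO", 1), "L2": ("tetrad", "CO", 2)},
        )
        t1 = pk.compute_tpm(m, {"L1": 100, "L2": 50})
        t2 = pk.compute_tpm(doubled, {"L1": 200, "L2": 100})
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_errors(self):
        m = counts_matrix({"L1": [2.0]}, {"L1": ("tetrad", "CO", 1)})
        with pytest.raises(KeyError):
            pk.compute_tpm(m, {})
        with pytest.raises(pk.PipelineError):
            pk.compute_tpm(m, {"L1": 0})
        with pytest.raises(pk.PipelineError):
            pk.compute_tpm(m, {"L1": 1})  # assigned reads exceed total


class TestDetectionThreshold:
    @pytest.mark.parametrize(
        "controls,expected",
        [([4.3, 1.2, 0.5], 5), ([0.0, 0.0], 1), ([5.0], 6), ([4.0], 5)],
    )
    def test_strictly_above_max(self, controls, expected):
        assert pk.derive_detection_threshold(controls) == expected

    def test_empty_controls_error(self):
        with pytest.raises(pk.PipelineError):
            pk.derive_detection_threshold([])

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_threshold_is_integer_strictly_above_controls(self, controls):
        thr = pk.derive_detection_threshold(controls)
        assert isinstance(thr, int) and thr >= 1
        assert thr > max(controls)
        assert thr - 1 <= max(max(controls), 0)


class TestTranscriptDetection:
    def test_zeroing_and_replicate_rule(self, two_rep_matrix):
        cfg = pk.DetectionConfig(tpm_threshold=5, transcript_min_replicates=2)
        filtered, flags = pk.apply_transcript_detection(two_rep_matrix, cfg)
        # (4.9, 6.0): one replicate zeroed -> not detected
        assert filtered.values.iloc[0].tolist() == [0.0, 6.0]
        assert not flags.iloc[0][("tetrad", "CO")]
        # (6.0, 7.0): detected
        assert flags.iloc[1][("tetrad", "CO")]
        # (0, 8.0): not detected
        assert not flags.iloc[2][("tetrad", "CO")]

    def test_idempotent(self, two_rep_matrix):
        cfg = pk.DetectionConfig(tpm_threshold=5)
        once, flags1 = pk.apply_transcript_detection(two_rep_matrix, cfg)
        twice, flags2 = pk.apply_transcript_detection(once, cfg)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_frame_equal(flags1, flags2)

    def test_detection_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 5, size=(50, 2))
        m = make_matrix(
            {"L1": vals[:, 0], "L2": vals[:, 1]},
            {"L1": ("tetrad", "CO", 1), "L2": ("tetrad", "CO", 2)},
        )
        counts = []
        for thr in (1, 5, 10, 20):
            _, flags = pk.apply_transcript_detection(
                m, pk.DetectionConfig(tpm_threshold=thr)
            )
            counts.append(int(flags[("tetrad", "CO")].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_replicates_error(self):
        m = make_matrix({"L1": [6.0]}, {"L1": ("tetrad", "CO", 1)})
        with pytest.raises(pk.PipelineError):
            pk.apply_transcript_detection(
                m, pk.DetectionConfig(transcript_min_replicates=2)
            )


class TestProteinDetection:
    def test_two_of_three_rule(self):
        members = {"PG1": ["a.1"], "PG2": ["b.1"], "PG3": ["c.1"]}
        intens = pd.DataFrame(
            {
                "P1": [0.0, 0.0, 1e6],
                "P2": [1e6, 0.0, 1e6],
                "P3": [2e6, 3e6, 1e6],
            },
            index=pd.Index(members, name="group_id"),
        )
        meta = pd.DataFrame(
            [
                {"library_id": f"P{r}", "level": "protein", "stage": "tetrad",
                 "condition": "CO", "replicate": r}
                for r in (1, 2, 3)
            ]
        ).set_index("library_id")
        pq = pk.ProteinQuantTable(members, intens, meta)
        flags = pk.apply_protein_detection(pq, pk.DetectionConfig())
        assert flags[("tetrad", "CO")].tolist() == [True, False, True]


class TestAverageReplicates:
    @pytest.mark.parametrize(
        "reps,expected", [([10.0, 0.0], 10.0), ([10.0, 20.0], 15.0), ([0.0, 0.0], 0.0)]
    )
    def test_zero_ignoring_mean(self, reps, expected):
        m = make_matrix(
            {"L1": [reps[0]], "L2": [reps[1]]},
            {"L1": ("tetrad", "CO", 1), "L2": ("tetrad", "CO", 2)},
        )
        avg = pk.average_replicates(m)
        assert avg.values.iloc[0, 0] == expected

    @given(
        st.lists(st.floats(0, 1e5), min_size=2, max_size=6).filter(
            lambda x: any(v > 0 for v in x)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_nonzero_replicates(self, reps):
        m = make_matrix(
            {f"L{i}": [v] for i, v in enumerate(reps)},
            {f"L{i}": ("tetrad", "CO", i + 1) for i in range(len(reps))},
        )
        avg = float(pk.average_replicates(m).values.iloc[0, 0])
        pos = [v for v in reps if v > 0]
        assert min(pos) - 1e-9 <= avg <= max(pos) + 1e-9


class TestUngroupProteins:
    def _pq(self, members, n_groups):
        intens = pd.DataFrame(
            {"P1": np.arange(1.0, n_groups + 1)},
            index=pd.Index(members, name="group_id"),
        )
        meta = pd.DataFrame(
            [{"library_id": "P1", "level": "protein", "stage": "tetrad",
              "condition": "CO", "replicate": 1}]
        ).set_index("library_id")
        return pk.ProteinQuantTable(members, intens, meta)

    def test_members_share_group_intensities(self):
        pq = self._pq({"PG1": ["a.1", "b.1"]}, 1)
        frame, unmapped = pk.ungroup_proteins(pq, {"a.1": "gA", "b.1": "gB"})
        assert sorted(frame.index) == ["gA", "gB"]
        assert frame.loc["gA", "P1"] == frame.loc["gB", "P1"] == 1.0
        assert unmapped == []

    def test_disjoint_groups_row_count(self):
        pq = self._pq({"PG1": ["a.1", "b.1"], "PG2": ["c.1"]}, 2)
        frame, _ = pk.ungroup_proteins(
            pq, {"a.1": "gA", "b.1": "gB", "c.1": "gC"}
        )
        assert len(frame) == 3

    def test_unmapped_member_excluded(self):
        pq = self._pq({"PG1": ["a.1", "zz.1"]}, 1)
        frame, unmapped = pk.ungroup_proteins(pq, {"a.1": "gA"})
        assert list(frame.index) == ["gA"]
        assert unmapped == ["zz.1"]

    def test_same_gene_rows_collapse_to_max(self):
        pq = self._pq({"PG1": ["a.1"], "PG2": ["a.2"]}, 2)
        frame, _ = pk.ungroup_proteins(pq, {"a.1": "gA", "a.2": "gA"})
        assert list(frame.index) == ["gA"]
        assert frame.loc["gA", "P1"] == 2.0


def test_mask_undetected_zeroes_undetected_groups(two_rep_matrix):
    cfg = pk.DetectionConfig(tpm_threshold=5)
    filtered, flags = pk.apply_transcript_detection(two_rep_matrix, cfg)
    avg = pk.average_replicates(filtered)
    masked = mask_undetected(avg, flags)
    assert masked.values.iloc[0, 0] == 0.0      # not detected -> zeroed
    assert masked.values.iloc[1, 0] == pytest.approx(6.5)
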