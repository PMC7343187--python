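"""Footprint filtering, centre-weighted coverage, RPKM and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rimsys.riboseq import (
    AlignedRead,
    CoverageTrack,
    GeneModel,
    center_weighted_coverage,
    classify_regulon,
    coverage_tracks,
    differential_protein_filter,
    filter_reads,
    rpkm_table,
)

from conftest import naive_coverage


def read(start, span, strand="+", ref="toy1"):
    return AlignedRead(reference=ref, strand=strand, start=start, span=span)


class TestFilterReads:
    @pytest.mark.parametrize(
        "span, kept",
        [(22, False), (23, True), (30, True), (41, True), (42, False)],
    )
    def test_window_bounds_inclusive(self, span, kept):
        out = list(filter_reads([read(0, span)]))
        assert (len(out) == 1) is kept

    def test_empty_stream(self):
        assert list(filter_reads([])) == []


class TestCenterWeightedCoverage:
    def test_thirty_mer_counts_eight_positions(self):
        # [100, 130) trimmed by 11 each end -> [111, 119), i.e. 30 - 22 = 8
        track = center_weighted_coverage([read(100, 30)], 200, "+")
        hit = np.flatnonzero(track.counts)
        assert list(hit) == list(range(111, 119))
        assert track.total == 8.0

    def test_minimal_footprint_counts_one_position(self):
        track = center_weighted_coverage([read(0, 23)], 50, "+")
        assert track.counts[11] == 1
        assert track.total == 1.0

    def test_no_reads_all_zero(self):
        track = center_weighted_coverage([], 100, "+")
        assert track.total == 0.0

    def test_strands_accumulate_separately(self):
        reads = [read(10, 30, "+"), read(10, 30, "-")]
        fwd = center_weighted_coverage(reads, 100, "+")
        rev = center_weighted_coverage(reads, 100, "-")
        assert fwd.total == rev.total == 8.0

    def test_window_past_reference_end_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            track = center_weighted_coverage([read(80, 30)], 95, "+")
        assert "clipped" in caplog.text
        assert track.total == 4.0  # positions 91..94 only

    def test_conservation_and_oracle_on_random_reads(self):
        rng = np.random.default_rng(12)
        ref_len = 2000
        reads = [
            read(
                int(rng.integers(0, ref_len - 41)),
                int(rng.integers(23, 42)),
                "+" if rng.random() < 0.5 else "-",
            )
            for _ in range(1000)
        ]
        for strand in "+-":
            track = center_weighted_coverage(reads, ref_len, strand)
            assert np.array_equal(
                track.counts, naive_coverage(reads, ref_len, strand)
            )
        total = sum(
            center_weighted_coverage(reads, ref_len, s).total for s in "+-"
        )
        assert total == sum(r.span - 22 for r in reads)


class TestRpkm:
    def _tracks(self, gene_count, genome=10_000):
        fwd = np.zeros(genome, dtype=np.int64)
        rev = np.zeros(genome, dtype=np.int64)
        fwd[1000 : 1000 + gene_count] = 1  # inside the 1001..3000 gene
        # pad the genome-wide total to one million counted positions
        rev[0] = 1_000_000 - gene_count
        return {
            ("toy1", "+"): CoverageTrack("toy1", "+", fwd),
            ("toy1", "-"): CoverageTrack("toy1", "-", rev),
        }

    def test_worked_example(self):
        # 200 counts on a 2 kb gene with a 1e6 genome-wide total -> RPKM 100
        tracks = self._tracks(200)
        genes = [GeneModel("g1", "toy1", "+", 1001, 3000)]
        table = rpkm_table(tracks, genes)
        assert table.loc["g1", "count"] == 200.0
        assert table.loc["g1", "rpkm"] == pytest.approx(100.0)

    def test_antisense_coverage_does_not_count(self):
        tracks = self._tracks(200)
        genes = [GeneModel("g1", "toy1", "-", 1001, 3000)]
        table = rpkm_table(tracks, genes)
        assert table.loc["g1", "rpkm"] == pytest.approx(0.0)

    def test_zero_count_zero_rpkm(self):
        tracks = self._tracks(200)
        genes = [GeneModel("g2", "toy1", "+", 5001, 6000)]
        assert rpkm_table(tracks, genes).loc["g2", "rpkm"] == 0.0

    def test_unknown_reference_rejected(self):
        tracks = self._tracks(10)
        with pytest.raises(KeyError, match="gX"):
            rpkm_table(tracks, [GeneModel("gX", "other", "+", 1, 10)])


class TestClassifyRegulon:
    @pytest.mark.parametrize(
        "a, b, label",
        [
            (1.5, -1.4, "class3"),
            (1.5, 0.2, "class1"),
            (1.5, 1.4, "class2"),
            (-1.5, -1.4, "class2"),
            (0.3, 1.2, "glutamation_only"),
            (0.0, 0.0, "unaffected"),
            (1.0, 1.0, "unaffected"),  # threshold is strict
        ],
    )
    def test_examples(self, a, b, label):
        table = pd.DataFrame({"log2_a": [a], "log2_b": [b]}, index=["g"])
        assert classify_regulon(table).loc["g"] == label

    def test_missing_contrast_unclassifiable(self):
        table = pd.DataFrame(
            {"log2_a": [np.nan], "log2_b": [2.0]}, index=["g"]
        )
        assert classify_regulon(table).loc["g"] == "unclassifiable"

    def test_invalid_tau_rejected(self):
        table = pd.DataFrame({"log2_a": [0.0], "log2_b": [0.0]})
        with pytest.raises(ValueError):
            classify_regulon(table, tau=0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(-20, 20, allow_nan=False),
        b=st.floats(-20, 20, allow_nan=False),
    )
    def test_partition_every_gene_gets_exactly_one_label(self, a, b):
        table = pd.DataFrame({"log2_a": [a], "log2_b": [b]}, index=["g"])
        label = classify_regulon(table).loc["g"]
        assert label in (
            "class1",
            "class2",
            "class3",
            "glutamation_only",
            "unaffected",
        )


class TestProteinFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["peptides", "log2_wt", "log2_mut", "p_wt", "p_mut"],
            index=[f"p{i}" for i in range(len(rows))],
        )

    def test_flagged_up(self):
        table = self._table([[2, 0.0, 1.1, 0.5, 0.04]])
        out = differential_protein_filter(table)
        assert list(out.index) == ["p0"]
        assert out.loc["p0", "direction"] == "up"

    def test_single_peptide_excluded_despite_strong_effect(self):
        table = self._table([[1, 0.0, 3.0, 0.001, 0.001]])
        assert differential_protein_filter(table).empty

    def test_small_difference_excluded(self):
        table = self._table([[3, 0.0, 0.5, 0.01, 0.01]])
        assert differential_protein_filter(table).empty

    def test_no_significant_pvalue_excluded(self):
        table = self._table([[3, 0.0, 2.0, 0.2, 0.6]])
        assert differential_protein_filter(table).empty

    def test_down_direction(self):
        table = self._table([[4, 1.0, -0.5, 0.01, 0.9]])
        out = differential_protein_filter(table)
        assert out.loc["p0", "direction"] == "down"

    def test_missing_pvalues_excluded_with_warning(self, caplog):
        table = self._table(
            [[3, 0.0, 2.0, np.nan, 0.01], [3, 0.0, 2.0, 0.01, 0.9]]
        )
        with caplog.at_level("WARNING"):
            out = differential_protein_filter(table)
        assert "missing p-values" in caplog.text
        assert list(out.index) == ["p1"]
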