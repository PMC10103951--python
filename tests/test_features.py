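import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braincirc import features, io
from braincirc.features import IntervalTrack
from braincirc.io import CircRecord, GeneModel

EXONS = ((100, 200), (300, 400), (500, 600), (700, 800))


def gene(strand="+", transcripts=None, gene_id="G1"):
    return GeneModel(
        gene_id=gene_id, chrom="chr1", strand=strand,
        transcripts=transcripts or {"t1": EXONS},
    )


def circ(start, end, blocks, strand="+", host="G1"):
    return CircRecord(
        chrom="chr1", start=start, end=end, strand=strand, circ_class="exonic",
        host_gene=host, exon_blocks=blocks, bsj_reads_total=5,
    )


class TestFlankingIntrons:
    def test_internal_exon_run(self):
        c = circ(300, 600, ((300, 100), (500, 100)))
        up, down = features.flanking_introns(c, gene())
        assert up == (200, 300) and down == (600, 700)

    def test_first_exon_has_no_upstream_intron(self):
        c = circ(100, 200, ((100, 100),))
        up, down = features.flanking_introns(c, gene())
        assert up is None and down == (200, 300)

    def test_minus_strand_swaps_labels(self):
        c = circ(300, 600, ((300, 100), (500, 100)), strand="-")
        up, down = features.flanking_introns(c, gene(strand="-"))
        assert up == (600, 700) and down == (200, 300)

    def test_strict_mode_rejects_mid_exon_boundary(self):
        c = circ(350, 600, ((350, 50), (500, 100)))
        with pytest.raises(features.BoundaryError):
            features.flanking_introns(c, gene(), strict=True)

    def test_lenient_mode_uses_nearest_exon_edges(self):
        c = circ(350, 600, ((350, 50), (500, 100)))
        up, down = features.flanking_introns(c, gene(), strict=False)
        assert up is None  # start is inside an exon: no clean upstream gap
        assert down == (600, 700)

    def test_exon_order_on_input_does_not_matter(self):
        shuffled = GeneModel(
            gene_id="G1", chrom="chr1", strand="+",
            transcripts={"t1": tuple(sorted(EXONS))},
        )
        c = circ(300, 600, ((300, 100), (500, 100)))
        assert features.flanking_introns(c, shuffled) == (
            (200, 300), (600, 700),
        )

    def test_longest_transcript_breaks_ambiguity(self):
        transcripts = {
            "short": EXONS[:3],
            "long": EXONS,
        }
        c = circ(300, 600, ((300, 100), (500, 100)))
        up, down = features.flanking_introns(c, gene(transcripts=transcripts))
        assert down == (600, 700)  # the long transcript has a following exon

    def test_wrong_host_gene_raises(self):
        c = circ(300, 600, ((300, 100), (500, 100)), host="OTHER")
        with pytest.raises(io.ValidationError):
            features.flanking_introns(c, gene())


class TestOverlapCount:
    def test_spanning_query_counts_both(self):
        track = IntervalTrack.from_intervals("t", [("chr1", 10, 20), ("chr1", 30, 40)])
        assert features.overlap_count(("chr1", 15, 35), track) == 2

    def test_half_open_touch_is_no_overlap(self):
        track = IntervalTrack.from_intervals("t", [("chr1", 10, 20)])
        assert features.overlap_count(("chr1", 20, 25), track) == 0

    def test_empty_track(self):
        track = IntervalTrack.from_intervals("t", [])
        assert features.overlap_count(("chr1", 0, 100), track) == 0

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 1000))
        starts = rng.integers(0, 10_000, n)
        ends = starts + rng.integers(1, 500, n)
        track = IntervalTrack.from_intervals(
            "t", [("chr1", int(s), int(e)) for s, e in zip(starts, ends)]
        )
        qs = int(rng.integers(0, 10_000))
        qe = qs + int(rng.integers(1, 1000))
        expected = int(np.sum((starts < qe) & (ends > qs)))
        assert features.overlap_count(("chr1", qs, qe), track) == expected


class TestCircPerGene:
    def _models(self, exon_counts):
        models = {}
        for i, n in enumerate(exon_counts):
            exons = tuple((1000 * j, 1000 * j + 100) for j in range(n))
            models[f"G{i}"] = GeneModel(
                gene_id=f"G{i}", chrom="chr1", strand="+", transcripts={"t1": exons}
            )
        return models

    def _circs(self, counts_per_gene, models):
        circs = []
        for i, n in enumerate(counts_per_gene):
            exons = models[f"G{i}"].transcripts["t1"]
            for j in range(n):
                s, e = exons[0][0], exons[0][1]
                circs.append(
                    CircRecord(
                        chrom="chr1", start=s, end=e, strand="+",
                        circ_class="exonic", host_gene=f"G{i}",
                        exon_blocks=((s, e - s),), bsj_reads_total=j,
                    )
                )
        return circs

    def test_perfectly_linear_relation(self):
        models = self._models([2, 4, 8])
        circs = self._circs([1, 2, 4], models)
        _, r, degenerate = features.circ_per_gene_vs_exons(circs, models)
        assert not degenerate
        assert r == pytest.approx(1.0)

    def test_constant_counts_flagged_as_degenerate(self):
        models = self._models([2, 4, 8])
        circs = self._circs([2, 2, 2], models)
        _, r, degenerate = features.circ_per_gene_vs_exons(circs, models)
        assert degenerate and r == 0.0

    def test_too_few_genes_rejected(self):
        models = self._models([2, 4])
        with pytest.raises(io.ValidationError):
            features.circ_per_gene_vs_exons([], models)

    def test_synthetic_annotation_is_correlated(self, small_dataset):
        _, r, _ = features.circ_per_gene_vs_exons(
            small_dataset["records"], small_dataset["models"]
        )
        assert r > 0.5


class TestSnpProximity:
    CIRC = [
        CircRecord(
            chrom="chr1", start=1_000_000, end=1_010_000, strand="+",
            circ_class="exonic", host_gene="G", bsj_reads_total=3,
            exon_blocks=((1_000_000, 10_000),),
        )
    ]

    def _snps(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "position": positions,
             "snp_id": [f"rs{i}" for i in range(len(positions))]}
        )

    def test_window_covers_half_the_snps(self):
        frac = features.snp_proximity_fraction(
            self._snps([1_500_000, 3_000_000]), self.CIRC, window=1_000_000
        )
        assert frac == 0.5

    def test_no_circs_gives_zero(self):
        assert features.snp_proximity_fraction(self._snps([5]), [], 100) == 0.0

    def test_zero_window_counts_only_interior_snps(self):
        frac = features.snp_proximity_fraction(
            self._snps([1_009_999, 1_010_000]), self.CIRC, window=0
        )
        assert frac == 0.5

    def test_empty_snp_table_rejected(self):
        with pytest.raises(io.ValidationError):
            features.snp_proximity_fraction(self._snps([]), self.CIRC, 10)

    @given(windows=st.lists(st.integers(0, 3_000_000), min_size=2, max_size=6))
    def test_monotone_in_window(self, windows):
        snps = self._snps([0, 900_000, 1_500_000, 2_500_000, 5_000_000])
        fracs = [
            features.snp_proximity_fraction(snps, self.CIRC, w)
            for w in sorted(windows)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestFeatureSummaryAndCompare:
    def test_summary_with_tracks(self):
        repeats = IntervalTrack.from_intervals(
            "rep", [("chr1", 210, 220), ("chr1", 250, 260), ("chr1", 650, 660)]
        )
        eclip = IntervalTrack.from_intervals("eclip", [("chr1", 320, 330)])
        c = circ(300, 600, ((300, 100), (500, 100)))
        table = features.feature_summary([c], {"G1": gene()}, repeats, eclip)
        row = table.iloc[0]
        assert row["upstream_intron_length"] == 100
        assert row["upstream_repeats"] == 2
        assert row["downstream_repeats"] == 1
        assert row["eclip_peaks"] == 1
        assert row["total_exon_length"] == 200

    def test_compare_feature_detects_shift(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(3, 0.3, 100)
        b = rng.lognormal(2, 0.3, 100)
        res, med_a, med_b = features.compare_feature(a, b)
        assert med_a > med_b
        assert res.pvalue < 1e-6

    def test_proportion_percent_printed_style(self):
        assert features.proportion_percent(96, 109) == 88.1
        assert features.proportion_percent(174, 217) == 80.2
        assert features.proportion_percent(2334, 2357, decimals=0) == 99
        with pytest.raises(io.ValidationError):
            features.proportion_percent(5, 0)
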