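"""FPKM, detectability, allele fractions, and discordance classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reanno.core import AnnotationSet, Feature, Location, ThresholdConfig
from reanno.expression import (
    GENOME_ABSENT,
    ExpressionRecord,
    SiteCounts,
    allele_fraction,
    annotate_site_context,
    call_rna_only_variant,
    detectability,
    fpkm,
)


class TestFpkm:
    @pytest.mark.parametrize(
        "reads,total,length,expected",
        [(0, 10**6, 500, 0.0), (10, 10**6, 1000, 10.0), (1, 10**9, 1000, 0.001)],
    )
    def test_formula(self, reads, total, length, expected):
        assert fpkm(reads, total, length) == pytest.approx(expected)

    @pytest.mark.parametrize("total,length", [(0, 100), (100, 0)])
    def test_zero_inputs_rejected(self, total, length):
        with pytest.raises(ValueError):
            fpkm(10, total, length)

    @given(reads=st.integers(0, 10**6), total=st.integers(1, 10**9),
           length=st.integers(1, 10**5), k=st.integers(2, 10))
    @settings(max_examples=200, deadline=None)
    def test_linear_in_reads_inverse_in_length_and_library(self, reads, total, length, k):
        base = fpkm(reads, total, length)
        assert fpkm(k * reads, total, length) == pytest.approx(k * base)
        assert fpkm(reads, k * total, length) == pytest.approx(base / k)
        assert fpkm(reads, total, k * length) == pytest.approx(base / k)


class TestDetectability:
    def _records(self, n_detectable, n_total):
        return [
            ExpressionRecord(f"nc{i:04d}", 100, 50 if i < n_detectable else 0, "s1")
            for i in range(n_total)
        ]

    def test_counts_reproduce_printed_fraction(self):
        """208 of 245 ncRNAs with reads -> 85% detectable."""
        fraction, detectable, undetectable = detectability(
            self._records(208, 245), total_mapped_reads=10**6
        )
        assert fraction == 85.0
        assert len(detectable) == 208 and len(undetectable) == 37

    def test_all_zero_counts_undetectable(self):
        fraction, detectable, _ = detectability(self._records(0, 10), total_mapped_reads=10**6)
        assert fraction == 0.0 and detectable == []

    def test_detectable_in_any_sample_counts(self):
        records = [
            ExpressionRecord("a", 100, 0, "s1"),
            ExpressionRecord("a", 100, 9, "s2"),
            ExpressionRecord("b", 100, 0, "s1"),
            ExpressionRecord("b", 100, 0, "s2"),
        ]
        fraction, detectable, undetectable = detectability(records, total_mapped_reads=10**6)
        assert detectable == ["a"] and undetectable == ["b"]
        assert fraction == 50.0

    def test_threshold_is_strict(self):
        cfg = ThresholdConfig(fpkm_detect_min=10.0)
        records = [ExpressionRecord("a", 1000, 10, "s1")]  # FPKM exactly 10
        fraction, detectable, _ = detectability(records, cfg, total_mapped_reads=10**6)
        assert detectable == []

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            detectability([])

    def test_planted_detectable_ids_recovered(self):
        from reanno.simulate import make_counts

        records = make_counts(None, "expression",
                              {"n_features": 60, "zero_fraction": 0.25}, seed=5)
        planted = {r.feature_id for r in records if r.assigned_reads > 0}
        _, detectable, _ = detectability(records, total_mapped_reads=10**6)
        assert set(detectable) == planted


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "alt,total,expected",
        [(655, 773, 85.0), (910_914, 911_345, 100.0), (0, 100, 0.0)],
    )
    def test_printed_read_counts(self, alt, total, expected):
        site = SiteCounts("c", 1_094_824, "C", "T", alt, total, "s")
        assert allele_fraction(site) == expected

    def test_bounded_and_monotone_in_alt_reads(self):
        prev = -1.0
        for alt in range(0, 101, 10):
            af = allele_fraction(SiteCounts("c", 1, "C", "T", alt, 100, "s"), decimals=2)
            assert 0 <= af <= 100
            assert af >= prev
            prev = af

    def test_invalid_counts_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SiteCounts("c", 1, "C", "T", 10, 5, "s")


class TestRnaOnlyCalls:
    def _site(self, alt, total, sample="r1", pos=1_094_824):
        return SiteCounts("chr", pos, "C", "T", alt, total, sample)

    def test_high_rna_fractions_with_absent_genomic_signal(self, cfg):
        reps = [self._site(910_914, 911_345, "Y1"), self._site(655, 773, "B1")]
        assert call_rna_only_variant(reps, GENOME_ABSENT, cfg) == "rna_only"

    def test_genomic_fraction_dominates(self, cfg):
        reps = [self._site(700, 773)]
        genomic = self._site(50, 100, "sanger")
        assert call_rna_only_variant(reps, genomic, cfg) == "genomic"

    def test_low_rna_fraction_unsupported(self, cfg):
        assert call_rna_only_variant([self._site(20, 100)], GENOME_ABSENT, cfg) == "unsupported"

    def test_low_genomic_fraction_does_not_block_rna_only(self, cfg):
        reps = [self._site(750, 773)]
        genomic = self._site(5, 100, "sanger")
        assert call_rna_only_variant(reps, genomic, cfg) == "rna_only"

    def test_invariant_to_replicate_order(self, cfg):
        reps = [self._site(750, 773, "a"), self._site(400, 773, "b"), self._site(700, 773, "c")]
        assert (call_rna_only_variant(reps, GENOME_ABSENT, cfg)
                == call_rna_only_variant(reps[::-1], GENOME_ABSENT, cfg))

    def test_mixed_positions_rejected(self, cfg):
        with pytest.raises(ValueError):
            call_rna_only_variant([self._site(700, 773, pos=1), self._site(700, 773, pos=2)],
                                  GENOME_ABSENT, cfg)


class TestSiteContext:
    def _ann(self, feats):
        return AnnotationSet("chr", feats)

    def _gene(self, fid, start, end, strand="+"):
        return Feature(fid, Location("chr", start, end, strand), "CDS", "coding",
                       provenance=frozenset({"t"}))

    def test_site_19bp_past_plus_strand_gene_is_downstream(self):
        # gene [1000, 1900); last base at 0-based 1899 = 1-based 1900.
        # 19 intervening bases puts the site at 1-based 1920.
        ann = self._ann([self._gene("lacI", 1000, 1900)])
        site = SiteCounts("chr", 1920, "C", "T", 9, 10, "s")
        ctx = annotate_site_context(site, ann)
        assert (ctx.feature_id, ctx.distance, ctx.relative_position) == ("lacI", 19, "downstream")

    def test_site_before_minus_strand_gene_is_downstream(self):
        ann = self._ann([self._gene("g", 1000, 1900, strand="-")])
        site = SiteCounts("chr", 990, "C", "T", 9, 10, "s")
        ctx = annotate_site_context(site, ann)
        assert ctx.relative_position == "downstream"
        assert ctx.distance == 10  # bases 991..1000 sit strictly between

    def test_site_inside_feature(self):
        ann = self._ann([self._gene("g", 1000, 1900)])
        ctx = annotate_site_context(SiteCounts("chr", 1500, "C", "T", 1, 2, "s"), ann)
        assert (ctx.distance, ctx.relative_position) == (0, "within")

    def test_equidistant_tie_broken_by_feature_id(self, caplog):
        ann = self._ann([self._gene("zzz", 100, 190), self._gene("aaa", 309, 399)])
        site = SiteCounts("chr", 250, "C", "T", 1, 2, "s")  # 59 bp from both edges
        with caplog.at_level("INFO"):
            ctx = annotate_site_context(site, ann)
        assert ctx.feature_id == "aaa"
        assert any("equidistant" in r.message for r in caplog.records)

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            annotate_site_context(SiteCounts("chr", 1, "C", "T", 1, 2, "s"), self._ann([]))
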