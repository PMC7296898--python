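"""Threshold engine: staged classification, strict bounds, alignment, novelty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reanno.core import GenomeSequence, Location, ThresholdConfig
from reanno.homology import (
    HomologyHit,
    align_pair,
    classify_stage1,
    is_redundant,
    passes_stage2,
    _get_aligner,
)
from reanno.orfs import GeneCall

from .oracles import sw_score


def _hit(evalue=1e-12, identity=90.0, coverage=0.95, query="q1", subject="s1",
         bitscore=300.0):
    return HomologyHit(query, subject, subject, evalue, identity, 100, coverage, bitscore)


class TestStage1:
    def test_strong_hit_is_coding_with_best_subject(self, cfg):
        hits = [_hit(evalue=1e-7, subject="weak", bitscore=100),
                _hit(evalue=1e-30, subject="best", bitscore=500)]
        d = classify_stage1("q1", hits, cfg)
        assert d.label == "coding"
        assert d.best_hit.subject_id == "best"

    def test_no_hits_is_hypothetical(self, cfg):
        assert classify_stage1("q1", [], cfg).label == "hypothetical"

    def test_evalue_above_threshold_is_hypothetical(self, cfg):
        assert classify_stage1("q1", [_hit(evalue=1e-5)], cfg).label == "hypothetical"

    def test_evalue_exactly_at_threshold_fails_strict_bound(self, cfg):
        assert classify_stage1("q1", [_hit(evalue=1e-6)], cfg).label == "hypothetical"

    def test_disruption_flag_makes_pseudogene_candidate(self, cfg):
        d = classify_stage1("q1", [_hit(evalue=1e-30)], cfg, disrupted=True)
        assert d.label == "pseudogene_candidate"

    def test_low_coverage_best_hit_makes_pseudogene_candidate(self, cfg):
        d = classify_stage1("q1", [_hit(evalue=1e-30, coverage=0.4)], cfg)
        assert d.label == "pseudogene_candidate"

    def test_tie_on_evalue_broken_by_bitscore_then_subject(self, cfg):
        hits = [_hit(evalue=1e-20, subject="b", bitscore=100),
                _hit(evalue=1e-20, subject="a", bitscore=100),
                _hit(evalue=1e-20, subject="c", bitscore=400)]
        assert classify_stage1("q1", hits, cfg).best_hit.subject_id == "c"
        hits = hits[:2]
        assert classify_stage1("q1", hits, cfg).best_hit.subject_id == "a"

    def test_foreign_hit_rejected(self, cfg):
        with pytest.raises(ValueError):
            classify_stage1("q1", [_hit(query="q2")], cfg)


class TestStage2:
    def test_clearly_passing_hit(self, cfg):
        assert passes_stage2(_hit(1e-12, 75.0, 0.85), cfg)

    def test_evalue_bound_is_binding(self, cfg):
        assert not passes_stage2(_hit(1e-8, 95.0, 0.95), cfg)

    @pytest.mark.parametrize(
        "evalue,identity,coverage",
        [(1e-10, 75.0, 0.85), (1e-12, 70.0, 0.85), (1e-12, 75.0, 0.80)],
    )
    def test_exact_boundary_values_rejected(self, cfg, evalue, identity, coverage):
        """All three inequalities are strict: equality at any bound fails."""
        assert not passes_stage2(_hit(evalue, identity, coverage), cfg)

    @given(
        evalue=st.floats(1e-60, 1e-2), identity=st.floats(0, 100),
        coverage=st.floats(0, 1), relax=st.sampled_from(
            ["stage2_evalue_max", "stage2_coverage_min", "stage2_identity_min"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_under_threshold_relaxation(self, evalue, identity, coverage, relax):
        """Relaxing any one threshold never rejects a previously accepted hit."""
        strict = ThresholdConfig()
        hit = _hit(evalue, identity, coverage)
        relaxed_value = {
            "stage2_evalue_max": strict.stage2_evalue_max * 100,
            "stage2_coverage_min": strict.stage2_coverage_min / 2,
            "stage2_identity_min": strict.stage2_identity_min / 2,
        }[relax]
        relaxed = ThresholdConfig(**{relax: relaxed_value})
        if passes_stage2(hit, strict):
            assert passes_stage2(hit, relaxed)


class TestAlignPair:
    def test_identical_sequences_score_perfectly(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 300))
        assert align_pair(a, a) == (100.0, 1.0)

    def test_unrelated_sequences_have_low_coverage(self, cfg):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        identity, coverage = align_pair(a, b)
        assert coverage < cfg.novelty_coverage_min

    def test_ten_percent_substitutions_give_about_ninety_identity(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = list(a)
        for i in rng.choice(300, size=30, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        identity, coverage = align_pair(a, "".join(b))
        assert 88 <= identity <= 92
        assert coverage > 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_optimal_score_matches_full_dp_oracle(self, seed):
        """The aligner's optimal local score equals an independent Gotoh DP."""
        rng = np.random.default_rng(seed)
        la, lb = rng.integers(20, 201, size=2)
        a = "".join(rng.choice(list("ACGT"), la))
        b = "".join(rng.choice(list("ACGT"), lb))
        assert _get_aligner().score(a, b) == pytest.approx(sw_score(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestIsRedundant:
    def _genome(self, seed=5, n=4000):
        rng = np.random.default_rng(seed)
        return GenomeSequence("g", "".join(rng.choice(list("ACGT"), n)))

    def _call(self, cid, start, end, strand="+"):
        return GeneCall(cid, Location("g", start, end, strand), "f")

    def test_identical_coordinates_are_redundant(self, cfg):
        g = self._genome()
        cand = self._call("c", 100, 400)
        redundant, matched = is_redundant(cand, [self._call("p", 100, 400)], g, cfg)
        assert redundant and matched == "p"

    def test_intergenic_candidate_is_novel(self, cfg):
        g = self._genome()
        redundant, matched = is_redundant(
            self._call("c", 100, 400), [self._call("p", 2000, 2300)], g, cfg
        )
        assert not redundant and matched is None

    def test_symmetric_on_identical_sequences(self, cfg):
        g = self._genome()
        a, b = self._call("a", 100, 400), self._call("b", 100, 400)
        assert is_redundant(a, [b], g, cfg)[0]
        assert is_redundant(b, [a], g, cfg)[0]

    def test_duplicated_sequence_elsewhere_caught_by_alignment(self, cfg):
        # same 300-mer at two loci: no coordinate overlap, alignment finds it
        rng = np.random.default_rng(9)
        unit = "".join(rng.choice(list("ACGT"), 300))
        pad = "".join(rng.choice(list("ACGT"), 500))
        g = GenomeSequence("g", pad + unit + pad + unit + pad)
        cand = self._call("c", 500, 800)
        prim = self._call("p", 1300, 1600)
        assert is_redundant(cand, [prim], g, cfg)[0]

    def test_hit_override_bypasses_alignment(self, cfg):
        cand = self._call("c", 100, 400)
        prim = self._call("p", 2000, 2300)
        hits = {"c": [HomologyHit("c", "p", "p", 1e-30, 95.0, 300, 0.9, 500.0)]}
        redundant, matched = is_redundant(cand, [prim], None, cfg, hits_override=hits)
        assert redundant and matched == "p"
        weak = {"c": [HomologyHit("c", "p", "p", 1e-30, 80.0, 300, 0.9, 500.0)]}
        assert not is_redundant(cand, [prim], None, cfg, hits_override=weak)[0]

    def test_planted_novelty_recovered_exactly(self, cfg, truth):
        """Alternate calls = primary set plus planted-novel intergenic ORFs;
        exactly the planted-novel ones are flagged novel (brute force over all)."""
        primary = [GeneCall(f.feature_id, f.location, "primary") for f in truth.planted_genes]
        novel_truth = {
            f.feature_id
            for p in truth.planted_pseudogenes if p.kind == "split"
            for f in p.sub_genes
        }
        candidates = primary[:12] + [
            GeneCall(f.feature_id, f.location, "alt")
            for p in truth.planted_pseudogenes if p.kind == "split"
            for f in p.sub_genes
        ]
        flagged_novel = {
            c.call_id for c in candidates
            if not is_redundant(c, primary, truth.genome, cfg)[0]
        }
        assert flagged_novel == novel_truth
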