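"""Homology threshold engine.

Two acceptance stages drive the CDS reannotation:

* **stage 1** — every call from the primary gene finder is classified by
  its best protein hit: *coding* when the best e-value beats
  ``stage1_evalue_max`` (default 1e-6, strict), *hypothetical* when no
  hit qualifies, *pseudogene_candidate* when a qualifying hit exists but
  the call looks disrupted (caller-supplied frameshift/internal-stop
  flag, or best-hit query coverage below ``pseudo_coverage_floor``).
* **stage 2** — a novel call from an alternate finder is admitted only
  when its best hit clears the strict triple bound: e-value <
  ``stage2_evalue_max`` (1e-10) AND query coverage > 80% AND identity >
  70%; all three inequalities strict.

The novelty (redundancy) test decides whether an alternate finder's call
is already represented in the primary set, via a coordinate fast path or
nucleotide alignment.  When no external nucleotide hit table is supplied
the built-in Smith-Waterman aligner is used: match +2, mismatch -3, gap
open -5 (first gapped column), gap extend -2 per additional column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .core import GenomeSequence, ThresholdConfig
from .orfs import GeneCall

__all__ = [
    "HomologyHit",
    "Stage1Decision",
    "classify_stage1",
    "passes_stage2",
    "align_pair",
    "is_redundant",
    "best_hit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    subject_name: str
    evalue: float
    identity: float  # percent, 0..100
    aln_length: int
    query_coverage: float  # fraction, 0..1
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(f"coverage {self.query_coverage} outside [0, 1]")


def _hit_rank(h: HomologyHit) -> tuple:
    # best first: lowest e-value, then highest bitscore, then subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def best_hit(hits: list[HomologyHit]) -> HomologyHit | None:
    return min(hits, key=_hit_rank) if hits else None


@dataclass(frozen=True)
class Stage1Decision:
    label: str  # coding | hypothetical | pseudogene_candidate
    best_hit: HomologyHit | None


def classify_stage1(
    call_id: str,
    hits: list[HomologyHit],
    cfg: ThresholdConfig,
    disrupted: bool = False,
) -> Stage1Decision:
    """Classify one primary call from its protein hits.

    ``disrupted`` is the caller-supplied flag for an observed frameshift or
    internal stop; it turns an otherwise-coding call into a pseudogene
    candidate, as does a best qualifying hit covering less than
    ``cfg.pseudo_coverage_floor`` of the query.
    """
    for h in hits:
        if h.query_id != call_id:
            raise ValueError(f"hit for {h.query_id!r} passed to call {call_id!r}")
    qualifying = [h for h in hits if h.evalue < cfg.stage1_evalue_max]
    if not qualifying:
        return Stage1Decision("hypothetical", None)
    best = best_hit(qualifying)
    if disrupted or best.query_coverage < cfg.pseudo_coverage_floor:
        return Stage1Decision("pseudogene_candidate", best)
    return Stage1Decision("coding", best)


def passes_stage2(hit: HomologyHit, cfg: ThresholdConfig) -> bool:
    """Strict triple bound for admitting novel CDSs from alternate finders."""
    return (
        hit.evalue < cfg.stage2_evalue_max
        and hit.query_coverage > cfg.stage2_coverage_min
        and hit.identity > cfg.stage2_identity_min
    )


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _aligner = a
    return _aligner


def align_pair(a: str, b: str) -> tuple[float, float]:
    """Local-align two DNA strings; return (identity %, coverage of shorter).

    Identity is matches over alignment columns (gap columns included);
    coverage is the aligned span of the shorter sequence over its length.
    Sequences with no positive-scoring local alignment score (0.0, 0.0).
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    aligner = _get_aligner()
    if aligner.score(a, b) <= 0:
        return 0.0, 0.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns * 100.0
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    if len(a) <= len(b):
        coverage = span_a / len(a)
    else:
        coverage = span_b / len(b)
    return identity, min(coverage, 1.0)


def _reciprocal_overlap_ok(a: GeneCall, b: GeneCall, min_frac: float) -> bool:
    la, lb = a.location, b.location
    if la.strand != lb.strand:
        return False
    ov = la.overlap(lb)
    return ov >= min_frac * la.length and ov >= min_frac * lb.length


def is_redundant(
    candidate: GeneCall,
    primary: list[GeneCall],
    genome: GenomeSequence | None,
    cfg: ThresholdConfig,
    hits_override: dict[str, list[HomologyHit]] | None = None,
) -> tuple[bool, str | None]:
    """Is ``candidate`` already represented in the primary call set?

    Order of evidence: (1) coordinate fast path — same-strand reciprocal
    overlap >= ``novelty_coverage_min``; (2) a supplied nucleotide hit
    table keyed by candidate call id with primary call ids as subjects;
    (3) pairwise alignment of extracted sequences against each primary.
    Returns (redundant, matched primary id).
    """
    for p in primary:
        if _reciprocal_overlap_ok(candidate, p, cfg.novelty_coverage_min):
            return True, p.call_id
    if hits_override is not None:
        primary_ids = {p.call_id for p in primary}
        for h in hits_override.get(candidate.call_id, []):
            if (
                h.subject_id in primary_ids
                and h.identity >= cfg.novelty_identity_min
                and h.query_coverage >= cfg.novelty_coverage_min
            ):
                return True, h.subject_id
        return False, None
    if genome is None:
        return False, None
    cand_seq = candidate.sequence(genome)
    for p in primary:
        identity, coverage = align_pair(cand_seq, p.sequence(genome))
        if identity >= cfg.novelty_identity_min and coverage >= cfg.novelty_coverage_min:
            return True, p.call_id
    return False, None
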