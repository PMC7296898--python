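"""Reannotation orchestration.

The two-stage CDS pipeline: stage 1 classifies the primary finder's
calls by protein homology; stage 2 pools the alternate finders' calls,
discards those redundant with the primary set, and admits the remainder
only under the strict triple threshold.  Pseudogene rescue re-calls ORFs
inside annotated pseudogene spans and reinstates any ORF whose protein
hit clears stage 2 — one region may split into several genes (the
insA/insB pattern, where one "pseudogene" span harbors two intact
insertion-element genes).  ncRNA/tRNA/rRNA predictions from dedicated
finders are merged by coordinates, and everything is assembled into a
single annotation with category accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .core import AnnotationSet, Feature, GenomeSequence, ThresholdConfig
from .homology import HomologyHit, Stage1Decision, best_hit, classify_stage1, is_redundant, passes_stage2
from .orfs import GeneCall, orfs_in_region

__all__ = [
    "StagePartition",
    "run_stage1",
    "run_stage2",
    "rescue_pseudogenes",
    "merge_ncrna",
    "build_annotation",
    "summarize",
]

logger = logging.getLogger(__name__)

HitProvider = Callable[[GeneCall], list[HomologyHit]]


@dataclass
class StagePartition:
    """Where every CDS landed; the six lists are disjoint by feature id."""

    coding: list[Feature] = field(default_factory=list)
    hypothetical: list[Feature] = field(default_factory=list)
    pseudogene_candidates: list[Feature] = field(default_factory=list)
    additions: list[Feature] = field(default_factory=list)
    rescued: list[Feature] = field(default_factory=list)
    retained_pseudogenes: list[Feature] = field(default_factory=list)

    def all_ids(self) -> list[str]:
        return [
            f.feature_id
            for lst in (
                self.coding, self.hypothetical, self.pseudogene_candidates,
                self.additions, self.rescued, self.retained_pseudogenes,
            )
            for f in lst
        ]


def _call_to_feature(
    call: GeneCall, status: str, decision: Stage1Decision | None, stage: str
) -> Feature:
    hit = decision.best_hit if decision else None
    return Feature(
        feature_id=call.call_id,
        location=call.location,
        ftype="CDS" if status != "pseudogene" else "pseudogene",
        status=status,
        gene_name=hit.subject_name if hit and status == "coding" else None,
        product=hit.subject_name if hit and status == "coding" else None,
        provenance=frozenset({call.finder, stage}),
    )


def run_stage1(
    primary_calls: list[GeneCall],
    hits_by_call: dict[str, list[HomologyHit]],
    genome: GenomeSequence,
    cfg: ThresholdConfig,
    disrupted_calls: set[str] | None = None,
) -> StagePartition:
    """Classify every primary call as coding / hypothetical / pseudogene candidate.

    ``disrupted_calls`` carries externally observed frameshift/internal-stop
    flags.  Every call lands in exactly one list; coding features inherit
    gene name and product from their best hit.
    """
    disrupted_calls = disrupted_calls or set()
    part = StagePartition()
    for call in primary_calls:
        decision = classify_stage1(
            call.call_id,
            hits_by_call.get(call.call_id, []),
            cfg,
            disrupted=call.call_id in disrupted_calls,
        )
        if decision.label == "coding":
            part.coding.append(_call_to_feature(call, "coding", decision, "stage1"))
        elif decision.label == "hypothetical":
            part.hypothetical.append(_call_to_feature(call, "hypothetical", None, "stage1"))
        else:
            part.pseudogene_candidates.append(
                _call_to_feature(call, "pseudogene", decision, "stage1")
            )
    return part


def run_stage2(
    alt_calls_by_finder: dict[str, list[GeneCall]],
    primary_coding: list[Feature],
    hits_by_call: dict[str, list[HomologyHit]],
    genome: GenomeSequence | None,
    cfg: ThresholdConfig,
    nucl_hits: dict[str, list[HomologyHit]] | None = None,
) -> list[Feature]:
    """Admit novel CDSs from alternate finders under the strict thresholds.

    Calls identical across finders (same contig, strand, coordinates) are
    pooled into one candidate with merged provenance before the novelty
    test; candidates redundant with the primary coding set are dropped;
    survivors are kept iff their best protein hit passes stage 2.
    ``nucl_hits`` optionally replaces the built-in aligner in the novelty
    test (nucleotide hits keyed by candidate id, primary ids as subjects).
    """
    # pool exact duplicates across finders
    pooled: dict[tuple, tuple[GeneCall, set[str]]] = {}
    for finder, calls in alt_calls_by_finder.items():
        for call in calls:
            loc = call.location
            key = (loc.contig_id, loc.strand, loc.start, loc.end)
            if key in pooled:
                pooled[key][1].add(finder)
            else:
                pooled[key] = (call, {finder})

    primary_as_calls = [
        GeneCall(f.feature_id, f.location, "primary") for f in primary_coding
    ]
    additions: list[Feature] = []
    n_redundant = 0
    n_failed = 0
    for key in sorted(pooled):
        call, finders = pooled[key]
        redundant, matched = is_redundant(call, primary_as_calls, genome, cfg, nucl_hits)
        if redundant:
            n_redundant += 1
            logger.debug("%s redundant with %s", call.call_id, matched)
            continue
        best = best_hit(hits_by_call.get(call.call_id, []))
        if best is None or not passes_stage2(best, cfg):
            n_failed += 1
            continue
        additions.append(
            Feature(
                feature_id=call.call_id,
                location=call.location,
                ftype="CDS",
                status="coding",
                gene_name=best.subject_name,
                product=best.subject_name,
                provenance=frozenset(finders) | {"stage2"},
            )
        )
    logger.info(
        "stage 2: %d pooled candidates, %d redundant, %d failed thresholds, %d admitted",
        len(pooled), n_redundant, n_failed, len(additions),
    )
    return additions


def rescue_pseudogenes(
    pseudo_regions: list[Feature],
    genome: GenomeSequence,
    hit_provider: HitProvider,
    cfg: ThresholdConfig,
) -> tuple[list[Feature], list[Feature]]:
    """Re-call ORFs inside annotated pseudogene spans and reinstate real genes.

    For each region, ORFs within the span (± ``cfg.rescue_flank``) are
    scored by ``hit_provider``; each ORF whose best hit clears stage 2
    becomes a coding feature (so a mislabeled span may split into several
    genes).  Regions yielding no acceptable ORF are retained as
    pseudogenes.  Feature ids are derived from coordinates, making the
    operation idempotent.
    """
    rescued: list[Feature] = []
    retained: list[Feature] = []
    for region in pseudo_regions:
        if region.location.end > genome.length or region.location.contig_id != genome.id:
            raise ValueError(f"{region.feature_id}: region outside genome")
        accepted: list[tuple[GeneCall, HomologyHit]] = []
        for orf in orfs_in_region(genome, region.location, cfg.rescue_flank, cfg):
            best = best_hit(hit_provider(orf))
            if best is not None and passes_stage2(best, cfg):
                accepted.append((orf, best))
        if accepted:
            for orf, hit in accepted:
                loc = orf.location
                rescued.append(
                    Feature(
                        feature_id=f"rescued|{loc.contig_id}|{loc.start + 1}-{loc.end}|{loc.strand}",
                        location=loc,
                        ftype="CDS",
                        status="coding",
                        gene_name=hit.subject_name,
                        product=hit.subject_name,
                        provenance=region.provenance | {"rescue"},
                    )
                )
        else:
            retained.append(region)
    return rescued, retained


def merge_ncrna(
    finder_feature_sets: list[list[Feature]], cfg: ThresholdConfig
) -> list[Feature]:
    """Union ncRNA/tRNA/rRNA predictions across finders, merging near-identicals.

    Features of the same type on the same contig and strand whose start
    and end each differ by <= ``cfg.merge_slop`` bp are unified (first
    finder's coordinates win, provenance merged); everything else passes
    through.  CDS/pseudogene input is an error.
    """
    merged: list[Feature] = []
    for feature_set in finder_feature_sets:
        for f in feature_set:
            if f.ftype in ("CDS", "pseudogene"):
                raise ValueError(f"{f.feature_id}: merge_ncrna accepts only RNA features")
            hit = None
            for m in merged:
                if (
                    m.ftype == f.ftype
                    and m.location.contig_id == f.location.contig_id
                    and m.location.strand == f.location.strand
                    and abs(m.location.start - f.location.start) <= cfg.merge_slop
                    and abs(m.location.end - f.location.end) <= cfg.merge_slop
                ):
                    hit = m
                    break
            if hit is not None:
                merged[merged.index(hit)] = hit.with_provenance(*f.provenance)
            else:
                merged.append(f)
    return merged


def build_annotation(
    partition: StagePartition,
    ncrna: list[Feature],
    genome: GenomeSequence,
) -> AnnotationSet:
    """Assemble the final annotation from the CDS partition and merged RNAs.

    Coding total = stage-1 coding + stage-2 additions + rescued, with no
    feature-id collisions allowed.
    """
    features = (
        partition.coding
        + partition.additions
        + partition.rescued
        + partition.hypothetical
        + partition.retained_pseudogenes
        + list(ncrna)
    )
    seen: set[str] = set()
    for f in features:
        if f.feature_id in seen:
            raise ValueError(f"duplicate feature id {f.feature_id!r} in assembly")
        seen.add(f.feature_id)
    ann = AnnotationSet(genome_id=genome.id, features=features)
    ann.features = ann.sorted_features()
    return ann


def summarize(ann: AnnotationSet) -> dict[str, int]:
    """Category counts: total = protein_coding + pseudogenes + tRNA + rRNA + misc RNA.

    Hypothetical CDSs count within protein_coding, as annotation overview
    tables conventionally group them.
    """
    counts = {
        "protein_coding": 0,
        "pseudogenes": 0,
        "tRNA": 0,
        "rRNA": 0,
        "misc_RNA": 0,
    }
    for f in ann.features:
        if f.ftype == "CDS":
            counts["protein_coding"] += 1
        elif f.ftype == "pseudogene":
            counts["pseudogenes"] += 1
        elif f.ftype == "tRNA":
            counts["tRNA"] += 1
        elif f.ftype == "rRNA":
            counts["rRNA"] += 1
        else:  # ncRNA and misc
            counts["misc_RNA"] += 1
    counts["total"] = sum(counts.values())
    return counts
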