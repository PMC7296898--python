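"""RNA-seq-derived statistics.

FPKM quantification and the detectability call for newly added ncRNAs;
per-site allele fractions from pileup-style read counts; and the
RNA-vs-genome discordance classification that flags a variant seen in
transcribed reads but absent from genomic evidence (an "RNA-only"
variant, e.g. a C>T change consistent with 5-methylcytosine deamination
at the transcript level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import AnnotationSet, ThresholdConfig
from .diff import proportion

__all__ = [
    "ExpressionRecord",
    "SiteCounts",
    "GENOME_ABSENT",
    "fpkm",
    "detectability",
    "allele_fraction",
    "call_rna_only_variant",
    "annotate_site_context",
    "SiteContext",
]

logger = logging.getLogger(__name__)

#: Sentinel for "no variant signal in genomic evidence" (e.g. a clean
#: Sanger trace), used where only a qualitative absence is available.
GENOME_ABSENT = "absent"

_BASES = frozenset("ACGT")


@dataclass
class ExpressionRecord:
    """Per-feature read assignment in one sample; ``fpkm`` filled on demand."""

    feature_id: str
    length_bp: int
    assigned_reads: int
    sample: str = ""
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.feature_id}: length_bp must be > 0")
        if self.assigned_reads < 0:
            raise ValueError(f"{self.feature_id}: assigned_reads must be >= 0")


@dataclass(frozen=True)
class SiteCounts:
    """Allele read counts at one genomic site in one sample (1-based pos)."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    alt_reads: int
    total_reads: int
    sample: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(
                f"{self.contig}:{self.position}: alt_reads {self.alt_reads} "
                f"outside [0, total_reads={self.total_reads}]"
            )
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(f"{self.contig}:{self.position}: bases must be in ACGT")


def fpkm(assigned_reads: int, total_mapped_reads: int, length_bp: int) -> float:
    """Fragments per kilobase of feature per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    return assigned_reads * 1e9 / (total_mapped_reads * length_bp)


def detectability(
    records: list[ExpressionRecord],
    cfg: ThresholdConfig | None = None,
    total_mapped_reads: int | None = None,
) -> tuple[float, list[str], list[str]]:
    """Fraction of features transcriptionally detectable in >= 1 sample.

    A feature is detectable when its FPKM exceeds ``cfg.fpkm_detect_min``
    (strict; default 0) in at least one sample.  Records may carry a
    precomputed ``fpkm``; otherwise ``total_mapped_reads`` (per library)
    is required to compute it.  Returns (percent detectable rounded to
    the nearest integer, detectable ids, undetectable ids).
    """
    if not records:
        raise ValueError("detectability requires at least one record")
    cfg = cfg or ThresholdConfig()
    values: dict[str, float] = {}
    for r in records:
        v = r.fpkm
        if v is None:
            if total_mapped_reads is None:
                raise ValueError(
                    f"{r.feature_id}: no fpkm on record and no total_mapped_reads given"
                )
            v = fpkm(r.assigned_reads, total_mapped_reads, r.length_bp)
        values[r.feature_id] = max(values.get(r.feature_id, 0.0), v)
    detectable = sorted(i for i, v in values.items() if v > cfg.fpkm_detect_min)
    undetectable = sorted(i for i in values if i not in set(detectable))
    fraction = proportion(len(detectable), len(values), 0)
    return fraction, detectable, undetectable


def allele_fraction(site: SiteCounts, decimals: int = 0) -> float:
    """Alternate-allele percentage at a site, half-up rounded."""
    if site.total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return proportion(site.alt_reads, site.total_reads, decimals)


def call_rna_only_variant(
    rna_sites: list[SiteCounts],
    genome_evidence: SiteCounts | str,
    cfg: ThresholdConfig | None = None,
) -> str:
    """Classify a candidate variant as rna_only / genomic / unsupported.

    All RNA replicates must be at the same (contig, position, alt).  The
    call is *rna_only* when every replicate's allele fraction reaches
    ``af_rna_min`` and the genomic evidence is either the
    :data:`GENOME_ABSENT` flag or an allele fraction <= ``af_genome_max``;
    *genomic* when the genomic fraction exceeds ``af_genome_max``;
    *unsupported* otherwise.  Invariant to replicate order.
    """
    if not rna_sites:
        raise ValueError("at least one RNA replicate required")
    cfg = cfg or ThresholdConfig()
    keys = {(s.contig, s.position, s.alt_base) for s in rna_sites}
    if len(keys) != 1:
        raise ValueError(f"mixed sites in RNA replicates: {sorted(keys)}")
    if isinstance(genome_evidence, SiteCounts):
        gfrac = genome_evidence.alt_reads / genome_evidence.total_reads
        if gfrac > cfg.af_genome_max:
            return "genomic"
    elif genome_evidence != GENOME_ABSENT:
        raise ValueError(f"genome_evidence must be SiteCounts or {GENOME_ABSENT!r}")
    rna_ok = all(s.alt_reads / s.total_reads >= cfg.af_rna_min for s in rna_sites)
    return "rna_only" if rna_ok else "unsupported"


@dataclass(frozen=True)
class SiteContext:
    feature_id: str
    distance: int  # bp strictly between site and nearest feature edge
    relative_position: str  # upstream | downstream | within


def annotate_site_context(site: SiteCounts, ann: AnnotationSet) -> SiteContext:
    """Locate a site relative to the nearest annotated feature.

    Distance counts the bases strictly between the site and the nearest
    feature edge (0 when within or immediately adjacent); upstream/
    downstream are resolved on the feature's own strand, so a site past a
    plus-strand gene's 3' end is *downstream*.  Equidistant candidates
    tie-break deterministically on feature id; ties are logged.
    """
    candidates = [f for f in ann.features if f.location.contig_id == site.contig]
    if not candidates:
        raise ValueError(f"no features on contig {site.contig!r}")
    p = site.position - 1  # 0-based point

    def dist(f) -> int:
        loc = f.location
        if loc.start <= p < loc.end:
            return 0
        return loc.start - p - 1 if p < loc.start else p - loc.end

    ranked = sorted(candidates, key=lambda f: (dist(f), f.feature_id))
    nearest = ranked[0]
    d = dist(nearest)
    if len(ranked) > 1 and dist(ranked[1]) == d:
        logger.info(
            "site %s:%d equidistant (%d bp) from %s and %s; keeping %s",
            site.contig, site.position, d,
            nearest.feature_id, ranked[1].feature_id, nearest.feature_id,
        )
    loc = nearest.location
    if loc.start <= p < loc.end:
        rel = "within"
    elif p < loc.start:
        rel = "upstream" if loc.strand == "+" else "downstream"
    else:
        rel = "downstream" if loc.strand == "+" else "upstream"
    return SiteContext(nearest.feature_id, d, rel)
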