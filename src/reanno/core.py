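"""Domain model shared by every stage of the reannotation engine.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open ``[start, end)`` on the
forward strand of a contig.  GFF3 emission converts to 1-based inclusive;
:func:`to_gff3_coords` / :func:`from_gff3_coords` are the single point of
conversion and are exact inverses of each other.

Minus-strand features denote the reverse complement of the located span;
reading frames are always computed on the oriented sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "Location",
    "Feature",
    "AnnotationSet",
    "ThresholdConfig",
    "FTYPES",
    "STATUSES",
    "validate_annotation",
    "to_gff3_coords",
    "from_gff3_coords",
    "reverse_complement",
]

FTYPES = ("CDS", "pseudogene", "tRNA", "rRNA", "ncRNA", "misc")
STATUSES = ("coding", "hypothetical", "pseudogene", "noncoding")

_VALID_RESIDUES = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig/replicon with its residues.

    ``circular`` is informational only: features wrapping the origin are
    rejected as invalid input in this version.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if set(self.residues) - _VALID_RESIDUES:
            bad = sorted(set(self.residues) - _VALID_RESIDUES)
            raise ValueError(f"genome {self.id}: invalid residues {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        seq = self.residues[start:end]
        return seq if strand == "+" else reverse_complement(seq)


@dataclass(frozen=True, order=True)
class Location:
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Location") -> int:
        """Overlap length in bp (0 when on different contigs)."""
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Feature:
    """One annotated feature with provenance and classification status."""

    feature_id: str
    location: Location
    ftype: str
    status: str
    gene_name: str | None = None
    product: str | None = None
    provenance: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ftype not in FTYPES:
            raise ValueError(f"{self.feature_id}: unknown ftype {self.ftype!r}")
        if self.status not in STATUSES:
            raise ValueError(f"{self.feature_id}: unknown status {self.status!r}")
        self.provenance = frozenset(self.provenance)

    @property
    def length(self) -> int:
        return self.location.length

    def with_provenance(self, *labels: str) -> "Feature":
        return replace(self, provenance=self.provenance | set(labels))

    def sequence(self, genome: GenomeSequence) -> str:
        loc = self.location
        return genome.subsequence(loc.start, loc.end, loc.strand)


@dataclass
class AnnotationSet:
    genome_id: str
    features: list[Feature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def sorted_features(self) -> list[Feature]:
        return sorted(
            self.features,
            key=lambda f: (f.location.contig_id, f.location.start, f.feature_id),
        )

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


@dataclass
class ThresholdConfig:
    """Every tunable threshold of the pipeline, with the staged defaults.

    Stage 1 classifies the primary finder's calls by protein homology
    (e-value < ``stage1_evalue_max``); stage 2 admits novel calls from
    alternate finders only under the strict triple bound (e-value,
    query coverage, percent identity — all strict inequalities).
    """

    stage1_evalue_max: float = 1e-6
    stage2_evalue_max: float = 1e-10
    stage2_coverage_min: float = 0.80  # strict >
    stage2_identity_min: float = 70.0  # strict >
    novelty_identity_min: float = 90.0
    novelty_coverage_min: float = 0.80
    min_orf_length: int = 90
    fpkm_detect_min: float = 0.0  # strict >
    af_rna_min: float = 0.5
    af_genome_max: float = 0.1
    pseudo_coverage_floor: float = 0.60
    rescue_flank: int = 0
    merge_slop: int = 0
    match_overlap_min: float = 0.90
    keep_nested: bool = False

    def __post_init__(self) -> None:
        for name in ("stage1_evalue_max", "stage2_evalue_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "stage2_coverage_min",
            "novelty_coverage_min",
            "af_rna_min",
            "af_genome_max",
            "pseudo_coverage_floor",
            "match_overlap_min",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("stage2_identity_min", "novelty_identity_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percent in [0, 100], got {v}")
        if self.min_orf_length < 3 or self.min_orf_length % 3:
            raise ValueError("min_orf_length must be a positive multiple of 3")
        if self.rescue_flank < 0 or self.merge_slop < 0:
            raise ValueError("rescue_flank and merge_slop must be >= 0")


@dataclass(frozen=True)
class Violation:
    feature_id: str
    rule: str
    detail: str = ""


def validate_annotation(
    ann: AnnotationSet, genome: GenomeSequence
) -> list[Violation]:
    """Report every invariant violation in ``ann`` against ``genome``.

    Returns an empty list iff the annotation is well formed.  Reporting,
    never raising: a partially broken annotation is still inspectable.
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for f in ann.features:
        if f.feature_id in seen:
            violations.append(Violation(f.feature_id, "duplicate id"))
        seen.add(f.feature_id)
        loc = f.location
        if loc.contig_id == genome.id and loc.end > genome.length:
            violations.append(
                Violation(
                    f.feature_id,
                    "out of bounds",
                    f"end {loc.end} > contig length {genome.length}",
                )
            )
        if f.ftype == "CDS" and f.status == "coding" and f.length % 3:
            violations.append(
                Violation(f.feature_id, "frame", f"length {f.length} not divisible by 3")
            )
        if f.status == "hypothetical" and f.ftype != "CDS":
            violations.append(
                Violation(f.feature_id, "status", "hypothetical requires ftype CDS")
            )
        if not f.provenance:
            violations.append(Violation(f.feature_id, "empty provenance"))
    return violations
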