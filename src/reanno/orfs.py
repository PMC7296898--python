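"""Built-in six-frame ORF finder.

Stands in for ab initio gene finders (Prodigal, GLIMMER, GeneMark, ZCURVE)
so the whole pipeline runs without external tools: it proposes candidate
CDSs which the homology stages then accept or reject.  Bacterial genetic
code (table 11); start codons ATG/GTG/TTG; stop codons TAA/TAG/TGA; the
reported span includes the stop codon.

By default only the longest ORF per stop codon is returned (the first
start codon after the previous in-frame stop); nested alternate starts
are recoverable with ``keep_nested``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomeSequence, Location, ThresholdConfig, reverse_complement

__all__ = ["GeneCall", "find_orfs", "orfs_in_region", "call_id_for"]

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GeneCall:
    """One putative CDS proposed by one gene finder."""

    call_id: str
    location: Location
    finder: str
    score: float | None = None

    @property
    def length(self) -> int:
        return self.location.length

    def sequence(self, genome: GenomeSequence) -> str:
        loc = self.location
        return genome.subsequence(loc.start, loc.end, loc.strand)


def call_id_for(loc: Location) -> str:
    """Deterministic id from coordinates (1-based inclusive, for readability)."""
    return f"orf|{loc.contig_id}|{loc.start + 1}-{loc.end}|{loc.strand}"


def _scan_frames(seq: str) -> list[tuple[int, int]]:
    """All (start, end) ORF spans on the forward strand of ``seq``.

    For each in-frame stop, the span from the first start codon seen since
    the previous stop; half-open, stop codon included.
    """
    n = len(seq)
    spans: list[tuple[int, int]] = []
    for frame in range(3):
        first_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    spans.append((first_start, pos + 3))
                first_start = None
            elif first_start is None and codon in START_CODONS:
                first_start = pos
    return spans


def _scan_frames_nested(seq: str) -> list[tuple[int, int]]:
    """Like :func:`_scan_frames` but emits every start for each stop."""
    n = len(seq)
    spans: list[tuple[int, int]] = []
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                spans.extend((s, pos + 3) for s in starts)
                starts = []
            elif codon in START_CODONS:
                starts.append(pos)
    return spans


def find_orfs(
    genome: GenomeSequence, cfg: ThresholdConfig | None = None, finder: str = "builtin"
) -> list[GeneCall]:
    """All complete ORFs of length >= ``cfg.min_orf_length`` on both strands.

    Every returned call begins with a start codon, ends with a stop codon
    and contains no internal in-frame stop.  Calls are sorted by
    (contig, start, end, strand).
    """
    cfg = cfg or ThresholdConfig()
    scan = _scan_frames_nested if cfg.keep_nested else _scan_frames
    n = genome.length
    calls: list[GeneCall] = []
    for strand, seq in (("+", genome.residues), ("-", reverse_complement(genome.residues))):
        for s, e in scan(seq):
            if e - s < cfg.min_orf_length:
                continue
            if strand == "+":
                loc = Location(genome.id, s, e, "+")
            else:
                loc = Location(genome.id, n - e, n - s, "-")
            calls.append(GeneCall(call_id_for(loc), loc, finder))
    calls.sort(key=lambda c: (c.location.contig_id, c.location.start, c.location.end, c.location.strand))
    return calls


def orfs_in_region(
    genome: GenomeSequence,
    region: Location,
    flank: int = 0,
    cfg: ThresholdConfig | None = None,
    finder: str = "builtin",
) -> list[GeneCall]:
    """ORFs wholly contained in ``region`` extended by ``flank`` bp each side.

    Both strands are searched regardless of the region's strand; the
    extended window is clipped to the genome bounds.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if region.contig_id != genome.id:
        raise ValueError(f"region contig {region.contig_id!r} != genome {genome.id!r}")
    if region.end > genome.length:
        raise ValueError("region outside genome bounds")
    lo = max(0, region.start - flank)
    hi = min(genome.length, region.end + flank)
    window = GenomeSequence(genome.id, genome.residues[lo:hi], genome.circular)
    calls = []
    for c in find_orfs(window, cfg, finder=finder):
        loc = Location(genome.id, c.location.start + lo, c.location.end + lo, c.location.strand)
        calls.append(GeneCall(call_id_for(loc), loc, finder))
    return calls
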