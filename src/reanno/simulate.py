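"""Seeded synthetic-data generator.

Builds genomes with planted truth — intact genes (valid ORFs with a
stop-codon guard immediately upstream so the built-in ORF finder
recovers each gene at its exact coordinates), disrupted pseudogenes
(1-bp frameshift, premature stop, or a "split" span concealing two
intact genes, the insA/insB pattern), and ncRNAs — plus emulators for
imperfect gene finders, homology hit tables, and read-count tables.

Every generator is a pure function of (parameters, seed): one
``numpy.random.default_rng`` stream per call, no global state, so the
same seed reproduces byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .core import Feature, GenomeSequence, Location, ThresholdConfig, reverse_complement
from .expression import ExpressionRecord, SiteCounts
from .homology import HomologyHit
from .io import HitTable
from .orfs import GeneCall

__all__ = [
    "SyntheticTruth",
    "PlantedPseudogene",
    "make_genome",
    "emulate_finder",
    "emulate_hits",
    "make_counts",
    "make_hit_provider",
]

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_MIN_GAP = 30


@dataclass
class PlantedPseudogene:
    region: Feature
    kind: str  # frameshift | premature_stop | split
    sub_genes: list[Feature] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic genome."""

    genome: GenomeSequence
    planted_genes: list[Feature]
    planted_pseudogenes: list[PlantedPseudogene]
    planted_ncrnas: list[Feature]
    seed: int
    #: feature_id -> synthetic protein accession of the homolog each
    #: planted (sub-)gene descends from; stands in for a reference
    #: protein database entry.
    subjects: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)  # accession -> aa seq

    def all_true_genes(self) -> list[Feature]:
        return list(self.planted_genes)

    def split_sub_genes(self) -> list[Feature]:
        return [g for p in self.planted_pseudogenes if p.kind == "split" for g in p.sub_genes]


def _random_gene(rng: np.random.Generator, n_body_codons: int) -> str:
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_body_codons))
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=p))


def _orient(block: str, spans: list[tuple[int, int]], strand: str):
    """Flip an oriented block (built 5'->3') onto the requested strand."""
    if strand == "+":
        return block, spans
    flipped = reverse_complement(block)
    n = len(block)
    return flipped, [(n - e, n - s) for s, e in spans]


def make_genome(
    seed: int,
    length_bp: int = 50_000,
    n_genes: int = 30,
    n_pseudogenes: int = 5,
    n_ncrnas: int = 10,
    gc: float = 0.50,
) -> SyntheticTruth:
    """Plant genes, pseudogenes and ncRNAs on a random background.

    Genes are complete ORFs (ATG start, clean frame, random stop) placed
    non-overlapping on random strands, each preceded in-frame by a stop
    codon so the longest-ORF rule recovers its exact span.  Pseudogene
    kinds rotate split / frameshift / premature_stop.  Raises when the
    requested features cannot be packed into ``length_bp``.
    """
    rng = np.random.default_rng(seed)
    gene_counter = 0
    subjects: dict[str, str] = {}
    proteins: dict[str, str] = {}

    def new_gene_seq() -> tuple[str, str, str]:
        nonlocal gene_counter
        gene_counter += 1
        name = f"sg{gene_counter:03d}"
        acc = f"SYNP{gene_counter:05d}"
        seq = _random_gene(rng, int(rng.integers(40, 140)))
        proteins[acc] = str(Seq(seq[:-3]).translate(table=11))
        return seq, name, acc

    # Each block is (oriented_seq, strand, kind, payload); inner spans are
    # offsets into the oriented block.
    blocks: list[tuple[str, str, str, dict]] = []

    for _ in range(n_genes):
        seq, name, acc = new_gene_seq()
        strand = "+" if rng.random() < 0.5 else "-"
        block = "TAA" + seq  # in-frame upstream guard
        blocks.append((block, strand, "gene", {"span": (3, len(block)), "name": name, "acc": acc}))

    kinds = ["split", "frameshift", "premature_stop"]
    for i in range(n_pseudogenes):
        kind = kinds[i % 3]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "split":
            sa, na, aa = new_gene_seq()
            sb, nb, ab = new_gene_seq()
            spacer = _background(rng, int(rng.integers(10, 40)), gc)
            block = "TAA" + sa + spacer + "TAA" + sb
            ga = (3, 3 + len(sa))
            gb_start = 3 + len(sa) + len(spacer) + 3
            gb = (gb_start, gb_start + len(sb))
            payload = {
                "region": (3, len(block)),
                "subs": [(ga, na, aa), (gb, nb, ab)],
            }
        else:
            seq, name, acc = new_gene_seq()
            if kind == "frameshift":
                mid = len(seq) // 2
                seq = seq[:mid] + seq[mid + 1 :]
            else:  # premature stop ~40% in, codon-aligned
                pos = 3 * (len(seq) // 3 * 2 // 5)
                seq = seq[:pos] + "TAA" + seq[pos + 3 :]
            block = "TAA" + seq
            payload = {"region": (3, len(block)), "subs": []}
        blocks.append((block, strand, kind, payload))

    for _ in range(n_ncrnas):
        n = int(rng.integers(80, 301))
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append((_background(rng, n, gc), strand, "ncrna", {"span": (0, n)}))

    total = sum(len(b[0]) for b in blocks)
    k = len(blocks)
    slack = length_bp - total - _MIN_GAP * (k + 1)
    if slack < 0:
        raise ValueError(
            f"cannot pack {total} bp of features (+gaps) into {length_bp} bp genome"
        )
    order = rng.permutation(k)
    gaps = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) + _MIN_GAP

    contig = f"synth_{seed}"
    pieces: list[str] = []
    cursor = 0
    genes: list[Feature] = []
    pseudos: list[PlantedPseudogene] = []
    ncrnas: list[Feature] = []
    n_nc = 0
    n_ps = 0

    def add(piece: str) -> int:
        nonlocal cursor
        pieces.append(piece)
        offset = cursor
        cursor += len(piece)
        return offset

    for gi, bi in enumerate(order):
        add(_background(rng, int(gaps[gi]), gc))
        block, strand, kind, payload = blocks[bi]
        oriented_spans: list[tuple[int, int]] = []
        if kind == "gene" or kind == "ncrna":
            oriented_spans = [payload["span"]]
        elif kind == "split":
            oriented_spans = [payload["region"]] + [s for s, _, _ in payload["subs"]]
        else:
            oriented_spans = [payload["region"]]
        flipped, spans = _orient(block, oriented_spans, strand)
        offset = add(flipped)
        abs_spans = [(offset + s, offset + e) for s, e in spans]
        if kind == "gene":
            s, e = abs_spans[0]
            f = Feature(
                feature_id=f"gene|{contig}|{s + 1}-{e}|{strand}",
                location=Location(contig, s, e, strand),
                ftype="CDS",
                status="coding",
                gene_name=payload["name"],
                product=payload["name"],
                provenance=frozenset({"truth"}),
            )
            genes.append(f)
            subjects[f.feature_id] = payload["acc"]
        elif kind == "ncrna":
            n_nc += 1
            s, e = abs_spans[0]
            ncrnas.append(
                Feature(
                    feature_id=f"ncrna{n_nc:03d}",
                    location=Location(contig, s, e, strand),
                    ftype="ncRNA",
                    status="noncoding",
                    provenance=frozenset({"truth"}),
                )
            )
        else:
            n_ps += 1
            rs, re_ = abs_spans[0]
            region = Feature(
                feature_id=f"pseudo{n_ps:03d}",
                location=Location(contig, rs, re_, strand),
                ftype="pseudogene",
                status="pseudogene",
                provenance=frozenset({"truth"}),
            )
            subs: list[Feature] = []
            for (span, name, acc), (s, e) in zip(payload["subs"], abs_spans[1:]):
                sf = Feature(
                    feature_id=f"gene|{contig}|{s + 1}-{e}|{strand}",
                    location=Location(contig, s, e, strand),
                    ftype="CDS",
                    status="coding",
                    gene_name=name,
                    product=name,
                    provenance=frozenset({"truth"}),
                )
                subs.append(sf)
                subjects[sf.feature_id] = acc
            pseudos.append(PlantedPseudogene(region=region, kind=kind, sub_genes=subs))
    add(_background(rng, int(gaps[k]), gc))

    genome = GenomeSequence(contig, "".join(pieces))
    assert genome.length == length_bp
    genes.sort(key=lambda f: f.location.start)
    ncrnas.sort(key=lambda f: f.location.start)
    pseudos.sort(key=lambda p: p.region.location.start)
    return SyntheticTruth(
        genome=genome,
        planted_genes=genes,
        planted_pseudogenes=pseudos,
        planted_ncrnas=ncrnas,
        seed=seed,
        subjects=subjects,
        proteins=proteins,
    )


def emulate_finder(
    truth: SyntheticTruth,
    finder_name: str,
    sensitivity: float = 1.0,
    fp_rate: float = 0.0,
    boundary_jitter: int = 0,
    seed: int = 0,
) -> list[GeneCall]:
    """Imperfect gene-finder output over the planted truth.

    Each planted gene is emitted with probability ``sensitivity``; its
    start may be moved up to ``boundary_jitter`` codons into the gene
    (frame-preserving, end fixed); spurious calls are added at
    ``fp_rate`` per kb of genome, placed in intergenic space.
    """
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    contig = truth.genome.id
    occupied = [g.location for g in truth.planted_genes]
    occupied += [p.region.location for p in truth.planted_pseudogenes]
    occupied += [f.location for f in truth.planted_ncrnas]

    calls: list[GeneCall] = []
    for gene in truth.planted_genes:
        if rng.random() >= sensitivity:
            continue
        loc = gene.location
        if boundary_jitter > 0:
            max_j = min(boundary_jitter, (loc.length - 90) // 3)
            j = int(rng.integers(0, max_j + 1)) if max_j > 0 else 0
            if loc.strand == "+":
                loc = Location(contig, loc.start + 3 * j, loc.end, "+")
            else:
                loc = Location(contig, loc.start, loc.end - 3 * j, "-")
        calls.append(GeneCall("", loc, finder_name))

    n_fp = rng.poisson(fp_rate * truth.genome.length / 1000.0)
    for _ in range(n_fp):
        for _attempt in range(50):
            length = 3 * int(rng.integers(30, 101))
            start = int(rng.integers(0, truth.genome.length - length))
            loc = Location(
                contig, start, start + length, "+" if rng.random() < 0.5 else "-"
            )
            if all(loc.overlap(o) == 0 for o in occupied):
                calls.append(GeneCall("", loc, finder_name))
                break

    calls.sort(key=lambda c: (c.location.start, c.location.end, c.location.strand))
    return [
        GeneCall(f"{finder_name}|{i + 1:05d}", c.location, finder_name)
        for i, c in enumerate(calls)
    ]


def _matches_gene(call_loc: Location, gene_loc: Location) -> bool:
    """Same stop end (strand-aware) and contained start: tolerates start jitter."""
    if call_loc.contig_id != gene_loc.contig_id or call_loc.strand != gene_loc.strand:
        return False
    if call_loc.strand == "+":
        return call_loc.end == gene_loc.end and gene_loc.start <= call_loc.start < gene_loc.end
    return call_loc.start == gene_loc.start and gene_loc.start < call_loc.end <= gene_loc.end


def emulate_hits(
    calls: list[GeneCall],
    truth: SyntheticTruth,
    mode: str = "protein",
    seed: int = 0,
) -> HitTable:
    """Homology hit table a reference-database search would have produced.

    Calls matching a planted (sub-)gene draw a strong hit (e-value
    log-uniform in [1e-50, 1e-12], identity 85-100, coverage 0.9-1.0);
    spurious calls draw no hit or a weak one (e-value >= 1e-4); ORFs over
    a frameshift/premature-stop pseudogene draw truncated hits with
    coverage < 0.6.
    """
    if mode not in ("protein", "nucleotide"):
        raise ValueError("mode must be 'protein' or 'nucleotide'")
    rng = np.random.default_rng(seed)
    true_genes = truth.planted_genes + truth.split_sub_genes()
    disrupted = [
        p.region.location for p in truth.planted_pseudogenes if p.kind != "split"
    ]
    table = HitTable(source=f"emulated:{mode}")
    for call in calls:
        table.query_lengths[call.call_id] = call.length
        gene = next((g for g in true_genes if _matches_gene(call.location, g.location)), None)
        if gene is not None:
            coverage = float(rng.uniform(0.90, 1.0))
            table.hits.append(
                HomologyHit(
                    query_id=call.call_id,
                    subject_id=truth.subjects[gene.feature_id],
                    subject_name=gene.gene_name or gene.feature_id,
                    evalue=float(10 ** rng.uniform(-50, -12)),
                    identity=float(rng.uniform(85, 100)),
                    aln_length=int(coverage * call.length),
                    query_coverage=coverage,
                    bitscore=float(rng.uniform(200, 800)),
                )
            )
            continue
        if any(call.location.overlap(d) > 0 for d in disrupted):
            coverage = float(rng.uniform(0.20, 0.55))
            table.hits.append(
                HomologyHit(
                    query_id=call.call_id,
                    subject_id=f"SYNTRUNC{rng.integers(1, 10**5):05d}",
                    subject_name="truncated homolog",
                    evalue=float(10 ** rng.uniform(-30, -12)),
                    identity=float(rng.uniform(85, 100)),
                    aln_length=int(coverage * call.length),
                    query_coverage=coverage,
                    bitscore=float(rng.uniform(50, 200)),
                )
            )
            continue
        if rng.random() < 0.5:
            coverage = float(rng.uniform(0.05, 0.4))
            table.hits.append(
                HomologyHit(
                    query_id=call.call_id,
                    subject_id=f"SYNWEAK{rng.integers(1, 10**5):05d}",
                    subject_name="spurious",
                    evalue=float(10 ** rng.uniform(-4, 1)),
                    identity=float(rng.uniform(30, 60)),
                    aln_length=int(coverage * call.length),
                    query_coverage=coverage,
                    bitscore=float(rng.uniform(20, 40)),
                )
            )
    return table


def make_hit_provider(truth: SyntheticTruth):
    """Deterministic per-ORF hit oracle for pseudogene rescue.

    ORFs coinciding with a planted gene or split sub-gene get one strong
    full-coverage hit; ORF fragments over a frameshift/premature-stop
    region get a truncated (coverage 0.5) hit; everything else gets none.
    """
    true_genes = truth.planted_genes + truth.split_sub_genes()
    disrupted = [
        p.region.location for p in truth.planted_pseudogenes if p.kind != "split"
    ]

    def provider(call: GeneCall) -> list[HomologyHit]:
        for g in true_genes:
            if _matches_gene(call.location, g.location):
                return [
                    HomologyHit(
                        query_id=call.call_id,
                        subject_id=truth.subjects[g.feature_id],
                        subject_name=g.gene_name or g.feature_id,
                        evalue=1e-30,
                        identity=98.0,
                        aln_length=call.length,
                        query_coverage=0.97,
                        bitscore=500.0,
                    )
                ]
        if any(call.location.overlap(d) > 0 for d in disrupted):
            return [
                HomologyHit(
                    query_id=call.call_id,
                    subject_id="SYNTRUNC00001",
                    subject_name="truncated homolog",
                    evalue=1e-20,
                    identity=95.0,
                    aln_length=call.length // 2,
                    query_coverage=0.5,
                    bitscore=100.0,
                )
            ]
        return []

    return provider


def make_counts(
    truth: SyntheticTruth | None,
    scenario: str,
    params: dict,
    seed: int = 0,
) -> list[ExpressionRecord] | list[SiteCounts]:
    """Seeded read-count tables.

    ``scenario='expression'``: negative-binomial reads per feature with a
    zero-inflated undetectable subset (params: n_features, zero_fraction,
    mean_reads, nb_size, sample, feature_ids).  ``scenario='site'``:
    binomial allele counts at a stated true fraction across replicate
    depths (params: contig, position, ref, alt, true_fraction, depths,
    sample_prefix).
    """
    rng = np.random.default_rng(seed)
    if scenario == "expression":
        ids = params.get("feature_ids")
        if ids is None:
            if truth is not None and truth.planted_ncrnas:
                ids = [f.feature_id for f in truth.planted_ncrnas]
            else:
                ids = [f"ncRNA{i + 1:04d}" for i in range(params.get("n_features", 245))]
        n = len(ids)
        zero_fraction = params.get("zero_fraction", 0.0)
        n_zero = int(round(zero_fraction * n))
        undetectable = set(rng.choice(n, size=n_zero, replace=False).tolist())
        mean = params.get("mean_reads", 200.0)
        size = params.get("nb_size", 2.0)
        sample = params.get("sample", "S1")
        records = []
        for i, fid in enumerate(ids):
            length = int(rng.integers(80, 301))
            if i in undetectable:
                reads = 0
            else:
                reads = max(1, int(rng.negative_binomial(size, size / (size + mean))))
            records.append(
                ExpressionRecord(feature_id=fid, length_bp=length, assigned_reads=reads, sample=sample)
            )
        return records
    if scenario == "site":
        f = params["true_fraction"]
        out = []
        for i, depth in enumerate(params["depths"]):
            alt = int(rng.binomial(depth, f))
            out.append(
                SiteCounts(
                    contig=params.get("contig", "chr"),
                    position=params.get("position", 1),
                    ref_base=params.get("ref", "C"),
                    alt_base=params.get("alt", "T"),
                    alt_reads=alt,
                    total_reads=depth,
                    sample=f"{params.get('sample_prefix', 'rep')}{i + 1}",
                )
            )
        return out
    raise ValueError(f"unknown scenario {scenario!r}")
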