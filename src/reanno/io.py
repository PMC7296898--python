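"""Readers and writers for the standard formats the pipeline touches.

FASTA via Bio.SeqIO; GFF3 (version 3, 1-based inclusive) via gffutils'
line parser; homology hits as BLAST outfmt-6 12-column TSV; read-count
tables as headered TSV.  Rejected rows are never dropped silently — each
is logged with its line number.

GFF3 attribute conventions (fixed, for bit-exact diffs): ``ID``,
``gene``, ``product``, ``status``, ``provenance`` (comma-joined labels,
the GFF3 multi-value idiom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Feature, GenomeSequence, Location, from_gff3_coords
from .expression import ExpressionRecord, SiteCounts
from .homology import HomologyHit

__all__ = [
    "FormatError",
    "HitTable",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_hits_tabular",
    "read_counts_tsv",
    "write_counts_tsv",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- FASTA

_KEEP = set("ACGTN")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly multi-record) FASTA into GenomeSequence objects.

    Residues are uppercased; IUPAC ambiguity codes other than N are
    mapped to N with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if set(residues) - _KEEP:
            bad = sorted(set(residues) - _KEEP)
            logger.warning("%s: %s: mapping ambiguity codes %s to N", path, rec.id, bad)
            residues = "".join(c if c in _KEEP else "N" for c in residues)
        seqs.append(GenomeSequence(rec.id, residues))
    return seqs


def write_fasta(seqs: list[GenomeSequence], path: str | Path, line_width: int = 70) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "ncRNA",
}

_DEFAULT_STATUS = {
    "CDS": "coding",
    "pseudogene": "pseudogene",
    "tRNA": "noncoding",
    "rRNA": "noncoding",
    "ncRNA": "noncoding",
    "misc": "noncoding",
}


def read_gff3(path: str | Path, source_label: str | None = None) -> list[Feature]:
    """Read GFF3 features, converting to the internal coordinate convention.

    ``source_label`` seeds provenance for files that carry none (e.g. raw
    finder output).  Unknown feature types map to ``misc`` with a warning.
    """
    features: list[Feature] = []
    counter = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise FormatError(f"{path}: missing ##gff-version header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gf = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: unparseable GFF3 line: {exc}") from exc
            if gf.strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing or invalid strand")
            if gf.start > gf.end:
                raise FormatError(f"{path}:{lineno}: start > end")
            ftype = _GFF_TYPE_MAP.get(gf.featuretype)
            if ftype is None:
                logger.warning(
                    "%s:%d: unknown feature type %r mapped to misc", path, lineno, gf.featuretype
                )
                ftype = "misc"
            attrs = gf.attributes
            counter += 1
            fid = attrs["ID"][0] if "ID" in attrs else f"{source_label or 'feat'}_{counter:05d}"
            status = attrs["status"][0] if "status" in attrs else _DEFAULT_STATUS[ftype]
            prov: set[str] = set(attrs["provenance"]) if "provenance" in attrs else set()
            if source_label:
                prov.add(source_label)
            if not prov:
                prov = {"unknown"}
            start, end = from_gff3_coords(gf.start, gf.end)
            features.append(
                Feature(
                    feature_id=fid,
                    location=Location(gf.seqid, start, end, gf.strand),
                    ftype=ftype,
                    status=status,
                    gene_name=attrs["gene"][0] if "gene" in attrs else None,
                    product=attrs["product"][0] if "product" in attrs else None,
                    provenance=frozenset(prov),
                )
            )
    return features


def write_gff3(features: list[Feature], path: str | Path, source: str = "reanno") -> None:
    """Emit features as GFF3, sorted by (contig, start, feature id)."""
    ordered = sorted(
        features, key=lambda f: (f.location.contig_id, f.location.start, f.feature_id)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ordered:
            attrs = {"ID": [f.feature_id]}
            if f.gene_name:
                attrs["gene"] = [f.gene_name]
            if f.product:
                attrs["product"] = [f.product]
            attrs["status"] = [f.status]
            attrs["provenance"] = sorted(f.provenance)
            gf = gffutils.Feature(
                seqid=f.location.contig_id,
                source=source,
                featuretype=f.ftype,
                start=f.location.start + 1,
                end=f.location.end,
                score=".",
                strand=f.location.strand,
                frame=".",
                attributes=attrs,
            )
            fh.write(str(gf) + "\n")


# ------------------------------------------------- BLAST outfmt-6 hits


@dataclass
class HitTable:
    """Parsed tabular homology hits plus the query-length map used for coverage."""

    hits: list[HomologyHit] = field(default_factory=list)
    query_lengths: dict[str, int] = field(default_factory=dict)
    source: str | None = None
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (lineno, reason)

    def by_query(self) -> dict[str, list[HomologyHit]]:
        out: dict[str, list[HomologyHit]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out


def read_hits_tabular(path: str | Path, query_lengths: dict[str, int]) -> HitTable:
    """Read 12-column BLAST outfmt-6 TSV and derive query coverage.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Coverage = alignment length / query
    length, clamped to 1.0 (with a warning) since local alignments can
    exceed the query via gaps.  Subject names are not carried by this
    format, so subject_name mirrors subject_id.
    """
    table = HitTable(query_lengths=dict(query_lengths), source=str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                logger.error("%s:%d: expected 12 columns, got %d; row rejected", path, lineno, len(cols))
                table.rejected.append((lineno, f"{len(cols)} columns"))
                continue
            qid, sid = cols[0], cols[1]
            try:
                pident = float(cols[2])
                aln_len = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                logger.error("%s:%d: malformed numeric field (%s); row rejected", path, lineno, exc)
                table.rejected.append((lineno, "malformed numeric"))
                continue
            if qid not in table.query_lengths:
                raise FormatError(f"{path}:{lineno}: query {qid!r} absent from length map")
            coverage = aln_len / table.query_lengths[qid]
            if coverage > 1.0:
                logger.warning(
                    "%s:%d: alignment length %d exceeds query length %d; coverage clamped",
                    path, lineno, aln_len, table.query_lengths[qid],
                )
                coverage = 1.0
            table.hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    subject_name=sid,
                    evalue=evalue,
                    identity=pident,
                    aln_length=aln_len,
                    query_coverage=coverage,
                    bitscore=bitscore,
                )
            )
    return table


def write_hits_tabular(hits: list[HomologyHit], path: str | Path) -> None:
    """Emit hits in the 12-column dialect (qstart/qend/sstart/send synthesized)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.identity:.2f}", str(h.aln_length),
                        "0", "0", "1", str(h.aln_length), "1", str(h.aln_length),
                        f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------- counts tables

_SITE_COLUMNS = ["contig", "pos", "ref", "alt", "alt_reads", "total_reads", "sample"]
_EXPR_COLUMNS = ["feature_id", "length_bp", "assigned_reads", "sample"]


def read_counts_tsv(path: str | Path, kind: str) -> list[SiteCounts] | list[ExpressionRecord]:
    """Read a headered counts TSV.

    ``kind='site'`` expects columns contig, pos, ref, alt, alt_reads,
    total_reads, sample; ``kind='expression'`` expects feature_id,
    length_bp, assigned_reads, sample.
    """
    if kind not in ("site", "expression"):
        raise ValueError(f"kind must be 'site' or 'expression', got {kind!r}")
    required = _SITE_COLUMNS if kind == "site" else _EXPR_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sample": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out: list = []
    for idx, row in df.iterrows():
        try:
            if kind == "site":
                out.append(
                    SiteCounts(
                        contig=str(row["contig"]),
                        position=int(row["pos"]),
                        ref_base=str(row["ref"]),
                        alt_base=str(row["alt"]),
                        alt_reads=int(row["alt_reads"]),
                        total_reads=int(row["total_reads"]),
                        sample=str(row["sample"]),
                    )
                )
            else:
                out.append(
                    ExpressionRecord(
                        feature_id=str(row["feature_id"]),
                        length_bp=int(row["length_bp"]),
                        assigned_reads=int(row["assigned_reads"]),
                        sample=str(row["sample"]),
                    )
                )
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_counts_tsv(records: list, path: str | Path) -> None:
    """Write SiteCounts or ExpressionRecords back to the documented TSV schema."""
    if records and isinstance(records[0], SiteCounts):
        rows = [
            {
                "contig": r.contig, "pos": r.position, "ref": r.ref_base, "alt": r.alt_base,
                "alt_reads": r.alt_reads, "total_reads": r.total_reads, "sample": r.sample,
            }
            for r in records
        ]
        cols = _SITE_COLUMNS
    else:
        rows = [
            {
                "feature_id": r.feature_id, "length_bp": r.length_bp,
                "assigned_reads": r.assigned_reads, "sample": r.sample,
            }
            for r in records
        ]
        cols = _EXPR_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
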