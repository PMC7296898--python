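# Methods

## Model and procedure

`reanno` treats bacterial reannotation as a sequence of explicit,
thresholded acceptance decisions over candidate CDSs, rather than a
single gene-finding model. The assumptions are: one circular or linear
replicon at a time, features never wrapping the origin (wrapping input
is rejected); bacterial genetic code 11 with starts ATG/GTG/TTG; a
CDS span includes its stop codon; and homology to a curated protein
database as the arbiter of coding status.

Internally every location is 0-based half-open on the forward strand;
GFF3 emission converts to 1-based inclusive, and the two conversions are
exact inverses (property-tested). Minus-strand features denote the
reverse complement of their span.

**Stage 1.** Each call from the primary finder is classified from its
protein hits. The best hit is the one with lowest e-value, ties broken
by higher bitscore, then lexicographic subject id (fully deterministic).
A call is *coding* when the best e-value is strictly below
`stage1_evalue_max`; *hypothetical* when no hit qualifies; a *pseudogene
candidate* when a qualifying hit exists but the call carries a
caller-supplied disruption flag (observed frameshift/internal stop) or
its best hit covers less than `pseudo_coverage_floor` of the query. The
floor formalizes what is otherwise a manual-inspection judgement — a
proxy with observable criteria, not a reimplementation of human review.

**Stage 2.** Alternate-finder calls identical in (contig, strand, start,
end) are pooled into one candidate with merged provenance; near-misses
are left to the novelty test rather than fuzzy-deduplicated, so the
dedup rule is exact and auditable. A candidate survives only if (a) it
is not redundant with the primary coding set and (b) its best protein
hit clears `e < stage2_evalue_max`, coverage `> stage2_coverage_min`,
identity `> stage2_identity_min` — all strict, so a hit exactly at a
bound fails. Acceptance is monotone under relaxing any one threshold
(property-tested).

**Novelty/redundancy.** Evidence is tried in order: a same-strand
reciprocal-overlap fast path (≥ `novelty_coverage_min` of both spans);
a supplied nucleotide hit table; otherwise the built-in local aligner.
The novelty thresholds (identity ≥ 90%, coverage ≥ 80% of the shorter
sequence) mirror common same-genome nucleotide dedup practice and are
configurable — they are inclusive (≥) because they test sameness,
whereas the stage-2 bounds are exclusive because they test acceptance.

**Pseudogene rescue.** ORFs are re-called inside each annotated
pseudogene span (± `rescue_flank`, default 0: the documented split cases
lie fully inside their spans); each ORF whose best protein hit clears
the stage-2 rule becomes a coding feature, so one span can yield several
genes. Feature ids are derived from coordinates, which makes rescue
idempotent. Spans yielding nothing are retained as pseudogenes.

**ORF finder.** A six-frame scan returning, per stop codon, the ORF from
the first start codon after the previous in-frame stop (the longest
open reading frame for that stop); nested starts are recoverable via
`keep_nested`. `min_orf_length` defaults to 90 nt (30 codons, a common
prokaryotic floor). The finder is verified against an independent
brute-force enumerator that walks codon-by-codon from every start.

**Alignment.** Local (Smith-Waterman) DNA alignment via Biopython's
`PairwiseAligner`: match +2, mismatch −3, gap open −5 (the first gapped
column), extension −2 per additional column. Identity is matches over
alignment columns including gaps; coverage is the aligned span of the
shorter sequence over its length. Scores are checked against an
independent full Gotoh DP in the test suite. Parameters are pinned
because reproducibility of accept/reject decisions matters more here
than matching any particular search tool's defaults.

**Diffing.** Same-genome matching pairs features of the same type,
contig and strand with reciprocal overlap ≥ `match_overlap_min`
(default 0.90); many-to-many candidates are resolved greedily by
largest overlap, deterministically ordered, and logged. Cross-genome
mode matches by case-insensitive gene name, for strain-to-strain
comparisons where coordinates are incommensurable. `shared_fraction` is
the percent of the *old* annotation retained, at one decimal.

**Ratios and rounding.** Every printed percentage goes through one
function, `proportion`, which rounds half-up (63.4% → 63 at zero
decimals, 84.73% → 85) via exact decimal arithmetic — matching how such
ratios are conventionally printed, and verified against rational
arithmetic by property test.

**Expression and variants.** `FPKM = reads × 10⁹ / (total_mapped ×
length_bp)`. A feature is *detectable* when FPKM strictly exceeds
`fpkm_detect_min` (default 0 — any mapped signal counts; the threshold
exists for stricter analyses) in at least one sample. A candidate
variant is *rna_only* when every RNA replicate's allele fraction is
≥ `af_rna_min` (default 0.5) and genomic evidence is either an explicit
absence flag (a qualitative clean Sanger trace is modeled as a flag,
not fabricated counts) or a fraction ≤ `af_genome_max` (default 0.1);
*genomic* when the genomic fraction exceeds that bound; *unsupported*
otherwise. The observed discordant site in the motivating use case sat
near 100% and 85% in RNA with a clean genomic trace, comfortably inside
these defaults; the defaults themselves are design choices since only
observations, not decision rules, are given. Site-to-feature distance
counts bases strictly between the site and the nearest feature edge
(a site "19 bp downstream" has 19 intervening bases), oriented by the
feature's strand; equidistant ties break on feature id and are logged.

## Synthetic data: what it emulates and what it does not

`make_genome` plants complete ORFs (random non-stop codons between a
start and a stop), each preceded by an in-frame stop codon so the
longest-ORF rule recovers its exact span; disrupted pseudogenes of three
rotating kinds — 1-bp frameshift, premature stop, and a "split" span
concealing two intact genes; and ncRNAs, all non-overlapping on a
background of stated GC content. `emulate_finder` drops genes at
1 − sensitivity, jitters starts frame-preservingly, and adds intergenic
false calls at a per-kb rate. `emulate_hits` gives true genes strong
hits (e-value log-uniform 10⁻⁵⁰–10⁻¹², identity 85–100, coverage
0.9–1.0), spurious calls weak-or-no hits (e ≥ 10⁻⁴), and ORFs over
disrupted pseudogenes truncated hits (coverage < 0.6). `make_counts`
draws negative-binomial expression with an exact zero-inflated subset,
and binomial allele counts at a stated true fraction. All generators are
pure functions of (parameters, seed) with a single RNG stream each.

Deliberately not emulated: codon usage and GC-frame bias of real genes,
overlapping genes, operon structure, paralog families (so the novelty
test sees no hard near-duplicate cases), database misannotation, and
read-level sequencing error. Passing the planted-truth suites therefore
shows the decision logic is correct under its stated rules — not that
the thresholds are optimal for any particular real genome.

## Problem sizes and numerical choices

The standard fixture is a 50 kb genome with 30 genes, 5 pseudogenes and
10 ncRNAs — large enough to exercise every pseudogene kind and strand
mix while keeping the full suite in seconds. Oracle-equivalence tests
run the ORF finder on 100 random sequences of 5–20 kb, and the aligner
against full DP on sequences ≤ 200 nt. Coverage parsed from tabular
hits is clamped to 1.0 (local alignments can exceed the query length
through gaps) with a warning. Degenerate inputs fail loudly: empty
FASTA, inverted GFF3 coordinates, missing strands, `alt_reads >
total_reads`, and zero denominators are errors, never silently fixed.

## Known limitations

Origin-wrapping features are rejected rather than handled. The
redundancy aligner is all-pairs per candidate and meant for
genome-segment scale, not for a 4000-CDS all-vs-all (supply a
nucleotide hit table for that). ncRNA merging defaults to exact
coordinate union (`merge_slop` 0) since finders were assumed
independent; real tRNA predictions sometimes differ by a base or two
and warrant a small slop. Stage-1 pseudogene candidacy is a proxy for
expert review and will miss disruptions that only synteny or manual
curation reveals.
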