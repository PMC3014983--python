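# Methods

`denovopost` analyses the outputs of a de novo overlap assembler run on a
pooled, sex-tracked transcriptome: contig and singleton sequences, per-read
placement records (including reads the assembler split between two contigs),
variant calls with coverage and a posterior probability, tabular homology
hits against reference protein databases, and a gene-level GO map.  This
note records the models, conventions and numerical choices behind each
stage, and what the bundled synthetic-data generator does and does not
emulate.

## Split-read contig graphs

When a pooled transcriptome carries divergent alleles, duplicated genes and
alternative splicing, an overlap assembler splits reads at variation
boundaries, producing separate contigs for the variable regions and one
contig for each shared region.  We build a graph whose nodes are contigs and
whose edges are reads split between two contigs (edge weight = number of
supporting split reads; edges below `min_edge_support`, default 1, are
dropped).  Connected components of this graph are the *graph-clusters*.

Within a cluster, nucleotide similarity separates the interpretations:

| pair identity        | interpretation                 |
|----------------------|--------------------------------|
| >= 0.95              | divergent alleles of one gene  |
| 0.80 <= id < 0.95    | diverged regions of a duplicated gene pair |
| lower or undefined   | alternatively spliced exons / non-overlapping pieces |

Similarity is evaluated between **all members** of a cluster, not only along
edges.  This is deliberate: the split-read topology places the two variant
contigs as siblings of a shared-exon hub, so the informative pair (allele A
vs allele B, or paralog A vs paralog B) is usually *not* itself an edge.
Bands are closed on the left (identity exactly 0.95 counts as allele,
exactly 0.80 as duplicate); the choice is measure-zero in practice and fixed
for reproducibility.

Cluster decomposition proceeds in a fixed order: (1) connected subgraphs of
allele-labelled pairs are contracted into one consensus super-node each
(a *merged alleles* component); (2) every duplicate-labelled node pair
yields a *duplicate pair* component; (3) with duplicate-pair nodes set
aside, each residual connected subgraph of two or more nodes joined by
splice-labelled edges yields an *alternative splicing* component.  A splice
subgraph that shares nodes with a duplicate pair is flagged `unresolved`
rather than forced into one type.  Note that a two-contig residual of a
merged allele pair plus its shared exon is reported as an alt-splice
component — it is genuinely a multi-contig transcript structure — so
alt-splice calls are a superset of "true" splicing events; the recovery
metrics therefore score whether each *planted* structure received its
correct type, not one-to-one call identity.

Each component's homology pattern is summarised into five categories (no
member hit / some hit, different subjects / some hit, one subject / all hit,
different subjects / all hit, one subject), computed from hits in one
database at a stated e-value cut-off (default NR at 1e-20).

## Alignment and consensus conventions

All pairwise alignment uses one scoring scheme: match +1, mismatch −1, gap
−2 (linear), with end gaps free in the overlap (semi-global) mode and
Smith–Waterman for local alignment (singleton rescue).  Identity is
matches / aligned columns; gap columns inside the aligned region count in
the denominator, free end-gap overhangs do not.  The overlap identity is
undefined (treated as splice evidence) when the aligned region is shorter
than `min_overlap` = 40 columns, mirroring the assembler's own minimum
overlap.

Co-optimal alignments can differ in identity, so the traceback is pinned:
the end cell is the boundary cell maximising (score, i, j), and ties in the
traceback prefer diagonal over up over left moves.  `overlap_identity`
evaluates the pair in canonical (lexicographic) order, which makes it
exactly symmetric.  The kernels are written directly (numba) rather than
through a library aligner precisely so these tie-breaks are specified.

Allele consensus is column-wise over the pairwise alignment: equal columns
keep the base, substitution columns (always a 1–1 tie) get the IUPAC
ambiguity code of the union, gap columns keep the present base; groups of
three or more alleles are merged progressively in sorted member order.
Ambiguity codes preserve the allelic information and keep the consensus
deterministic.

## Variant filtering and selection statistics

High-confidence filter: a call is removed iff coverage < 5 OR coverage >
100 OR probability < 0.9 — strict inequalities, so the boundary values 5,
100 and 0.9 all survive.  INS/DEL calls inside *or immediately adjacent to*
a homopolymer run of >= 3 identical bases are additionally removed: short
homopolymer runs are the classic pyrosequencing error mode, and 3 is the
conventional trouble threshold (configurable).  The filter is idempotent.

Per contig with surviving variants:

* **TS/TV** — transitions (purine<->purine, pyrimidine<->pyrimidine) vs
  transversions over all SNPs, reported as the smoothed ratio
  `(TS+1)/(TV+1)` so contigs with a zero count still get a value.
* **Ka/Ks** — SNPs falling inside the contig's longest predicted ORF are
  classified synonymous/nonsynonymous by translating the containing codon
  with the reference and the alternate base (standard code; minus-strand
  ORFs are reverse-complemented first; a stop codon counts as an amino-acid
  state; each SNP is evaluated one at a time against the reference codon —
  the data model has no haplotype phase).  Reported as `(Ka+1)/(Ks+1)`.
  These are raw polymorphism counts with +1 smoothing, *not* per-site
  dN/dS rates: the screen ranks contigs, it does not estimate ω.
* **Density** — variants per bp (and per 200-bp window).  Contigs at or
  above the nearest-rank 99th percentile of density (computed over contigs
  with >= 1 variant, rank = floor(q·n)+1, so 100 distinct densities flag
  exactly the maximum) are *highly variable*.

ORF prediction scans all six frames for ATG..stop spans (stop included),
keeps the longest of at least 30 nt, and breaks ties toward the + strand,
then the lowest frame, then the smallest start.  When a contig has several
ORFs only the longest is used for Ka/Ks.

The diversifying-selection candidate set is the intersection Ka/Ks > 1 AND
TS/TV < 1 AND highly variable.  The variant-count-on-length relationship is
an OLS regression over contigs with >= 1 variant (slope, R², F, df, p).

## Sex-specific gene calling

Reads come from one female and one male normalized pool; each read's sex is
tracked through assembly, so a contig is FC (all reads female), MC (all
male) or BC (both), and a singleton carries its read's sex.  Because the
libraries are normalized the comparison is presence/absence, never
quantitative.

A homology accession is **female-specific** iff (a) at least one FC contig
or F singleton hits it at e <= `strict_cutoff` (default 1e-50) and (b) no
MC contig, M singleton or BC contig hits it at e <= `screen_cutoff`
(default 1e-5); symmetric for males.  Two readings of "no homology down to
the strict cut-off" are possible; we adopt the conservative one — any
opposite-sex homology at the *loosest* cut-off of the ladder disqualifies —
and expose both cut-offs.  BC contigs contain reads of both sexes, so a BC
hit disqualifies specificity on both sides.  Accessions with screen-level
evidence from both sides are *shared*; the rest *insufficient*.  Screening
is per accession; screening across whole homology groups would be stricter
still and is noted as an alternative.

GO enrichment between the female- and male-specific sets runs one Fisher's
exact test per term present in either set (two-sided by the
point-probability rule; one-sided available), Benjamini–Hochberg corrected
across terms.

## Homology tools

* **Homology clusters**: all sequences hitting one subject accession in one
  database at a cut-off; a sequence joins every cluster it hits and
  multi-membership is reported separately (a domain shared across a family
  legitimately joins several clusters).
* **Unique-homolog counts**: distinct subject accessions per database at
  the ladder 1e-5, 1e-10, 1e-20, 1e-50; monotone non-increasing by nesting.
* **Presence sets**: per sequence, the subset of databases with a
  qualifying hit; region counts partition the annotated sequences.
* **Chimeras**: a sequence with two hits at e < 1e-20 to different
  accessions whose query intervals overlap by <= 20% of the shorter
  interval and whose midpoints fall in opposite halves of the query.  The
  geometry replaces manual inspection of "hits at different ends"; both
  knobs are parameters.  A subject-pair whitelist suppresses known
  co-transcribed neighbours (e.g. adjacent mitochondrial genes).
* **Singleton rescue**: a singleton is redundant with a contig when a local
  alignment reaches >= 95% identity over the aligned columns (gaps count
  against identity) with fewer than 10 unaligned singleton bases at each
  end.  Candidates come from a shared-20-mer index (seed-and-extend); ties
  prefer higher identity, then longer span, then the smaller contig id.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every recovery property is evaluated.  Default conditions are a
200-gene, roughly 20k-read pooled design: mean read length 366 bp (sd 40),
mean per-gene depth 20× (deep enough that every variation boundary is
crossed by split reads with high probability), equal sex ratio, 7.5% of
reads left as singletons and 5.7% discarded.  Categories: 90 single-copy
genes (10 female-only, 10 male-only), 25 divergent allele pairs (divergence
3.2–4.3%, i.e. identity 0.957–0.968 — above the 0.95 allele threshold but
below the 0.97 assembler merge identity, so the classifier has real work to
do), 15 low-divergence pairs (0.5–2%) that the emulated assembler collapses
into variant-bearing contigs, 25 duplicate pairs (divergence 7–18%,
identity 0.82–0.93), 35 alternatively spliced genes (3–4 exons, 2–3
isoforms sharing at least one exon) and 10 planted chimeras concatenating
halves of two unrelated sequences.

Mutation realizes an exact count of substituted sites, round(d·L), so the
identity bands hold deterministically; substitutions are transitions with
probability w/(w+1) (w = 2 by default), giving an expected TS:TV of w:1.
True variant calls get Poisson(depth) coverage and Beta(20,1) probability
(most above the 0.9 cut-off); injected false calls get Beta(2,2)
probability and wide uniform coverage (most fail the filter), plus
homopolymer-adjacent INDELs that only the homopolymer rule can catch.
True INDELs on collapsed contigs are injected as records at
homopolymer-free positions (the simulated allele sequences themselves
differ only by substitutions).  Homology evidence is emulated, not
searched: genes flagged no-homolog get no hits; allele contigs of one gene
hit one accession; the two diverged contigs of a duplicate pair hit
different paralog accessions (their shared contig hits both); chimera
contigs get two strong hits on opposite query halves; a weak-homolog
fraction with e-values between 1e-18 and 1e-6 makes the cut-off ladder
informative.  Sex bias is assigned only among genes with an accession,
because the presence/absence caller can only see genes with a homology ID;
bias is absolute (an optional leakage rate exists for robustness
experiments).  GO terms come from a small vocabulary, with a biosynthesis
term preferentially attached to female-only genes so enrichment has a
planted signal.

What the generator does **not** emulate: per-base sequencing error (read
cleaning is upstream), quantitative expression levels (the normalized
design makes detection presence/absence), realistic homopolymer
length-miscall processes, misassembly other than the planted chimeras, and
any real database biology (accessions and e-values are synthetic).
Passing recovery tests therefore demonstrates the correctness of the
*post-assembly logic* under an idealized assembler, not robustness to raw
platform noise.  One further idealization: every read spanning a
variation boundary with at least 30 bp on each side becomes exactly one
split read; real assemblers split less regularly.

## Determinism and problem sizes

Every random choice flows from one integer seed through spawned generator
streams, so identical parameters and seed give byte-identical outputs; the
pipeline writes per-stage wall-clock to a separate `timings.json` so all
analytic outputs compare byte-for-byte across runs.  The shipped test suite
and the reproduction script run the full pipeline at the default 200-gene /
~17k-read scale (seconds to a few minutes on one core), with smaller
fixtures (~45 genes) for unit-level checks; these sizes were chosen so that
every recovery property is measured on hundreds of planted structures while
the whole suite stays quick to run.

## Known limitations

* Isoform structure is reported as exon components and split-read edges;
  transcript paths are not enumerated (no unambiguous enumeration rule
  exists without expression weights).
* Duplicate pairs are called from pairwise identity alone; reciprocal-best
  constraints are not imposed.
* Ka/Ks uses raw counts, uncorrected for the number of synonymous vs
  nonsynonymous sites; it ranks contigs rather than estimating selection
  coefficients.
* The variant data model is unphased; compound codon changes are evaluated
  one SNP at a time.
* Chimera geometry assumes roughly end-to-end hit placement; a chimera
  joining two genes at 10%/90% of the contig can escape the opposite-half
  test.
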