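# Methods

## Scope and model

The package implements a family census for WRKY transcription factors: a
plant TF family defined by a ~60-residue DNA-binding domain — the
heptapeptide `WRKYGQK` followed by a zinc finger — that binds the W-box
element `(T)TGAC(C/T)` in target promoters. Family structure follows the
classical three-group scheme: group I proteins carry two WRKY domains with
C2H2 fingers, group II one C2H2 domain (subgroups IIa–IIe defined by
domain sequence, read here from tree placement), group III one C2HC
finger. The census is the per-gene table of name, locus, pI, MW,
heptapeptide, finger type, domain count, group and length, plus the
companion artifacts (tree, structures, tandem pairs, promoter hits,
expression folds).

## Domain detection

*Heptapeptide admission.* A 7-mer is admitted when its first three
residues are exactly `WRK` and its Hamming distance to `WRKYGQK` is at
most `max_mismatch` (default 2, range 0–2). A single relaxation admits
7-mers with exact `WR` prefix at Hamming ≤ 2 when they equal a named
variant; this is the tightest rule that covers the variant spectrum
observed in published censuses (`WRKYGEK`, `WRKYGKK`, `WRKYGSK`,
`WRKSGQR`) without opening the scan to arbitrary W-initial words. Named
variants are reported by their literal name, anything else as `other`.

*Zinc fingers.* One generalized layout `C-X(3..7)-C-X(22..23)-H-X-[H|C]`
is scanned rather than separate per-group dialects, so finger typing
cannot prejudge classification. Matches resolve leftmost-first,
non-overlapping, with lazy spacers (shortest spacer wins where several
fit). The terminal coordinating residue sets the type: H → C2H2, C → C2HC.

*Domains.* Each heptapeptide is paired with the nearest downstream zinc
finger whose first Cys lies within `linker_max` residues of the
heptapeptide's end (default 50, consistent with the ~60-residue domain
span; the true upper bound is not standardized, so this is configurable).
Each finger is consumed at most once, left to right. Proteins with zero
complete domains fail the family inclusion criterion and are excluded
with a logged warning.

*HARF.* The subgroup IId signature `RTGHARFRR[A/G]P` is reported
separately; its function is unknown and it plays no role in
classification.

## Physico-chemical predictions

MW is the sum of average (not monoisotopic) residue masses plus one water,
via Biopython's tables, reported in kDa to two decimals; unknown residues
(X) contribute zero mass. pI is found by bisection on [0, 14] of the
net-charge function (termini plus D/E/C/Y side-chain acids and H/K/R
bases, single Bjellqvist-style pKa per group: N-term 9.094, C-term 2.869,
D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0). The charge
function is strictly decreasing in pH, so the root is unique; bisection
stops at |charge| < 1e-4. Full position-specific pKa models (as used by
some web servers) differ by up to a few tenths of a pH unit; the simpler
set keeps the computation transparent and exactly testable.

## Redundancy removal

Greedy longest-first clustering: a sequence joins a cluster when its
global-alignment identity (matches / alignment columns) to the
representative is ≥ the threshold (default 0.95), else founds a new
cluster. This mirrors the intent of word-heuristic tools (collapse
isoforms and fragments) without reproducing their internals. At the
default threshold, close paralog pairs occasionally exceed 0.95 identity
and collapse; the stage can be disabled (`run_dedup=False`) when inputs
are known non-redundant.

## Alignment and phylogeny

Pairwise alignment is Gotoh three-state dynamic programming with affine
gaps costing `open + (L-1)·extend` (defaults BLOSUM62, 10/0.5 — the
EMBOSS-style convention). The DP is row-vectorized; the horizontal gap
state collapses to a running maximum so each row is a handful of numpy
operations. Traceback tie-breaking is fixed (match state preferred,
diagonal > up > left) for determinism; scores are validated in the test
suite against explicit enumeration of all alignments of short sequences.

The progressive MSA builds a UPGMA guide tree on 3-mer distances
(1 − shared/min k-mer count) and merges profiles leaves-inward with
profile–profile alignment over the same DP engine (column frequency
vectors, gaps scoring zero; "once a gap, always a gap"). An externally
computed gapped-FASTA alignment can be substituted at any point; the
downstream statistics (group-level clading) depend on the alignment only
weakly. Full-length proteins are aligned by default; domain-only
alignment is possible by slicing but makes no equivalence claim.

Distances are p-distances (mismatches / compared sites) under pairwise
deletion: columns gapped in either row are skipped for that pair; a pair
with zero comparable sites is an error naming the pair. Trees are built
with Saitou–Nei neighbor joining: minimum-Q pair chosen in row-major
(lexicographic) order among ties, negative branch lengths clamped to zero
with the deficit moved to the sister branch so the pair's summed length is
preserved; the final three nodes are solved by the three-point formulas
around a trifurcating root. On additive matrices NJ reproduces the
generating tree's path lengths to 1e-9 (tested 4–8 taxa).

Bootstrap supports resample alignment columns with replacement; replicate
r draws from `numpy.default_rng([seed, r])` — a counter-derived stream, so
results are reproducible and independent of evaluation order. Support is
the percentage of replicate NJ trees containing each internal bipartition
of the full-data tree, emitted as internal node labels in Newick. The
default replicate count is 1,000; the acceptance script and test suite run
100, which the census conclusions do not depend on.

## Classification and naming

Feature evidence (domain count + finger type) fixes a provisional group;
tree evidence labels a query by majority vote among its k = 3 nearest
labeled reference leaves by path length (ties: smaller total path length,
then lexicographic label). k = 3 is small enough to respect subgroup
clades and robust to one misplaced reference. Reconciliation: if the
major groups agree, the tree's subgroup stands; if they disagree but the
k-neighborhood is unanimous, the tree wins — this is how a one-domain
protein can still land in group I, or a two-domain C2HC protein in group
III, when its clade is clear-cut; if they disagree and the neighborhood
is mixed, the gene is NG, with a machine-readable trace recording both
labels and any finger-type conflict. Published censuses assign groups by
reading clades off the tree by eye; this rule is an explicit,
reproducible reconstruction of that practice, not a published algorithm.

Names are positional: sort by chromosome (natural numeric order, Chr2 <
Chr10) then start coordinate, and number `prefix1…prefixN`. Duplicate
(chromosome, start) pairs tie-break by end then id with a warning.

## Gene structure

Exons are recovered by exact-match chaining of the CDS against the
genomic sequence: the longest exact extension anchors each exon, each
intron resumes at the next exact occurrence of the remaining CDS,
preferring GT…AG-flanked introns, then leftmost. Resumption points must
carry an exact match of ≥ min(10, remaining CDS) bases — without this
anchor, single-base coincidences would let the chain fragment the CDS
arbitrarily; 10 bp is shorter than any biologically plausible internal
exon. The search backtracks, so a coincidental overlap at a boundary
cannot derail the chain, and the exon concatenation is verified to equal
the CDS exactly. Introns shorter than 4 bp (GT + AG) are impossible. The
genomic record may extend past the final exon (3' UTR); leading sequence
before the first exon is not modeled.

## Tandem duplications and clusters

Two genes are a tandem pair when they lie on the same chromosome with a
span gap (0 if overlapping) ≤ 100 kbp and their *proteins* reach ≥ 70 %
local-alignment similarity — similarity being positive-scoring aligned
pairs over all alignment columns, the "Similarity" percentage EMBOSS
Water prints. Protein alignment is the conservative choice for paralogy
(the molecule used by published censuses is typically unstated);
nucleotide mode is available via the matrix argument. Clusters chain
consecutive genes whose start-to-start distance is ≤ 100 kbp
(transitive); cluster definitions in the literature are visual, so this
chaining rule is a stated stand-in and cluster counts are descriptive
only.

## Promoters

The promoter is the `length_bp` (default 1,500) bases immediately
upstream of the start (plus strand) or the reverse complement of the
bases after the end (minus strand), truncated with a warning at
chromosome edges. Elements are IUPAC patterns scanned on both strands;
all matches, including overlaps, are reported with 1-based positions on
the extracted promoter, ordered (position, name, strand). The shipped
library uses literature-standard cores (W-box `TTGACY`, ABRE `ACGTG`,
G-box `CACGTG`, MBS `CAACTG`, …) and is a plain TSV the user can edit;
database scanners use proprietary matrices, so hit lists here are
format-compatible with theirs, not value-identical — counts that depend
on a specific database's definitions are deliberately not asserted
anywhere.

## Expression

2^−ΔΔCt with 100 % amplification efficiency assumed: per replicate,
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the gene's mean
calibrator ΔCt; folds are exponentiated per replicate and averaged
(mean-of-folds, with standard error across replicates), the common
practice for this method; exponentiating the replicate-mean ΔΔCt is a
config switch (`aggregate="fold-of-means"`). The calibrator column is
fixed at exactly 1 (it defines the unit). The fold filter keeps genes
moving ≥ t-fold in either direction (inclusive; default t = 2.5).
Hierarchical clustering uses 1 − Pearson correlation with average
linkage via scipy; zero-variance genes are rejected with a pointer to
the Euclidean fallback.

## Synthetic families

The generator's defaults are the study conditions of the census it
emulates: 94 genes with subgroup counts 11/4/8/20/6/12/31
(I/IIa/IIb/IIc/IId/IIe/III), 13 heptapeptide-variant carriers
(6 `WRKYGEK`, 5 `WRKYGKK`, 1 `WRKYGSK`, 1 `WRKSGQR`), intron histogram
{0: 4, 1: 10, 2: 58, 3: 8, 4: 8, 5: 5, 7: 1}, two tandem pairs inside
100-kbp windows on shared chromosomes, 1,500-bp promoters, and Ct tables
spanning five timepoints with three replicates and fold changes up to
~90×, matching the dynamic range reported for drought-induced WRKYs.

Subgroup ancestors are built from the printed pattern layouts plus random
filler; each gene mutates from its ancestor at the divergence rate
(default 0.1 substitutions per non-critical site — a moderate
within-family divergence at which tree placement is still unambiguous;
reference panels use 0.05, three labeled references per subgroup). Two
deliberate simplifications keep ground truth exact rather than merely
probable: substitutions draw from a reduced alphabet excluding every
motif-defining residue (W, R, K, Y, G, Q, E, S, C, H), so no spurious
heptapeptide or finger can arise or vanish; and no indels are introduced
by default, so the MSA's site homology is exactly testable. Tandem
partners diverge at 0.15 from their donor — similar enough to pass the
70 % similarity criterion, distinct enough not to look like isoforms to
the redundancy filter. Reverse translation draws uniformly over
synonymous codons; introns (20–80 bp, GT…AG) are inserted at CDS
positions chosen so exact-match chaining stops precisely at each
boundary. Genes are spaced 250 kbp apart (beyond the tandem window) on
10 chromosomes.

What passing synthetic tests does **not** show: robustness to real-world
mess — indels in domains, degenerate variants beyond the named set,
assembly gaps, non-canonical splice sites, isoform redundancy at
intermediate identity, GC/codon bias. The generator makes no attempt to
match real codon usage or intergenic architecture.

## Problem sizes and determinism

The shipped test-and-acceptance configuration runs a 94-gene family with
21 references (115-taxon tree), 100 bootstrap replicates, and a
1,000-gene structure-inversion suite; the full test suite completes in
about a minute on one CPU and the acceptance script in well under one.
All randomness flows from explicit seeds (numpy `default_rng`); identical
config + seed reproduces every artifact byte-for-byte, which the test
suite asserts.

## Known limitations

- Group II subgroup boundaries are only as good as the reference panel;
  with no panel the census reports the major group only ("II").
- The reconciliation rule reproduces by-eye clade reading; borderline
  genes near clade boundaries can flip between a subgroup and NG under
  different panels or alignments.
- pI uses a single-pKa-per-group model (see above).
- The exact-match structure chaining assumes the CDS is a perfect
  subsequence of the genomic sequence; sequencing errors or polymorphism
  between the two sources produce an error rather than an approximate
  answer.
- Promoter hit lists depend entirely on the element library supplied.
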