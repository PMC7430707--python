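"""Exon–intron structure inference and tandem-duplication detection.

Structure inference reconstructs exons by exact-match chaining of the CDS
against the genomic sequence, preferring canonical GT…AG introns and
leftmost resumption points, with backtracking so a coincidental sequence
overlap at an exon boundary cannot derail the chain.

Tandem duplications follow the classical census criterion: two genes on
one chromosome within a 100-kbp window whose protein sequences share >= 70%
local-alignment similarity (EMBOSS-Water-style percentage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

from .pairwise import load_matrix, smith_waterman
from .records import GeneLocus, NucleotideRecord, SequenceSet


@dataclass
class GeneStructure:
    gene_id: str
    exons: list[tuple[int, int]]  # 1-based inclusive intervals on the genomic seq
    splice_sites: list[tuple[str, str]]  # per-intron (donor, acceptor) dinucleotides

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    gap_bp: int
    similarity: float


@dataclass
class GeneCluster:
    chromosome: str
    members: list[str]
    span_bp: int


def infer_structure(
    genomic: NucleotideRecord, cds: NucleotideRecord
) -> GeneStructure:
    """Recover exon intervals such that the exons concatenate to the CDS.

    Depth-first chaining: the longest exact extension anchors each exon
    (longest-first among candidate exon ends), introns resume at the next
    exact match of the remaining CDS, preferring GT…AG-flanked introns and
    then leftmost positions. A resumption point must carry an exact match
    of at least ``min(10, remaining CDS)`` bases — single-base coincidences
    would otherwise let the chain fragment the CDS arbitrarily. The first
    complete chain under this preference order is returned; failure
    reports the CDS offset reached.
    """
    g, c = genomic.seq, cds.seq
    n, m = len(g), len(c)
    best_fail = 0
    min_intron = 4  # GT + AG; shorter gaps cannot be spliced
    min_anchor = 10  # shortest biologically sane internal exon

    def extension(gi: int, ci: int) -> int:
        k = 0
        while gi + k < n and ci + k < m and g[gi + k] == c[ci + k]:
            k += 1
        return k

    seen: set[tuple[int, int]] = set()

    def search(gi: int, ci: int, exon_start: int) -> list[tuple[int, int]] | None:
        # gi/ci: 0-based positions where an exon currently extends
        nonlocal best_fail
        if (gi, ci) in seen:
            return None
        seen.add((gi, ci))
        ext = extension(gi, ci)
        best_fail = max(best_fail, ci + ext)
        if ci + ext == m:
            return [(exon_start + 1, gi + ext)]  # to 1-based inclusive
        # exon must be non-empty; try longest exon end first
        for exon_len in range(ext, 0, -1):
            ci_next = ci + exon_len
            intron_start = gi + exon_len
            candidates: list[tuple[int, int]] = []  # (priority, resume gpos)
            pos = intron_start + min_intron
            anchor = c[ci_next : ci_next + min(min_anchor, m - ci_next)]
            donor = g[intron_start : intron_start + 2]
            while pos < n:
                idx = g.find(anchor, pos)
                if idx == -1:
                    break
                acceptor = g[idx - 2 : idx]
                canonical = 0 if (donor == "GT" and acceptor == "AG") else 1
                candidates.append((canonical, idx))
                pos = idx + 1
            candidates.sort()
            for _, resume in candidates:
                result = search(resume, ci_next, resume)
                if result is not None:
                    return [(exon_start + 1, intron_start)] + result
        return None

    exons = search(0, 0, 0)
    if exons is None:
        raise ValueError(
            f"{cds.id}: CDS not reconstructible from genomic sequence; "
            f"first failure at CDS offset {best_fail}"
        )
    splice = []
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        splice.append((g[e1 : e1 + 2], g[s2 - 3 : s2 - 1]))
    # sanity: exon concatenation equals CDS
    rebuilt = "".join(g[s - 1 : e] for s, e in exons)
    if rebuilt != c:
        raise AssertionError(f"{cds.id}: exon chain does not rebuild the CDS")
    return GeneStructure(gene_id=cds.id, exons=exons, splice_sites=splice)


def smith_waterman_similarity(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent similarity of the optimal local alignment.

    Similarity counts aligned residue pairs with a positive substitution
    score, over all alignment columns (gaps included) — the convention
    EMBOSS Water prints as "Similarity".
    """
    if not a or not b:
        warnings.warn("empty sequence in similarity computation; returning 0%")
        return 0.0
    aln = smith_waterman(a, b, matrix, gap_open, gap_extend)
    if aln.columns == 0:
        return 0.0
    alphabet, subst = load_matrix(matrix)
    index = {ch: i for i, ch in enumerate(alphabet)}
    positive = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != "-" and y != "-" and subst[index[x], index[y]] > 0
    )
    return 100.0 * positive / aln.columns


def locus_gap(a: GeneLocus, b: GeneLocus) -> int:
    """Gap in bp between two spans on the same chromosome (0 if they overlap)."""
    if a.chromosome != b.chromosome:
        raise ValueError("loci on different chromosomes have no gap")
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def detect_tandem(
    loci: list[GeneLocus],
    proteins: SequenceSet,
    window_bp: int = 100_000,
    min_similarity: float = 70.0,
    matrix: str = "BLOSUM62",
) -> list[TandemPair]:
    """Same-chromosome gene pairs within the window whose proteins meet
    the similarity threshold. Output order is (chromosome, start) sorted,
    independent of input order."""
    for loc in loci:
        if loc.gene_id not in proteins:
            raise ValueError(f"no protein sequence for locus {loc.gene_id!r}")
    ordered = sorted(
        loci, key=lambda l: (l.chromosome, l.start, l.end, l.gene_id)
    )
    pairs = []
    for a, b in combinations(ordered, 2):
        if a.chromosome != b.chromosome:
            continue
        gap = locus_gap(a, b)
        if gap > window_bp:
            continue
        sim = smith_waterman_similarity(
            proteins[a.gene_id].seq, proteins[b.gene_id].seq, matrix
        )
        if sim >= min_similarity:
            pairs.append(
                TandemPair(
                    gene_a=a.gene_id, gene_b=b.gene_id, gap_bp=gap,
                    similarity=sim,
                )
            )
    return pairs


def find_clusters(
    loci: list[GeneLocus], chain_window_bp: int = 100_000
) -> list[GeneCluster]:
    """Transitive chaining of same-chromosome neighbors whose start-to-start
    distance is within the window; clusters of >= 2 genes reported."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        current = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            if nxt.start - prev.start <= chain_window_bp:
                current.append(nxt)
            else:
                if len(current) >= 2:
                    clusters.append(_make_cluster(chrom, current))
                current = [nxt]
        if len(current) >= 2:
            clusters.append(_make_cluster(chrom, current))
    return clusters


def _make_cluster(chrom: str, members: list[GeneLocus]) -> GeneCluster:
    return GeneCluster(
        chromosome=chrom,
        members=[m.gene_id for m in members],
        span_bp=members[-1].end - members[0].start + 1,
    )
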