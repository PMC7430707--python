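"""Progressive multiple sequence alignment.

A guide tree is built by UPGMA on k-mer distances, then profiles are merged
leaves-inward with profile–profile affine-gap alignment over the same DP
engine used for pairwise alignment. Once a gap is introduced into a profile
it is never removed ("once a gap, always a gap").

An externally computed alignment (gapped FASTA) can be substituted for this
aligner anywhere downstream; the tree and classification stages only see
the :class:`MultipleAlignment` container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .pairwise import global_align_ops, load_matrix
from .records import SequenceSet


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, idx: int) -> str:
        return self.rows[idx].replace("-", "")

    def subset(self, ids: list[str]) -> "MultipleAlignment":
        index = {g: i for i, g in enumerate(self.ids)}
        return MultipleAlignment(
            ids=list(ids), rows=[self.rows[index[g]] for g in ids]
        )


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - shared k-mers / min k-mer count; crude but adequate for a guide
    tree, which only sets the merge order."""
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows: list[str], alphabet: str) -> np.ndarray:
    """Column frequency matrix (L, |alphabet|); gaps contribute nothing."""
    index = {c: i for i, c in enumerate(alphabet)}
    L = len(rows[0])
    prof = np.zeros((L, len(alphabet)))
    for row in rows:
        for pos, ch in enumerate(row):
            if ch != "-":
                prof[pos, index[ch]] += 1.0
    return prof / len(rows)


def _merge(
    rows_a: list[str],
    rows_b: list[str],
    alphabet: str,
    subst: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    pa = _profile(rows_a, alphabet)
    pb = _profile(rows_b, alphabet)
    grid = pa @ subst @ pb.T
    _, ops = global_align_ops(grid, gap_open, gap_extend)
    buf_a: list[list[str]] = [[] for _ in rows_a]
    buf_b: list[list[str]] = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in ("M", "X"):
            for r, row in enumerate(rows_a):
                buf_a[r].append(row[i])
            i += 1
        else:
            for buf in buf_a:
                buf.append("-")
        if op in ("M", "Y"):
            for r, row in enumerate(rows_b):
                buf_b[r].append(row[j])
            j += 1
        else:
            for buf in buf_b:
                buf.append("-")
    return ["".join(x) for x in buf_a], ["".join(x) for x in buf_b]


def progressive_msa(
    seqs: SequenceSet,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Progressive alignment following a UPGMA guide tree."""
    n = len(seqs)
    if n == 0:
        raise ValueError("no sequences to align")
    if n == 1:
        rec = seqs[0]
        return MultipleAlignment(ids=[rec.id], rows=[rec.seq])
    alphabet, subst = load_matrix(matrix)
    sequences = [seqs[i].seq for i in range(n)]
    if n == 2:
        rows_a, rows_b = _merge(
            [sequences[0]], [sequences[1]], alphabet, subst, gap_open, gap_extend
        )
        return MultipleAlignment(ids=list(seqs.ids), rows=rows_a + rows_b)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _kmer_distance(sequences[i], sequences[j])
    Z = linkage(squareform(dmat, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        ids_a, rows_a = clusters.pop(ia)
        ids_b, rows_b = clusters.pop(ib)
        merged_a, merged_b = _merge(
            rows_a, rows_b, alphabet, subst, gap_open, gap_extend
        )
        clusters[n + step] = (ids_a + ids_b, merged_a + merged_b)
    (_, (order, rows)), = clusters.items()
    # restore input order
    id_list = seqs.ids
    paired = sorted(zip(order, rows))
    return MultipleAlignment(
        ids=[id_list[i] for i, _ in paired], rows=[r for _, r in paired]
    )


def read_alignment_fasta(path) -> MultipleAlignment:
    """Load an externally computed alignment (gapped FASTA)."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"{path}: empty alignment file")
    return MultipleAlignment(ids=ids, rows=rows)
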