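"""Promoter extraction and cis-acting element scanning.

Elements are named IUPAC-degenerate motifs (W-box, ABRE, MBS, …) scanned on
both strands of a fixed-length upstream region (default 1,500 bp). The
library ships as an editable TSV (name, IUPAC pattern, functional class);
it uses literature-standard cores, so hit lists are format-compatible with
database scanners rather than value-identical to any particular one.
"""

from __future__ import annotations

import importlib.resources
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .records import GeneLocus, NucleotideRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

FUNCTIONAL_CLASSES = (
    "stress", "hormone", "light", "development", "promoter-core", "unknown"
)


@dataclass(frozen=True)
class CisElement:
    name: str
    iupac_pattern: str
    functional_class: str

    def __post_init__(self) -> None:
        bad = set(self.iupac_pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"element {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"element {self.name!r}: unknown class {self.functional_class!r}"
            )

    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(IUPAC[c] for c in self.iupac_pattern.upper())
        )


@dataclass(frozen=True)
class CisHit:
    element: str
    gene_id: str
    position: int  # 1-based on the extracted promoter, 5'->3' of the gene
    strand: str  # + | -
    matched: str


def load_element_library(path: str | Path | None = None) -> list[CisElement]:
    """Element library from TSV (name, iupac, class); default ships with
    the package."""
    if path is None:
        path = importlib.resources.files("wrkycensus.data") / "cis_elements.tsv"
    df = pd.read_csv(str(path), sep="\t")
    elements = [
        CisElement(r.name, r.iupac, r.functional_class)
        for r in df.itertuples(index=False)
    ]
    names = [e.name for e in elements]
    if len(set(names)) != len(names):
        raise ValueError("duplicate element names in library")
    return elements


def extract_promoter(
    chrom_seq: NucleotideRecord,
    locus: GeneLocus,
    length_bp: int = 1500,
    strand: str = "+",
) -> NucleotideRecord:
    """The ``length_bp`` bases immediately upstream of the gene.

    Plus strand: bases ending just before ``start``. Minus strand: reverse
    complement of the bases beginning just after ``end``. Truncated with a
    warning at chromosome edges.
    """
    if length_bp < 1:
        raise ValueError("promoter length must be >= 1")
    n = len(chrom_seq.seq)
    if locus.start > n or locus.end > n:
        raise ValueError(
            f"{locus.gene_id}: locus {locus.start}-{locus.end} outside "
            f"sequence of length {n}"
        )
    if strand == "+":
        end0 = locus.start - 1  # exclusive, 0-based
        start0 = max(0, end0 - length_bp)
        segment = chrom_seq.seq[start0:end0]
    elif strand == "-":
        start0 = locus.end  # 0-based inclusive
        segment = chrom_seq.seq[start0 : start0 + length_bp]
        segment = str(Seq(segment).reverse_complement())
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if len(segment) < length_bp:
        warnings.warn(
            f"{locus.gene_id}: promoter truncated to {len(segment)} bp at "
            "chromosome edge"
        )
    if not segment:
        raise ValueError(f"{locus.gene_id}: no upstream sequence available")
    return NucleotideRecord(id=f"{locus.gene_id}_promoter", seq=segment)


def scan_elements(
    promoter: NucleotideRecord, library: list[CisElement]
) -> list[CisHit]:
    """All matches of all elements on both strands, overlaps included.

    Positions are 1-based on the promoter as given (5'->3' of the gene's
    strand); minus-strand hits report the position of the match's leftmost
    base on that coordinate system. Ordering is (position, name, strand).
    """
    if not library:
        raise ValueError("element library is empty")
    seq = promoter.seq
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)
    gene_id = promoter.id.removesuffix("_promoter")
    hits = []
    for element in library:
        rx = element.regex()
        width = len(element.iupac_pattern)
        for i in range(L - width + 1):
            if rx.match(seq, i) and rx.match(seq, i).start() == i:
                hits.append(
                    CisHit(element.name, gene_id, i + 1, "+", seq[i : i + width])
                )
            m = rx.match(rc, i)
            if m and m.start() == i:
                # map the rc match back to plus-strand coordinates
                pos = L - (i + width) + 1
                hits.append(
                    CisHit(element.name, gene_id, pos, "-", rc[i : i + width])
                )
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def element_summary(
    hits: list[CisHit], genes: list[str], library: list[CisElement]
) -> tuple[pd.DataFrame, pd.Series]:
    """(per-gene x per-element count matrix, per-element gene presence counts)."""
    names = [e.name for e in library]
    counts = pd.DataFrame(0, index=list(genes), columns=names)
    for h in hits:
        if h.gene_id in counts.index:
            counts.loc[h.gene_id, h.element] += 1
    presence = (counts > 0).sum(axis=0)
    return counts, presence
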