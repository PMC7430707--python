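"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing is delegated to Biopython; the census table, gene loci and Ct
tables travel as plain TSV so every artifact is diffable text.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .records import (
    CENSUS_COLUMNS,
    CensusRow,
    CensusTable,
    GeneLocus,
    NucleotideRecord,
    ProteinRecord,
    SequenceSet,
)


def read_fasta(path: str | Path, alphabet: str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequence lines are concatenated, whitespace-stripped and upper-cased;
    the record id is the first whitespace-delimited token of the header.
    Empty files, duplicate ids and alphabet violations raise ``ValueError``.
    """
    path = Path(path)
    cls = ProteinRecord if alphabet == "protein" else NucleotideRecord
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        records.append(cls(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    return SequenceSet(records, alphabet)


def write_fasta(seqs: Iterable, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_census(table: CensusTable, path: str | Path) -> None:
    """Write the census as TSV with a fixed column order.

    Deterministic: identical tables yield byte-identical files. pI and MW
    are printed to two decimals, the census convention.
    """
    table.validate()
    with open(path, "w") as fh:
        fh.write("\t".join(CENSUS_COLUMNS) + "\n")
        for row in table:
            fields = []
            for col in CENSUS_COLUMNS:
                value = getattr(row, col)
                if col in ("pi", "mw_kda"):
                    fields.append(f"{value:.2f}")
                else:
                    fields.append(str(value))
            fh.write("\t".join(fields) + "\n")


def read_census(path: str | Path) -> CensusTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing census columns {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            CensusRow(
                gene_name=rec.gene_name,
                locus_id=rec.locus_id,
                chromosome=rec.chromosome,
                start=int(rec.start),
                end=int(rec.end),
                pi=float(rec.pi),
                mw_kda=float(rec.mw_kda),
                heptapeptide=rec.heptapeptide,
                zinc_finger=rec.zinc_finger,
                domain_count=int(rec.domain_count),
                group=rec.group,
                length_aa=int(rec.length_aa),
            )
        )
    table = CensusTable(rows)
    table.validate()
    return table


def load_reference_census() -> CensusTable:
    """The published 94-gene sorghum WRKY census shipped with the package."""
    path = importlib.resources.files("wrkycensus.data") / "sorghum_wrky_census.tsv"
    return read_census(str(path))


def loci_from_census(table: CensusTable) -> list[GeneLocus]:
    return [
        GeneLocus(r.gene_name, r.chromosome, r.start, r.end) for r in table
    ]


def read_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from TSV with columns gene_id, chromosome, start, end."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GeneLocus(r.gene_id, r.chromosome, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_loci(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\n")
        for loc in loci:
            fh.write(f"{loc.gene_id}\t{loc.chromosome}\t{loc.start}\t{loc.end}\n")


def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylogenetic tree (with optional supports) to Newick."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_gff3(structures: Iterable, path: str | Path, source: str = "wrkycensus") -> None:
    """Write inferred gene structures as GFF3 exon features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for st in structures:
            for i, (start, end) in enumerate(st.exons, start=1):
                fh.write(
                    f"{st.gene_id}\t{source}\texon\t{start}\t{end}\t.\t+\t.\t"
                    f"ID=exon:{st.gene_id}.{i};Parent={st.gene_id}\n"
                )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format qPCR table: gene, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return df
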