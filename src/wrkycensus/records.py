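"""Core record types shared by every pipeline stage.

Coordinates are 1-based inclusive throughout the package; conversion to
half-open 0-based intervals happens only at format boundaries (GFF3 writer,
python slicing inside readers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
NUCLEOTIDES = set("ACGT")
NUCLEOTIDE_ALPHABET = NUCLEOTIDES | {"N"}

# "II" marks a subgroup-undetermined group II call (no reference panel)
GROUP_LABELS = ("I", "II", "IIa", "IIb", "IIc", "IId", "IIe", "III", "NG")

CENSUS_COLUMNS = [
    "gene_name",
    "locus_id",
    "chromosome",
    "start",
    "end",
    "pi",
    "mw_kda",
    "heptapeptide",
    "zinc_finger",
    "domain_count",
    "group",
    "length_aa",
]


@dataclass(frozen=True)
class SeqRecordBase:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord(SeqRecordBase):
    """A named amino-acid sequence (20 canonical letters plus X)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        bad = sorted(set(self.seq) - PROTEIN_ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-amino-acid characters {''.join(bad)!r}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NucleotideRecord(SeqRecordBase):
    def __post_init__(self) -> None:
        super().__post_init__()
        bad = sorted(set(self.seq) - NUCLEOTIDE_ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-nucleotide characters {''.join(bad)!r}"
            )


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal span of a gene, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: chromosome label must be non-empty")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) precedes start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class SequenceSet:
    """Ordered collection of records sharing one alphabet, with unique ids."""

    def __init__(self, records: Iterable[SeqRecordBase], alphabet: str) -> None:
        if alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {alphabet!r}")
        self.alphabet = alphabet
        self._records: list[SeqRecordBase] = []
        self._index: dict[str, int] = {}
        expected = ProteinRecord if alphabet == "protein" else NucleotideRecord
        for rec in records:
            if not isinstance(rec, expected):
                raise TypeError(
                    f"record {rec.id!r} is {type(rec).__name__}, expected "
                    f"{expected.__name__} for alphabet {alphabet!r}"
                )
            if rec.id in self._index:
                raise ValueError(f"duplicate record id {rec.id!r}")
            self._index[rec.id] = len(self._records)
            self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SeqRecordBase]:
        return iter(self._records)

    def __getitem__(self, key: str | int) -> SeqRecordBase:
        if isinstance(key, int):
            return self._records[key]
        return self._records[self._index[key]]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]


@dataclass
class CensusRow:
    """One gene's line of the family census table."""

    gene_name: str
    locus_id: str
    chromosome: str
    start: int
    end: int
    pi: float
    mw_kda: float
    heptapeptide: str
    zinc_finger: str
    domain_count: int
    group: str
    length_aa: int

    def validate(self) -> None:
        for fieldname in CENSUS_COLUMNS:
            value = getattr(self, fieldname)
            if value is None or value == "":
                raise ValueError(
                    f"census row {self.gene_name!r}: missing field {fieldname!r}"
                )
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"census row {self.gene_name!r}: invalid group {self.group!r}"
            )
        if self.zinc_finger not in ("C2H2", "C2HC", "mixed"):
            raise ValueError(
                f"census row {self.gene_name!r}: invalid zinc finger "
                f"{self.zinc_finger!r}"
            )


@dataclass
class CensusTable:
    rows: list[CensusRow] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            row.validate()
            if row.gene_name in seen:
                raise ValueError(f"duplicate census gene {row.gene_name!r}")
            seen.add(row.gene_name)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[CensusRow]:
        return iter(self.rows)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows], columns=CENSUS_COLUMNS)
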