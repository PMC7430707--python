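"""Ground-truthed synthetic WRKY families.

The generator emulates the statistical structure a family census assumes:
subgroup ancestors with the correct domain architecture (two C2H2 domains
for group I, one C2H2 for IIa–IIe, one C2HC for III), per-gene divergence
that never touches pattern-critical residues unless a heptapeptide variant
is explicitly drawn, GT…AG introns, tandem duplicate pairs inside 100-kbp
windows, promoters with planted IUPAC elements, and Ct tables realizing
known fold changes.

Non-critical sites (ancestral filler and substitutions) are drawn from a
reduced amino-acid alphabet that excludes every motif-defining residue, so
the only heptapeptides and zinc fingers in any generated protein are the
planted ones; motif ground truth is therefore exact, not merely probable. Real
proteomes are messier — see the methods note for what this does and does
not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GeneLocus, NucleotideRecord, ProteinRecord, SequenceSet

#: residues that can never create or destroy a heptapeptide (canonical or
#: any named variant) or a zinc finger: W/R/K/Y/G/Q/E/S (motif letters) and
#: C/H (finger anchors) are excluded
FILLER_AA = "ADFILMNPTV"

SUBGROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: published group sizes of the sorghum family (of 94), used as default
#: generation frequencies
DEFAULT_GROUP_COUNTS = {
    "I": 11, "IIa": 4, "IIb": 8, "IIc": 20, "IId": 6, "IIe": 12, "III": 31,
}

#: published heptapeptide variant tallies (13 variant carriers of 94)
DEFAULT_VARIANT_COUNTS = {
    "WRKYGEK": 6, "WRKYGKK": 5, "WRKYGSK": 1, "WRKSGQR": 1,
}

#: published intron-count histogram (0..7 introns)
DEFAULT_INTRON_COUNTS = {0: 4, 1: 10, 2: 58, 3: 8, 4: 8, 5: 5, 7: 1}

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass
class FamilyConfig:
    seed: int
    n_genes: int = 94
    group_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    variant_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_COUNTS)
    )
    intron_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_INTRON_COUNTS)
    )
    divergence: float = 0.1  # substitutions per non-critical site
    tandem_pairs: int = 2
    tandem_divergence: float = 0.15  # tandem paralogs: similar, not isoforms
    n_chromosomes: int = 10
    gene_spacing_bp: int = 250_000  # beyond the 100-kbp tandem window
    tandem_gap_bp: int = 20_000
    n_references_per_subgroup: int = 3
    reference_divergence: float = 0.05
    promoter_length: int = 1500
    planted_elements: dict = field(
        default_factory=lambda: {"W-box": 2, "ABRE": 1}
    )
    expression_conditions: tuple = ("0h", "3h", "6h", "12h", "24h")
    expression_replicates: int = 3
    ct_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.tandem_pairs * 2 > self.n_genes:
            raise ValueError("more tandem genes than genes")
        if set(self.group_counts) - set(SUBGROUPS):
            raise ValueError("unknown subgroup in group_counts")


@dataclass
class GroundTruth:
    group: dict[str, str] = field(default_factory=dict)
    heptapeptide: dict[str, str] = field(default_factory=dict)
    domain_count: dict[str, int] = field(default_factory=dict)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    promoter_elements: dict[str, list[tuple[str, int]]] = field(
        default_factory=dict
    )
    expression_folds: pd.DataFrame | None = None
    excluded: set[str] = field(default_factory=set)


@dataclass
class SyntheticFamily:
    config: FamilyConfig
    proteins: SequenceSet
    cds: SequenceSet
    genomic: SequenceSet
    loci: list[GeneLocus]
    references: SequenceSet
    reference_labels: dict[str, str]
    promoters: SequenceSet
    ct_table: pd.DataFrame
    truth: GroundTruth


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(
        FILLER_AA[i] for i in rng.integers(0, len(FILLER_AA), size=n)
    )


def _domain(rng: np.random.Generator, finger: str, linker_len: int = 10) -> str:
    hepta = "WRKYGQK"
    link = _filler(rng, linker_len)
    if finger == "C2H2":
        zf = "C" + _filler(rng, 4) + "C" + _filler(rng, 23) + "H" + _filler(rng, 1) + "H"
    else:
        zf = "C" + _filler(rng, 7) + "C" + _filler(rng, 23) + "H" + _filler(rng, 1) + "C"
    return hepta + link + zf


def _ancestor(rng: np.random.Generator, subgroup: str) -> str:
    nterm = _filler(rng, 30)
    signature = _filler(rng, 30)  # subgroup-specific region
    cterm = _filler(rng, 25)
    if subgroup == "I":
        return (
            nterm + _domain(rng, "C2H2") + signature
            + _domain(rng, "C2H2") + cterm
        )
    finger = "C2HC" if subgroup == "III" else "C2H2"
    return nterm + signature + _domain(rng, finger) + cterm


def _critical_positions(seq: str) -> set[int]:
    """Indices whose residue defines a planted motif: all heptapeptide
    residues plus zinc-finger coordinating residues. With filler drawn
    from FILLER_AA these are exactly the W/R/K/Y/Q, C and H sites."""
    return {i for i, ch in enumerate(seq) if ch not in FILLER_AA}


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    critical = _critical_positions(seq)
    for i in range(len(chars)):
        if i in critical:
            continue
        if rng.random() < rate:
            chars[i] = FILLER_AA[rng.integers(0, len(FILLER_AA))]
    return "".join(chars)


def _apply_variant(seq: str, variant: str) -> str:
    idx = seq.find("WRKYGQK")
    if idx == -1:
        raise AssertionError("no canonical heptapeptide to vary")
    return seq[:idx] + variant + seq[idx + 7 :]


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return (
        "".join(
            CODONS[aa][rng.integers(0, len(CODONS[aa]))] for aa in protein
        )
        + "TAA"
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _insert_introns(
    rng: np.random.Generator, cds: str, n_introns: int
) -> tuple[str, list[tuple[int, int]]]:
    """Insert GT…AG introns; returns (genomic, 1-based exon intervals).

    Insertion points avoid CDS positions starting with G so exact-match
    chaining stops exactly at each exon boundary.
    """
    if n_introns == 0:
        return cds, [(1, len(cds))]
    usable = [
        p
        for p in range(10, len(cds) - 10)
        if cds[p] != "G"
    ]
    points: list[int] = []
    for p in rng.permutation(len(usable)):
        cand = usable[p]
        if all(abs(cand - q) >= 10 for q in points):
            points.append(cand)
            if len(points) == n_introns:
                break
    if len(points) < n_introns:
        raise ValueError("CDS too short for requested intron count")
    points.sort()
    pieces = []
    exons = []
    prev = 0
    gpos = 0
    for cut in points:
        exon_seq = cds[prev:cut]
        pieces.append(exon_seq)
        exons.append((gpos + 1, gpos + len(exon_seq)))
        gpos += len(exon_seq)
        ilen = int(rng.integers(20, 81))
        intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
        pieces.append(intron)
        gpos += len(intron)
        prev = cut
    pieces.append(cds[prev:])
    exons.append((gpos + 1, gpos + len(cds) - prev))
    return "".join(pieces), exons


def _counts_to_assignment(
    rng: np.random.Generator, counts: dict, n: int
) -> list:
    """Expand a count histogram to n draws, scaling proportionally and
    resolving rounding by largest remainder; order is then shuffled."""
    total = sum(counts.values())
    keys = sorted(counts, key=str)
    exact = {k: counts[k] * n / total for k in keys}
    base = {k: int(exact[k]) for k in keys}
    short = n - sum(base.values())
    for k in sorted(keys, key=lambda k: -(exact[k] - base[k]))[:short]:
        base[k] += 1
    out = [k for k in keys for _ in range(base[k])]
    rng.shuffle(out)
    return out


def generate_family(config: FamilyConfig) -> SyntheticFamily:
    rng = np.random.default_rng(config.seed)
    ancestors = {sg: _ancestor(rng, sg) for sg in SUBGROUPS}

    # reference panel
    ref_records, ref_labels = [], {}
    for sg in SUBGROUPS:
        for i in range(config.n_references_per_subgroup):
            rid = f"REF_{sg}_{i + 1}"
            ref_records.append(
                ProteinRecord(
                    rid,
                    _mutate(rng, ancestors[sg], config.reference_divergence),
                )
            )
            ref_labels[rid] = sg

    # per-gene subgroup, variant and intron assignments
    n = config.n_genes
    n_primary = n - config.tandem_pairs
    groups = _counts_to_assignment(rng, config.group_counts, n_primary)
    n_variant = round(
        n * sum(config.variant_counts.values()) / 94
    )
    variant_pool = _counts_to_assignment(
        rng, config.variant_counts, min(n_variant, n_primary)
    ) + [None] * (n_primary - min(n_variant, n_primary))
    variants = variant_pool[:n_primary]
    rng.shuffle(variants)
    intron_assign = _counts_to_assignment(rng, config.intron_counts, n)

    proteins: list[ProteinRecord] = []
    truth = GroundTruth()
    gene_group: list[str] = []
    for idx in range(n_primary):
        sg = groups[idx]
        seq = _mutate(rng, ancestors[sg], config.divergence)
        hepta = "WRKYGQK"
        if variants[idx] is not None:
            seq = _apply_variant(seq, variants[idx])
            hepta = variants[idx]
        gid = f"GENE{idx + 1:03d}"
        proteins.append(ProteinRecord(gid, seq))
        gene_group.append(sg)
        truth.group[gid] = sg
        truth.heptapeptide[gid] = hepta
        truth.domain_count[gid] = 2 if sg == "I" else 1

    # tandem duplicates: near-copies of chosen primaries, placed adjacent
    donor_idx = list(
        rng.choice(n_primary, size=config.tandem_pairs, replace=False)
    )
    for t, di in enumerate(donor_idx):
        donor = proteins[di]
        gid = f"GENE{n_primary + t + 1:03d}"
        seq = _mutate(rng, donor.seq, config.tandem_divergence)
        proteins.append(ProteinRecord(gid, seq))
        sg = gene_group[di]
        gene_group.append(sg)
        truth.group[gid] = sg
        truth.heptapeptide[gid] = truth.heptapeptide[donor.id]
        truth.domain_count[gid] = truth.domain_count[donor.id]
        truth.tandem_pairs.append((donor.id, gid))

    # CDS, introns, genomic
    cds_records, genomic_records = [], []
    for rec, n_introns in zip(proteins, intron_assign):
        cds = _reverse_translate(rng, rec.seq)
        genomic, exons = _insert_introns(rng, cds, n_introns)
        cds_records.append(NucleotideRecord(rec.id, cds))
        genomic_records.append(NucleotideRecord(rec.id, genomic))
        truth.exons[rec.id] = exons

    # chromosome placement; tandem partners are placed next to their donor
    tandem_partner = {a: b for a, b in truth.tandem_pairs}
    partner_ids = set(tandem_partner.values())
    glen = {r.id: len(r.seq) for r in genomic_records}
    loci: list[GeneLocus] = []
    placement = [r.id for r in proteins if r.id not in partner_ids]
    positions: dict[str, tuple[str, int]] = {}
    per_chrom = -(-len(placement) // config.n_chromosomes)
    for i, gid in enumerate(placement):
        chrom = f"Chr{i // per_chrom + 1:02d}"
        slot = i % per_chrom
        start = 50_000 + slot * config.gene_spacing_bp
        positions[gid] = (chrom, start)
    for donor_id, partner_id in truth.tandem_pairs:
        chrom, start = positions[donor_id]
        positions[partner_id] = (
            chrom, start + glen[donor_id] + config.tandem_gap_bp
        )
    for gid in sorted(positions, key=lambda g: (positions[g], g)):
        chrom, start = positions[gid]
        loci.append(GeneLocus(gid, chrom, start, start + glen[gid] - 1))

    # promoters with planted elements
    from .promoter import load_element_library

    library = {e.name: e for e in load_element_library()}
    promoter_records = []
    for rec in proteins:
        seq = list(_random_dna(rng, config.promoter_length))
        planted: list[tuple[str, int]] = []
        cursor = 7
        for name, count in sorted(config.planted_elements.items()):
            element = library[name]
            width = len(element.iupac_pattern)
            from .promoter import IUPAC

            choices = [
                IUPAC[c].strip("[]") for c in element.iupac_pattern.upper()
            ]
            concrete = "".join(
                opts[rng.integers(0, len(opts))] for opts in choices
            )
            for _ in range(count):
                pos = cursor
                seq[pos : pos + width] = concrete
                planted.append((name, pos + 1))
                cursor += width + 40
        promoter_records.append(
            NucleotideRecord(f"{rec.id}_promoter", "".join(seq))
        )
        truth.promoter_elements[rec.id] = planted

    # Ct table realizing known folds
    conditions = list(config.expression_conditions)
    calibrator = conditions[0]
    tested = [r.id for r in proteins[: min(5, len(proteins))]]
    fold_rows = {}
    ct_rows = []
    ref_ct = 20.0
    for gid in tested:
        base_dct = float(rng.uniform(2.0, 6.0))
        folds = {calibrator: 1.0}
        for cond in conditions[1:]:
            folds[cond] = float(2.0 ** rng.uniform(-2.0, 6.5))
        fold_rows[gid] = folds
        for cond in conditions:
            dct = base_dct - np.log2(folds[cond])
            for rep in range(1, config.expression_replicates + 1):
                noise = (
                    rng.normal(0.0, config.ct_noise_sd)
                    if config.ct_noise_sd > 0
                    else 0.0
                )
                ct_rows.append(
                    {
                        "gene": gid, "condition": cond, "replicate": rep,
                        "ct": ref_ct + dct + noise,
                    }
                )
            ct_rows.extend(
                {
                    "gene": "GAPDH", "condition": cond, "replicate": rep,
                    "ct": ref_ct,
                }
                for rep in range(1, config.expression_replicates + 1)
                if gid == tested[0]
            )
    truth.expression_folds = pd.DataFrame(fold_rows).T[conditions]

    return SyntheticFamily(
        config=config,
        proteins=SequenceSet(proteins, "protein"),
        cds=SequenceSet(cds_records, "nucleotide"),
        genomic=SequenceSet(genomic_records, "nucleotide"),
        loci=loci,
        references=SequenceSet(ref_records, "protein"),
        reference_labels=ref_labels,
        promoters=SequenceSet(promoter_records, "nucleotide"),
        ct_table=pd.DataFrame(ct_rows),
        truth=truth,
    )


def corrupt(
    family: SyntheticFamily, ops: list[tuple[str, str]], seed: int = 0
) -> SyntheticFamily:
    """Negative controls: degrade targeted genes so they fail inclusion.

    ops are (operation, gene_id) with operation one of break-heptapeptide
    (W -> A), delete-zinc-finger (coordinating Cys -> A) or
    shuffle-sequence. Ground truth marks the gene excluded.
    """
    import copy
    import re as _re

    rng = np.random.default_rng(seed)
    new = copy.deepcopy(family)
    records = {r.id: r for r in new.proteins}
    for op, gid in ops:
        rec = records[gid]
        seq = rec.seq
        if op == "break-heptapeptide":
            seq = _re.sub(r"WRK[A-Z]{4}", lambda m: "A" + m.group(0)[1:], seq)
        elif op == "delete-zinc-finger":
            seq = seq.replace("C", "A")
        elif op == "shuffle-sequence":
            chars = list(seq)
            rng.shuffle(chars)
            seq = "".join(chars)
        else:
            raise ValueError(f"unknown corruption op {op!r}")
        records[gid] = ProteinRecord(gid, seq)
        new.truth.excluded.add(gid)
    new.proteins = SequenceSet(
        [records[r.id] for r in family.proteins], "protein"
    )
    return new


def write_family(family: SyntheticFamily, outdir: str | Path) -> None:
    """Emit the family as plain-text artifacts (FASTA/TSV), deterministically."""
    from .io import write_fasta, write_loci

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(family.proteins, outdir / "proteins.faa")
    write_fasta(family.cds, outdir / "cds.fna")
    write_fasta(family.genomic, outdir / "genomic.fna")
    write_fasta(family.references, outdir / "references.faa")
    write_fasta(family.promoters, outdir / "promoters.fna")
    write_loci(family.loci, outdir / "loci.tsv")
    with open(outdir / "reference_labels.tsv", "w") as fh:
        fh.write("id\tsubgroup\n")
        for rid, sg in family.reference_labels.items():
            fh.write(f"{rid}\t{sg}\n")
    family.ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    with open(outdir / "truth_groups.tsv", "w") as fh:
        fh.write("gene_id\tgroup\theptapeptide\tdomain_count\n")
        for gid in sorted(family.truth.group):
            fh.write(
                f"{gid}\t{family.truth.group[gid]}\t"
                f"{family.truth.heptapeptide[gid]}\t"
                f"{family.truth.domain_count[gid]}\n"
            )
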