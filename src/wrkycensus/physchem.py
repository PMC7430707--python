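"""Predicted molecular weight and isoelectric point.

MW follows the ExPASy convention: average (not monoisotopic) residue masses
plus one water, via Biopython's mass tables. pI is the pH at which the net
charge of the termini plus ionizable side chains vanishes, solved by
bisection with a Bjellqvist-style pKa set.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight as _bio_mw

from .records import ProteinRecord

# pKa set (Bjellqvist-style, single value per group).
PKA_NTERM = 9.094
PKA_CTERM = 2.869
PKA_SIDECHAIN_ACID = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDECHAIN_BASE = {"H": 5.98, "K": 10.0, "R": 12.0}


@dataclass(frozen=True)
class PhysChem:
    mw_kda: float
    pi: float


def molecular_weight(protein: ProteinRecord) -> float:
    """Average molecular weight in kDa (residue masses + one water).

    X residues carry zero mass: they denote unknown residues and the
    census convention is to ignore them rather than guess.
    """
    seq = protein.seq.replace("X", "")
    if not seq:
        raise ValueError(f"{protein.id}: no canonical residues for MW")
    daltons = _bio_mw(seq, seq_type="protein", monoisotopic=False)
    return daltons / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Net protein charge at the given pH (Henderson–Hasselbalch per group)."""
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    neg = 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa, pka in PKA_SIDECHAIN_BASE.items():
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_SIDECHAIN_ACID.items():
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka - ph))
    return pos - neg


def isoelectric_point(protein: ProteinRecord, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique; bisection runs until |charge| < tol.
    """
    seq = protein.seq
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(seq, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def physchem(protein: ProteinRecord) -> PhysChem:
    return PhysChem(
        mw_kda=molecular_weight(protein), pi=isoelectric_point(protein)
    )
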