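"""WRKY domain feature detection.

The family's signature is a ~60-residue DNA-binding domain: the heptapeptide
WRKYGQK (or a variant) followed downstream by a zinc finger whose last
coordinating residue distinguishes C2H2 (…H-X-H) from C2HC (…H-X-C) fingers.
Group I proteins carry two such domains, groups II/III carry one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records import ProteinRecord, SequenceSet

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"

#: Variants reported across plant WRKY families; a 7-mer equal to one of
#: these is classed by its literal name rather than "other".
NAMED_VARIANTS = ("WRKYGQK", "WRKYGEK", "WRKYGKK", "WRKYGSK", "WRKSGQR")

#: Generalized zinc-finger layout C-X(3..7)-C-X(22..23)-H-X(1)-[H|C], the
#: union of the group-specific spacer dialects. Lazy quantifiers prefer the
#: shortest spacers; X never coordinates zinc so it is excluded from the
#: anchor positions implicitly (patterns match literal C/H only).
_ZF_RE = re.compile(r"C([A-Z]{3,7}?)C([A-Z]{22,23}?)H[A-Z]([HC])")

_HARF_RE = re.compile(r"RTGHARFRR[AG]P")


@dataclass(frozen=True)
class HeptapeptideHit:
    position: int  # 1-based index of the W
    motif: str
    variant_class: str  # the literal motif name, or "other"
    hamming_to_canonical: int

    @property
    def is_canonical(self) -> bool:
        return self.motif == CANONICAL_HEPTAPEPTIDE


@dataclass(frozen=True)
class ZincFingerHit:
    position: int  # 1-based index of the first Cys
    pattern_string: str
    finger_type: str  # C2H2 | C2HC
    spacer_lengths: tuple[int, int]


@dataclass(frozen=True)
class WRKYDomain:
    heptapeptide: HeptapeptideHit
    zinc_finger: ZincFingerHit

    @property
    def span(self) -> tuple[int, int]:
        start = self.heptapeptide.position
        end = self.zinc_finger.position + len(self.zinc_finger.pattern_string) - 1
        return (start, end)

    @property
    def finger_type(self) -> str:
        return self.zinc_finger.finger_type


@dataclass
class ScanConfig:
    max_mismatch: int = 2
    linker_max: int = 50  # residues between heptapeptide end and first Cys


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_heptapeptides(
    protein: ProteinRecord, max_mismatch: int = 2
) -> list[HeptapeptideHit]:
    """All heptapeptide-signature 7-mers, in order of position.

    Admission rule: exact WRK prefix with Hamming distance to WRKYGQK at
    most ``max_mismatch``; additionally, 7-mers with exact WR prefix are
    admitted at Hamming <= 2 (this relaxation covers the WRKSGQR variant
    class without opening the scan to arbitrary W-initial words).
    """
    if not 0 <= max_mismatch <= 2:
        raise ValueError(f"max_mismatch must be in [0, 2], got {max_mismatch}")
    seq = protein.seq
    hits = []
    for i in range(len(seq) - 6):
        word = seq[i : i + 7]
        d = _hamming(word, CANONICAL_HEPTAPEPTIDE)
        admitted = (word.startswith("WRK") and d <= max_mismatch) or (
            word.startswith("WR") and d <= 2 and word in NAMED_VARIANTS
        )
        if not admitted:
            continue
        variant = word if word in NAMED_VARIANTS else "other"
        hits.append(
            HeptapeptideHit(
                position=i + 1,
                motif=word,
                variant_class=variant,
                hamming_to_canonical=d,
            )
        )
    return hits


def find_zinc_fingers(
    protein: ProteinRecord, search_start: int = 1
) -> list[ZincFingerHit]:
    """Zinc-finger motifs from ``search_start`` (1-based), leftmost-first.

    Matches C-X(3..7)-C-X(22..23)-H-X(1)-[H|C]; the final coordinating
    residue sets the finger type. Overlaps resolve leftmost-first, then
    non-overlapping.
    """
    seq = protein.seq
    if not 1 <= search_start <= len(seq):
        raise ValueError(
            f"{protein.id}: search_start {search_start} outside sequence"
        )
    hits = []
    for m in _ZF_RE.finditer(seq, search_start - 1):
        pattern = m.group(0)
        spacer1 = len(m.group(1))
        spacer2 = len(m.group(2))
        finger_type = "C2H2" if m.group(3) == "H" else "C2HC"
        hits.append(
            ZincFingerHit(
                position=m.start() + 1,
                pattern_string=pattern,
                finger_type=finger_type,
                spacer_lengths=(spacer1, spacer2),
            )
        )
    return hits


def scan_domains(
    protein: ProteinRecord, config: ScanConfig | None = None
) -> list[WRKYDomain]:
    """Pair each heptapeptide with the nearest downstream zinc finger.

    A pair forms a domain when the finger's first Cys lies within
    ``config.linker_max`` residues of the heptapeptide's end; each finger
    is consumed by at most one heptapeptide (left to right). Unpaired hits
    on either side are not domains.
    """
    config = config or ScanConfig()
    hepta = find_heptapeptides(protein, config.max_mismatch)
    fingers = find_zinc_fingers(protein)
    domains = []
    used = 0  # fingers are ordered; greedy left-to-right pairing
    for h in hepta:
        hept_end = h.position + 6
        while used < len(fingers) and fingers[used].position <= h.position:
            used += 1
        if used >= len(fingers):
            break
        zf = fingers[used]
        gap = zf.position - hept_end - 1
        if 0 <= gap <= config.linker_max:
            domains.append(WRKYDomain(heptapeptide=h, zinc_finger=zf))
            used += 1
    return domains


def find_harf(protein: ProteinRecord) -> list[int]:
    """1-based start positions of the HARF motif R-T-G-H-A-R-F-R-R-[A|G]-P.

    A conserved signature of WRKY subgroup IId members, function unknown.
    """
    return [m.start() + 1 for m in _HARF_RE.finditer(protein.seq)]


def domain_summary(domains: list[WRKYDomain]) -> tuple[int, str, str]:
    """(domain count, finger-type label, representative heptapeptide).

    The finger label is C2H2/C2HC when all fingers agree and "mixed"
    otherwise; the representative heptapeptide is the first non-canonical
    variant if any (the census prints the variant), else WRKYGQK.
    """
    if not domains:
        return 0, "", ""
    types = {d.finger_type for d in domains}
    label = types.pop() if len(types) == 1 else "mixed"
    hept = next(
        (d.heptapeptide.motif for d in domains if not d.heptapeptide.is_canonical),
        domains[0].heptapeptide.motif,
    )
    return len(domains), label, hept


def dedup_sequences(
    seqs: SequenceSet, identity_threshold: float = 0.95
) -> SequenceSet:
    """Greedy longest-first redundancy removal.

    Records are visited longest-first; a record joins an existing cluster
    when its global-alignment identity (matches / alignment columns) to the
    cluster representative is >= the threshold, else it founds a new
    cluster. Representatives are returned in the original input order.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError(
            f"identity threshold must be in (0.5, 1.0], got {identity_threshold}"
        )
    from .pairwise import global_identity

    order = sorted(range(len(seqs)), key=lambda i: -len(seqs[i]))
    rep_indices: list[int] = []
    for i in order:
        rec = seqs[i]
        for j in rep_indices:
            if global_identity(rec.seq, seqs[j].seq) >= identity_threshold:
                break
        else:
            rep_indices.append(i)
    rep_set = set(rep_indices)
    return SequenceSet(
        [seqs[i] for i in range(len(seqs)) if i in rep_set], seqs.alphabet
    )
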