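"""Group/subgroup assignment and positional gene naming.

Two evidence streams are reconciled per protein: the domain architecture
(how many WRKY domains, which zinc-finger type) and the placement of the
protein in a phylogenetic tree relative to a labeled reference panel
(classically the Arabidopsis WRKYs). Feature rules decide the major group;
the tree decides the subgroup; disagreements resolve toward the tree only
when its local evidence is unanimous, otherwise the gene is NG (no group).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .features import WRKYDomain
from .records import GeneLocus
from .tree import PhyloTree

SUBGROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: zinc-finger type expected for each subgroup label
EXPECTED_FINGER = {
    "I": "C2H2",
    "IIa": "C2H2",
    "IIb": "C2H2",
    "IIc": "C2H2",
    "IId": "C2H2",
    "IIe": "C2H2",
    "III": "C2HC",
}


@dataclass(frozen=True)
class GroupLabel:
    value: str  # I | IIa..IIe | III | II (provisional) | NG
    evidence: str  # feature-based | tree-based | reconciled
    detail: str = ""

    @property
    def major(self) -> str:
        if self.value in ("I", "III", "NG", ""):
            return self.value
        if self.value.startswith("II"):
            return "II"
        return self.value


@dataclass
class ReferencePanel:
    """Labeled reference proteins: id -> subgroup label."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("reference panel must be non-empty")
        bad = {v for v in self.labels.values() if v not in SUBGROUPS}
        if bad:
            raise ValueError(f"invalid reference subgroup labels {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        labels = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("id"):
                raise ValueError(f"{path}: expected header 'id\\tsubgroup'")
            for line in fh:
                if line.strip():
                    ref_id, subgroup = line.split("\t")[:2]
                    labels[ref_id.strip()] = subgroup.strip()
        return cls(labels)


def feature_group(domains: list[WRKYDomain]) -> GroupLabel:
    """Provisional group from domain architecture alone.

    Two domains with C2H2 fingers -> I; one C2H2 domain -> II (subgroup
    undetermined); one C2HC domain -> III; two domains involving a C2HC
    finger -> provisional III (a group I architecture with a group III
    finger leans III, pending tree evidence).
    """
    if not domains:
        raise ValueError("zero WRKY domains: not a family member")
    types = [d.finger_type for d in domains]
    if len(domains) >= 2:
        if all(t == "C2H2" for t in types):
            return GroupLabel("I", "feature-based")
        return GroupLabel("III", "feature-based", detail="two-domain C2HC")
    if types[0] == "C2H2":
        return GroupLabel("II", "feature-based")
    return GroupLabel("III", "feature-based")


def tree_subgroup(
    tree: PhyloTree, panel: ReferencePanel, query_id: str, k: int = 3
) -> GroupLabel:
    """Subgroup of the k nearest labeled reference leaves by path length.

    Majority label wins; ties break by smallest total path length to the
    tied label's neighbors, then lexicographically.
    """
    dists = tree.distances_from(query_id)  # KeyError if absent
    labeled = [
        (d, ref_id) for ref_id, d in dists.items() if ref_id in panel.labels
    ]
    if not labeled:
        raise ValueError("no labeled reference leaves present in the tree")
    labeled.sort()
    nearest = labeled[:k]
    votes: dict[str, list[float]] = {}
    for d, ref_id in nearest:
        votes.setdefault(panel.labels[ref_id], []).append(d)
    best = sorted(
        votes.items(), key=lambda kv: (-len(kv[1]), sum(kv[1]), kv[0])
    )[0][0]
    unanimous = len(votes) == 1
    return GroupLabel(
        best,
        "tree-based",
        detail="unanimous" if unanimous else "mixed",
    )


def reconcile(
    feature: GroupLabel, tree: GroupLabel, finger_type: str | None = None
) -> GroupLabel:
    """Final label from feature and tree evidence.

    Agreement on the major group -> the tree's subgroup. Disagreement with
    a unanimous k-neighborhood -> the tree label (this is how a one-domain
    protein lands in group I, or a two-domain C2HC protein in group III,
    when its clade is clear-cut). Disagreement with mixed neighbors -> NG;
    a finger type contradicting the neighbors' expected type is recorded
    in the trace.
    """
    trace = f"feature={feature.value};tree={tree.value}({tree.detail})"
    if feature.major == tree.major:
        return GroupLabel(tree.value, "reconciled", detail=trace)
    if tree.detail == "unanimous":
        return GroupLabel(tree.value, "reconciled", detail=trace)
    if finger_type and EXPECTED_FINGER.get(tree.value) not in (None, finger_type):
        trace += ";finger-conflict"
    return GroupLabel("NG", "reconciled", detail=trace)


def _chrom_key(chromosome: str) -> tuple:
    """Natural chromosome order: numeric suffix sorts numerically."""
    m = re.match(r"^(\D*)(\d+)$", chromosome)
    if m:
        return (m.group(1).lower(), int(m.group(2)))
    return (chromosome.lower(), -1)


def assign_names(loci: list[GeneLocus], prefix: str = "WRKY") -> dict[str, str]:
    """Positional names: sort by (chromosome natural order, start) and
    number ``prefix``1..N. Duplicate (chromosome, start) pairs tie-break
    by end then gene id, with a warning."""
    seen: dict[tuple, str] = {}
    for loc in loci:
        key = (loc.chromosome, loc.start)
        if key in seen:
            warnings.warn(
                f"duplicate locus position {key} for {seen[key]} and "
                f"{loc.gene_id}; tie-broken by end then id"
            )
        seen[key] = loc.gene_id
    ordered = sorted(
        loci, key=lambda l: (_chrom_key(l.chromosome), l.start, l.end, l.gene_id)
    )
    return {loc.gene_id: f"{prefix}{i}" for i, loc in enumerate(ordered, start=1)}
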