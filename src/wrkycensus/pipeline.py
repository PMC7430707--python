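"""End-to-end census orchestration.

``run_census`` drives the stages in order — redundancy removal, domain
scan, physico-chemical prediction, alignment + NJ tree (+ bootstrap),
classification against a labeled reference panel, positional naming, gene
structure, tandem/cluster detection, promoter scan, expression — skipping
stages whose inputs are absent, and writes every artifact as text under
one output directory.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import features as _features
from . import genestruct as _struct
from . import physchem as _physchem
from .io import write_census, write_gff3, write_newick
from .msa import MultipleAlignment, progressive_msa
from .phylo import bootstrap_supports, neighbor_joining, p_distance_matrix
from .promoter import element_summary, load_element_library, scan_elements
from .records import CensusRow, CensusTable, GeneLocus, SequenceSet
from .tree import PhyloTree

log = logging.getLogger("wrkycensus")


@dataclass
class RunConfig:
    seed: int = 0
    name_prefix: str = "WRKY"
    max_mismatch: int = 2
    linker_max: int = 50
    run_dedup: bool = True
    dedup_identity: float = 0.95
    tandem_window_bp: int = 100_000
    tandem_min_similarity: float = 70.0
    cluster_window_bp: int = 100_000
    promoter_length: int = 1500
    bootstrap_replicates: int = 1000
    run_bootstrap: bool = True
    fold_threshold: float = 2.5
    reference_gene: str = "GAPDH"
    calibrator: str = "0h"
    knn: int = 3


@dataclass
class CensusResult:
    census: CensusTable
    tree: PhyloTree | None = None
    alignment: MultipleAlignment | None = None
    structures: list = field(default_factory=list)
    tandem_pairs: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    promoter_hits: list = field(default_factory=list)
    promoter_counts: pd.DataFrame | None = None
    folds: object | None = None  # qpcr.FoldChangeMatrix
    fold_filtered: list[str] = field(default_factory=list)
    traces: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_census(self.census, outdir / "census.tsv")
        if self.tree is not None:
            write_newick(self.tree, outdir / "tree.nwk")
        if self.structures:
            write_gff3(self.structures, outdir / "structures.gff3")
        with open(outdir / "tandem_pairs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\tgap_bp\tsimilarity\n")
            for p in self.tandem_pairs:
                fh.write(
                    f"{p.gene_a}\t{p.gene_b}\t{p.gap_bp}\t{p.similarity:.2f}\n"
                )
        with open(outdir / "clusters.tsv", "w") as fh:
            fh.write("chromosome\tmembers\tspan_bp\n")
            for c in self.clusters:
                fh.write(
                    f"{c.chromosome}\t{','.join(c.members)}\t{c.span_bp}\n"
                )
        if self.promoter_hits:
            with open(outdir / "promoter_hits.tsv", "w") as fh:
                fh.write("gene_id\telement\tposition\tstrand\tmatched\n")
                for h in sorted(
                    self.promoter_hits,
                    key=lambda h: (h.gene_id, h.position, h.element, h.strand),
                ):
                    fh.write(
                        f"{h.gene_id}\t{h.element}\t{h.position}\t"
                        f"{h.strand}\t{h.matched}\n"
                    )
        if self.folds is not None:
            self.folds.folds.to_csv(outdir / "expression_folds.tsv", sep="\t")
        summary = summarize(self.census, self.structures)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_tree(
    queries: SequenceSet,
    references: SequenceSet | None,
    config: RunConfig,
) -> tuple[MultipleAlignment, PhyloTree]:
    """Alignment and NJ tree over queries plus any reference panel."""
    records = [queries[i] for i in range(len(queries))]
    if references is not None:
        records += [references[i] for i in range(len(references))]
    combined = SequenceSet(records, "protein")
    aln = progressive_msa(combined)
    if config.run_bootstrap:
        tree = bootstrap_supports(
            aln, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
    else:
        tree = neighbor_joining(p_distance_matrix(aln))
    return aln, tree


def run_census(
    proteins: SequenceSet,
    loci: list[GeneLocus] | None = None,
    cds: SequenceSet | None = None,
    genomic: SequenceSet | None = None,
    references: SequenceSet | None = None,
    reference_labels: dict[str, str] | None = None,
    promoters: SequenceSet | None = None,
    ct_table: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> CensusResult:
    config = config or RunConfig()
    result = CensusResult(census=CensusTable())
    scan_cfg = _features.ScanConfig(
        max_mismatch=config.max_mismatch, linker_max=config.linker_max
    )

    # 1. redundancy removal, then the inclusion criterion (>=1 full domain)
    if config.run_dedup:
        proteins = _features.dedup_sequences(proteins, config.dedup_identity)
    domains_by_gene = {}
    kept = []
    for rec in proteins:
        doms = _features.scan_domains(rec, scan_cfg)
        if not doms:
            log.warning("%s: no complete WRKY domain; excluded", rec.id)
            result.excluded.append(rec.id)
            continue
        domains_by_gene[rec.id] = doms
        kept.append(rec)
    proteins = SequenceSet(kept, "protein")

    # 2. tree + classification
    tree = None
    panel = None
    if references is not None and reference_labels:
        panel = _classify.ReferencePanel(reference_labels)
        result.alignment, tree = build_tree(proteins, references, config)
        result.tree = tree

    labels: dict[str, str] = {}
    for rec in proteins:
        feat = _classify.feature_group(domains_by_gene[rec.id])
        if tree is not None and panel is not None:
            tre = _classify.tree_subgroup(tree, panel, rec.id, k=config.knn)
            _, finger, _ = _features.domain_summary(domains_by_gene[rec.id])
            final = _classify.reconcile(feat, tre, finger_type=finger)
        else:
            final = feat
        labels[rec.id] = final.value
        result.traces[rec.id] = final.detail

    # 3. positional naming
    if loci is not None:
        loci = [l for l in loci if l.gene_id in proteins]
        names = _classify.assign_names(loci, prefix=config.name_prefix)
        loci_by_gene = {l.gene_id: l for l in loci}
    else:
        names = {rec.id: rec.id for rec in proteins}
        loci_by_gene = {}

    # 4. census rows (ordered by assigned name where loci exist)
    def name_rank(gid: str) -> tuple:
        n = names.get(gid, gid)
        digits = "".join(ch for ch in n if ch.isdigit())
        return (int(digits) if digits else 0, n)

    for gid in sorted((r.id for r in proteins), key=name_rank):
        rec = proteins[gid]
        doms = domains_by_gene[gid]
        count, finger, hepta = _features.domain_summary(doms)
        pc = _physchem.physchem(rec)
        loc = loci_by_gene.get(gid)
        result.census.rows.append(
            CensusRow(
                gene_name=names.get(gid, gid),
                locus_id=gid,
                chromosome=loc.chromosome if loc else "NA",
                start=loc.start if loc else 1,
                end=loc.end if loc else rec.length_aa,
                pi=round(pc.pi, 2),
                mw_kda=round(pc.mw_kda, 2),
                heptapeptide=hepta,
                zinc_finger=finger,
                domain_count=count,
                group=labels[gid],
                length_aa=rec.length_aa,
            )
        )

    # 5. gene structure
    if cds is not None and genomic is not None:
        for rec in proteins:
            if rec.id in cds and rec.id in genomic:
                result.structures.append(
                    _struct.infer_structure(genomic[rec.id], cds[rec.id])
                )

    # 6. tandem duplications and clusters
    if loci:
        result.tandem_pairs = _struct.detect_tandem(
            loci,
            proteins,
            window_bp=config.tandem_window_bp,
            min_similarity=config.tandem_min_similarity,
        )
        result.clusters = _struct.find_clusters(
            loci, chain_window_bp=config.cluster_window_bp
        )

    # 7. promoter scan
    if promoters is not None:
        library = load_element_library()
        hits = []
        for rec in promoters:
            hits.extend(scan_elements(rec, library))
        result.promoter_hits = hits
        genes = [r.id.removesuffix("_promoter") for r in promoters]
        result.promoter_counts, _ = element_summary(hits, genes, library)

    # 8. expression
    if ct_table is not None:
        from .qpcr import delta_delta_ct, fold_filter

        result.folds = delta_delta_ct(
            ct_table, config.reference_gene, config.calibrator
        )
        result.fold_filtered = fold_filter(result.folds, config.fold_threshold)

    return result


def summarize(census: CensusTable, structures: list | None = None) -> dict:
    """In-text census statistics: group/subgroup sizes, heptapeptide
    tallies, per-chromosome counts, intron histogram, length/pI/MW stats."""
    if not census.rows:
        warnings.warn("empty census; emitting empty summary")
        return {"n_genes": 0}
    df = census.to_dataframe()
    n = len(df)
    major = df["group"].map(
        lambda g: "II" if (g.startswith("II") and g != "III") else g
    )
    group_sizes = major.value_counts().to_dict()
    out = {
        "n_genes": int(n),
        "group_sizes": {k: int(v) for k, v in sorted(group_sizes.items())},
        "group_percent": {
            k: round(100.0 * v / n, 1) for k, v in sorted(group_sizes.items())
        },
        "subgroup_sizes": {
            k: int(v)
            for k, v in sorted(df["group"].value_counts().to_dict().items())
        },
        "heptapeptide_tallies": {
            k: int(v)
            for k, v in sorted(
                df["heptapeptide"].value_counts().to_dict().items()
            )
        },
        "per_chromosome": {
            k: int(v)
            for k, v in sorted(df["chromosome"].value_counts().to_dict().items())
        },
        "two_domain_genes": int((df["domain_count"] >= 2).sum()),
        "length_aa": {
            "min": int(df["length_aa"].min()),
            "max": int(df["length_aa"].max()),
            "mean": round(float(df["length_aa"].mean()), 1),
        },
        "pi": {
            "min": round(float(df["pi"].min()), 2),
            "max": round(float(df["pi"].max()), 2),
        },
        "mw_kda": {
            "min": round(float(df["mw_kda"].min()), 2),
            "max": round(float(df["mw_kda"].max()), 2),
        },
    }
    if structures:
        intron_counts = pd.Series([s.intron_count for s in structures])
        out["intron_histogram"] = {
            str(k): int(v)
            for k, v in sorted(intron_counts.value_counts().to_dict().items())
        }
        out["intronless_genes"] = int((intron_counts == 0).sum())
        out["three_exon_genes"] = int((intron_counts == 2).sum())
    return out
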