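"""Relative expression by the 2^-ddCt method, fold filtering, and
hierarchical clustering of expression matrices.

dCt = Ct(target) - Ct(reference) per replicate; ddCt subtracts the mean
calibrator dCt of the same gene; relative expression is 2^-ddCt, assuming
100% amplification efficiency. Replicates are exponentiated first and then
averaged (mean of folds, with standard error); the alternative
(exponentiate the replicate-mean ddCt) is available via ``aggregate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class FoldChangeMatrix:
    folds: pd.DataFrame  # genes x conditions, calibrator column == 1
    stderr: pd.DataFrame
    calibrator: str


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator: str,
    aggregate: str = "mean-of-folds",
) -> FoldChangeMatrix:
    """Fold-change matrix from a long-format Ct table.

    ``ct`` columns: gene, condition, replicate, ct. The reference gene
    must be measured in every condition/replicate that targets are; the
    calibrator condition (e.g. the 0 h sample) must be present.
    """
    if aggregate not in ("mean-of-folds", "fold-of-means"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    conditions = sorted(ct["condition"].unique(), key=str)
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} absent")
    ref = ct[ct["gene"] == reference_gene]
    missing = set(conditions) - set(ref["condition"])
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in conditions "
            f"{sorted(missing, key=str)}"
        )
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]
    genes = [g for g in ct["gene"].unique() if g != reference_gene]
    folds = pd.DataFrame(index=genes, columns=conditions, dtype=float)
    err = pd.DataFrame(index=genes, columns=conditions, dtype=float)
    for gene in genes:
        sub = ct[ct["gene"] == gene]
        dct = {}
        for row in sub.itertuples(index=False):
            key = (row.condition, row.replicate)
            if key not in ref_ct.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} not measured for "
                    f"condition {row.condition!r} replicate {row.replicate!r}"
                )
            dct.setdefault(row.condition, []).append(row.ct - ref_ct[key])
        if calibrator not in dct:
            raise ValueError(f"gene {gene!r} lacks the calibrator condition")
        base = float(np.mean(dct[calibrator]))
        for cond, values in dct.items():
            ddct = np.asarray(values) - base
            per_rep = np.power(2.0, -ddct)
            if aggregate == "mean-of-folds":
                folds.loc[gene, cond] = per_rep.mean()
            else:
                folds.loc[gene, cond] = 2.0 ** (-ddct.mean())
            err.loc[gene, cond] = (
                per_rep.std(ddof=1) / np.sqrt(len(per_rep))
                if len(per_rep) > 1
                else 0.0
            )
    # The calibrator column is identically 1 by construction only under
    # fold-of-means; normalize it exactly for both modes.
    folds[calibrator] = folds[calibrator] / folds[calibrator]
    return FoldChangeMatrix(folds=folds, stderr=err, calibrator=calibrator)


def fold_filter(matrix: FoldChangeMatrix, threshold: float = 2.5) -> list[str]:
    """Genes whose expression moves at least ``threshold``-fold in either
    direction in any condition (inclusive bounds)."""
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    f = matrix.folds
    mask = (f >= threshold) | (f <= 1.0 / threshold)
    return [g for g in f.index if bool(mask.loc[g].any())]


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "correlation", method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of expression profiles.

    Default distance is 1 - Pearson correlation with average linkage.
    Returns (scipy linkage matrix, leaf order as gene names). Zero-variance
    genes are rejected under correlation distance with a pointer to the
    Euclidean fallback.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 genes to cluster")
    values = matrix.to_numpy(dtype=float)
    if metric == "correlation":
        variances = values.var(axis=1)
        if np.any(variances == 0):
            flat = [matrix.index[i] for i in np.flatnonzero(variances == 0)]
            raise ValueError(
                f"zero-variance genes {flat} under correlation distance; "
                "use metric='euclidean'"
            )
    Z = hierarchy.linkage(pdist(values, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.index[i] for i in order]
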