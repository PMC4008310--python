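"""Cross-species and cross-gene codon-usage structure.

RSCU over the 59 synonymous codons is the feature space: rows (species or
genes) are clustered by complete-linkage on Euclidean distances and embedded
by PCA (mean-centered, unscaled), with variance-contribution ratios and the
per-row cos-squared quality of representation. Gene-level relations cover
the ENC-vs-GC3s plot against the expected-ENC curve, the CAI-GC3s
correlation, and CAI/GC3s tertile grouping for category-proportion trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.decomposition import PCA as _PCA
from statsmodels.stats.proportion import proportions_ztest

from .codon_metrics import CodonCountTable, expected_enc, rscu
from .genetic_code import STANDARD_CODE, GeneticCode

log = logging.getLogger(__name__)


@dataclass
class ClusterTree:
    """Complete-linkage dendrogram over matrix rows (or columns)."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignment = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assignment)}


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows x retained components
    loadings: pd.DataFrame  # columns x retained components
    variance_ratio: np.ndarray  # all components
    accumulated_ratio: np.ndarray
    cos2: pd.DataFrame  # rows x retained components


@dataclass
class GroupComparison:
    by: str  # cai | gc3s
    groups: dict[str, list[str]]  # low / mid / high -> member ids
    table: pd.DataFrame | None = None  # per-category proportions and flags


def build_rscu_matrix(
    tables: Mapping[str, CodonCountTable],
    impute: float = 1.0,
    max_missing_frac: float = 0.20,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Rows = labels, columns = the 59 synonymous codons, values = RSCU.

    Families unobserved in a row are imputed at *impute* (1.0 = neutral
    usage); rows missing more than *max_missing_frac* of cells are dropped
    with a warning.
    """
    cols = list(code.synonymous_codons)
    rows = {}
    for label, table in tables.items():
        values = rscu(table, code)
        present = [c for c in cols if c in values]
        if not present:
            log.warning("%s: no countable codons; row rejected", label)
            continue
        if 1 - len(present) / len(cols) > max_missing_frac:
            log.warning("%s: >%d%% RSCU cells missing; row dropped",
                        label, int(100 * max_missing_frac))
            continue
        rows[label] = [values.get(c, impute) for c in cols]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows for a comparative RSCU matrix")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def cluster_rows(matrix: pd.DataFrame, axis: str = "rows") -> ClusterTree:
    """Agglomerative complete-linkage clustering on Euclidean distances.

    ``axis`` selects rows, columns, or (via two calls) both; scipy's
    deterministic ordering (lower index first on ties) makes trees
    reproducible byte for byte.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if len(matrix) < 2:
        raise ValueError("need at least 2 observations to cluster")
    z = linkage(matrix.to_numpy(), method="complete", metric="euclidean")
    return ClusterTree(labels=tuple(matrix.index), linkage_matrix=z)


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-mean-centered PCA (no variance scaling).

    Variance contribution ratios are eigenvalue shares over all components;
    a row's cos-squared for a component is its squared score divided by its
    squared distance to the center, so the per-row cos-squared over all
    components sums to 1.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise ValueError("matrix has zero variance")
    full = _PCA(n_components=min(x.shape[0] - 1, x.shape[1]))
    all_scores = full.fit_transform(x)
    variance_ratio = full.explained_variance_ratio_
    n_components = min(n_components, all_scores.shape[1])
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        all_scores[:, :n_components], index=matrix.index, columns=comp_names
    )
    loadings = pd.DataFrame(
        full.components_[:n_components].T, index=matrix.columns, columns=comp_names
    )
    sq_dist = (centered**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = pd.DataFrame(
            (all_scores[:, :n_components] ** 2) / sq_dist[:, None],
            index=matrix.index,
            columns=comp_names,
        )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_ratio=variance_ratio,
        accumulated_ratio=np.cumsum(variance_ratio),
        cos2=cos2,
    )


def gene_level_relations(metrics: pd.DataFrame) -> dict:
    """ENC-vs-GC3s against the expected curve, and the CAI-GC3s correlation.

    *metrics* is the per-gene table from :func:`codon_metrics.gene_metrics`.
    Returns per-gene residuals (ENC minus expected ENC at the gene's GC3s),
    the fraction of genes below the curve, and Pearson r / p for CAI vs
    GC3s. Genes with undefined fields are skipped and counted.
    """
    enc_ok = metrics.dropna(subset=["enc", "gc3s"])
    residuals = enc_ok["enc"] - enc_ok["gc3s"].map(expected_enc)
    frame = pd.DataFrame(
        {
            "id": enc_ok["id"],
            "gc3s": enc_ok["gc3s"],
            "enc": enc_ok["enc"],
            "expected_enc": enc_ok["gc3s"].map(expected_enc),
            "residual": residuals,
        }
    )
    cai_ok = metrics.dropna(subset=["cai", "gc3s"])
    if len(cai_ok) >= 3 and cai_ok["cai"].nunique() > 1 and cai_ok["gc3s"].nunique() > 1:
        r, p = stats.pearsonr(cai_ok["cai"], cai_ok["gc3s"])
    else:
        r = p = float("nan")
    return {
        "enc_table": frame,
        "fraction_below_expected": float((residuals < 0).mean()) if len(residuals) else float("nan"),
        "cai_gc3s_r": float(r),
        "cai_gc3s_p": float(p),
        "n_enc": len(enc_ok),
        "n_cai": len(cai_ok),
        "n_skipped": len(metrics) - min(len(enc_ok), len(cai_ok)),
    }


def tertile_groups(metrics: pd.DataFrame, by: str = "cai") -> GroupComparison:
    """Rank genes by *by* (cai or gc3s) and split into low / mid / high
    groups of sizes (floor(n/3), n - 2*floor(n/3), floor(n/3)); the
    remainder goes to the middle group (1,066 genes -> 355, 356, 355).
    Ties are broken by id for determinism.
    """
    if by not in ("cai", "gc3s"):
        raise ValueError("grouping variable must be 'cai' or 'gc3s'")
    usable = metrics.dropna(subset=[by])
    n = len(usable)
    if n < 3:
        raise ValueError("need at least 3 records to form tertiles")
    ranked = usable.sort_values([by, "id"], kind="mergesort")
    low_n = n // 3
    ids = list(ranked["id"])
    groups = {
        "low": ids[:low_n],
        "mid": ids[low_n : n - low_n],
        "high": ids[n - low_n :],
    }
    return GroupComparison(by=by, groups=groups)


def category_trend_test(
    groups: GroupComparison,
    annotations: Mapping[str, set[str] | Sequence[str]],
    alpha: float = 0.05,
    method: str = "ztest",
) -> GroupComparison:
    """Per-category proportions across the low/mid/high groups with trend
    flags: '*' when the high group's proportion significantly (two-sided
    two-proportion test at *alpha*) exceeds the low group's and the mid
    group is intermediate; '^' for the decreasing analogue.
    """
    if method not in ("ztest", "fisher"):
        raise ValueError("method must be 'ztest' or 'fisher'")
    sizes = {g: len(ids) for g, ids in groups.groups.items()}
    categories: set[str] = set()
    for cats in annotations.values():
        categories.update(cats)
    rows = []
    for cat in sorted(categories):
        hits = {
            g: sum(1 for i in ids if cat in annotations.get(i, ()))
            for g, ids in groups.groups.items()
        }
        props = {g: hits[g] / sizes[g] if sizes[g] else float("nan") for g in hits}
        if all(x == 0 for x in hits.values()):
            continue
        if method == "ztest" and hits["low"] + hits["high"] > 0:
            _, p = proportions_ztest(
                [hits["high"], hits["low"]], [sizes["high"], sizes["low"]]
            )
        elif method == "fisher":
            table = [
                [hits["high"], sizes["high"] - hits["high"]],
                [hits["low"], sizes["low"] - hits["low"]],
            ]
            _, p = stats.fisher_exact(table)
        else:
            p = float("nan")
        flag = ""
        if p < alpha:
            if (
                props["high"] > props["low"]
                and props["low"] <= props["mid"] <= props["high"]
            ):
                flag = "*"
            elif (
                props["high"] < props["low"]
                and props["high"] <= props["mid"] <= props["low"]
            ):
                flag = "^"
        rows.append(
            {
                "category": cat,
                "prop_low": props["low"],
                "prop_mid": props["mid"],
                "prop_high": props["high"],
                "p_value": p,
                "flag": flag,
            }
        )
    groups.table = pd.DataFrame(rows)
    return groups
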