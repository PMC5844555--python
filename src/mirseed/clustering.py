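"""miRNA activity-profile clustering.

Each miRNA's activity profile is its vector of average interaction scores
across the screened genes.  Pairwise Pearson correlations over complete-case
genes form a correlation matrix whose row vectors are clustered
agglomeratively under Euclidean distance; miRNA families sharing seed
sequences should co-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class MirnaDendrogram:
    leaves: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix
    correlation_matrix: pd.DataFrame
    dropped: tuple[str, ...] = ()


def mirna_correlation_matrix(
    avg: pd.DataFrame, min_shared: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation per miRNA pair over shared (complete-case) genes.

    ``avg`` has columns mirna, gene, avg_score.  Zero-variance profiles are
    dropped and reported in the second return value; the diagonal is 1.
    """
    wide = avg.pivot_table(index="mirna", columns="gene", values="avg_score")
    variances = wide.var(axis=1, ddof=0)
    dropped = sorted(variances.index[(variances == 0) | variances.isna()])
    wide = wide.drop(index=dropped)
    corr = wide.T.corr(min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr, dropped


def cluster_mirnas(corr: pd.DataFrame, method: str = "average") -> MirnaDendrogram:
    """Agglomerative clustering of correlation row-vectors (Euclidean).

    Rows are sorted lexicographically by miRNA id before linkage so ties
    resolve deterministically.
    """
    if method not in ("average", "complete", "single"):
        raise ClusteringError(f"unsupported linkage {method!r}")
    if corr.shape[0] < 2:
        raise ClusteringError("need at least 2 miRNAs to cluster")
    corr = corr.loc[sorted(corr.index), sorted(corr.index)]
    if corr.isna().any().any():
        raise ClusteringError("correlation matrix contains missing values")
    z = linkage(pdist(corr.to_numpy(), metric="euclidean"), method=method)
    return MirnaDendrogram(tuple(corr.index), z, corr)


def _clade_leafsets(dendro: MirnaDendrogram) -> list[frozenset[str]]:
    """Leaf sets of every clade (internal node) of the dendrogram."""
    n = len(dendro.leaves)
    sets: dict[int, frozenset[str]] = {
        i: frozenset([leaf]) for i, leaf in enumerate(dendro.leaves)
    }
    out = []
    for j, (a, b, _, _) in enumerate(dendro.merges):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + j] = merged
        out.append(merged)
    return out


def family_coclustering(
    dendro: MirnaDendrogram, families: dict[str, list[str]]
) -> pd.DataFrame:
    """Largest exclusive clade per family, reported as "k of n".

    For each family the report gives the size of the biggest dendrogram
    subtree whose leaves are *only* family members.  Families with fewer
    than 2 members among the leaves are skipped.
    """
    leaves = set(dendro.leaves)
    clades = _clade_leafsets(dendro)
    rows = []
    for fam, members in families.items():
        present = leaves & set(members)
        if len(present) < 2:
            continue
        k = 1 if present else 0  # a single leaf is trivially exclusive
        for clade in clades:
            if clade <= present and len(clade) > k:
                k = len(clade)
        rows.append((fam, k, len(present)))
    return pd.DataFrame(rows, columns=["family", "k_clustered", "n_members"])


def to_newick(dendro: MirnaDendrogram) -> str:
    """Newick serialization with merge heights as branch lengths."""
    n = len(dendro.leaves)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: leaf for i, leaf in enumerate(dendro.leaves)}
    for j, (a, b, h, _) in enumerate(dendro.merges):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + j] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + j] = h
    return nodes[n + len(dendro.merges) - 1] + ";"
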