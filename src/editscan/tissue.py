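"""Site x library editing-ratio matrices and hierarchical clustering.

Mirrors the tissue-specificity analysis: ratios below the 2% noise cutoff in
every library are dropped, and the remaining sites are clustered with
average linkage on the 1 - Pearson correlation distance (pairwise-complete
over missing ratios). 17-nt and 20-nt evidence can be analysed separately.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calling import EditingSite

logger = logging.getLogger("editscan.tissue")


def build_ratio_matrix(
    sites: Sequence[EditingSite], libraries: Sequence[str] | None = None
) -> pd.DataFrame:
    """Sites as rows, libraries as columns, editing ratios as values (NaN = missing)."""
    if libraries is None:
        libraries = sorted({lib for s in sites for lib in s.per_library_ratio})
    data = {}
    for site in sites:
        row = [
            np.nan if site.per_library_ratio.get(lib) is None
            else site.per_library_ratio[lib]
            for lib in libraries
        ]
        data[site.site_id] = row
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=list(libraries))
    if matrix.index.has_duplicates:
        raise ValueError("duplicate site identifiers in matrix")
    return matrix


def filter_for_clustering(
    matrix: pd.DataFrame, threshold: float = 0.02, mode: str = "any"
) -> pd.DataFrame:
    """Keep rows whose ratio exceeds ``threshold`` (strictly) in at least one
    library (``mode="any"``) or in every library with data (``mode="all"``)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    above = matrix > threshold
    if mode == "any":
        keep = above.any(axis=1)
    elif mode == "all":
        keep = above.where(matrix.notna(), True).all(axis=1) & matrix.notna().any(axis=1)
    else:
        raise ValueError("mode must be 'any' or 'all'")
    return matrix.loc[keep]


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r over pairwise-complete observations.

    Rows with zero variance (or pairs with <2 shared observations) get
    distance 1 to everything, never NaN.
    """
    corr = matrix.T.corr(method="pearson", min_periods=2)
    degenerate = int(corr.isna().any(axis=1).sum())
    if degenerate:
        logger.warning(
            "%d rows with undefined correlations set to distance 1", degenerate
        )
    dist = (1.0 - corr).to_numpy()
    dist[np.isnan(dist)] = 1.0
    np.clip(dist, 0.0, 2.0, out=dist)  # guard fp drift in |r| <= 1
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry for squareform
    dist = (dist + dist.T) / 2.0
    return dist


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    ordered_matrix: pd.DataFrame
    newick: str


def to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a SciPy linkage matrix as a rooted Newick tree."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    assert tree is not None
    if tree.is_leaf():
        return f"{labels[tree.id]}:0;"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_sites(
    matrix: pd.DataFrame, metric: str = "pearson", linkage_method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of sites on correlation distance.

    Distance is 1 - Pearson r (pairwise-complete over missing values);
    linkage is UPGMA/average by default. Leaf order is SciPy's deterministic
    dendrogram order; ties resolve by input order.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if metric != "pearson":
        raise ValueError("only the pearson correlation distance is supported")
    dist = correlation_distance_matrix(matrix)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    labels = list(matrix.index)
    leaf_order = [labels[i] for i in order]
    return ClusterResult(
        labels=labels,
        linkage=Z,
        leaf_order=leaf_order,
        ordered_matrix=matrix.loc[leaf_order],
        newick=to_newick(Z, labels),
    )


def first_level_split(result: ClusterResult) -> tuple[set[str], set[str]]:
    """The two clades below the root merge."""
    n = len(result.labels)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (a, b, _, _) in enumerate(result.linkage):
        members[n + k] = members[int(a)] | members[int(b)]
    a, b = int(result.linkage[-1, 0]), int(result.linkage[-1, 1])
    lab = result.labels
    return {lab[i] for i in members[a]}, {lab[i] for i in members[b]}


def split_by_tag_length(
    sites: Sequence[EditingSite],
) -> dict[int, list[EditingSite]]:
    """Partition sites by the length of their supporting tags.

    A site supported by both 17-nt and 20-nt tags appears in both groups
    (logged), matching the separate-analysis design.
    """
    out: dict[int, list[EditingSite]] = {}
    mixed = 0
    for site in sites:
        lengths = site.tag_lengths
        if len(lengths) > 1:
            mixed += 1
        for L in lengths:
            out.setdefault(L, []).append(site)
    if mixed:
        logger.info("%d sites supported by multiple tag lengths placed in both", mixed)
    return out
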