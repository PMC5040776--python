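"""Cross-genome conservation profiling of small noncoding RNAs.

Each identified sncRNA is searched against a panel of related genomes; the
best-hit identity (percent, 0-100) fills an sncRNA x genome matrix, with 0
recorded where no hit passes the e-value cutoff ("no match").  Genomes are
then compared by the Spearman rank correlation of their identity profiles
over all sncRNAs, turned into the dissimilarity ``d = 1 - rho`` (range
[0, 2]), and clustered agglomeratively (average linkage / UPGMA by default)
into an ultrametric tree exported as Newick.

A genome whose profile is constant (typically all-zero: nothing found) has
an undefined rank correlation; such columns are assigned the maximal
dissimilarity 2 to every other genome rather than failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import DEFAULT_SCHEME, ScoringScheme, best_identity

__all__ = [
    "ConservationMatrix",
    "ClusterTree",
    "TreeNode",
    "ConstantVectorError",
    "build_matrix",
    "count_present",
    "fraction_above",
    "spearman_rho",
    "dissimilarity_matrix",
    "hierarchical_cluster",
    "newick",
    "heatmap_export",
]


class ConstantVectorError(ValueError):
    """Spearman correlation is undefined for an all-constant vector."""


@dataclass(frozen=True)
class ConservationMatrix:
    """sncRNA x genome table of best-hit identities (0 = no accepted hit)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("conservation matrix has missing cells")
        if ((v.values < 0) | (v.values > 100)).any():
            raise ValueError("identities must lie in [0, 100]")
        if v.index.has_duplicates:
            raise ValueError("duplicate sncRNA ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate genome names")

    @property
    def sncrna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.values.columns)

    def column(self, genome: str) -> np.ndarray:
        if genome not in self.values.columns:
            raise KeyError(f"unknown genome {genome!r}")
        return self.values[genome].to_numpy(dtype=float)


def build_matrix(
    queries: Sequence[tuple[str, str]],
    genomes: Mapping[str, Sequence],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    scheme_for: "Callable[[str, str], ScoringScheme] | None" = None,
) -> ConservationMatrix:
    """Search every query against every genome and collect best identities.

    ``queries`` are (id, sequence) pairs; ``genomes`` maps genome name to a
    list of contigs.  ``scheme_for(query_id, sequence)`` may override the
    scoring scheme per query (e.g. the relaxed miRNA cutoff for short
    queries).  Deterministic given inputs and scheme.
    """
    ids = [qid for qid, _ in queries]
    if len(set(ids)) != len(ids):
        dupes = sorted({q for q in ids if ids.count(q) > 1})
        raise ValueError(f"duplicate query ids: {dupes}")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    data = {}
    for name, contigs in genomes.items():
        col = []
        for qid, seq in queries:
            sch = scheme_for(qid, seq) if scheme_for is not None else scheme
            col.append(
                best_identity(seq, contigs, sch, query_id=qid, genome_name=name)
            )
        data[name] = col
    return ConservationMatrix(pd.DataFrame(data, index=ids, dtype=float))


def count_present(
    matrix: ConservationMatrix,
    min_genomes: int,
    subset: Sequence[str] | None = None,
) -> int:
    """Count sncRNAs detected (identity > 0) in at least ``min_genomes``
    of the given genome subset (all genomes by default)."""
    cols = list(subset) if subset is not None else matrix.genomes
    for c in cols:
        if c not in matrix.values.columns:
            raise KeyError(f"unknown genome {c!r}")
    if not 1 <= min_genomes <= len(cols):
        raise ValueError("min_genomes out of range")
    present = (matrix.values[cols] > 0).sum(axis=1)
    return int((present >= min_genomes).sum())


def fraction_above(
    matrix: ConservationMatrix, genome: str, identity_threshold: float
) -> tuple[int, float]:
    """(count, percent) of sncRNAs with identity strictly above a threshold
    in one genome; percent is over all matrix rows, two decimals."""
    from .context import round_half_away

    col = matrix.column(genome)
    count = int((col > identity_threshold).sum())
    return count, round_half_away(100.0 * count / len(col))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


#: Dissimilarity assigned when rank correlation is undefined (constant
#: profile, e.g. an all-zero genome column).
MAX_DISSIMILARITY = 2.0


def dissimilarity_matrix(matrix: ConservationMatrix) -> pd.DataFrame:
    """Pairwise genome dissimilarities ``d = 1 - rho`` (zero diagonal)."""
    genomes = matrix.genomes
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    m = len(genomes)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                rho = spearman_rho(matrix.column(genomes[i]), matrix.column(genomes[j]))
                dij = 1.0 - rho
            except ConstantVectorError:
                dij = MAX_DISSIMILARITY
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=genomes, columns=genomes)


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric cluster tree; leaves have height 0."""

    name: str | None
    height: float
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            assert self.name is not None
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass(frozen=True)
class ClusterTree:
    """Rooted binary tree over genome names with merge heights."""

    root: TreeNode

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def merge_heights(self) -> list[float]:
        out: list[float] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(out)


_LINKAGES = {"average", "complete", "single"}


def hierarchical_cluster(
    d: pd.DataFrame, linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of a symmetric dissimilarity matrix.

    Average linkage (UPGMA) by default, giving an ultrametric tree whose
    merge heights are half the inter-cluster dissimilarity.  Ties are broken
    deterministically: among equal-dissimilarity pairs, the pair whose
    smaller member label is lexicographically least wins (then the other
    label).
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    labels = list(d.index)
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    if list(d.columns) != labels:
        raise ValueError("dissimilarity matrix must be square with equal labels")
    arr = d.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    # active clusters: sort key label -> (node, size, index row in dist dict)
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab, height=0.0) for lab in labels
    }
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = arr[i, j]
    while len(nodes) > 1:
        best_pair: tuple[str, str] | None = None
        best_d = np.inf
        for key, val in dist.items():
            a, b = sorted(key)
            if val < best_d or (val == best_d and (a, b) < best_pair):
                best_d = val
                best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        height = best_d / 2.0
        merged = TreeNode(name=None, height=height, children=(nodes[a], nodes[b]))
        new_label = min(a, b)
        na, nb = sizes[a], sizes[b]
        for other in list(nodes):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "average":
                dn = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = min(da, db)
            dist[frozenset((new_label, other))] = dn
        dist.pop(frozenset((a, b)))
        del nodes[a], nodes[b], sizes[a], sizes[b]
        nodes[new_label] = merged
        sizes[new_label] = na + nb
    return ClusterTree(root=next(iter(nodes.values())))


def newick(tree: ClusterTree, decimals: int = 6) -> str:
    """Serialise an ultrametric cluster tree as a rooted Newick string.

    Branch lengths are parent height minus child height, so leaf-to-root
    path lengths equal the root merge height.
    """

    def fmt(x: float) -> str:
        s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
        return s if s else "0"

    def walk(node: TreeNode, parent_height: float) -> str:
        branch = fmt(parent_height - node.height)
        if node.is_leaf:
            return f"{node.name}:{branch}"
        inner = ",".join(walk(c, node.height) for c in node.children)
        return f"({inner}):{branch}"

    root = tree.root
    inner = ",".join(walk(c, root.height) for c in root.children)
    return f"({inner});"


NO_MATCH = "no_match"


def heatmap_export(
    matrix: ConservationMatrix, tree: ClusterTree
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order matrix columns by tree leaf order and flag zero cells.

    Returns (values, flags): flags contain ``no_match`` where the identity
    is exactly 0 (nothing passed the cutoff) and ``match`` elsewhere.
    """
    order = tree.leaf_order()
    if sorted(order) != sorted(matrix.genomes):
        raise ValueError("tree leaves do not match matrix columns")
    values = matrix.values[order].copy()
    flags = values.map(lambda v: NO_MATCH if v == 0 else "match")
    return values, flags
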