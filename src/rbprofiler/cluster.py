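"""Hierarchical clustering, cohort-admixture detection and co-expression
cluster extraction.

Sample and probe clustering uses complete linkage, either on Pearson
distance (1 - r) or on Euclidean distance.  Agglomeration is written here
rather than delegated so that tie-breaking is fully deterministic across
platforms: among all cluster pairs at the minimal distance, the pair with
the lexicographically smallest (id_a, id_b) merges first (original leaves
are 0..n-1, merged clusters take ids n, n+1, ... in creation order).

Complete linkage has the property that every member pair of a cluster cut
at height h is within distance h of each other; cutting a 1 - r tree at
1 - r_min therefore *guarantees* min pairwise correlation >= r_min inside
every emitted co-expression cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GroupDesign, ValidationError

MAX_PEARSON_DISTANCE = 2.0  # 1 - (-1); assigned to constant (undefined-r) items


def signature_matrix(
    matrix: ExpressionMatrix, probes: Sequence[str]
) -> pd.DataFrame:
    """Per-probe median-centered log2 signature over all samples.

    Each probe row is divided by its own median across samples and
    log2-transformed, so values are relative fold changes over the probe's
    typical level; the row median of the output is 0.
    """
    missing = set(probes) - set(matrix.probeset_ids)
    if missing:
        raise ValidationError(f"probes not in matrix: {sorted(missing)[:5]}")
    sub = matrix.intensities.loc[list(probes)]
    med = sub.median(axis=1)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValidationError(f"zero/negative median for probes: {bad[:5]}")
    return np.log2(sub.div(med, axis=0))


def pearson_distance(data: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """1 - Pearson r between rows; constant rows get the maximal distance.

    Returns the distance matrix and the indices of constant (zero-variance)
    rows, whose correlation is undefined.
    """
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    constant = [int(i) for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.atleast_2d(r)
    d = 1.0 - r
    d[~np.isfinite(d)] = MAX_PEARSON_DISTANCE
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # clip float noise at r slightly > 1
    return d, constant


def euclidean_distance(data: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(data, dtype=float), metric="euclidean"))


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Deterministic complete-linkage agglomeration of a distance matrix.

    Returns a linkage matrix in the standard (id_a, id_b, height, size)
    encoding with id_a < id_b.  Ties in the minimal inter-cluster distance
    are broken toward the lowest cluster-id pair.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if n < 2:
        raise ValidationError("need >= 2 items to cluster")
    # D grows to hold inter-cluster distances for merged clusters too
    m = 2 * n - 1
    D = np.full((m, m), np.inf)
    D[:n, :n] = dist
    np.fill_diagonal(D, np.inf)
    active = list(range(n))  # kept sorted ascending
    sizes = np.ones(m, dtype=int)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        # row-major argmin over the sorted-id submatrix = lowest-index tie-break
        flat = int(np.argmin(sub))
        i_pos, j_pos = divmod(flat, len(idx))
        a, b = int(idx[i_pos]), int(idx[j_pos])
        if a > b:
            a, b = b, a
        h = D[a, b]
        new = n + step
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            D[new, c] = D[c, new] = max(D[a, c], D[b, c])
        active.remove(a)
        active.remove(b)
        # insert keeping ascending order (new is always the largest id)
        active.append(new)
        Z[step] = (a, b, h, sizes[new])
    return Z


@dataclass
class Dendrogram:
    """Binary merge tree over labeled items."""

    linkage: np.ndarray  # (n-1, 4) rows: id_a, id_b, height, size
    labels: list[str]
    constant_items: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leaves(self, node: int) -> set[str]:
        """Labels under a node id (leaves are 0..n-1, merges n..2n-2)."""
        n = self.n_leaves
        stack = [node]
        out: set[str] = set()
        while stack:
            k = stack.pop()
            if k < n:
                out.add(self.labels[k])
            else:
                row = self.linkage[k - n]
                stack.extend([int(row[0]), int(row[1])])
        return out

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.linkage[node - n, 2])

    def cut(self, height: float) -> list[set[str]]:
        """Flat clusters: maximal subtrees whose merge height is <= height."""
        n = self.n_leaves
        parent = {}
        for step, (a, b, h, _) in enumerate(self.linkage):
            parent[int(a)] = n + step
            parent[int(b)] = n + step
        roots: list[int] = []
        # a node is a cluster root if its height <= cut but its parent's is not
        for node in range(2 * n - 1):
            h = self.node_height(node)
            if h > height:
                continue
            p = parent.get(node)
            if p is None or self.node_height(p) > height:
                roots.append(node)
        return [self.node_leaves(r) for r in roots]

    def to_newick(self) -> str:
        n = self.n_leaves

        def rec(node: int, parent_h: float) -> str:
            bl = max(parent_h - self.node_height(node), 0.0)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b, h, _ = self.linkage[node - n]
            return f"({rec(int(a), h)},{rec(int(b), h)}):{bl:.6g}"

        root = 2 * n - 2
        root_h = self.node_height(root)
        a, b, _, _ = self.linkage[-1]
        return f"({rec(int(a), root_h)},{rec(int(b), root_h)});"


def hier_cluster(
    data: pd.DataFrame,
    metric: str = "pearson",
    linkage: str = "complete",
) -> Dendrogram:
    """Complete-linkage dendrogram over the rows of ``data``.

    ``metric`` is ``"pearson"`` (distance 1 - r) or ``"euclidean"``.
    Rows with zero variance are flagged under Pearson distance and placed
    at the maximal distance (2) from everything.
    """
    if linkage != "complete":
        raise ValidationError(f"unsupported linkage: {linkage}")
    if len(data) < 2:
        raise ValidationError("need >= 2 items to cluster")
    values = data.to_numpy(dtype=float)
    labels = [str(i) for i in data.index]
    if metric == "pearson":
        dist, const_idx = pearson_distance(values)
        constant = [labels[i] for i in const_idx]
    elif metric == "euclidean":
        dist = euclidean_distance(values)
        constant = []
    else:
        raise ValidationError(f"unsupported metric: {metric}")
    Z = complete_linkage(dist)
    return Dendrogram(linkage=Z, labels=labels, constant_items=constant)


def admixture_detect(
    dend: Dendrogram,
    design: GroupDesign,
    disease_label: str,
) -> tuple[list[str], float]:
    """Control samples falling inside the disease branch of a sample tree.

    Starts from the smallest subtree containing every disease-group sample
    and widens it to the "disease clade": the ancestor of that subtree
    most separated from the remainder of the cohort, i.e. the one with the
    largest jump between its own merge height and its parent's (ties go to
    the higher ancestor, so a tree of identical samples degenerates to the
    whole cohort).  Returns the non-disease leaves inside the clade
    (sorted) with the clade height; an empty list means the disease
    samples form a well-separated pure subtree.
    """
    disease = set(design.samples_in(disease_label))
    leaves = set(dend.labels)
    if not disease <= leaves:
        raise ValidationError("dendrogram leaves do not cover the disease group")
    n = dend.n_leaves
    best_node, best_size = None, None
    for node in range(2 * n - 1):
        under = dend.node_leaves(node)
        if disease <= under and (best_size is None or len(under) < best_size):
            best_node, best_size = node, len(under)
    assert best_node is not None
    parent: dict[int, int] = {}
    for step, (a, b, _, _) in enumerate(dend.linkage):
        parent[int(a)] = n + step
        parent[int(b)] = n + step
    chain = [best_node]
    while chain[-1] in parent:
        chain.append(parent[chain[-1]])
    clade = chain[-1]  # root fallback; overwritten unless all gaps tie at 0
    best_gap = -1.0
    for node in chain[:-1]:
        gap = dend.node_height(parent[node]) - dend.node_height(node)
        if gap >= best_gap:  # >= : ties resolve toward the higher ancestor
            best_gap, clade = gap, node
    if best_gap <= 0.0 and len(chain) > 1:
        clade = chain[-1]
    under = dend.node_leaves(clade)
    flagged = sorted(under - disease)
    return flagged, dend.node_height(clade)


@dataclass
class CoexpressionClusterSet:
    """Probe clusters in which every pair is correlated at r >= r_min."""

    clusters: list[list[str]]
    r_min: float
    min_pairwise_r: list[float]

    def __len__(self) -> int:
        return len(self.clusters)


def min_pairwise_correlation(rows: pd.DataFrame) -> float:
    """Smallest pairwise Pearson r among the rows (1.0 for a single row)."""
    if len(rows) < 2:
        return 1.0
    r = np.corrcoef(rows.to_numpy(dtype=float))
    return float(np.min(r[np.triu_indices_from(r, k=1)]))


def extract_coexpression_clusters(
    signature: pd.DataFrame,
    r_min: float = 0.70,
    size_min: int = 2,
) -> CoexpressionClusterSet:
    """Extract co-expression clusters from a probe x sample signature.

    Probes are clustered by complete linkage on 1 - r and the tree is cut
    at 1 - r_min; complete linkage guarantees that min pairwise r >= r_min
    inside every resulting group.  Groups below ``size_min`` are dropped;
    clusters are reported in decreasing size (ties: by first probe id).
    """
    if len(signature) < 2:
        raise ValidationError("need >= 2 probes")
    dend = hier_cluster(signature, metric="pearson")
    groups = dend.cut(1.0 - r_min)
    clusters = [sorted(g) for g in groups if len(g) >= size_min]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    min_r = [min_pairwise_correlation(signature.loc[c]) for c in clusters]
    return CoexpressionClusterSet(
        clusters=clusters, r_min=r_min, min_pairwise_r=min_r
    )
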