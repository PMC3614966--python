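"""Between-sample community comparison: Bray-Curtis, Chao-Sørensen L_abd,
weighted UniFrac and UPGMA dendrograms.

Three complementary views of how clone libraries differ:

* **Bray-Curtis** — compositional dissimilarity on raw OTU counts,
  BC = Σ|x_i − y_i| / Σ(x_i + y_i).
* **Abundance-based Sørensen (L_abd)** — the Chao et al. shared-OTU
  similarity L = 2UV/(U+V), where U and V estimate the proportion of
  individuals in each sample that belong to shared OTUs, optionally with
  the unseen-shared-species correction.
* **Weighted UniFrac** — a phylogenetic distance that weights each branch
  of a community tree by the difference in relative abundance of the tips
  below it: raw = Σ_i b_i |A_i/A_T − B_i/B_T|; the normalized variant
  divides by Σ_i b_i (A_i/A_T + B_i/B_T) so the result lies in [0, 1].

Sample dissimilarity matrices are displayed as UPGMA (average linkage)
dendrograms, the standard rendering in clone-library surveys.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .errors import MissingTipError, ValidationError
from .otu import validate_distance_matrix

__all__ = [
    "bray_curtis",
    "chao_sorensen_abd",
    "weighted_unifrac",
    "sample_distance_matrix",
    "shared_otu_matrix",
    "upgma",
    "matrix_correlation_check",
]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("abundance vectors must be 1-D and aligned")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundances must be non-negative")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y), in [0, 1]."""
    x, y = _pair(x, y)
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two empty samples")
    return float(np.abs(x - y).sum() / denom)


def chao_sorensen_abd(x, y, corrected: bool = True) -> float:
    """Abundance-based Sørensen similarity L_abd = 2UV/(U+V).

    U (resp. V) is the proportion of individuals in sample x (resp. y)
    belonging to OTUs shared with the other sample. With
    ``corrected=True`` the Chao estimator adds the unseen-shared term
    ((m−1)/m)·(f₊₁/(2 f₊₂))·Σ_{shared, y_i=1} x_i/n (and symmetrically for
    V), where f₊₁/f₊₂ count shared OTUs that are singletons/doubletons in
    the *other* sample; each of U, V is clamped to ≤ 1. When f₊₂ = 0 the
    denominator uses 2·max(f₊₂, 1). Samples with no shared OTUs have
    L_abd = 0 by definition.
    """
    x, y = _pair(x, y)
    n, m = x.sum(), y.sum()
    if n == 0 or m == 0:
        raise ValidationError("both samples must be non-empty")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 0.0
    U = x[shared].sum() / n
    V = y[shared].sum() / m
    if corrected:
        f1 = int(((y == 1) & shared).sum())
        f2 = int(((y == 2) & shared).sum())
        U += (m - 1) / m * f1 / (2 * max(f2, 1)) * x[shared & (y == 1)].sum() / n
        g1 = int(((x == 1) & shared).sum())
        g2 = int(((x == 2) & shared).sum())
        V += (n - 1) / n * g1 / (2 * max(g2, 1)) * y[shared & (x == 1)].sum() / m
    U = min(U, 1.0)
    V = min(V, 1.0)
    if U + V == 0:
        return 0.0
    return float(2 * U * V / (U + V))


def weighted_unifrac(
    tree: TreeNode,
    x,
    y,
    otu_ids: Sequence[str],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two samples on a community tree.

    ``x``/``y`` are abundance vectors aligned to ``otu_ids``; every OTU with
    non-zero abundance must be a tip of ``tree``. Branch lengths of ``None``
    (e.g. the root) contribute 0.
    """
    x, y = _pair(x, y)
    if len(otu_ids) != x.size:
        raise ValidationError("otu_ids must align with the abundance vectors")
    a_tot, b_tot = x.sum(), y.sum()
    if a_tot == 0 or b_tot == 0:
        raise ValidationError("both samples must be non-empty")

    tips = {t.name for t in tree.tips()}
    present = {o for o, xi, yi in zip(otu_ids, x, y) if xi > 0 or yi > 0}
    missing = present - tips
    if missing:
        raise MissingTipError(missing)

    xa = dict(zip(otu_ids, x))
    ya = dict(zip(otu_ids, y))
    raw = 0.0
    denom = 0.0
    below: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            a = xa.get(node.name, 0.0)
            b = ya.get(node.name, 0.0)
        else:
            a = sum(below[id(c)][0] for c in node.children)
            b = sum(below[id(c)][1] for c in node.children)
        below[id(node)] = (a, b)
        length = node.length or 0.0
        pa, pb = a / a_tot, b / b_tot
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if not normalized:
        return raw
    if denom == 0:
        raise ValidationError("tree has zero abundance-weighted depth")
    return raw / denom


def sample_distance_matrix(
    otu_table: pd.DataFrame,
    metric: str = "braycurtis",
    tree: TreeNode | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise sample dissimilarity matrix from an OTU count table.

    ``metric`` is ``braycurtis`` or ``unifrac`` (requires ``tree``).
    """
    labels = list(otu_table.index.astype(str))
    data = otu_table.to_numpy(dtype=float)
    n = len(labels)
    d = np.zeros((n, n))
    otu_ids = list(otu_table.columns.astype(str))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "braycurtis":
                dij = bray_curtis(data[i], data[j])
            elif metric == "unifrac":
                if tree is None:
                    raise ValidationError("unifrac metric requires a tree")
                dij = weighted_unifrac(tree, data[i], data[j], otu_ids, normalized)
            else:
                raise ValidationError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, labels)


def shared_otu_matrix(otu_table: pd.DataFrame, corrected: bool = True) -> pd.DataFrame:
    """Pairwise L_abd similarity matrix (1 on the diagonal)."""
    labels = list(otu_table.index.astype(str))
    data = otu_table.to_numpy(dtype=float)
    n = len(labels)
    L = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            L[i, j] = L[j, i] = chao_sorensen_abd(data[i], data[j], corrected)
    return pd.DataFrame(L, index=labels, columns=labels)


def upgma(dm: DistanceMatrix, method: str = "average") -> TreeNode:
    """Agglomerative dendrogram of a sample distance matrix.

    Default UPGMA (average linkage); ``single``/``complete`` selectable.
    Node heights are half the linkage distance, so the output is
    ultrametric and cophenetic distances match the linkage heights.
    Labels are sorted before clustering so tie-breaking follows label
    order deterministically.
    """
    validate_distance_matrix(dm, upper=np.inf)
    if len(dm.ids) < 2:
        raise ValidationError("need at least 2 samples for a dendrogram")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    Z = linkage(squareform(dm.data, checks=False), method=method)
    root, nodes = to_tree(Z, rd=True)

    def build(node) -> tuple[str, float]:
        """Return (newick fragment without trailing length, node height)."""
        if node.is_leaf():
            return order[node.id], 0.0
        height = node.dist / 2.0
        parts = []
        for child in (node.left, node.right):
            frag, ch = build(child)
            parts.append(f"{frag}:{height - ch:.10g}")
        return f"({','.join(parts)})", height

    frag, _ = build(root)
    return TreeNode.read([f"{frag};"])


def matrix_correlation_check(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    method: str = "pearson",
):
    """Mantel correlation between two sample distance matrices.

    Convenience wrapper (e.g. OTU-based vs UniFrac-based matrices must tell
    the same story if the clustering is robust); delegates to
    :func:`thaumflow.ecostats.mantel`.
    """
    from .ecostats import mantel

    return mantel(dm1, dm2, permutations=permutations, seed=seed, method=method)
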