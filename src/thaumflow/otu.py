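"""Furthest-neighbor OTU clustering and sample × OTU count tables.

Clone-library surveys group marker-gene sequences into operational
taxonomic units (OTUs) at a fixed divergence cutoff — 5% here. The
*furthest neighbor* (complete linkage) criterion is the strictest of the
agglomerative family: a cluster is only valid if **every** pair of its
members is within the cutoff, so each OTU carries a certificate that all
intra-OTU pairwise distances are ≤ the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .errors import ValidationError

__all__ = [
    "OTUAssignment",
    "validate_distance_matrix",
    "cluster_furthest_neighbor",
    "build_otu_table",
    "p_distance",
    "fraction_pct",
    "classification_report",
]


@dataclass(frozen=True)
class OTUAssignment:
    """Sequence → OTU labelling at one divergence cutoff.

    OTU labels are the alphabetically first member id, which keeps them
    stable and human-readable across reruns.
    """

    cutoff: float
    mapping: Mapping[str, str]

    @property
    def n_otus(self) -> int:
        return len(set(self.mapping.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seq_id, otu in self.mapping.items():
            out.setdefault(otu, []).append(seq_id)
        return {k: sorted(v) for k, v in out.items()}


def validate_distance_matrix(dm: DistanceMatrix, upper: float = 1.0) -> None:
    """Check symmetry, zero diagonal and the [0, upper] range."""
    d = dm.data
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix diagonal is not zero")
    if d.min() < 0 or d.max() > upper:
        raise ValidationError(f"distances outside [0, {upper}]")


def cluster_furthest_neighbor(dm: DistanceMatrix, cutoff: float) -> OTUAssignment:
    """Complete-linkage OTU clustering at a divergence cutoff.

    Clusters are merged while the smallest inter-cluster complete-linkage
    distance is ≤ ``cutoff``; consequently every intra-OTU pairwise distance
    is ≤ ``cutoff``. Output is deterministic for a fixed input matrix.
    """
    if not (0 <= cutoff < 1):
        raise ValidationError(f"cutoff must be in [0, 1), got {cutoff}")
    validate_distance_matrix(dm)
    ids = list(dm.ids)
    if len(ids) == 1:
        return OTUAssignment(cutoff, {ids[0]: ids[0]})
    condensed = squareform(dm.data, checks=False)
    Z = linkage(condensed, method="complete")
    flat = fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for seq_id, c in zip(ids, flat):
        clusters.setdefault(int(c), []).append(seq_id)
    mapping = {}
    for members in clusters.values():
        label = min(members)
        for seq_id in members:
            mapping[seq_id] = label
    return OTUAssignment(cutoff, mapping)


def build_otu_table(
    assignment: OTUAssignment, membership: Mapping[str, str]
) -> pd.DataFrame:
    """Sample × OTU integer count table.

    ``membership`` maps each sequence id to its sample (clone library).
    Every clustered sequence must have a sample label. Rows are samples,
    columns OTU labels, both sorted; there are no all-zero columns by
    construction.
    """
    missing = set(assignment.mapping) - set(membership)
    if missing:
        raise KeyError(f"sequences without a sample label: {sorted(missing)[:5]}")
    seq_ids = list(assignment.mapping)
    samples = [membership[s] for s in seq_ids]
    otus = [assignment.mapping[s] for s in seq_ids]
    table = pd.crosstab(pd.Series(samples, name="sample"), pd.Series(otus, name="otu"))
    return table.sort_index(axis=0).sort_index(axis=1).astype(int)


def p_distance(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Ungapped p-distance matrix from equal-length aligned sequences.

    Helper for synthetic tests: proportion of differing positions among
    columns where neither sequence has a gap ('-' or '.').
    """
    ids = sorted(sequences)
    lengths = {len(sequences[i]) for i in ids}
    if len(lengths) != 1:
        raise ValidationError("aligned sequences must have equal length")
    arr = np.array([list(sequences[i].upper()) for i in ids])
    gap = (arr == "-") | (arr == ".")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            denom = ok.sum()
            if denom == 0:
                raise ValidationError(f"no comparable positions between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = (arr[i][ok] != arr[j][ok]).mean()
    return DistanceMatrix(d, ids)


def fraction_pct(part: int | float, total: int | float, decimals: int = 1) -> float:
    """Percentage share rounded to ``decimals`` (survey-report convention)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * part / total, decimals)


def classification_report(
    counts: Mapping[str, int], total: int | None = None
) -> pd.DataFrame:
    """Sequence-fraction summary over lineage (or OTU) counts.

    One row per group with its count and percentage share of ``total``
    (default: the sum of the counts). This is the arithmetic behind
    statements like "the shallow cluster contained 86.3% of all sequences".
    """
    if total is None:
        total = sum(counts.values())
    rows = [
        {"group": g, "n": int(n), "pct": fraction_pct(n, total)}
        for g, n in counts.items()
    ]
    return pd.DataFrame(rows).set_index("group")
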