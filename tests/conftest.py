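"""Shared fixtures and independent oracles used across the suite.

The oracles here are deliberately separate code paths from the package:
a brute-force primer scanner, a naive agglomerative clusterer and naive
diversity estimators, so that package results can be checked against
independent recomputation rather than against themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from skbio import DistanceMatrix

from thaumflow.primers import (
    IUPAC_SETS,
    DegeneratePrimer,
    Orientation,
    TemplateRecord,
)
from thaumflow.simulate import reference_mismatch_panel

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}


def brute_force_align(primer: DegeneratePrimer, template: TemplateRecord):
    """All-offset exhaustive scan with per-position set comparison.

    Independent re-derivation of the minimum mismatch count and its
    offset: reverse primers are handled by complementing the primer
    character-by-character and walking it 3'->5' along the plus strand.
    """
    tseq = template.sequence
    L = len(primer.sequence)
    best = (L + 1, -1)
    for start in range(len(tseq) - L + 1):
        count = 0
        for i, pc in enumerate(primer.sequence):
            if primer.orientation is Orientation.FORWARD:
                tc = tseq[start + i]
                pset = IUPAC_SETS[pc]
            else:
                tc = tseq[start + (L - 1 - i)]
                pset = {_COMP[b] for b in IUPAC_SETS[pc]}
            if not (IUPAC_SETS[tc] <= pset):
                count += 1
        if count < best[0]:
            best = (count, start)
    return best  # (min mismatches, plus-strand offset)


def naive_complete_linkage(dm: DistanceMatrix, cutoff: float) -> set[frozenset[str]]:
    """Greedy agglomerative furthest-neighbor clustering, O(n^3).

    Merges the pair of clusters with the smallest complete-linkage
    distance while that distance is <= cutoff; returns the partition as a
    set of frozensets of sequence ids.
    """
    ids = list(dm.ids)
    lookup = {s: i for i, s in enumerate(ids)}
    clusters: list[set[str]] = [{s} for s in ids]

    def cl_dist(a: set[str], b: set[str]) -> float:
        return max(dm.data[lookup[x], lookup[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cl_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        if d > cutoff:
            break
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def naive_diversity(counts):
    """Straightforward re-derivation of S_obs, F1, F2, C, H', Chao1."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    coverage = 1 - f1 / n
    h = -sum((c / n) * np.log(c / n) for c in counts)
    chao = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return {"n": n, "s_obs": s_obs, "f1": f1, "f2": f2, "coverage": coverage,
            "shannon": h, "chao1": chao}


def branch_by_branch_unifrac(tree, x, y, otu_ids, normalized):
    """Per-branch accumulation using explicit tip sets below each node."""
    xa = dict(zip(otu_ids, x))
    ya = dict(zip(otu_ids, y))
    a_tot = sum(x)
    b_tot = sum(y)
    raw = 0.0
    depth = 0.0
    for node in tree.traverse(include_self=True):
        tips_below = {t.name for t in node.tips()} or {node.name}
        a = sum(xa.get(t, 0.0) for t in tips_below)
        b = sum(ya.get(t, 0.0) for t in tips_below)
        length = node.length or 0.0
        raw += length * abs(a / a_tot - b / b_tot)
        depth += length * (a / a_tot + b / b_tot)
    return raw / depth if normalized else raw


def random_symmetric(rng: np.random.Generator, n: int, scale: float = 1.0) -> DistanceMatrix:
    """Random distance matrix with distinct off-diagonal entries."""
    d = rng.uniform(0.01, scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [f"s{i:02d}" for i in range(n)])


def random_iupac_primer(rng: np.random.Generator, name: str = "rnd") -> DegeneratePrimer:
    length = int(rng.integers(15, 26))
    chars = []
    codes = list(IUPAC_SETS)
    for _ in range(length):
        if rng.random() < 0.2:
            chars.append(codes[int(rng.integers(4, len(codes)))])
        else:
            chars.append("ACGT"[int(rng.integers(4))])
    orientation = Orientation.FORWARD if rng.random() < 0.5 else Orientation.REVERSE
    return DegeneratePrimer(name, "".join(chars), orientation)


def random_template(rng: np.random.Generator, name: str = "tmpl", min_len: int = 60) -> TemplateRecord:
    length = int(rng.integers(min_len, min_len + 60))
    seq = "".join("ACGT"[int(i)] for i in rng.integers(4, size=length))
    return TemplateRecord(name, seq)


@pytest.fixture(scope="session")
def panel():
    return reference_mismatch_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20130402)
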