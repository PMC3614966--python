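"""Permutation and rank statistics for community ecology.

Mann-Whitney U, Spearman rank correlation and OLS R² wrap scipy; ANOSIM
and the Mantel test are permutation procedures implemented here with
vectorized permutation loops and explicit seeding, since reproducibility
of permutation p-values is part of the package contract. Environmental
and geographic sample distances feed the Mantel analyses.

Conventions: ANOSIM and Mantel p-values are one-sided upper-tail and
computed as (1 + #{perm ≥ obs}) / (permutations + 1), so the smallest
attainable p is 1/(permutations+1). Mann-Whitney is two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ValidationError

__all__ = [
    "TestResult",
    "mann_whitney",
    "spearman",
    "linreg_r2",
    "anosim",
    "mantel",
    "env_distance",
    "geo_distance",
    "significance_stars",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    pvalue: float
    n: int
    permutations: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"p-value {self.pvalue} outside (0, 1]")


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's ``method='auto'`` policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue), a.size + b.size)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties; p via t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    # a monotone permutation gives r = ±1 and a degenerate t; clamp p into (0,1]
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return TestResult("spearman", float(r), p, x.size)


def linreg_r2(x, y) -> float:
    """Coefficient of determination of the OLS fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def _condensed_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _permutation_indices(rng: np.random.Generator, n: int, permutations: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (permutations, 1)), axis=1)


def anosim(
    dm: DistanceMatrix,
    grouping,
    permutations: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Analysis of similarities on a sample distance matrix.

    R = (mean between-group rank − mean within-group rank) / (N(N−1)/4)
    over the ranked off-diagonal distances; p by permuting group labels.
    ``grouping`` is a mapping sample → label or a sequence aligned to
    ``dm.ids``. Every group needs ≥ 2 members and there must be ≥ 2 groups.
    """
    ids = list(dm.ids)
    n = len(ids)
    if isinstance(grouping, dict):
        labels = np.array([grouping[i] for i in ids])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != n:
            raise ValidationError("grouping length does not match matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValidationError(f"groups with < 2 members: {list(small)}")
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")

    iu, ju = _condensed_indices(n)
    ranks = stats.rankdata(dm.data[iu, ju])
    denom = n * (n - 1) / 4.0
    codes = np.unique(labels, return_inverse=True)[1]

    def r_stat(within: np.ndarray) -> float | np.ndarray:
        w = within.sum(axis=-1)
        mean_within = (ranks * within).sum(axis=-1) / w
        mean_between = (ranks * ~within).sum(axis=-1) / (ranks.size - w)
        return (mean_between - mean_within) / denom

    r_obs = float(r_stat(codes[iu] == codes[ju]))

    rng = np.random.default_rng(seed)
    perm_idx = _permutation_indices(rng, n, permutations)
    lp = codes[perm_idx]  # (P, n)
    within_p = lp[:, iu] == lp[:, ju]  # (P, n_pairs)
    r_perm = r_stat(within_p)
    p = (1 + int((r_perm >= r_obs).sum())) / (permutations + 1)
    return TestResult("anosim", r_obs, p, n, permutations, seed)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> TestResult:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson (default) or Spearman correlation of the off-diagonal entries;
    the null distribution permutes rows and columns of the first matrix
    jointly. One-sided upper-tail p.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValidationError("distance matrices must share labels and order")
    n = len(dm1.ids)
    if n < 3:
        raise ValidationError("need at least 3 samples")
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")

    iu, ju = _condensed_indices(n)
    d1 = dm1.data.astype(float)
    v2 = dm2.data[iu, ju].astype(float)
    if method == "spearman":
        # rank-transforming first commutes with joint row/column permutation
        d1 = squareform(stats.rankdata(d1[iu, ju]), checks=False)
        v2 = stats.rankdata(v2)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    v1 = d1[iu, ju]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValidationError("Mantel undefined for constant distances")

    v2c = v2 - v2.mean()
    v2n = np.sqrt((v2c**2).sum())

    def corr(rows: np.ndarray) -> np.ndarray:
        c = rows - rows.mean(axis=-1, keepdims=True)
        return (c * v2c).sum(axis=-1) / (np.sqrt((c**2).sum(axis=-1)) * v2n)

    r_obs = float(corr(v1[None, :])[0])

    rng = np.random.default_rng(seed)
    perm_idx = _permutation_indices(rng, n, permutations)
    rows = d1[perm_idx[:, iu], perm_idx[:, ju]]  # (P, n_pairs)
    r_perm = corr(rows)
    p = (1 + int((r_perm >= r_obs).sum())) / (permutations + 1)
    return TestResult(f"mantel-{method}", r_obs, p, n, permutations, seed)


def env_distance(
    env: pd.DataFrame,
    variables=("temperature", "salinity"),
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean sample distance on (z-scored) environmental variables.

    With one variable this is |Δz|; with several, the multivariate
    Euclidean distance on the standardized columns (sample SD, ddof=1).
    Missing values raise, naming the offending samples.
    """
    variables = list(variables)
    missing_cols = [v for v in variables if v not in env.columns]
    if missing_cols:
        raise ValidationError(f"variables not in table: {missing_cols}")
    sub = env[variables].astype(float)
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        raise ValidationError(f"missing values for samples: {list(map(str, bad))}")
    data = sub.to_numpy()
    if standardize:
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("cannot standardize a constant variable")
        data = (data - data.mean(axis=0)) / sd
    d = squareform(pdist(data, metric="euclidean"))
    return DistanceMatrix(d, list(env.index.astype(str)))


def geo_distance(env: pd.DataFrame, lat_col: str = "latitude", lon_col: str = "longitude") -> DistanceMatrix:
    """Great-circle (haversine) distance between stations, in km."""
    lat = env[lat_col].to_numpy(dtype=float)
    lon = env[lon_col].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("coordinates outside valid ranges")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return DistanceMatrix(d, list(env.index.astype(str)))


def significance_stars(p: float) -> str:
    """Survey-table annotation: * for P<0.05, ** for P<0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
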