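"""Alpha-diversity and coverage estimators for clone libraries.

Per-library columns of a classic clone-library diversity table:
``n`` (library size), observed OTU richness, Good's coverage
C = 1 − F1/n, Shannon diversity H' = −Σ p_i ln p_i, and the
bias-corrected Chao1 richness estimate S_obs + F1(F1−1)/(2(F2+1)),
where F1/F2 are the singleton/doubleton OTU counts.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["chao1", "shannon", "goods_coverage", "library_summary"]

logger = logging.getLogger(__name__)


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("abundance vector must be 1-D and non-empty")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("abundances must be non-negative integers")
    arr = arr.astype(int)
    if arr.sum() < 1:
        raise ValidationError("abundance vector must contain at least one individual")
    return arr[arr > 0]


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 nonparametric richness estimate.

    Default is the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), which is
    defined even when there are no doubletons and reduces to S_obs when
    F1 ≤ 1. ``bias_corrected=False`` selects the classic S_obs + F1²/(2 F2)
    for comparison with software using that variant (undefined at F2=0 with
    F1>0, where the corrected form is substituted).
    """
    arr = _as_counts(counts)
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H' = −Σ p_i log p_i (natural log by default)."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def goods_coverage(counts) -> float:
    """Good's coverage C = 1 − F1/n, as a proportion in [0, 1]."""
    arr = _as_counts(counts)
    return 1.0 - float((arr == 1).sum()) / float(arr.sum())


def library_summary(otu_table: pd.DataFrame) -> pd.DataFrame:
    """Per-library diversity table (one row per sample).

    Columns: n, otus (S_obs), coverage_pct (Good's C as a percentage,
    one decimal), shannon (H', nats) and chao1. Empty libraries are
    skipped with a warning rather than raising.
    """
    rows = {}
    for sample, counts in otu_table.iterrows():
        vec = counts.to_numpy()
        vec = vec[vec > 0]
        if vec.size == 0:
            logger.warning("sample %s has no sequences; row suppressed", sample)
            continue
        rows[sample] = {
            "n": int(vec.sum()),
            "otus": int(vec.size),
            "coverage_pct": round(100.0 * goods_coverage(vec), 1),
            "shannon": shannon(vec),
            "chao1": chao1(vec),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
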