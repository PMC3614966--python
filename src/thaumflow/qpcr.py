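"""Absolute quantitation from SYBR-green qPCR.

A ten-fold dilution series of a plasmid standard gives a straight line of
Ct against log10(copies); its slope determines the amplification
efficiency E = 10^(−1/slope) − 1 (slope −3.3219 ↔ E = 100%, perfect
doubling per cycle). Unknowns are read off the curve as
copies = 10^((Ct − intercept)/slope), summarized over triplicates, and
converted to gene copies per litre of seawater via the volume chain
(template volume → DNA eluate volume → filtered water volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "quantify",
    "to_copies_per_liter",
    "gene_ratio",
    "summarize_plate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """Ct = intercept + slope·log10(copies) fit of a dilution series."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if self.slope >= 0:
            raise ValidationError(f"standard curve slope must be negative, got {self.slope}")
        if not (0 <= self.r_squared <= 1):
            raise ValidationError("R^2 outside [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(−1/slope) − 1 (proportion)."""
        return 10 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.efficiency


@dataclass(frozen=True)
class QuantResult:
    """Triplicate-summarized abundance of one gene in one sample."""

    sample: str
    gene: str
    copies_per_liter: float
    sd: float
    n_replicates: int
    below_detection: bool = False


def fit_standard_curve(standards) -> StandardCurve:
    """Least-squares fit of Ct on log10(known copies).

    ``standards`` is an iterable of (known_copies, ct) pairs with at least
    three distinct dilution levels. A non-negative slope (no dilution
    response) raises.
    """
    pairs = [(float(c), float(ct)) for c, ct in standards]
    if any(c <= 0 for c, _ in pairs):
        raise ValidationError("standard copy numbers must be positive")
    levels = {c for c, _ in pairs}
    if len(levels) < 3:
        raise ValidationError(f"need >= 3 distinct dilution levels, got {len(levels)}")
    x = np.log10([c for c, _ in pairs])
    y = np.array([ct for _, ct in pairs])
    res = stats.linregress(x, y)
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def quantify(curve: StandardCurve, ct: float, detection_ct: float | None = None) -> tuple[float, bool]:
    """Convert one Ct value to copies per reaction.

    Returns (copies, below_detection). A Ct at or beyond ``detection_ct``
    (e.g. the Ct of the lowest standard or a no-template threshold) flags
    the value as below detection instead of raising; NaN Ct (no
    amplification) likewise.
    """
    if math.isnan(ct):
        return 0.0, True
    copies = 10 ** ((ct - curve.intercept) / curve.slope)
    if detection_ct is not None and ct >= detection_ct:
        return copies, True
    return copies, False


def to_copies_per_liter(
    copies_per_rxn: float,
    template_volume_ul: float,
    elution_volume_ul: float,
    filtered_volume_l: float,
) -> float:
    """Scale a per-reaction copy number to copies per litre of seawater."""
    for name, v in (
        ("template_volume_ul", template_volume_ul),
        ("elution_volume_ul", elution_volume_ul),
        ("filtered_volume_l", filtered_volume_l),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    return copies_per_rxn * (elution_volume_ul / template_volume_ul) / filtered_volume_l


def summarize_plate(
    plate: pd.DataFrame,
    template_volume_ul: float,
    elution_volume_ul: float,
    filtered_volume_l: float | dict[str, float],
    detection_ct: float | None = None,
) -> tuple[dict[str, StandardCurve], list[QuantResult]]:
    """Full plate workflow: fit per-gene curves, quantify unknowns.

    ``plate`` columns: sample, gene, replicate, ct, role
    (standard|unknown|ntc) and known_copies for standards. Triplicates are
    summarized as mean ± SD of copies per litre; a sample is below
    detection when any replicate is flagged. ``filtered_volume_l`` may be a
    single volume or a per-sample mapping.
    """
    required = {"sample", "gene", "replicate", "ct", "role"}
    if not required <= set(plate.columns):
        raise ValidationError(f"plate missing columns: {sorted(required - set(plate.columns))}")

    curves: dict[str, StandardCurve] = {}
    for gene, grp in plate[plate["role"] == "standard"].groupby("gene"):
        curves[str(gene)] = fit_standard_curve(zip(grp["known_copies"], grp["ct"]))

    results: list[QuantResult] = []
    unknowns = plate[plate["role"] == "unknown"]
    for (sample, gene), grp in unknowns.groupby(["sample", "gene"], sort=True):
        gene = str(gene)
        if gene not in curves:
            raise ValidationError(f"no standard curve for gene {gene!r}")
        curve = curves[gene]
        per_l = []
        flagged = False
        for ct in grp["ct"]:
            copies, below = quantify(curve, float(ct), detection_ct)
            flagged = flagged or below
            vol = (
                filtered_volume_l[str(sample)]
                if isinstance(filtered_volume_l, dict)
                else filtered_volume_l
            )
            per_l.append(
                to_copies_per_liter(copies, template_volume_ul, elution_volume_ul, vol)
            )
        arr = np.asarray(per_l)
        results.append(
            QuantResult(
                sample=str(sample),
                gene=gene,
                copies_per_liter=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                n_replicates=int(arr.size),
                below_detection=flagged,
            )
        )
    return curves, results


def gene_ratio(
    functional: list[QuantResult], reference: list[QuantResult]
) -> dict[str, float | int]:
    """Per-sample functional/reference gene ratio, summarized across samples.

    Pairs samples present in both lists with both genes detected, computes
    100·functional/reference per sample, and reports the mean, SE and the
    number of samples used/excluded. An empty pairing returns a summary
    with n_used = 0 and NaN mean (with a warning) rather than raising.
    """
    f = {q.sample: q for q in functional}
    r = {q.sample: q for q in reference}
    ratios = []
    excluded = 0
    for sample in sorted(set(f) & set(r)):
        qf, qr = f[sample], r[sample]
        if qf.below_detection or qr.below_detection or qr.copies_per_liter == 0:
            excluded += 1
            continue
        ratios.append(100.0 * qf.copies_per_liter / qr.copies_per_liter)
    if not ratios:
        logger.warning("no paired detections for gene ratio")
        return {"mean_pct": float("nan"), "se_pct": float("nan"), "n_used": 0, "n_excluded": excluded}
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "mean_pct": float(arr.mean()),
        "se_pct": sd / math.sqrt(arr.size),
        "n_used": int(arr.size),
        "n_excluded": excluded,
    }
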