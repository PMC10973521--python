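"""Segmentation-quality and measurement-agreement statistics.

Covers the pixel-overlap metrics used to score segmentation against a
reference (global/mean accuracy, mean and frequency-weighted IoU, Dice),
the intraclass correlation coefficient for rater/method agreement on the
alignment angles, and simple paired-difference summaries.

Conventions: mean DSC averages over foreground classes only (a background
Dice would inflate the score); accuracy and IoU averages include the
background class.  A Dice of two empty masks is defined as 1 and flagged.
The ICC defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measurement — the standard choice when an algorithm is compared to
human raters on absolute values; reliability bands follow the Altman
cut-points (>= 0.81 very good, 0.61-0.80 good, 0.41-0.60 moderate, below
that fair or poor).  A DSC >= 0.7 is banded as excellent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

DSC_EXCELLENT_THRESHOLD = 0.7


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationScores:
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_dsc: float

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    band: str
    flags: tuple = ()


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of binary masks."""
    a, b = np.asarray(a).astype(bool), np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise MetricsError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0  # both empty: vacuous agreement (flagged by callers)
    return 2.0 * int((a & b).sum()) / denom


def confusion_scores(pred: np.ndarray, truth: np.ndarray) -> SegmentationScores:
    """Overlap scores from the per-class confusion tally.

    Accepts binary masks or integer label rasters; classes are the union of
    labels present in either input (background = 0 always included).
    """
    pred, truth = np.asarray(pred).astype(int), np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise MetricsError(f"shape mismatch {pred.shape} vs {truth.shape}")
    classes = np.union1d(np.union1d(pred, truth), [0])
    n = pred.size
    accs, ious, dscs, freqs = [], [], [], []
    correct = int((pred == truth).sum())
    for c in classes:
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        support = tp + fn
        accs.append(tp / support if support else 1.0)
        union = tp + fp + fn
        ious.append(tp / union if union else 1.0)
        freqs.append(support / n)
        if c != 0:
            dscs.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0)
    return SegmentationScores(
        global_accuracy=correct / n,
        mean_accuracy=float(np.mean(accs)),
        mean_iou=float(np.mean(ious)),
        weighted_iou=float(np.dot(freqs, ious)),
        mean_dsc=float(np.mean(dscs)) if dscs else 1.0,
    )


ALTMAN_BANDS = (
    (0.81, "very_good"),
    (0.61, "good"),
    (0.41, "moderate"),
)


def altman_band(icc_value: float) -> str:
    for lo, name in ALTMAN_BANDS:
        if icc_value >= lo:
            return name
    return "fair_or_poor"


def icc(ratings: np.ndarray, model: str = "two_way_random_absolute_single") -> ICCResult:
    """Intraclass correlation of an (n_subjects x k_raters) table.

    The default model is ICC(2,1): two-way random effects, absolute
    agreement, single measurement; ``two_way_mixed_consistency_single``
    selects ICC(3,1).  The 95% CI and the p-value against ICC = 0 come from
    the standard F-distribution bounds.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise MetricsError("ratings must be a 2-D subjects x raters table")
    n, k = table.shape
    if n < 5 or k < 2:
        raise MetricsError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(table)):
        raise MetricsError("missing cells are not supported")
    icc_type = {"two_way_random_absolute_single": "ICC(A,1)",
                "two_way_mixed_consistency_single": "ICC(C,1)"}.get(model)
    if icc_type is None:
        raise MetricsError(f"unknown ICC model {model!r}")

    flags: List[str] = []
    if np.allclose(table.var(axis=1, ddof=0), 0) and np.allclose(table, table[:, :1]):
        # Raters identical on every subject: perfect absolute agreement.
        if np.isclose(table[:, 0].var(), 0):
            flags.append("zero-between-subject-variance")
            return ICCResult(np.nan, np.nan, np.nan, np.nan, "fair_or_poor", tuple(flags))
        return ICCResult(1.0, 1.0, 1.0, 0.0, "very_good", tuple(flags))
    if np.isclose(table.mean(axis=1).var(), 0):
        flags.append("zero-between-subject-variance")

    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": table.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    row = res.loc[icc_type]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    result = ICCResult(
        icc=value,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(row["pval"]),
        band=altman_band(value),
        flags=tuple(flags),
    )
    return result


@dataclass(frozen=True)
class AgreementReport:
    """Paired-difference summary between two raters/methods per angle."""

    angles: tuple
    mean_diff: Dict[str, float]
    sd_diff: Dict[str, float]
    mean_a: Dict[str, float]
    sd_a: Dict[str, float]
    mean_b: Dict[str, float]
    sd_b: Dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_diff": self.mean_diff,
                "sd_diff": self.sd_diff,
                "mean_a": self.mean_a,
                "sd_a": self.sd_a,
                "mean_b": self.mean_b,
                "sd_b": self.sd_b,
            }
        )


def agreement_report(
    a: Sequence[Dict[str, float]], b: Sequence[Dict[str, float]]
) -> AgreementReport:
    """Per-angle mean +- SD of the paired differences a - b.

    ``a`` and ``b`` are same-length sequences of {angle: value} mappings
    over the same subjects and the same angle names.
    """
    if len(a) != len(b) or len(a) == 0:
        raise MetricsError("subject lists must match and be non-empty")
    names = tuple(a[0].keys())
    if any(tuple(x.keys()) != names for x in list(a) + list(b)):
        raise MetricsError("angle sets must match across subjects and raters")
    da = pd.DataFrame(list(a))
    db = pd.DataFrame(list(b))
    diff = da - db
    return AgreementReport(
        angles=names,
        mean_diff=diff.mean().to_dict(),
        sd_diff=diff.std(ddof=1).fillna(0.0).to_dict(),
        mean_a=da.mean().to_dict(),
        sd_a=da.std(ddof=1).fillna(0.0).to_dict(),
        mean_b=db.mean().to_dict(),
        sd_b=db.std(ddof=1).fillna(0.0).to_dict(),
    )


def dsc_band(dsc_value: float) -> str:
    """'excellent' for DSC >= 0.7 (inclusive), else 'not_excellent'."""
    if not (0.0 <= dsc_value <= 1.0):
        raise MetricsError(f"DSC {dsc_value} outside [0, 1]")
    return "excellent" if dsc_value >= DSC_EXCELLENT_THRESHOLD else "not_excellent"
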