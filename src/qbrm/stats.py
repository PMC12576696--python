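"""Detector scoring and group-level statistics.

Detector performance is scored by one-to-one greedy matching of predicted
to reference boxes (descending confidence, IoU threshold), yielding
sensitivity tp/(tp+fn), positive predictive value tp/(tp+fp), and two
false-positive measures: the fraction of retained predictions that are
false, fp/(tp+fp), and the areal rate FP/mm^2.  Note that fp/(tp+fp) is
algebraically 1 - PPV; published "false positive rates" sometimes use a
different (unstated) denominator, so both measures are reported rather
than one being inferred.

Group comparisons follow the study design: one max-damage value per
animal, one-way ANOVA across groups, then Tukey's HSD (Tukey-Kramer
standard errors for unequal n) for all pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import BoundingBox, Detection, iou

__all__ = [
    "MatchResult",
    "EvalReport",
    "AnovaResult",
    "match_detections",
    "detection_metrics",
    "density_correlation",
    "one_way_anova",
    "tukey_hsd",
]


@dataclass
class MatchResult:
    """One-to-one prediction/reference pairing at a given IoU threshold."""

    pairs: list[tuple[int, int, float]]
    unmatched_pred: list[int]
    unmatched_gt: list[int]
    iou_thr: float


@dataclass
class EvalReport:
    """Detection performance counts and derived rates.

    ``sensitivity`` is None when there are no reference boxes and ``ppv``/
    ``fp_fraction`` are None when nothing was predicted (the rates are
    undefined, not zero).
    """

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    fp_fraction: float | None
    fp_per_mm2: float | None = None


def _as_box(obj) -> BoundingBox:
    return obj.box if isinstance(obj, Detection) else obj


def _confidence(obj) -> float:
    return obj.confidence if isinstance(obj, Detection) else 1.0


def match_detections(
    pred: list[Detection] | list[BoundingBox],
    reference: list[BoundingBox] | list[Detection],
    iou_thr: float = 0.3,
) -> MatchResult:
    """Greedy one-to-one matching by descending prediction confidence.

    Each prediction, in confidence order, claims the highest-IoU unclaimed
    reference box provided IoU >= ``iou_thr``.  The default threshold of
    0.3 suits very small objects, for which stricter overlap criteria
    penalize one-pixel localization offsets disproportionately.
    """
    ref_boxes = [_as_box(r) for r in reference]
    order = sorted(
        range(len(pred)), key=lambda i: (-_confidence(pred[i]), i)
    )
    claimed: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    unmatched_pred: list[int] = []
    for i in order:
        box = _as_box(pred[i])
        best_j, best_iou = -1, 0.0
        for j, ref in enumerate(ref_boxes):
            if j in claimed:
                continue
            v = iou(box, ref)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thr:
            claimed.add(best_j)
            pairs.append((i, best_j, best_iou))
        else:
            unmatched_pred.append(i)
    unmatched_gt = [j for j in range(len(ref_boxes)) if j not in claimed]
    return MatchResult(pairs, unmatched_pred, unmatched_gt, iou_thr)


def detection_metrics(
    match: MatchResult, evaluated_area_mm2: float | None = None
) -> EvalReport:
    """Reduce a match result to tp/fp/fn and the derived rates."""
    tp = len(match.pairs)
    fp = len(match.unmatched_pred)
    fn = len(match.unmatched_gt)
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    fp_fraction = fp / (tp + fp) if (tp + fp) > 0 else None
    fp_per_mm2 = (
        fp / evaluated_area_mm2 if evaluated_area_mm2 and evaluated_area_mm2 > 0 else None
    )
    return EvalReport(tp, fp, fn, sensitivity, ppv, fp_fraction, fp_per_mm2)


def density_correlation(
    network_densities, reference_densities
) -> tuple[float, float, float]:
    """OLS fit of network vs. reference densities: (slope, intercept, R^2)."""
    y = np.asarray(network_densities, dtype=float)
    x = np.asarray(reference_densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in reference densities: R^2 undefined")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need >= 2 groups")
    for label, vals in clean.items():
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError(f"group {label!r} needs n >= 2 observations")
    return clean


def one_way_anova(groups: dict[str, list[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Partitions total sum of squares into between-group and within-group
    components; F = MS_between / MS_within, p from the F distribution.
    """
    clean = _validate_groups(groups)
    all_vals = np.concatenate(list(clean.values()))
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in clean.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in clean.values())
    df_between = len(clean) - 1
    df_within = all_vals.size - len(clean)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else np.inf
    else:
        f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), df_between, df_within, p, float(ms_within))


def tukey_hsd(groups: dict[str, list[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's Honestly Significant Difference test for all group pairs.

    Uses the Tukey-Kramer standard error ``sqrt(MSW/2 * (1/ni + 1/nj))``
    so unequal group sizes are handled; adjusted p-values come from the
    studentized range distribution with k groups and the ANOVA's within
    degrees of freedom.
    """
    clean = _validate_groups(groups)
    anova = one_way_anova(groups)
    k = len(clean)
    labels = list(clean.keys())
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = clean[labels[a]], clean[labels[b]]
            diff = float(va.mean() - vb.mean())
            se = np.sqrt(anova.ms_within / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
            else:
                q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
            rows.append(
                {
                    "group_a": labels[a],
                    "group_b": labels[b],
                    "diff": diff,
                    "se": float(se),
                    "q": float(q),
                    "p_adj": min(p_adj, 1.0),
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)
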