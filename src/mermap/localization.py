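"""Maximum-parameter target localization and its evaluation.

The working hypothesis: the depth (and trajectory) at which a parameter
attains its maximum marks the target. Detection accuracy counts exact
coincidences with ground truth; discrimination is additionally scored with
trapezoidal ROC/AUC (Hanley-McNeil standard error) and feature-to-clinical
Pearson correlations under Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .data_model import FEATURE_NAMES, TRAJECTORIES, SiteFeatures, SiteKey, ValidationError


@dataclass
class DepthPrediction:
    depth_mm: Optional[int]
    tie: bool = False
    note: str = ""


@dataclass
class LocationPrediction:
    trajectory: Optional[str]
    tie: bool = False
    note: str = ""


@dataclass
class ClinicalCorrelation:
    feature_name: str
    score_name: str
    r: float
    p: float
    p_bonferroni: float
    n: int


@dataclass
class LocalizationReport:
    """Per-parameter localization outcome for one or more sessions."""

    depth_predictions: Dict[str, Dict[str, DepthPrediction]] = field(default_factory=dict)
    location_predictions: Dict[str, LocationPrediction] = field(default_factory=dict)
    depth_accuracy: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    location_accuracy: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    auc: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)


def predict_depth(
    values_by_depth: Mapping[int, float],
    region_mask: Optional[Sequence[int]] = None,
) -> DepthPrediction:
    """Depth with the maximum parameter value.

    ``region_mask`` optionally restricts which depths compete. Ties break
    toward the dorsal-most (most negative) depth and are flagged. All-NaN
    input yields a missing prediction (counted as a failure downstream).
    """
    depths = sorted(values_by_depth)
    if region_mask is not None:
        depths = [d for d in depths if d in set(region_mask)]
    vals = np.array([values_by_depth[d] for d in depths], dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() == 0:
        return DepthPrediction(depth_mm=None, note="all values missing")
    if ok.sum() < 2:
        return DepthPrediction(depth_mm=None, note="fewer than 2 usable depths")
    vmax = np.nanmax(vals)
    winners = [d for d, v in zip(depths, vals) if not math.isnan(v) and v == vmax]
    tie = len(winners) > 1
    return DepthPrediction(
        depth_mm=winners[0], tie=tie, note="tie" if tie else ""
    )


def predict_location(
    values_by_trajectory: Mapping[str, float],
) -> LocationPrediction:
    """Trajectory with the maximum parameter value (each at its own best
    depth). Ties break by the fixed trajectory order and are flagged."""
    usable = {
        t: v for t, v in values_by_trajectory.items() if v is not None and not math.isnan(v)
    }
    if len(usable) < 2:
        return LocationPrediction(trajectory=None, note="fewer than 2 usable trajectories")
    vmax = max(usable.values())
    winners = [t for t in TRAJECTORIES if t in usable and usable[t] == vmax]
    tie = len(winners) > 1
    return LocationPrediction(
        trajectory=winners[0], tie=tie, note="tie" if tie else ""
    )


def detection_accuracy(
    predictions: Sequence[object], truths: Sequence[object]
) -> Tuple[float, str]:
    """Fraction and "x/y" string of exact prediction/truth matches."""
    if len(predictions) != len(truths):
        raise ValidationError("predictions and truths must pair up")
    if not predictions:
        raise ValidationError("empty prediction set")
    hits = sum(1 for p, t in zip(predictions, truths) if p is not None and p == t)
    return hits / len(predictions), f"{hits}/{len(predictions)}"


def roc_auc(
    values: Sequence[float], labels: Sequence[int]
) -> Tuple[float, float]:
    """Trapezoidal AUC with the Hanley-McNeil standard error.

    ``labels`` are binary (1 = target region). Equals the Mann-Whitney
    statistic U / (n1 n0).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.size != y.size or v.size == 0:
        raise ValidationError("values and labels must pair up")
    pos, neg = v[y == 1], v[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    thresholds = np.concatenate(([math.inf], np.unique(v)[::-1], [-math.inf]))
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    auc = float(np.trapezoid(tpr, fpr))
    n1, n0 = pos.size, neg.size
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return auc, float(math.sqrt(max(var, 0.0)))


def mann_whitney_auc(values: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney U statistic (tie-corrected)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = v[y == 1], v[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def correlate_clinical(
    feature_values: Sequence[float],
    scores: Sequence[float],
    family_size: int,
    feature_name: str = "feature",
    score_name: str = "score",
) -> ClinicalCorrelation:
    """Pearson r with two-sided p and Bonferroni-corrected p."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant vector has no correlation")
    r, p = stats.pearsonr(x, y)
    return ClinicalCorrelation(
        feature_name=feature_name,
        score_name=score_name,
        r=float(r),
        p=float(p),
        p_bonferroni=min(1.0, float(p) * family_size),
        n=x.size,
    )


# ---------------------------------------------------------------------------
# session-level evaluation
# ---------------------------------------------------------------------------

def _values_by_depth(
    features: Mapping[SiteKey, SiteFeatures], trajectory: str, parameter: str
) -> Dict[int, float]:
    return {
        depth: feats.get(parameter)
        for (traj, depth), feats in features.items()
        if traj == trajectory
    }


def localize_session(
    features: Mapping[SiteKey, SiteFeatures],
    parameter: str,
    region_masks: Optional[Mapping[str, Sequence[int]]] = None,
) -> Tuple[Dict[str, DepthPrediction], LocationPrediction]:
    """Per-trajectory depth prediction plus cross-trajectory location.

    Each trajectory contributes its own best depth's value to the location
    comparison.
    """
    if parameter not in FEATURE_NAMES:
        raise ValidationError(f"unknown parameter {parameter!r}")
    trajs = sorted({traj for traj, _ in features}, key=TRAJECTORIES.index)
    depth_preds: Dict[str, DepthPrediction] = {}
    best_values: Dict[str, float] = {}
    for traj in trajs:
        vals = _values_by_depth(features, traj, parameter)
        mask = region_masks.get(traj) if region_masks else None
        pred = predict_depth(vals, region_mask=mask)
        depth_preds[traj] = pred
        if pred.depth_mm is not None:
            best_values[traj] = vals[pred.depth_mm]
        else:
            best_values[traj] = math.nan
    return depth_preds, predict_location(best_values)


def evaluate_sessions(
    feature_maps: Sequence[Mapping[SiteKey, SiteFeatures]],
    truths: Sequence[object],
    parameters: Sequence[str] = FEATURE_NAMES,
) -> LocalizationReport:
    """Score depth (STN/SNr) and location detection across sessions.

    STN depth success: the argmax over the target trajectory's full depth
    series equals the true target depth. SNr success (evaluated only when
    the parameter is computable on >= 2 SNr-span depths) compares against
    the trajectory's SNr peak depth. Location success: predicted trajectory
    equals the true one.
    """
    if len(feature_maps) != len(truths):
        raise ValidationError("feature maps and truths must pair up")
    report = LocalizationReport()
    for parameter in parameters:
        stn_hits = stn_total = 0
        snr_hits = snr_total = 0
        loc_hits = loc_total = 0
        for features, truth in zip(feature_maps, truths):
            depth_preds, loc_pred = localize_session(features, parameter)
            traj = truth.true_target_trajectory
            # STN depth detection on the target trajectory's full series
            stn_total += 1
            pred = depth_preds.get(traj)
            if pred is not None and pred.depth_mm == truth.true_target_depth_mm:
                stn_hits += 1
            # SNr depth detection, restricted to the SNr span
            snr_depths = [
                d for (t, d), r in truth.region.items() if t == traj and r == "snr"
            ]
            vals = _values_by_depth(features, traj, parameter)
            computable = [
                d for d in snr_depths if d in vals and not math.isnan(vals[d])
            ]
            if len(computable) >= 2:
                snr_total += 1
                snr_pred = predict_depth(vals, region_mask=snr_depths)
                if snr_pred.depth_mm == truth.snr_peak_depth.get(traj):
                    snr_hits += 1
            # location detection
            loc_total += 1
            if loc_pred.trajectory == traj:
                loc_hits += 1
        report.depth_accuracy[parameter] = (stn_hits, stn_total)
        report.depth_accuracy[parameter + "_snr"] = (snr_hits, snr_total)
        report.location_accuracy[parameter] = (loc_hits, loc_total)
    return report


def roc_per_parameter(
    features: Mapping[SiteKey, SiteFeatures],
    region: Mapping[SiteKey, str],
    positive_region: str = "stn",
    parameters: Sequence[str] = FEATURE_NAMES,
) -> Dict[str, Tuple[float, float]]:
    """AUC ± SE per parameter, positives = sites in ``positive_region``."""
    out: Dict[str, Tuple[float, float]] = {}
    for parameter in parameters:
        vals, labels = [], []
        for key, feats in features.items():
            v = feats.get(parameter)
            if math.isnan(v):
                continue
            vals.append(v)
            labels.append(1 if region[key] == positive_region else 0)
        if len(set(labels)) < 2:
            continue
        out[parameter] = roc_auc(vals, labels)
    return out
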