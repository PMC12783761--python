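"""Model-comparison statistics for binary progression scores.

ROC AUC with DeLong structural-component variance and Wald confidence
intervals, Youden-optimal cutoffs and confusion metrics, integrated
discrimination improvement (IDI) and continuous net reclassification
improvement (NRI) with asymptotic z-tests, decision-curve net benefit,
calibration curves, stratified 5-fold cross-validation, and unpaired DeLong
comparison of subgroup AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScoreSet", "RocResult", "ComparisonResult", "DecisionCurve",
    "CalibrationCurve", "CutoffResult", "ConfusionMetrics",
    "roc_auc_delong", "optimal_cutoff", "confusion_metrics", "idi_nri",
    "decision_curve", "calibration_curve", "crossval_5fold",
    "stratified_compare",
]


@dataclass
class ScoreSet:
    """Predicted probabilities with binary labels and optional subgroups."""

    scores: np.ndarray
    labels: np.ndarray
    subgroups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass
class RocResult:
    auc: float
    variance: float
    ci95: tuple[float, float]


@dataclass
class ComparisonResult:
    idi: float
    idi_z: float
    idi_p: float
    nri: float
    nri_z: float
    nri_p: float


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray
    event_rate: np.ndarray
    counts: np.ndarray


@dataclass
class CutoffResult:
    threshold: float
    youden: float
    degenerate: bool


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    undefined: list[str]


# ---------------------------------------------------------------------------
# DeLong AUC
# ---------------------------------------------------------------------------

def _placements(s: ScoreSet) -> tuple[np.ndarray, np.ndarray, float]:
    pos = s.scores[s.labels == 1]
    neg = s.scores[s.labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)          # one structural component per positive
    v01 = cmp.mean(axis=0)          # one per negative
    return v10, v01, float(cmp.mean())


def roc_auc_delong(s: ScoreSet) -> RocResult:
    """AUC with DeLong structural-components variance and Wald 95% CI.

    Ties count one half; a degenerate (zero-variance) score configuration
    yields a zero-width interval at the AUC.
    """
    s.require_both_classes()
    v10, v01, auc = _placements(s)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    return RocResult(auc=float(auc), variance=float(var), ci95=ci)


def delong_unpaired_test(a: ScoreSet, b: ScoreSet) -> tuple[float, float]:
    """Unpaired DeLong z-test between two independent AUCs."""
    ra, rb = roc_auc_delong(a), roc_auc_delong(b)
    denom = np.sqrt(ra.variance + rb.variance)
    if denom == 0:
        return 0.0, 1.0
    z = (ra.auc - rb.auc) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cutoffs and confusion metrics
# ---------------------------------------------------------------------------

def optimal_cutoff(train: ScoreSet) -> CutoffResult:
    """Youden-maximizing threshold over midpoints of adjacent unique scores.

    Ties break toward the lower threshold; a single unique score value is a
    degenerate case and is returned as-is with Youden 0.  A best Youden <= 0
    (label-inverted scores) is flagged degenerate with a warning.
    """
    train.require_both_classes()
    uniq = np.unique(train.scores)
    if len(uniq) == 1:
        return CutoffResult(threshold=float(uniq[0]), youden=0.0,
                            degenerate=True)
    mids = (uniq[:-1] + uniq[1:]) / 2
    pos = train.scores[train.labels == 1]
    neg = train.scores[train.labels == 0]
    best_t, best_j = mids[0], -np.inf
    for t in mids:
        sens = (pos >= t).mean()
        spec = (neg < t).mean()
        j = sens + spec - 1
        if j > best_j:           # strict: lower threshold wins ties
            best_t, best_j = t, j
    degenerate = best_j <= 0
    if degenerate:
        warnings.warn("optimal cutoff has Youden <= 0 (scores may be "
                      "label-inverted)", RuntimeWarning, stacklevel=2)
    return CutoffResult(threshold=float(best_t), youden=float(best_j),
                        degenerate=bool(degenerate))


def confusion_metrics(s: ScoreSet, threshold: float) -> ConfusionMetrics:
    """Confusion counts and ratios at ``score >= threshold => positive``."""
    if len(s.scores) == 0:
        raise ValueError("empty score set")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = s.scores >= threshold
    tp = int(np.sum(pred & (s.labels == 1)))
    fp = int(np.sum(pred & (s.labels == 0)))
    fn = int(np.sum(~pred & (s.labels == 1)))
    tn = int(np.sum(~pred & (s.labels == 0)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=undefined)


# ---------------------------------------------------------------------------
# IDI / NRI
# ---------------------------------------------------------------------------

def idi_nri(old: ScoreSet, new: ScoreSet) -> ComparisonResult:
    """IDI and continuous (category-free) NRI with asymptotic z-tests.

    IDI is the change in discrimination slope; NRI sums the net proportions
    of events whose score moved up and nonevents whose score moved down.
    Antisymmetric: swapping old and new negates both.
    """
    if len(old.scores) != len(new.scores) or \
            not np.array_equal(old.labels, new.labels):
        raise ValueError("old and new must score the same subjects")
    ev = old.labels == 1
    ne = ~ev
    if ev.sum() == 0 or ne.sum() == 0:
        raise ValueError("both classes must be present")
    d = new.scores - old.scores
    idi = float(d[ev].mean() - d[ne].mean())
    se_idi = np.sqrt(
        (d[ev].var(ddof=1) / ev.sum() if ev.sum() > 1 else 0.0)
        + (d[ne].var(ddof=1) / ne.sum() if ne.sum() > 1 else 0.0))
    idi_z = idi / se_idi if se_idi > 0 else 0.0
    idi_p = float(2 * stats.norm.sf(abs(idi_z))) if se_idi > 0 else 1.0

    def net(mask):
        up = float((d[mask] > 0).mean())
        down = float((d[mask] < 0).mean())
        var = (up + down - (up - down) ** 2) / mask.sum()
        return up, down, var

    up_e, down_e, var_e = net(ev)
    up_n, down_n, var_n = net(ne)
    nri = (up_e - down_e) + (down_n - up_n)
    se_nri = np.sqrt(var_e + var_n)
    nri_z = nri / se_nri if se_nri > 0 else 0.0
    nri_p = float(2 * stats.norm.sf(abs(nri_z))) if se_nri > 0 else 1.0
    return ComparisonResult(idi=idi, idi_z=float(idi_z), idi_p=idi_p,
                            nri=float(nri), nri_z=float(nri_z), nri_p=nri_p)


# ---------------------------------------------------------------------------
# decision and calibration curves
# ---------------------------------------------------------------------------

def decision_curve(s: ScoreSet,
                   thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) over a threshold grid.

    Default grid 0.01..0.60 in steps of 0.01; treat-all and treat-none
    references included.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.601, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any() or (thresholds >= 1).any():
        raise ValueError("thresholds must lie in [0, 1)")
    n = len(s.scores)
    pi = float((s.labels == 1).mean())
    nb = np.empty(len(thresholds))
    for i, pt in enumerate(thresholds):
        pred = s.scores >= pt
        tp = np.sum(pred & (s.labels == 1)) / n
        fp = np.sum(pred & (s.labels == 0)) / n
        odds = pt / (1 - pt)
        nb[i] = tp - fp * odds
    treat_all = pi - (1 - pi) * thresholds / (1 - thresholds)
    return DecisionCurve(thresholds=thresholds, net_benefit=nb,
                         treat_all=treat_all,
                         treat_none=np.zeros_like(thresholds))


def calibration_curve(s: ScoreSet, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width bins on [0, 1]: mean prediction vs observed event rate."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(s.scores, edges[1:-1]), 0, n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    rate = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            mean_pred[b] = s.scores[mask].mean()
            rate[b] = s.labels[mask].mean()
    return CalibrationCurve(bin_edges=edges, mean_predicted=mean_pred,
                            event_rate=rate, counts=counts)


# ---------------------------------------------------------------------------
# cross-validation and stratified analysis
# ---------------------------------------------------------------------------

def crossval_5fold(images: np.ndarray, labels: np.ndarray,
                   fit_score: Callable[[np.ndarray, np.ndarray, np.ndarray],
                                       np.ndarray],
                   seed: int = 0, n_folds: int = 5, max_redraws: int = 10
                   ) -> tuple[list[float], float, float]:
    """Stratified k-fold AUCs of a fit-and-score pipeline.

    ``fit_score(train_images, train_labels, test_images)`` must refit the
    whole pipeline per fold and return test scores.  A fold whose validation
    side lacks a class triggers a redraw with the next sub-seed (logged via
    warning).  Returns (per-fold AUCs, mean, SD).
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    if len(labels) < 10:
        raise ValueError("need >= 10 records for cross-validation")
    for redraw in range(max_redraws):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + redraw)
        folds = list(skf.split(np.zeros(len(labels)), labels))
        if all(len(np.unique(labels[va])) == 2 for _, va in folds):
            break
        warnings.warn(f"single-class fold at sub-seed {seed + redraw}; "
                      "redrawing", RuntimeWarning, stacklevel=2)
    else:
        raise ValueError("could not stratify folds with both classes")
    aucs = []
    for tr, va in folds:
        scores = fit_score(images[tr], labels[tr], images[va])
        aucs.append(roc_auc_delong(ScoreSet(scores, labels[va])).auc)
    arr = np.asarray(aucs)
    return aucs, float(arr.mean()), float(arr.std(ddof=1))


def stratified_compare(s: ScoreSet, tag: str
                       ) -> tuple[dict[str, RocResult], float, float]:
    """Per-stratum AUCs plus an unpaired two-tailed DeLong test.

    Strata with a single outcome class are excluded with a warning; exactly
    two valid strata are compared.
    """
    if tag not in s.subgroups:
        raise KeyError(f"no subgroup tag {tag!r}")
    values = np.asarray(s.subgroups[tag])
    per: dict[str, RocResult] = {}
    sets: dict[str, ScoreSet] = {}
    for level in np.unique(values):
        mask = values == level
        sub = ScoreSet(s.scores[mask], s.labels[mask])
        if len(np.unique(sub.labels)) < 2:
            warnings.warn(f"stratum {level!r} of {tag!r} has a single "
                          "class; excluded", RuntimeWarning, stacklevel=2)
            continue
        per[str(level)] = roc_auc_delong(sub)
        sets[str(level)] = sub
    if len(sets) != 2:
        raise ValueError(f"need exactly 2 valid strata, got {len(sets)}")
    a, b = (sets[k] for k in sorted(sets))
    z, p = delong_unpaired_test(a, b)
    return per, z, p
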