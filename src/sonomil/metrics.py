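"""Diagnostic-accuracy statistics for patient-level prediction models.

Implements the evaluation stack used around the two-stage model: rank
AUC, threshold metrics, the paired DeLong test for correlated ROC
curves, PR curves, decision-curve analysis (net benefit), segmentation
mIoU, Pearson chi-square cohort comparisons and the clinical logistic
baseline on BI-RADS grade and clinical T stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve

BIRADS_LEVELS = ("4A", "4B", "4C", "5")
T_STAGE_LEVELS = ("T1", "T2", "T3", "T4")


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels.astype(int)


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney statistic (ties count 1/2)."""
    scores, labels = _check_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    f1: float = field(init=False)
    mistake_rate: float = field(init=False)
    omission_rate: float = field(init=False)

    def __post_init__(self):
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        n = tp + fp + tn + fn

        def frac(a, b):
            return a / b if b else float("nan")

        self.accuracy = frac(tp + tn, n)
        self.sensitivity = frac(tp, tp + fn)
        self.specificity = frac(tn, tn + fp)
        self.ppv = frac(tp, tp + fp)
        self.npv = frac(tn, tn + fn)
        self.f1 = frac(2 * tp, 2 * tp + fp + fn)
        self.mistake_rate = frac(fp, fp + tn)    # 1 - specificity
        self.omission_rate = frac(fn, fn + tp)   # 1 - sensitivity


def confusion_at(scores, labels, threshold: float = 0.5) -> ConfusionSummary:
    """Threshold metrics with predicted-positive = (score >= threshold)."""
    scores, labels = _check_scores(scores, labels)
    pred = scores >= threshold
    return ConfusionSummary(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing sensitivity + specificity - 1."""
    scores, labels = _check_scores(scores, labels)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        c = confusion_at(scores, labels, t)
        j = c.sensitivity + c.specificity - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# -- DeLong test -----------------------------------------------------------


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong comparison of two correlated AUCs.

    Returns ``(auc_a, auc_b, cov, z, p)`` where ``cov`` is the 2x2
    variance-covariance matrix of the AUC estimates from the structural
    components, ``z = (auc_a - auc_b) / se`` and ``p`` is the two-sided
    normal p-value. Identical score vectors give z = 0, p = 1.
    """
    scores_a, labels = _check_scores(scores_a, labels)
    scores_b, labels_b = _check_scores(scores_b, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired test requires equal-length score vectors")
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValueError("labels must contain both classes")
    v10 = np.empty((2, pos.sum()))
    v01 = np.empty((2, (~pos).sum()))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        v10[i], v01[i] = _structural_components(s[pos], s[~pos])
        aucs[i] = v10[i].mean()
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var_diff <= np.finfo(float).eps:
        z = 0.0
        p = 1.0
    else:
        z = float(delta / np.sqrt(var_diff))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), cov, z, p


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    scores, labels = _check_scores(scores, labels)
    pos = labels == 1
    v10, v01 = _structural_components(scores[pos], scores[~pos])
    m, n = len(v10), len(v01)
    var10 = v10.var(ddof=1) if m > 1 else 0.0
    var01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(var10 / m + var01 / n)


def auc_ci(scores, labels, level: float = 0.95):
    """AUC with a normal-approximation confidence interval (DeLong SE)."""
    auc = roc_auc(scores, labels)
    se = np.sqrt(auc_variance(scores, labels))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return auc, max(auc - zq * se, 0.0), min(auc + zq * se, 1.0)


# -- PR and decision curves -----------------------------------------------


def pr_curve(scores, labels):
    """Precision-recall points and step-integrated average precision."""
    scores, labels = _check_scores(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PR analysis requires positive cases")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    ap = float(average_precision_score(labels, scores))
    return precision, recall, thresholds, ap


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray


def dca(scores, labels, thresholds=None) -> DcaCurve:
    """Decision curve analysis: net benefit over threshold probabilities.

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt) with predicted-positive =
    (score >= pt); treat-all uses the all-positive counts and
    treat-none is identically zero.
    """
    scores, labels = _check_scores(scores, labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    n_pos = labels.sum()
    n_neg = n - n_pos
    odds = thresholds / (1.0 - thresholds)
    tp = np.array([(scores >= t)[labels == 1].sum() for t in thresholds])
    fp = np.array([(scores >= t)[labels == 0].sum() for t in thresholds])
    nb_model = tp / n - fp / n * odds
    nb_all = n_pos / n - n_neg / n * odds
    return DcaCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


# -- segmentation ---------------------------------------------------------


def miou(pred_masks, gt_masks, threshold: float = 0.5,
         include_background: bool = False) -> float:
    """Mean per-image foreground IoU of predicted probability maps.

    An image where prediction and ground truth are both empty counts as
    IoU 1. With ``include_background`` the two-class (foreground and
    background) mean IoU is returned instead.
    """
    ious = []
    for pred, gt in zip(pred_masks, gt_masks, strict=True):
        pred = np.asarray(pred)
        gt = np.asarray(gt).astype(bool)
        if pred.shape != gt.shape:
            raise ValueError("prediction/ground-truth shape mismatch")
        pb = pred >= threshold if pred.dtype != bool else pred

        def iou(a, b):
            union = (a | b).sum()
            return 1.0 if union == 0 else (a & b).sum() / union

        fg = iou(pb, gt)
        ious.append((fg + iou(~pb, ~gt)) / 2.0 if include_background else fg)
    return float(np.mean(ious))


# -- chi-square ------------------------------------------------------------


def chi_square(table, correction: bool = False):
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (matching the cohort-comparison
    convention used throughout); returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# -- clinical logistic baseline -------------------------------------------


@dataclass
class ClinicalRecord:
    birads: str    # one of BIRADS_LEVELS
    t_stage: str   # one of T_STAGE_LEVELS
    label: int


def _clinical_design(records: list[ClinicalRecord]) -> np.ndarray:
    """One-hot design with first-level reference (4A, T1) plus intercept."""
    rows = []
    for r in records:
        if r.birads not in BIRADS_LEVELS:
            raise ValueError(f"unknown BI-RADS grade: {r.birads!r}")
        if r.t_stage not in T_STAGE_LEVELS:
            raise ValueError(f"unknown T stage: {r.t_stage!r}")
        row = [1.0]
        row += [1.0 if r.birads == lv else 0.0 for lv in BIRADS_LEVELS[1:]]
        row += [1.0 if r.t_stage == lv else 0.0 for lv in T_STAGE_LEVELS[1:]]
        rows.append(row)
    return np.asarray(rows)


CLINICAL_COEF_NAMES = (
    ["intercept"]
    + [f"birads_{lv}" for lv in BIRADS_LEVELS[1:]]
    + [f"t_stage_{lv}" for lv in T_STAGE_LEVELS[1:]]
)


@dataclass
class ClinicalModel:
    coef: np.ndarray
    coef_se: np.ndarray | None
    converged: bool

    def predict(self, records: list[ClinicalRecord]) -> np.ndarray:
        x = _clinical_design(records)
        logit = x @ self.coef
        return 1.0 / (1.0 + np.exp(-logit))


def fit_clinical_model(records: list[ClinicalRecord]) -> ClinicalModel:
    """Maximum-likelihood logistic regression of label on BI-RADS + T stage.

    Falls back to a ridge-stabilised fit (with a warning) under complete
    separation or non-convergence.
    """
    import statsmodels.api as sm

    x = _clinical_design(records)
    y = np.array([r.label for r in records], dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("did not converge")
        return ClinicalModel(coef=np.asarray(fit.params),
                             coef_se=np.asarray(fit.bse), converged=True)
    except Exception:
        warnings.warn("logistic fit unstable (possible separation); "
                      "using ridge-stabilised fallback", stacklevel=2)
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=100.0, fit_intercept=False, max_iter=2000)
        lr.fit(x, y)
        return ClinicalModel(coef=lr.coef_.ravel(), coef_se=None,
                             converged=False)


def simulate_clinical_records(n: int, coef: np.ndarray,
                              rng: np.random.Generator,
                              level_probs=None) -> list[ClinicalRecord]:
    """Draw records with known log-odds (for calibration / recovery tests)."""
    coef = np.asarray(coef, dtype=np.float64)
    if level_probs is None:
        birads_p = (0.1, 0.2, 0.4, 0.3)
        t_p = (0.3, 0.55, 0.1, 0.05)
    else:
        birads_p, t_p = level_probs
    records = []
    for _ in range(n):
        b = BIRADS_LEVELS[rng.choice(4, p=birads_p)]
        t = T_STAGE_LEVELS[rng.choice(4, p=t_p)]
        rec = ClinicalRecord(b, t, 0)
        eta = float((_clinical_design([rec]) @ coef)[0])
        rec.label = int(rng.uniform() < 1.0 / (1.0 + np.exp(-eta)))
        records.append(rec)
    return records


# -- report assembly -------------------------------------------------------

METRIC_COLUMNS = ["auc", "auc_lo", "auc_hi", "accuracy", "sensitivity",
                  "specificity", "ppv", "npv", "f1"]


def model_report(model_scores: dict[str, np.ndarray], labels,
                 threshold: float = 0.5) -> pd.DataFrame:
    """Per-model threshold metrics plus AUC with DeLong CI (one row each)."""
    rows = []
    for name, scores in model_scores.items():
        auc, lo, hi = auc_ci(scores, labels)
        c = confusion_at(scores, labels, threshold)
        rows.append({"model": name, "auc": auc, "auc_lo": lo, "auc_hi": hi,
                     "accuracy": c.accuracy, "sensitivity": c.sensitivity,
                     "specificity": c.specificity, "ppv": c.ppv,
                     "npv": c.npv, "f1": c.f1, "tp": c.tp, "fp": c.fp,
                     "tn": c.tn, "fn": c.fn})
    return pd.DataFrame(rows)


def pairwise_delong(model_scores: dict[str, np.ndarray], labels) -> pd.DataFrame:
    rows = []
    names = list(model_scores)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            auc_a, auc_b, _, z, p = delong_test(model_scores[a],
                                                model_scores[b], labels)
            rows.append({"model_a": a, "model_b": b, "auc_a": auc_a,
                         "auc_b": auc_b, "z": z, "p": p})
    return pd.DataFrame(rows)
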