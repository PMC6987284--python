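"""Diagnostic-accuracy reporting: confusion-matrix metrics, exact binomial
confidence intervals, ROC/AUC from the discrete P(+) score, and the crossed
A/B evaluation.

Point estimates are kept at full precision internally; the display layer
rounds half-up to integer percent (and likelihood ratios to integers),
matching the convention of clinical diagnostic-accuracy tables.  Confidence
intervals are exact Clopper-Pearson intervals from beta quantiles — the
only common binomial interval that reproduces the degenerate x = n bounds
(e.g. lower bound 87% for 27/27).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import knn
from .twist import TwistResult, _split_table


def round_half_up(x: float) -> int:
    """Display rounding: 0.5 always rounds away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    return ConfusionMatrix(int((t & p).sum()), int((~t & ~p).sum()),
                           int((~t & p).sum()), int((t & ~p).sum()))


def _ratio(num: int, den: int):
    return 100.0 * num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> dict:
    """Point estimates in percent (full precision; LRs as plain ratios).

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    sens = _ratio(cm.TP, cm.TP + cm.FN)
    spec = _ratio(cm.TN, cm.TN + cm.FP)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": _ratio(cm.TP + cm.TN, cm.total),
        "ppv": _ratio(cm.TP, cm.TP + cm.FP),
        "npv": _ratio(cm.TN, cm.TN + cm.FN),
    }
    if sens is None or spec is None:
        out["lr_positive"] = None
        out["lr_negative"] = None
    else:
        s, c = sens / 100.0, spec / 100.0
        out["lr_positive"] = s / (1.0 - c) if c < 1.0 else None
        out["lr_negative"] = (1.0 - s) / c if c > 0.0 else None
    return out


def display_metrics(m: dict) -> dict:
    """Half-up integer rendering of a metrics dict (Table-style display)."""
    out = {}
    for key, val in m.items():
        if val is None:
            out[key] = "n/a"
        elif key.startswith("lr_"):
            out[key] = str(round_half_up(val))
        else:
            out[key] = f"{round_half_up(val)}%"
    return out


def clopper_pearson(successes: int, n: int, confidence: float = 0.95):
    """Exact binomial CI in percent, via beta quantiles.

    x = 0 gives lower = 0; x = n gives upper = 100 and lower =
    100 * (alpha/2)^(1/n); the interval is symmetric under x <-> n - x.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    return 100.0 * lo, 100.0 * hi


def proportion_cis(cm: ConfusionMatrix, confidence: float = 0.95) -> dict:
    """Clopper-Pearson CIs for each defined proportion metric."""
    pairs = {
        "sensitivity": (cm.TP, cm.TP + cm.FN),
        "specificity": (cm.TN, cm.TN + cm.FP),
        "accuracy": (cm.TP + cm.TN, cm.total),
        "ppv": (cm.TP, cm.TP + cm.FP),
        "npv": (cm.TN, cm.TN + cm.FN),
    }
    return {name: (clopper_pearson(x, n, confidence) if n > 0 else None)
            for name, (x, n) in pairs.items()}


def roc_auc(p_values, labels):
    """ROC points and trapezoidal AUC from the discrete P(+) scores.

    Thresholds sweep the distinct score values (predict positive when
    score >= t), producing a step curve from (0, 0) to (1, 1); the AUC is
    the trapezoidal area, which equals the tie-corrected rank statistic
    (concordant + ties/2) / (n+ * n-).
    """
    p = np.asarray(p_values, dtype=float)
    y = np.asarray(labels, dtype=bool) if np.asarray(labels).dtype == bool \
        else knn._as_labels(labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    points = [(0.0, 0.0)]
    for t in sorted(np.unique(p))[::-1]:
        pred = p >= t
        tpr = float((pred & y).sum()) / n_pos
        fpr = float((pred & ~y).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return points, auc


@dataclass
class ArmResult:
    name: str
    cm: ConfusionMatrix
    metrics: dict
    cis: dict
    roc_points: list
    auc: float


@dataclass
class DiagnosticReport:
    """Machine-readable twin of a crossed-evaluation performance table."""

    arms: dict                   # "A->B", "B->A" -> ArmResult
    pooled_cm: ConfusionMatrix
    pooled_metrics: dict
    pooled_cis: dict
    auc_mean: float
    predictions: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def arm_dict(a: ArmResult) -> dict:
            return {
                "confusion": {"TP": a.cm.TP, "TN": a.cm.TN,
                              "FP": a.cm.FP, "FN": a.cm.FN},
                "metrics": a.metrics,
                "metrics_display": display_metrics(a.metrics),
                "ci95": {k: list(v) if v else None for k, v in a.cis.items()},
                "roc_points": [list(pt) for pt in a.roc_points],
                "auc": a.auc,
            }
        return {
            "arms": {name: arm_dict(a) for name, a in self.arms.items()},
            "pooled": {
                "confusion": {"TP": self.pooled_cm.TP, "TN": self.pooled_cm.TN,
                              "FP": self.pooled_cm.FP, "FN": self.pooled_cm.FN},
                "metrics": self.pooled_metrics,
                "metrics_display": display_metrics(self.pooled_metrics),
                "ci95": {k: list(v) if v else None
                         for k, v in self.pooled_cis.items()},
            },
            "auc_mean": self.auc_mean,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        """Render the crossed-evaluation grid (arms, totals, 95% CIs)."""
        names = list(self.arms)
        rows = []
        disp = {n: display_metrics(self.arms[n].metrics) for n in names}
        pooled_disp = display_metrics(self.pooled_metrics)
        ci = {k: (f"{round_half_up(v[0])}-{round_half_up(v[1])}" if v else "n/a")
              for k, v in self.pooled_cis.items()}
        metric_rows = [("Sensitivity", "sensitivity"), ("Specificity", "specificity"),
                       ("Accuracy", "accuracy"), ("Positive predictive value", "ppv"),
                       ("Negative predictive value", "npv")]
        for label, key in metric_rows:
            rows.append((label, *(disp[n][key] for n in names),
                         pooled_disp[key], ci.get(key, "")))
        cms = [self.arms[n].cm for n in names]
        for label, attr in [("True positives", "TP"), ("True negatives", "TN"),
                            ("False positives", "FP"), ("False negatives", "FN")]:
            rows.append((label, *(str(getattr(c, attr)) for c in cms),
                         str(getattr(self.pooled_cm, attr)), ""))
        for label, key in [("Positive likelihood ratio", "lr_positive"),
                           ("Negative likelihood ratio", "lr_negative")]:
            rows.append((label, *(disp[n][key] for n in names),
                         pooled_disp[key], ""))
        rows.append(("Area under the curve",
                     *(f"{self.arms[n].auc:.2f}" for n in names),
                     f"{self.auc_mean:.2f}", ""))
        header = ("Metric", *names, "Total", "95% CI (%)")
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join(["---"] * len(header)) + "|"]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines) + "\n"


def _evaluate_arm(name: str, table: pd.DataFrame, features: list,
                  train_idx: np.ndarray, test_idx: np.ndarray,
                  k: int) -> tuple:
    X, y, cols = _split_table(table)
    sel = [cols.index(f) for f in features]
    Xtr, ytr = X[train_idx][:, sel], y[train_idx]
    Xte, yte = X[test_idx][:, sel], y[test_idx]
    if ytr.all() or not ytr.any() or yte.all() or not yte.any():
        raise ValueError(f"arm {name}: a group lacks one of the classes")
    model = knn.fit(Xtr, ytr, k=k)
    probs = knn.predict_proba(model, Xte)
    pred = probs > 0.5
    cm = confusion_matrix(yte, pred)
    points, auc = roc_auc(probs, yte)
    arm = ArmResult(name, cm, metrics(cm), proportion_cis(cm), points, auc)
    pred_df = pd.DataFrame({
        "case_id": table.index.to_numpy()[test_idx],
        "arm": name,
        "p_positive": probs,
        "predicted_class": np.where(pred, "malignant", "benign"),
        "true_class": np.where(yte, "malignant", "benign"),
    })
    return arm, pred_df


def crossed_evaluation(table: pd.DataFrame, twist_result: TwistResult,
                       k: int = 3) -> DiagnosticReport:
    """Fit on A / predict B, fit on B / predict A (selected features only);
    pooled confusion matrix is the element-wise sum of the two arms, and the
    reported AUC summary is the mean of the per-arm AUCs."""
    ids = table.index.to_numpy().astype(str)
    in_a = np.isin(ids, twist_result.group_A)
    in_b = np.isin(ids, twist_result.group_B)
    if not (in_a | in_b).all() or (in_a & in_b).any():
        raise ValueError("groups A and B must partition the table")
    a_idx, b_idx = np.where(in_a)[0], np.where(in_b)[0]
    feats = list(twist_result.selected_features)
    arm_ab, pred_ab = _evaluate_arm("A->B", table, feats, a_idx, b_idx, k)
    arm_ba, pred_ba = _evaluate_arm("B->A", table, feats, b_idx, a_idx, k)
    pooled = arm_ab.cm + arm_ba.cm
    return DiagnosticReport(
        arms={"A->B": arm_ab, "B->A": arm_ba},
        pooled_cm=pooled,
        pooled_metrics=metrics(pooled),
        pooled_cis=proportion_cis(pooled),
        auc_mean=float(np.mean([arm_ab.auc, arm_ba.auc])),
        predictions=pd.concat([pred_ab, pred_ba], ignore_index=True),
    )
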