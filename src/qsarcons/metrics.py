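"""Classification and regression accuracy metrics.

Sens = TP/(FN+TP); Spec = TN/(TN+FP); Acc = (TP+TN)/all; BA = (Sens+Spec)/2;
RMSE = sqrt(mean squared error); R2 = 1 - SS_res/SS_tot with the reference
mean taken, by default, from the training set of the corresponding fold (the
convention for externally validated (Q)SAR models); the conventional
test-set-mean R2 is reported alongside under a distinct name.

Cells whose denominator is zero are NaN in memory and the explicit string
"NA" when serialized — never a silent zero.
"""

from __future__ import annotations

import numpy as np

ACTIVE, INACTIVE = "active", "inactive"


def confusion_counts(y_true, y_pred) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    tp = int(np.sum((y_true == ACTIVE) & (y_pred == ACTIVE)))
    fn = int(np.sum((y_true == ACTIVE) & (y_pred == INACTIVE)))
    tn = int(np.sum((y_true == INACTIVE) & (y_pred == INACTIVE)))
    fp = int(np.sum((y_true == INACTIVE) & (y_pred == ACTIVE)))
    return {"TP": tp, "FN": fn, "TN": tn, "FP": fp}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(y_true, y_pred) -> dict:
    """Confusion counts plus sensitivity, specificity, accuracy and BA."""
    c = confusion_counts(y_true, y_pred)
    sens = _safe_div(c["TP"], c["TP"] + c["FN"])
    spec = _safe_div(c["TN"], c["TN"] + c["FP"])
    acc = _safe_div(c["TP"] + c["TN"], sum(c.values()))
    ba = (sens + spec) / 2.0
    return {**c, "sensitivity": sens, "specificity": spec, "accuracy": acc, "balanced_accuracy": ba}


def regression_metrics(y_exp, y_pred, train_mean: float | None = None) -> dict:
    """RMSE and R2 of quantitative predictions.

    `train_mean` is the reference mean for R2 (the training-set mean of the
    fold that produced the predictions); `r2_test_mean` uses the evaluation
    set's own mean instead.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    if len(y_exp) < 2:
        raise ValueError("need at least 2 values")
    rss = float(np.sum((y_exp - y_pred) ** 2))
    rmse = float(np.sqrt(rss / len(y_exp)))
    tss_test = float(np.sum((y_exp - y_exp.mean()) ** 2))
    ref = y_exp.mean() if train_mean is None else float(train_mean)
    tss_ref = float(np.sum((y_exp - ref) ** 2))
    return {
        "rmse": rmse,
        "r2": _nan_if_zero_tss(rss, tss_ref),
        "r2_test_mean": _nan_if_zero_tss(rss, tss_test),
        "n": len(y_exp),
    }


def _nan_if_zero_tss(rss: float, tss: float) -> float:
    if tss == 0.0:
        return 1.0 if rss == 0.0 else float("nan")
    return 1.0 - rss / tss


def quantitative_to_class(p_pred, threshold_uM: float = 1.0, boundary_active: bool = True):
    """Map predicted p-values onto active/inactive with the curation threshold rule."""
    from .curation import label_class

    return label_class(p_pred, threshold_uM, boundary_active)


def serialize_value(x) -> object:
    """NaN -> "NA" for report files; everything else unchanged."""
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return x


def serializable_report(report: dict) -> dict:
    return {k: serialize_value(v) for k, v in report.items()}
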