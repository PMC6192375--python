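"""Fivefold external cross-validation, Y-randomization and the SAR-vs-QSAR
comparison.

`crossvalidate` runs the full benchmarking protocol on a curated dataset:
for each of the five sorted-cyclic folds a consensus model is built on the
other four and scored on the held-out fold; the report carries per-fold,
mean-over-folds and pooled metrics, the percent of test compounds inside
the applicability domain, and an explicit record of folds whose build ended
in the "no model" state (those folds are scored against the training-mean /
majority-class baseline and excluded from the model means).

`y_randomization` shuffles the response, refits a single model and collects
the leave-one-out Q2 over several repeats; a real structure-activity signal
shows a large gap between the original Q2 and the shuffled average.

`compare_modes` aggregates paired SAR/QSAR reports across datasets and
attaches a two-sided Wilcoxon signed-rank p-value per metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import MoleculeGraph, whole_molecule_matrix
from .consensus import ConsensusModel
from .metrics import classification_metrics, quantitative_to_class, regression_metrics
from .qna import chebyshev_basis_indices, chebyshev_features, qna_atom_values
from .scr import SelfConsistentRegressor


class DescriptorTables:
    """Per-molecule descriptor cache shared across folds and model builds.

    QNA atom values, whole-molecule descriptors and (optionally) the full
    PASS Pa - Pi matrix are computed once; `features_for(train_idx)` then
    assembles the feature matrix for any training split, freezing the
    Chebyshev squashing scales on the training molecules only.
    """

    def __init__(self, mols: list[MoleculeGraph], pass_model=None, degree: int = 6):
        self.mols = mols
        self.degree = degree
        self.pq = [qna_atom_values(m) for m in mols]
        self.wm = whole_molecule_matrix(mols)
        self.papi = pass_model.pa_minus_pi(mols) if pass_model is not None else None

    def features_for(self, train_idx: np.ndarray) -> tuple[np.ndarray, dict]:
        train_idx = np.asarray(train_idx)
        sp = float(np.median(np.concatenate([np.abs(self.pq[i][0]) for i in train_idx])))
        sq = float(np.median(np.concatenate([np.abs(self.pq[i][1]) for i in train_idx])))
        Xq = np.array([chebyshev_features(P, Q, self.degree, sp, sq) for P, Q in self.pq])
        parts = [Xq]
        nq = Xq.shape[1]
        blocks = {"QNA": np.arange(nq)}
        off = nq
        if self.papi is not None:
            parts.append(self.papi)
            blocks["MNA"] = off + np.arange(self.papi.shape[1])
            off += self.papi.shape[1]
        parts.append(self.wm)
        blocks["shared"] = off + np.arange(self.wm.shape[1])
        return np.hstack(parts), blocks


def _code_labels(labels) -> np.ndarray:
    return np.where(np.asarray(labels) == "active", 1.0, -1.0)


def crossvalidate(
    curated: pd.DataFrame,
    tables: DescriptorTables,
    mode: str = "QSAR",
    n_models: int = 32,
    seed: int = 0,
    threshold_uM: float = 1.0,
    consensus_kwargs: dict | None = None,
) -> dict:
    """Fivefold external cross-validation of the consensus pipeline.

    `curated` must be row-aligned with `tables.mols` and carry p_value,
    label and fold columns. Returns a report dict (see module docstring).
    """
    if len(curated) != len(tables.mols):
        raise ValueError("curated table and molecule list are not aligned")
    folds = sorted(curated["fold"].unique())
    y_p = curated["p_value"].to_numpy(dtype=float)
    labels = curated["label"].to_numpy()
    rng = np.random.default_rng(seed)

    per_fold = []
    pooled_pred = np.full(len(curated), np.nan)
    pooled_modeled = np.zeros(len(curated), dtype=bool)
    pooled_in_ad = np.zeros(len(curated), dtype=bool)
    pooled_train_mean = np.full(len(curated), np.nan)
    pred_labels = np.empty(len(curated), dtype=object)

    for fold in folds:
        test = np.flatnonzero(curated["fold"].to_numpy() == fold)
        train = np.flatnonzero(curated["fold"].to_numpy() != fold)
        X, blocks = tables.features_for(train)
        y = y_p if mode == "QSAR" else _code_labels(labels)
        cm = ConsensusModel(
            mode=mode,
            n_models=n_models,
            feature_blocks=blocks,
            random_state=int(rng.integers(0, 2**31 - 1)),
            **(consensus_kwargs or {}),
        )
        cm.fit(X[train], y[train])
        entry = {
            "fold": int(fold),
            "n_train": len(train),
            "n_test": len(test),
            "n_built": cm.n_built_,
            "n_retained": cm.n_retained_,
            "no_model": bool(cm.no_model_),
        }
        if cm.no_model_:
            # baseline fallback so the fold still yields predictions:
            # training mean (QSAR) / majority class (SAR), flagged as such
            value = np.full(len(test), y[train].mean())
            in_ad = np.zeros(len(test), dtype=bool)
        else:
            table = cm.predict_table(X[test])
            value = table["value"].to_numpy()
            in_ad = table["in_ad"].to_numpy()
        pooled_pred[test] = value
        pooled_in_ad[test] = in_ad
        pooled_modeled[test] = not cm.no_model_
        pooled_train_mean[test] = y_p[train].mean()

        if mode == "QSAR":
            entry.update(regression_metrics(y_p[test], value, train_mean=y_p[train].mean()))
            cls = quantitative_to_class(value, threshold_uM)
        else:
            cls = np.where(value >= 0.0, "active", "inactive")
        pred_labels[test] = cls
        entry.update(classification_metrics(labels[test], cls))
        entry["pct_in_ad"] = 100.0 * in_ad.mean()
        per_fold.append(entry)

    report = {
        "mode": mode,
        "n_folds": len(folds),
        "per_fold": per_fold,
        "no_model_folds": [e["fold"] for e in per_fold if e["no_model"]],
    }
    modeled = [e for e in per_fold if not e["no_model"]]
    metric_keys = [k for k in per_fold[0] if k not in ("fold", "no_model")]
    report["mean_over_folds"] = {
        k: float(np.mean([e[k] for e in modeled])) if modeled else float("nan") for k in metric_keys
    }
    # pooled metrics over every compound (fallback predictions included)
    pooled = dict(classification_metrics(labels, pred_labels))
    if mode == "QSAR":
        rss = float(np.sum((y_p - pooled_pred) ** 2))
        tss = float(np.sum((y_p - pooled_train_mean) ** 2))
        pooled["r2"] = 1.0 - rss / tss if tss > 0 else float("nan")
        pooled["rmse"] = float(np.sqrt(rss / len(y_p)))
    pooled["pct_in_ad"] = 100.0 * pooled_in_ad.mean()
    report["pooled"] = pooled
    report["predictions"] = pd.DataFrame(
        {
            "compound_id": curated["compound_id"].to_numpy(),
            "fold": curated["fold"].to_numpy(),
            "y_true": y_p,
            "label_true": labels,
            "y_pred": pooled_pred,
            "label_pred": pred_labels,
            "in_ad": pooled_in_ad,
            "modeled": pooled_modeled,
        }
    )
    return report


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    repeats: int = 5,
    seed: int = 0,
    estimator: SelfConsistentRegressor | None = None,
) -> dict:
    """Shuffled-response robustness check on a single-model fit.

    Fits the model on the original response (reference Q2), then `repeats`
    times on a randomly shuffled response with the descriptor matrix fixed,
    and averages the shuffled leave-one-out Q2 values.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    est = estimator if estimator is not None else SelfConsistentRegressor()
    from sklearn.base import clone

    q2_orig = float(clone(est).fit(X, y).q2_train_)
    rng = np.random.default_rng(seed)
    q2_rand = [float(clone(est).fit(X, rng.permutation(y)).q2_train_) for _ in range(repeats)]
    return {
        "q2_original": q2_orig,
        "q2_yrand": q2_rand,
        "q2_yrand_mean": float(np.mean(q2_rand)),
        "repeats": repeats,
    }


def compare_modes(sar_reports: list[dict], qsar_reports: list[dict], metrics: tuple = (
    "accuracy", "balanced_accuracy", "sensitivity", "specificity")) -> pd.DataFrame:
    """Paired SAR-vs-QSAR comparison across datasets.

    Inputs are same-length lists of metric dicts (one per dataset, paired by
    position). Output rows: metric, SAR mean, QSAR mean, delta and two-sided
    Wilcoxon signed-rank p-value.
    """
    if len(sar_reports) != len(qsar_reports) or len(sar_reports) < 2:
        raise ValueError("need >= 2 paired (SAR, QSAR) reports")
    rows = []
    for m in metrics:
        a = np.array([r[m] for r in sar_reports], dtype=float)
        b = np.array([r[m] for r in qsar_reports], dtype=float)
        diff = b - a
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)
        rows.append(
            {
                "metric": m,
                "sar_mean": float(a.mean()),
                "qsar_mean": float(b.mean()),
                "delta_qsar_minus_sar": float(diff.mean()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
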