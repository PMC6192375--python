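"""Consensus (Q)SAR model: an ensemble of randomized single models filtered
by validation thresholds, combined by similarity-weighted averaging.

For one training set, ``n_models`` single models are built with varied
descriptor context: QNA-family models draw random subsets of the
Chebyshev-feature block, MNA-family models draw random activity subsets of
PASS Pa - Pi features; every model also gets its own internal-validation
split seed. A single model is retained only if R2_train > 0.5, leave-one-out
Q2_train > 0.5 and the mean internal-validation R2 (five random 80/20
splits) > 0.5; retaining nothing is an explicit, reportable "no model"
state rather than an error hidden downstream.

Predictions are weighted averages of the retained models, each weight being
the query's similarity to that model's training set in its selected-variable
space (s = 1/(1 + mean distance to the 3 nearest training compounds),
standardized coordinates). A query is inside the applicability domain of a
model when its similarity reaches the threshold calibrated from the training
self-distances (mean + 3 SD); the consensus-level flag is a majority vote of
the contributing models.

In SAR mode the response is the class coded +1 (active) / -1 (inactive) and
the consensus score is thresholded at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .scr import SelfConsistentRegressor, internal_validation


class NoModelError(RuntimeError):
    """Raised when a consensus model retained zero single models."""


@dataclass
class _SingleModel:
    family: str                 # "QNA" or "MNA"
    columns: np.ndarray         # offered columns (indices into the full X)
    est: SelfConsistentRegressor
    r2_train: float
    q2_train: float
    internal_r2: float
    seed: int
    # applicability-domain calibration in the model's selected-variable space
    ad_mean: np.ndarray | None = None
    ad_scale: np.ndarray | None = None
    ad_train: np.ndarray | None = None
    ad_threshold: float = 0.0
    _nn: NearestNeighbors | None = None


class ConsensusModel(BaseEstimator):
    """Similarity-weighted consensus of self-consistent-regression models.

    Parameters
    ----------
    mode : "QSAR" (continuous p-units) or "SAR" (+1/-1 coded classes)
    n_models : ensemble size built per training set (default 320; use a
        few dozen for desk-scale experiments)
    feature_blocks : dict mapping family name ("QNA", "MNA") to the column
        indices of the full feature matrix belonging to that family; a
        "shared" key (whole-molecule block) is appended to every model's
        offered columns. With a single entry all models come from it.
    threshold : validation threshold applied to R2_train, Q2_train and
        internal R2 alike
    subset_fraction : fraction of a family block offered to one model when
        the block is subsampled (half of the builds use the full block)
    k_neighbors : neighborhood size for the similarity / AD computation
    random_state : seed for all per-model draws
    """

    def __init__(
        self,
        mode: str = "QSAR",
        n_models: int = 320,
        feature_blocks: dict | None = None,
        threshold: float = 0.5,
        subset_fraction: float = 0.5,
        k_neighbors: int = 3,
        alpha_grid: tuple = (0.01, 0.1, 1.0, 10.0),
        random_state: int = 0,
    ):
        self.mode = mode
        self.n_models = n_models
        self.feature_blocks = feature_blocks
        self.threshold = threshold
        self.subset_fraction = subset_fraction
        self.k_neighbors = k_neighbors
        self.alpha_grid = alpha_grid
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Build, validate and filter the ensemble on one training set.

        y is the continuous response in QSAR mode and +1/-1 class codes in
        SAR mode.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.mode not in ("QSAR", "SAR"):
            raise ValueError("mode must be 'QSAR' or 'SAR'")
        if len(y) == 0:
            raise ValueError("empty training set")
        blocks = self.feature_blocks or {"QNA": np.arange(X.shape[1])}
        shared = np.asarray(blocks.get("shared", []), dtype=int)
        families = [(name, np.asarray(cols, dtype=int)) for name, cols in blocks.items() if name != "shared"]
        rng = np.random.default_rng(self.random_state)

        self.models_: list[_SingleModel] = []
        self.n_built_ = 0
        for i in range(self.n_models):
            family, cols = families[i % len(families)]
            # half of the builds drop a random part of the family block
            if rng.random() < 0.5 and len(cols) > 2:
                k = max(2, int(round(self.subset_fraction * len(cols))))
                cols = np.sort(rng.choice(cols, size=k, replace=False))
            offered = np.concatenate([cols, shared]) if shared.size else cols
            seed = int(rng.integers(0, 2**31 - 1))
            self.n_built_ += 1
            est = SelfConsistentRegressor(alpha_grid=self.alpha_grid)
            try:
                est.fit(X[:, offered], y)
            except ValueError:
                continue
            if est.r2_train_ <= self.threshold or est.q2_train_ <= self.threshold:
                continue
            fixed = SelfConsistentRegressor(alpha=est.alpha_, alpha_grid=self.alpha_grid)
            internal_r2 = internal_validation(fixed, X[:, offered], y, seed=seed)
            if internal_r2 <= self.threshold:
                continue
            sm = _SingleModel(
                family=family,
                columns=offered,
                est=est,
                r2_train=float(est.r2_train_),
                q2_train=float(est.q2_train_),
                internal_r2=float(internal_r2),
                seed=seed,
            )
            self._calibrate_ad(sm, X, y)
            self.models_.append(sm)
        self.n_retained_ = len(self.models_)
        self.no_model_ = self.n_retained_ == 0
        self.train_mean_ = float(y.mean())
        return self

    def _calibrate_ad(self, sm: _SingleModel, X: np.ndarray, y: np.ndarray) -> None:
        sel = sm.columns[sm.est.selected_] if len(sm.est.selected_) else sm.columns
        Z = X[:, sel]
        mean = Z.mean(axis=0)
        scale = Z.std(axis=0)
        scale[scale == 0] = 1.0
        Zs = (Z - mean) / scale
        k = min(self.k_neighbors, len(Zs) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Zs)
        dist, _ = nn.kneighbors(Zs)
        self_d = dist[:, 1:].mean(axis=1)  # exclude the zero self-distance
        cut_d = float(self_d.mean() + 3.0 * self_d.std())
        sm.ad_mean, sm.ad_scale, sm.ad_train = mean, scale, Zs
        sm.ad_threshold = 1.0 / (1.0 + cut_d)
        sm._nn = nn
        sm._ad_cols = sel

    # -- prediction --------------------------------------------------------

    def _similarities(self, sm: _SingleModel, X: np.ndarray) -> np.ndarray:
        Zq = (X[:, sm._ad_cols] - sm.ad_mean) / sm.ad_scale
        k = min(self.k_neighbors, len(sm.ad_train))
        dist, _ = sm._nn.kneighbors(Zq, n_neighbors=k)
        return 1.0 / (1.0 + dist.mean(axis=1))

    def predict_table(self, X, ids=None) -> pd.DataFrame:
        """Per-compound consensus prediction with AD diagnostics.

        Columns: value (weighted-average score; p-units in QSAR mode, class
        score in SAR mode), label (SAR mode), in_ad, n_models, mean_similarity.
        """
        if getattr(self, "no_model_", True) and not getattr(self, "models_", None):
            raise NoModelError(
                "no single model passed the validation thresholds; "
                "inspect n_built_/n_retained_ and rebuild with other data or settings"
            )
        X = np.asarray(X, dtype=float)
        n = len(X)
        preds = np.empty((len(self.models_), n))
        sims = np.empty((len(self.models_), n))
        in_ad = np.empty((len(self.models_), n), dtype=bool)
        for m, sm in enumerate(self.models_):
            preds[m] = sm.est.predict(X[:, sm.columns])
            sims[m] = self._similarities(sm, X)
            in_ad[m] = sims[m] >= sm.ad_threshold
        wsum = sims.sum(axis=0)
        value = np.einsum("mn,mn->n", sims, preds) / wsum
        table = pd.DataFrame(
            {
                "compound_id": ids if ids is not None else np.arange(n),
                "value": value,
                "in_ad": in_ad.mean(axis=0) >= 0.5,
                "n_models": len(self.models_),
                "mean_similarity": sims.mean(axis=0),
            }
        )
        if self.mode == "SAR":
            table["label"] = np.where(value >= 0.0, "active", "inactive")
        table.attrs["single_model_predictions"] = preds
        return table

    def predict(self, X):
        """Consensus value per compound (p-units or SAR score)."""
        return self.predict_table(X)["value"].to_numpy()

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize the fitted consensus model (deterministic byte output)."""
        payload = {
            "mode": self.mode,
            "n_models": self.n_models,
            "threshold": self.threshold,
            "k_neighbors": self.k_neighbors,
            "random_state": self.random_state,
            "n_built": self.n_built_,
            "n_retained": self.n_retained_,
            "train_mean": self.train_mean_,
            "models": [
                {
                    "family": sm.family,
                    "columns": sm.columns.tolist(),
                    "selected": sm.est.selected_.tolist(),
                    "coef": sm.est.coef_.tolist(),
                    "intercept": sm.est.intercept_,
                    "alpha": sm.est.alpha_,
                    "r2_train": sm.r2_train,
                    "q2_train": sm.q2_train,
                    "internal_r2": sm.internal_r2,
                    "seed": sm.seed,
                    "ad_threshold": sm.ad_threshold,
                }
                for sm in self.models_
            ],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))
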