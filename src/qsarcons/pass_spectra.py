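"""Activity-spectrum estimation from MNA descriptors (PASS-style Pa/Pi).

For every activity in a configurable vocabulary the model learns, from a
labeled corpus, which MNA descriptors are informative: a descriptor is
selected for an activity when its Laplace-smoothed conditional activity
frequency deviates from the activity's base rate with hypergeometric tail
probability at most ``p_select`` (an exact enrichment/depletion test, so
selection also works on very small corpora). A query compound's raw score
for an activity is
the sum, over its descriptors that were selected for that activity, of the
smoothed log-odds ratio log[P(d|active)/P(d|inactive)].

Raw scores are calibrated against the leave-one-out score distributions of
the training corpus (each training compound scored with its own
contribution removed from the counts, exactly how an external query is
scored) into

* Pa — the fraction of training *inactives* the query outscores, and
* Pi — the fraction of training *actives* that outscore the query,

with ties counted half. Pa and Pi are probabilities in [0, 1] that do not
sum to one; Pa - Pi in [-1, 1] is the decision value, positive when the
compound resembles the actives. A compound sharing no descriptor with the
corpus is assigned Pa = Pi = 0.5, i.e. Pa - Pi = 0.

Descriptor selection is frozen on the full corpus; the leave-one-out
calibration re-estimates the per-descriptor frequencies but not the
selection, a deliberate approximation that keeps scoring exact and cheap.

The Pa - Pi values of a (seeded) random subset of activities serve as
independent variables for the regression stage, one subset per single
model, which is what diversifies the descriptor context across an ensemble.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .chem import MoleculeGraph
from .mna import descriptor_sets


class PassActivitySpectra(BaseEstimator):
    """Multi-activity Pa/Pi estimator over MNA descriptor sets.

    Parameters
    ----------
    level : MNA recursion depth used for descriptor generation
    alpha : Laplace smoothing for per-descriptor activity frequencies
    p_select : hypergeometric tail probability below which a descriptor is
        considered informative for an activity and contributes to its score

    Fitted attributes: ``vocabulary_`` (descriptor -> column),
    ``activities_``, ``log_odds_`` (selected-descriptor log-odds table,
    zero elsewhere), ``loo_scores_`` (calibration scores) and the sorted
    per-activity score distributions.
    """

    def __init__(self, level: int = 2, alpha: float = 1.0, p_select: float = 0.01):
        self.level = level
        self.alpha = alpha
        self.p_select = p_select

    # -- fitting -----------------------------------------------------------

    def fit(self, mols: list[MoleculeGraph], Y: np.ndarray, activity_names: list[str] | None = None):
        """Fit from a corpus of molecules and a binary (n_mols x n_activities) label matrix."""
        Y = np.asarray(Y, dtype=bool)
        if len(mols) == 0 or Y.shape[0] != len(mols):
            raise ValueError("corpus empty or label matrix shape mismatch")
        if Y.shape[1] == 0:
            raise ValueError("empty activity vocabulary")
        if not Y.any(axis=0).all():
            raise ValueError("every activity needs at least one active compound")
        self.activities_ = list(activity_names) if activity_names is not None else [
            f"activity_{j}" for j in range(Y.shape[1])
        ]
        dsets = descriptor_sets(mols, self.level)
        vocab = sorted(set().union(*dsets))
        self.vocabulary_ = {d: i for i, d in enumerate(vocab)}
        X = self._incidence(dsets)
        n = len(mols)
        a = self.alpha
        self._n_with = X.sum(axis=0)
        self._n_act = X.T @ Y.astype(float)
        self._n_actives = Y.sum(axis=0).astype(float)
        self._n = n
        # descriptor selection by exact hypergeometric enrichment/depletion:
        # drawing n_d compounds (those containing d) from the corpus, how
        # surprising is the observed number of actives among them?
        from scipy.stats import hypergeom

        K = self._n_actives[None, :]
        nd = self._n_with[:, None]
        k = self._n_act
        p_over = hypergeom.sf(k - 1, n, K, nd)
        p_under = hypergeom.cdf(k, n, K, nd)
        self.selected_ = np.minimum(p_over, p_under) <= self.p_select
        self.selected_ &= self._n_with[:, None] > 0
        self.log_odds_ = self._log_odds(self._n_act, self._n_with, self._n_actives, n) * self.selected_
        self.Y_ = Y
        self.loo_scores_ = self._loo_scores(X, Y)
        self._act_sorted = [np.sort(self.loo_scores_[Y[:, j], j]) for j in range(Y.shape[1])]
        self._inact_sorted = [np.sort(self.loo_scores_[~Y[:, j], j]) for j in range(Y.shape[1])]
        return self

    def _log_odds(self, n_act, n_with, n_actives, n) -> np.ndarray:
        """log P(d|active) - log P(d|inactive), Laplace-smoothed."""
        a = self.alpha
        n_inact_d = n_with[:, None] - n_act
        n_inactives = n - n_actives
        return np.log((n_act + a) / (n_actives + 2 * a)[None, :]) - np.log(
            (n_inact_d + a) / (n_inactives + 2 * a)[None, :]
        )

    def _loo_scores(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Training scores with each compound's own contribution removed."""
        n, a_count = len(X), Y.shape[1]
        scores = np.zeros((n, a_count))
        for i in range(n):
            d_idx = np.flatnonzero(X[i])
            if d_idx.size == 0:
                continue
            y = Y[i].astype(float)
            lo = self._log_odds(
                self._n_act[d_idx] - y[None, :],
                self._n_with[d_idx] - 1.0,
                self._n_actives - y,
                n - 1,
            )
            scores[i] = (lo * self.selected_[d_idx]).sum(axis=0)
        return scores

    def _incidence(self, dsets: list[set[str]]) -> np.ndarray:
        X = np.zeros((len(dsets), len(self.vocabulary_)))
        for i, ds in enumerate(dsets):
            for d in ds:
                j = self.vocabulary_.get(d)
                if j is not None:
                    X[i, j] = 1.0
        return X

    # -- prediction --------------------------------------------------------

    def _raw_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(scores, n corpus-known descriptors) per query row."""
        known = X @ (self._n_with > 0).astype(float)
        return X @ self.log_odds_, known

    def pa_pi(self, mols: list[MoleculeGraph]) -> tuple[np.ndarray, np.ndarray]:
        """(Pa, Pi) matrices of shape (n_mols, n_activities)."""
        X = self._incidence(descriptor_sets(mols, self.level))
        scores, known = self._raw_scores(X)
        n, a = scores.shape
        Pa = np.empty((n, a))
        Pi = np.empty((n, a))
        for j in range(a):
            inact, act = self._inact_sorted[j], self._act_sorted[j]
            if inact.size:
                lo = np.searchsorted(inact, scores[:, j], side="left")
                hi = np.searchsorted(inact, scores[:, j], side="right")
                Pa[:, j] = (lo + hi) / (2.0 * inact.size)  # ties count half
            else:
                Pa[:, j] = 0.5
            lo = np.searchsorted(act, scores[:, j], side="left")
            hi = np.searchsorted(act, scores[:, j], side="right")
            Pi[:, j] = 1.0 - (lo + hi) / (2.0 * act.size)
        unknown = known == 0
        Pa[unknown] = 0.5
        Pi[unknown] = 0.5
        return Pa, Pi

    def pa_minus_pi(self, mols: list[MoleculeGraph]) -> np.ndarray:
        Pa, Pi = self.pa_pi(mols)
        return Pa - Pi

    def leave_one_out_accuracy(self) -> float:
        """Mean LOO accuracy of the sign(Pa - Pi) decision over the corpus.

        Each compound's leave-one-out score is calibrated against the other
        compounds' leave-one-out score distributions, so neither the
        frequency table nor the calibration sees the compound itself.
        """
        Y = self.Y_
        n, a = self.loo_scores_.shape
        correct = 0
        total = 0
        for i in range(n):
            for j in range(a):
                others = np.ones(n, dtype=bool)
                others[i] = False
                act = np.sort(self.loo_scores_[others & Y[:, j], j])
                inact = np.sort(self.loo_scores_[others & ~Y[:, j], j])
                if act.size == 0 or inact.size == 0:
                    continue
                s = self.loo_scores_[i, j]
                pa = (np.searchsorted(inact, s, "left") + np.searchsorted(inact, s, "right")) / (2 * inact.size)
                pi = 1 - (np.searchsorted(act, s, "left") + np.searchsorted(act, s, "right")) / (2 * act.size)
                correct += int((pa - pi > 0) == Y[i, j])
                total += 1
        return correct / total if total else float("nan")


def select_activities(n_total: int, n_select: int, seed: int) -> np.ndarray:
    """Seeded random activity subset (sorted column indices), reproducible."""
    if n_select > n_total:
        raise ValueError("subset larger than vocabulary")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=n_select, replace=False))


def pass_features(
    model: PassActivitySpectra,
    mols: list[MoleculeGraph],
    n_activities: int,
    seed: int,
    pa_pi_matrix: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pa - Pi features for a seeded random activity subset.

    Returns (features, selected column indices). A precomputed full
    Pa - Pi matrix can be passed to avoid rescoring the same molecules.
    """
    full = pa_pi_matrix if pa_pi_matrix is not None else model.pa_minus_pi(mols)
    if n_activities == 0:
        return np.empty((len(mols), 0)), np.array([], dtype=int)
    cols = select_activities(full.shape[1], n_activities, seed)
    return full[:, cols], cols
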