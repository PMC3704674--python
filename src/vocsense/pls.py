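"""Two-group partial least squares discriminant analysis (PLS-DA).

The classifier regresses a 0/1 class indicator (control -> 0, cancer -> 1)
on the full standardized chromatogram.  Latent factors are extracted
sequentially: each weight vector is the direction maximizing covariance
between the (deflated) predictor scores and the centered indicator — for a
univariate response this is the closed-form ``X' y`` direction, so no
inner iteration is needed — and the predictor block is deflated by the
rank-one score–loading product after every round.  Only the predictors are
deflated; response deflation is redundant with a univariate response.
Columns are centered inside the fit; no per-column scaling is applied (the
profiles are already standardized within-sample).

Predicted scores above 0.5 are called cancer; a score exactly at the
threshold goes to control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cohort import Cohort
from .preprocess import StandardizedProfile, standardize_cohort


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS1 regression of a binary class indicator, thresholded at 0.5.

    Parameters
    ----------
    n_components : int
        Number of latent factors to extract (the study sweeps 1-10).
    decision_threshold : float
        Score cut for calling the positive class (default 0.5, the
        midpoint of the 0/1 coding).

    Attributes
    ----------
    x_weights_ : (p, A) unit-norm weight vectors, one column per factor.
    x_loadings_ : (p, A) predictor loadings.
    y_loadings_ : (A,) response loadings.
    x_scores_ : (n, A) training score vectors (mutually orthogonal).
    coef_ : (p,) regression vector mapping a centered profile to a score.
    x_mean_ : (p,) column centering vector;  y_mean_ : scalar.
    """

    def __init__(self, n_components: int = 9,
                 decision_threshold: float = 0.5) -> None:
        self.n_components = n_components
        self.decision_threshold = decision_threshold

    def fit(self, X, y) -> "PLSDAClassifier":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLSDAClassifier requires exactly two classes")
        n, p = X.shape
        max_rank = min(n - 1, p)
        if not 1 <= self.n_components <= max_rank:
            raise ValueError(f"n_components={self.n_components} outside "
                             f"feasible range [1, {max_rank}]")
        yb = (y == self.classes_[1]).astype(float)  # 0/1 indicator
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(yb.mean())
        E = X - self.x_mean_
        f = yb - self.y_mean_

        A = self.n_components
        W = np.empty((p, A))
        P = np.empty((p, A))
        q = np.empty(A)
        T = np.empty((n, A))
        for a in range(A):
            w = E.T @ f
            norm = np.linalg.norm(w)
            if norm <= 1e-14:
                raise ValueError(f"factor {a + 1} exceeds the effective rank "
                                 "of the centered predictors")
            w /= norm
            t = E @ w
            tt = t @ t
            if tt <= 1e-14:
                raise ValueError(f"degenerate score vector at factor {a + 1}")
            pa = E.T @ t / tt
            q[a] = f @ t / tt
            E = E - np.outer(t, pa)
            W[:, a], P[:, a], T[:, a] = w, pa, t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        # B = W (P'W)^-1 q  composes all factors into one vector
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Predicted response score, y_mean + (x - x_mean) . coef."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > self.decision_threshold,
                        self.classes_[1], self.classes_[0])

    def coefficients_for(self, n_factors: int) -> tuple[np.ndarray, float]:
        """Regression vector using only the first ``n_factors`` factors.

        Truncating the factor sequence reproduces exactly the model that a
        fresh fit with ``n_components=n_factors`` would give, so a single
        full-depth fit serves the whole factor sweep.
        """
        check_is_fitted(self, "coef_")
        if not 1 <= n_factors <= self.n_components:
            raise ValueError("n_factors outside the fitted range")
        W = self.x_weights_[:, :n_factors]
        P = self.x_loadings_[:, :n_factors]
        q = self.y_loadings_[:n_factors]
        return W @ np.linalg.solve(P.T @ W, q), self.y_mean_


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def plsda_fit(X: np.ndarray, labels: np.ndarray,
              n_factors: int) -> PLSDAClassifier:
    """Fit the two-group PLS-DA classifier with ``n_factors`` factors."""
    return PLSDAClassifier(n_components=n_factors).fit(X, labels)


def plsda_predict(model: PLSDAClassifier,
                  profile: StandardizedProfile) -> tuple[str, float]:
    """Classify one standardized profile; returns (label, response score)."""
    check_is_fitted(model, "coef_")
    if profile.grid_length != len(model.x_mean_):
        raise ValueError(f"profile grid length {profile.grid_length} does "
                         f"not match model grid {len(model.x_mean_)}")
    score = float(model.decision_function(profile.values[None, :])[0])
    label = "cancer" if score > model.decision_threshold else "control"
    return label, score


def _counts_by_group(y: np.ndarray, preds: np.ndarray) -> tuple[int, int]:
    """(cancer correct, control correct) counts; y coded control=0/cancer=1."""
    cancer = int(np.sum((y == 1) & (preds == 1)))
    control = int(np.sum((y == 0) & (preds == 0)))
    return cancer, control


def loocv_sweep(cohort: Cohort, max_factors: int = 10) -> pd.DataFrame:
    """Within-sample and leave-one-out correct counts for 1..max_factors.

    For each left-out sample one full-depth model is fitted on the
    remaining n-1 profiles (centering included) and truncated to every
    factor count, so the sweep costs one fit per fold.  Returns one row
    per factor count with correct counts and one-decimal percentages per
    group, mirroring the published sweep layout.
    """
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    y = cohort.y
    n = len(cohort)
    n_cancer = int(np.sum(y == 1))
    n_control = int(np.sum(y == 0))
    if min(n_cancer, n_control) < 3:
        raise ValueError("factor sweep requires >= 3 samples per group")
    X = standardize_cohort(cohort)
    depth = min(max_factors, n - 2)  # every fold must support full depth

    full = PLSDAClassifier(n_components=depth).fit(X, y)
    within = np.empty((depth, n), dtype=int)
    for a in range(1, depth + 1):
        coef, y_mean = full.coefficients_for(a)
        score = y_mean + (X - full.x_mean_) @ coef
        within[a - 1] = (score > full.decision_threshold).astype(int)

    loo = np.empty((depth, n), dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        fold = PLSDAClassifier(n_components=depth).fit(X[keep], y[keep])
        centered = X[i] - fold.x_mean_
        for a in range(1, depth + 1):
            coef, y_mean = fold.coefficients_for(a)
            score = y_mean + centered @ coef
            loo[a - 1, i] = int(score > fold.decision_threshold)

    rows = []
    for a in range(1, depth + 1):
        w_can, w_con = _counts_by_group(y, within[a - 1])
        l_can, l_con = _counts_by_group(y, loo[a - 1])
        rows.append({
            "n_factors": a,
            "within_cancer_correct": w_can,
            "within_cancer_pct": round(100.0 * w_can / n_cancer, 1),
            "within_control_correct": w_con,
            "within_control_pct": round(100.0 * w_con / n_control, 1),
            "loo_cancer_correct": l_can,
            "loo_cancer_pct": round(100.0 * l_can / n_cancer, 1),
            "loo_control_correct": l_con,
            "loo_control_pct": round(100.0 * l_con / n_control, 1),
        })
    return pd.DataFrame(rows)
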