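"""Two-group Fisher linear discriminant analysis with forward stepwise
time-point selection.

The discriminative workflow treats every half-second sampling index of the
standardized chromatogram as a candidate predictor.  Forward stepwise
selection enters, at each step, the time point that minimizes Wilks'
lambda (within-group over total generalized variance) of the augmented
model, subject to two guards: the model never grows beyond the smallest
group size, and a candidate whose tolerance (1 - R^2 against the already
selected predictors) falls below a floor is skipped to avoid
multicollinearity.  Entry stops when no candidate's F-to-enter exceeds the
threshold.  The final model is the classical Fisher discriminant on the
selected columns, validated by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cohort import Cohort
from .preprocess import StandardizedProfile, standardize_cohort

_EPS = 1e-12


class MulticollinearityError(np.linalg.LinAlgError):
    """Pooled within-group covariance is singular on the selected features."""


class EmptyModelError(ValueError):
    """Forward selection entered no feature at the configured thresholds."""


# ---------------------------------------------------------------------------
# Wilks' lambda machinery
# ---------------------------------------------------------------------------

def _scatter_views(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total mean-centered views of the data matrix."""
    Xw = X.astype(float, copy=True)
    for g in np.unique(y):
        mask = y == g
        Xw[mask] -= Xw[mask].mean(axis=0)
    Xt = X - X.mean(axis=0)
    return Xw, Xt


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given feature set."""
    Xw, Xt = _scatter_views(np.atleast_2d(X), np.asarray(y))
    W = Xw.T @ Xw
    T = Xt.T @ Xt
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("singular total scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class SelectedFeatures:
    """Stepwise-selected time points, in entry order, with diagnostics.

    ``indices`` are 1-based half-second sampling indices (t = 1..grid).
    ``entry_statistics`` holds the F-to-enter value at each step,
    ``tolerances`` the candidate's tolerance (1 - R^2 against the features
    already in the model) at entry, and ``wilks_path`` the Wilks' lambda
    of the model after each entry (non-increasing by construction).
    """

    indices: list[int] = field(default_factory=list)
    entry_statistics: list[float] = field(default_factory=list)
    tolerances: list[float] = field(default_factory=list)
    wilks_path: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)


def _stepwise_scan(X: np.ndarray, y: np.ndarray, max_features: int,
                   tolerance_floor: float, entry_threshold: float
                   ) -> SelectedFeatures:
    """Greedy Wilks'-lambda forward selection over the columns of X.

    Returns 0-based column positions in ``indices`` (callers re-base to
    time indices).  Uses rank-one determinant updates so each step scans
    all candidates with two k x p solves instead of per-candidate
    determinants.
    """
    n, p = X.shape
    Xw, Xt = _scatter_views(X, y)
    diag_W = np.einsum("ij,ij->j", Xw, Xw)
    diag_T = np.einsum("ij,ij->j", Xt, Xt)

    selected: list[int] = []
    out = SelectedFeatures()
    lam_current = 1.0
    available = diag_T > _EPS  # constant columns can never enter

    while len(selected) < max_features:
        if selected:
            S = np.array(selected)
            A_W = Xw[:, S].T @ Xw          # (k, p) cross products
            A_T = Xt[:, S].T @ Xt
            W_SS = A_W[:, S]
            T_SS = A_T[:, S]
            resid_W = diag_W - np.einsum(
                "kp,kp->p", A_W, np.linalg.solve(W_SS, A_W))
            resid_T = diag_T - np.einsum(
                "kp,kp->p", A_T, np.linalg.solve(T_SS, A_T))
        else:
            resid_W = diag_W.copy()
            resid_T = diag_T.copy()

        with np.errstate(divide="ignore", invalid="ignore"):
            tolerance = np.where(diag_T > _EPS, resid_T / diag_T, 0.0)
        eligible = (available
                    & (tolerance >= tolerance_floor)
                    & (resid_T > _EPS))
        eligible[selected] = False
        if not np.any(eligible):
            break

        ratio = np.full(p, np.inf)
        ratio[eligible] = np.clip(resid_W[eligible], 0.0, None) \
            / resid_T[eligible]
        j = int(np.argmin(ratio))
        lam_new = lam_current * ratio[j]
        k = len(selected)
        df = n - 2 - k
        if df <= 0:
            break
        f_enter = df * (lam_current / max(lam_new, _EPS) - 1.0)
        if f_enter <= entry_threshold:
            break
        selected.append(j)
        lam_current = lam_new
        out.indices.append(j)
        out.entry_statistics.append(float(f_enter))
        out.tolerances.append(float(tolerance[j]))
        out.wilks_path.append(float(lam_current))

    return out


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class FisherLDA(ClassifierMixin, BaseEstimator):
    """Two-group Fisher linear discriminant on a given feature matrix.

    The discriminant direction is ``S_W^-1 (mu_1 - mu_0)`` with ``S_W``
    the pooled within-group covariance; the decision threshold combines
    the projected group means with the class priors.  The second class in
    sorted label order (``classes_[1]``) is the positive class; a score
    exactly at the threshold is assigned to the negative class.

    Parameters
    ----------
    priors : "equal", "proportional", or a pair of floats summing to 1
        Prior probabilities for (negative, positive) class, entering the
        threshold as ``log(pi_0 / pi_1)``.
    """

    def __init__(self, priors: str | tuple[float, float] = "equal") -> None:
        self.priors = priors

    def _resolve_priors(self, n0: int, n1: int) -> np.ndarray:
        if self.priors == "equal":
            return np.array([0.5, 0.5])
        if self.priors == "proportional":
            n = n0 + n1
            return np.array([n0 / n, n1 / n])
        pri = np.asarray(self.priors, dtype=float)
        if pri.shape != (2,) or not np.isclose(pri.sum(), 1.0) or np.any(pri <= 0):
            raise ValueError("priors must be 'equal', 'proportional', or two "
                             "positive values summing to 1")
        return pri

    def fit(self, X, y) -> "FisherLDA":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("FisherLDA requires exactly two classes")
        mask1 = y == self.classes_[1]
        X0, X1 = X[~mask1], X[mask1]
        # a single-sample group contributes no scatter but still defines a
        # mean; the Cholesky guard below catches any resulting singularity
        if len(X0) < 1 or len(X1) < 1 or len(X) < 3:
            raise ValueError("need both groups present and >= 3 samples")
        self.priors_ = self._resolve_priors(len(X0), len(X1))
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        W = ((X0 - mu0).T @ (X0 - mu0)) + ((X1 - mu1).T @ (X1 - mu1))
        S_w = W / (len(X) - 2)
        try:
            c = np.linalg.cholesky(S_w)
            coef = np.linalg.solve(c.T, np.linalg.solve(c, mu1 - mu0))
        except np.linalg.LinAlgError as exc:
            raise MulticollinearityError(
                "singular pooled within-group covariance — selected features "
                "are multicollinear") from exc
        self.means_ = np.stack([mu0, mu1])
        self.coef_ = coef
        self.threshold_ = float(
            0.5 * (mu0 + mu1) @ coef
            + np.log(self.priors_[0] / self.priors_[1]))
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ - self.threshold_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        # tie at the threshold goes to the negative (control) class
        return np.where(score > 0, self.classes_[1], self.classes_[0])


class StepwiseLDA(ClassifierMixin, BaseEstimator):
    """Forward stepwise Wilks'-lambda selection + Fisher discriminant.

    Parameters
    ----------
    max_features : int or None
        Hard cap on the number of entered predictors; additionally capped
        at the smallest group size.  ``None`` means the group-size cap only.
    entry_threshold : float
        Minimum F-to-enter (default 3.84, the chi-square 0.05 critical
        value with 1 df — the conventional stepwise default).
    tolerance_floor : float
        Minimum tolerance (1 - R^2 against already-entered predictors)
        for a candidate to be considered (default 0.001).
    features : sequence of int, optional
        0-based column positions to use directly, skipping selection
        (the fixed-features cross-validation protocol).
    priors : as in :class:`FisherLDA`.

    Attributes
    ----------
    support_ : 0-based positions of the selected columns, entry order.
    selection_ : :class:`SelectedFeatures` diagnostics (1-based indices).
    estimator_ : the fitted :class:`FisherLDA` on the selected columns.
    """

    def __init__(self, max_features: int | None = 9,
                 entry_threshold: float = 3.84,
                 tolerance_floor: float = 1e-3,
                 features=None,
                 priors: str | tuple[float, float] = "equal") -> None:
        self.max_features = max_features
        self.entry_threshold = entry_threshold
        self.tolerance_floor = tolerance_floor
        self.features = features
        self.priors = priors

    def fit(self, X, y) -> "StepwiseLDA":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("StepwiseLDA requires exactly two classes")
        if not 0 < self.tolerance_floor < 1:
            raise ValueError("tolerance_floor must lie in (0, 1)")
        counts = [int(np.sum(y == c)) for c in self.classes_]
        smallest = min(counts)
        cap = smallest if self.max_features is None \
            else min(self.max_features, smallest)
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")

        if self.features is not None:
            self.support_ = np.asarray(self.features, dtype=int)
            self.selection_ = None
        else:
            sel = _stepwise_scan(X, y, cap, self.tolerance_floor,
                                 self.entry_threshold)
            self.support_ = np.asarray(sel.indices, dtype=int)
            # expose 1-based time indices in the diagnostics
            self.selection_ = SelectedFeatures(
                indices=[j + 1 for j in sel.indices],
                entry_statistics=sel.entry_statistics,
                tolerances=sel.tolerances,
                wilks_path=sel.wilks_path)
        if len(self.support_) == 0:
            raise EmptyModelError("no feature passed the entry criterion")
        self.estimator_ = FisherLDA(priors=self.priors).fit(
            X[:, self.support_], y)
        self.coef_ = self.estimator_.coef_
        self.threshold_ = self.estimator_.threshold_
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = check_array(X)
        return self.estimator_.decision_function(X[:, self.support_])

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def fisher_fit(X: np.ndarray, labels: np.ndarray,
               priors: str | tuple[float, float] = "equal") -> FisherLDA:
    """Fit the two-group Fisher discriminant on pre-selected features."""
    return FisherLDA(priors=priors).fit(X, labels)


def forward_stepwise_select(cohort: Cohort, max_features: int = 9,
                            tolerance_floor: float = 1e-3,
                            entry_threshold: float = 3.84) -> SelectedFeatures:
    """Stepwise time-point selection on a cohort's standardized profiles.

    Returns 1-based half-second sampling indices in entry order.
    """
    y = cohort.y
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both groups")
    smallest = min(int(np.sum(y == 0)), int(np.sum(y == 1)))
    if max_features > smallest:
        raise ValueError(f"max_features={max_features} exceeds smallest "
                         f"group size {smallest}")
    X = standardize_cohort(cohort)
    model = StepwiseLDA(max_features=max_features,
                        tolerance_floor=tolerance_floor,
                        entry_threshold=entry_threshold).fit(X, y)
    return model.selection_


def classify(model: StepwiseLDA, profile: StandardizedProfile
             ) -> tuple[str, float]:
    """Classify one standardized profile; returns (label, signed score)."""
    check_is_fitted(model, "estimator_")
    if profile.grid_length <= int(np.max(model.support_)):
        raise ValueError("profile too short for the model's feature indices")
    score = float(model.decision_function(profile.values[None, :])[0])
    label = "cancer" if score > 0 else "control"
    return label, score


def loocv(cohort: Cohort, protocol: str = "fixed_features",
          max_features: int = 9, tolerance_floor: float = 1e-3,
          entry_threshold: float = 3.84,
          priors: str | tuple[float, float] = "equal"):
    """Leave-one-out cross-validation of the stepwise-LDA pipeline.

    ``fixed_features`` selects time points once on the full cohort and
    refits only the discriminant coefficients in each fold (mirroring
    standard stepwise-DA software); ``reselect_per_fold`` repeats the
    selection inside every fold, which is the honest protocol for
    assessing selection-induced optimism.  Returns a
    :class:`~vocsense.evaluation.ConfusionMatrix` of the held-out
    predictions (cancer = positive).
    """
    from .evaluation import confusion

    if protocol not in ("fixed_features", "reselect_per_fold"):
        raise ValueError(f"unknown protocol {protocol!r}")
    y = cohort.y
    n = len(cohort)
    if min(int(np.sum(y == 0)), int(np.sum(y == 1))) < 2:
        raise ValueError("leave-one-out requires >= 2 samples per group")
    X = standardize_cohort(cohort)

    support = None
    if protocol == "fixed_features":
        try:
            full = StepwiseLDA(max_features=max_features,
                               tolerance_floor=tolerance_floor,
                               entry_threshold=entry_threshold,
                               priors=priors).fit(X, y)
        except EmptyModelError:
            # nothing discriminative on the whole cohort: the empty model
            # scores 0 everywhere and the tie rule sends all to control
            return confusion(y, np.zeros(n, dtype=int), positive=1)
        support = full.support_

    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X[keep], y[keep]
        if protocol == "fixed_features":
            model = StepwiseLDA(features=support, priors=priors
                                ).fit(X_tr, y_tr)
        else:
            cap = min(max_features,
                      int(np.sum(y_tr == 0)), int(np.sum(y_tr == 1)))
            try:
                model = StepwiseLDA(max_features=cap,
                                    tolerance_floor=tolerance_floor,
                                    entry_threshold=entry_threshold,
                                    priors=priors).fit(X_tr, y_tr)
            except EmptyModelError:
                # no predictor cleared the entry criterion in this fold:
                # the empty discriminant scores 0 everywhere, which the
                # tie rule assigns to control
                preds[i] = 0
                continue
        preds[i] = model.predict(X[i][None, :])[0]
    return confusion(y, preds, positive=1)
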