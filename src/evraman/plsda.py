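"""Partial least squares discriminant analysis (PLS-DA) for spectral ensembles.

The classifier regresses one-hot class indicators on mean-centered spectra
with the SIMPLS algorithm (de Jong 1993), assigns classes by argmax of the
predicted indicators, and reports the X-block variance captured per latent
variable (LV).  Model diagnostics follow standard chemometric practice:

* venetian-blinds cross-validation — fold k holds out samples whose index is
  congruent to k modulo the number of splits, in dataset order;
* outlier exclusion on the joint exceedance of Q residuals (squared distance
  off the LV subspace) and Hotelling T^2 (leverage within it) at a
  configurable confidence;
* per-class one-vs-rest sensitivity/specificity and ROC/AUC from the
  continuous predicted indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


def simpls(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """SIMPLS decomposition of centered blocks.

    Returns (R, T, P, Q, V): X-weights applicable directly to centered X,
    orthonormal X-scores, X-loadings, Y-loadings and the orthonormal
    deflation basis.  Regression coefficients are ``R @ Q.T``.
    """
    n, p = Xc.shape
    q = Yc.shape[1]
    A = n_components
    R = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    V = np.zeros((p, A))
    S = Xc.T @ Yc
    for a in range(A):
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] < 1e-14:
            raise np.linalg.LinAlgError(
                f"covariance exhausted after {a} latent variables"
            )
        r = U[:, 0]
        t = Xc @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-14:
            raise np.linalg.LinAlgError(
                f"degenerate score vector at latent variable {a + 1}"
            )
        t /= normt
        r /= normt
        p_a = Xc.T @ t
        q_a = Yc.T @ t
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, p_a, q_a, v
    return R, T, P, Q, V


@dataclass
class ClassificationReport:
    """Per-class one-vs-rest performance of a (cross-)validated model."""

    class_names: list
    confusion: pd.DataFrame
    sensitivity: dict
    specificity: dict
    auc: dict | None = None
    macro_auc: float | None = None
    excluded_ids: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = {
            c: {
                "sensitivity": self.sensitivity[c],
                "specificity": self.specificity[c],
                **({"auc": self.auc[c]} if self.auc else {}),
            }
            for c in self.class_names
        }
        return pd.DataFrame(rows).T


def _one_vs_rest_rates(y_true, y_pred, class_names):
    confusion = pd.DataFrame(
        0, index=list(class_names), columns=list(class_names), dtype=int
    )
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1
    sens, spec = {}, {}
    for c in class_names:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = confusion.values.sum() - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) else float("nan")
        spec[c] = tn / (tn + fp) if (tn + fp) else float("nan")
    return confusion, sens, spec


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: SIMPLS-family PLS2 on one-hot class indicators.

    Mean centering only (no variance scaling); the class decision is the
    argmax of the predicted indicator block.  Fitted attributes follow the
    scikit-learn convention (trailing underscore):

    ``x_weights_`` (R), ``x_scores_`` (orthonormal T), ``x_loadings_`` (P,
    the LV pseudospectra), ``y_loadings_`` (Q), ``coef_``,
    ``variance_captured_`` (% of X variance per LV), ``t2_limit_`` and
    ``q_limit_`` (training outlier reference limits at ``confidence``).
    """

    def __init__(self, n_components: int = 3, confidence: float = 0.95):
        self.n_components = n_components
        self.confidence = confidence

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA requires at least two classes")
        n, p = X.shape
        if self.n_components > min(p, n - 1):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(channels, "
                f"samples-1) = {min(p, n - 1)}"
            )
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_

        R, T, P, Q, V = simpls(Xc, Yc, self.n_components)
        self.x_weights_, self.x_scores_ = R, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.coef_ = R @ Q.T
        ss_x = float((Xc**2).sum())
        self.variance_captured_ = 100.0 * (P**2).sum(axis=0) / ss_x

        # outlier reference limits from the training distribution
        A = self.n_components
        self._score_var_ = T.var(axis=0, ddof=1)
        if n > A:
            f = stats.f.ppf(self.confidence, A, n - A)
            self.t2_limit_ = A * (n**2 - 1) / (n * (n - A)) * f
        else:
            self.t2_limit_ = np.inf
        q_train = self.q_residuals(X)
        m, v = float(q_train.mean()), float(q_train.var(ddof=1))
        if v > 0:
            g, h = v / (2 * m), 2 * m**2 / v
            self.q_limit_ = g * stats.chi2.ppf(self.confidence, h)
        else:
            self.q_limit_ = np.inf
        self.n_features_in_ = p
        return self

    # -- projections ---------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """LV scores of new samples (same convention as the training scores)."""
        check_is_fitted(self, "x_weights_")
        X = check_array(X, dtype=float)
        return (X - self.x_mean_) @ self.x_weights_

    def decision_function(self, X) -> np.ndarray:
        """Continuous predicted class indicators (one column per class)."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels, model was trained on "
                f"{self.n_features_in_}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    # -- outlier statistics ---------------------------------------------------

    def q_residuals(self, X) -> np.ndarray:
        """Per-sample squared residual off the LV subspace."""
        check_is_fitted(self, "x_loadings_")
        X = check_array(X, dtype=float)
        Xc = X - self.x_mean_
        T = Xc @ self.x_weights_
        resid = Xc - T @ self.x_loadings_.T
        return (resid**2).sum(axis=1)

    def hotelling_t2(self, X) -> np.ndarray:
        """Per-sample leverage: sum over LVs of score^2 / training score var."""
        check_is_fitted(self, "x_scores_")
        T = self.transform(X)
        return ((T**2) / self._score_var_).sum(axis=1)


def fit_plsda(X, y, n_lv: int = 3) -> PLSDAClassifier:
    """Thin functional wrapper over :class:`PLSDAClassifier`."""
    return PLSDAClassifier(n_components=n_lv).fit(X, y)


class VenetianBlinds:
    """Venetian-blinds cross-validation splitter (scikit-learn protocol).

    Fold k holds out samples with index congruent to k modulo ``splits`` in
    dataset order (no shuffling by default; pass a seed for an explicit
    pre-shuffle).
    """

    def __init__(self, splits: int = 10, shuffle_seed: int | None = None):
        if splits < 2:
            raise ValueError("splits must be >= 2")
        self.splits = splits
        self.shuffle_seed = shuffle_seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.splits

    def split(self, X, y=None, groups=None):
        n = len(X)
        order = np.arange(n)
        if self.shuffle_seed is not None:
            order = np.random.default_rng(self.shuffle_seed).permutation(n)
        for k in range(self.splits):
            test = order[k::self.splits]
            train = np.setdiff1d(order, test)
            yield train, test


def cross_validate(
    X, y, n_lv: int = 3, splits: int = 10, shuffle_seed: int | None = None
) -> ClassificationReport:
    """Venetian-blinds cross-validated classification report.

    The model is refit per fold; per-class sensitivity = TP/(TP+FN) and
    specificity = TN/(TN+FP), one-vs-rest, pooled over folds.  AUCs come from
    the pooled held-out indicator values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_names = list(np.unique(y))
    counts = pd.Series(y).value_counts()
    if (counts < splits).any():
        small = counts[counts < splits].index.tolist()
        raise ValueError(
            f"classes {small} have fewer members than splits={splits}"
        )
    cv = VenetianBlinds(splits, shuffle_seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    scores = np.zeros((len(y), len(class_names)))
    for train, test in cv.split(X, y):
        if len(np.unique(y[train])) < len(class_names):
            raise ValueError(
                "a venetian-blinds fold removes an entire class from training; "
                "reorder the samples or use fewer splits"
            )
        model = PLSDAClassifier(n_components=n_lv).fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        scores[test] = model.decision_function(X[test])

    confusion, sens, spec = _one_vs_rest_rates(y, y_pred, class_names)
    aucs = {}
    for j, c in enumerate(class_names):
        fpr, tpr, _ = _roc_curve((y == c).astype(int), scores[:, j])
        aucs[c] = float(_trapezoid_auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values())))
    return ClassificationReport(class_names, confusion, sens, spec, aucs, macro)


def exclude_outliers(
    model: PLSDAClassifier, X, y, *, refit: bool = True, warn_fraction: float = 0.2
):
    """Exclude samples whose Q residual AND Hotelling T^2 both exceed the
    training reference limits, then refit on the survivors.

    Requiring joint exceedance keeps the excluded fraction small; either
    statistic alone flags far more samples.  Returns
    ``(refit_model, keep_mask, diagnostics)``.
    """
    check_is_fitted(model, "q_limit_")
    X = np.asarray(X, dtype=float)
    q = model.q_residuals(X)
    t2 = model.hotelling_t2(X)
    outlier = (q > model.q_limit_) & (t2 > model.t2_limit_)
    keep = ~outlier
    frac = float(outlier.mean())
    if frac > warn_fraction:
        warnings.warn(
            f"{100 * frac:.1f}% of samples excluded as outliers; "
            "the model may be unstable", RuntimeWarning,
        )
    diagnostics = {"q": q, "t2": t2, "q_limit": model.q_limit_,
                   "t2_limit": model.t2_limit_, "excluded_fraction": frac}
    refit_model = model
    if refit and outlier.any():
        refit_model = PLSDAClassifier(
            n_components=model.n_components, confidence=model.confidence
        ).fit(X[keep], np.asarray(y)[keep])
    return refit_model, keep, diagnostics


def predict_report(
    model: PLSDAClassifier, X_new, y_true=None
) -> ClassificationReport | np.ndarray:
    """Predict new samples; with labels supplied, also score the prediction."""
    y_pred = model.predict(X_new)
    if y_true is None:
        return y_pred
    y_true = np.asarray(y_true)
    class_names = list(model.classes_)
    confusion, sens, spec = _one_vs_rest_rates(y_true, y_pred, class_names)
    scores = model.decision_function(X_new)
    aucs = {}
    for j, c in enumerate(class_names):
        mask_pos = (y_true == c)
        if mask_pos.any() and (~mask_pos).any():
            fpr, tpr, _ = _roc_curve(mask_pos.astype(int), scores[:, j])
            aucs[c] = float(_trapezoid_auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values()))) if aucs else None
    return ClassificationReport(class_names, confusion, sens, spec,
                                aucs or None, macro)


def plot_scores(model: PLSDAClassifier, X, y, out: str | None = None,
                lv_pair: tuple[int, int] = (0, 1)):
    """LV score scatter (one panel) plus per-LV violin plots by class."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    T = model.transform(X)
    y = np.asarray(y)
    classes = list(model.classes_)
    A = model.n_components
    fig, axes = plt.subplots(1, A + 1, figsize=(3.2 * (A + 1), 3.2))
    ax = axes[0]
    for c in classes:
        sel = y == c
        ax.scatter(T[sel, lv_pair[0]], T[sel, lv_pair[1]], s=6, label=str(c),
                   alpha=0.6)
    ax.set_xlabel(f"LV{lv_pair[0] + 1} score")
    ax.set_ylabel(f"LV{lv_pair[1] + 1} score")
    ax.legend(fontsize=7)
    for a in range(A):
        axv = axes[a + 1]
        axv.violinplot([T[y == c, a] for c in classes], showmedians=True)
        axv.set_xticks(np.arange(1, len(classes) + 1))
        axv.set_xticklabels([str(c) for c in classes], rotation=45,
                            fontsize=7)
        axv.set_title(f"LV{a + 1}", fontsize=9)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150, metadata={"Software": None})
        plt.close(fig)
        return out
    return fig


def roc_curves(model: PLSDAClassifier, X, y):
    """One-vs-rest ROC points and trapezoid AUC per class, plus the macro
    average.  Classes absent from ``y`` are skipped (recorded in the result)."""
    y = np.asarray(y)
    scores = model.decision_function(X)
    curves, aucs, skipped = {}, {}, []
    for j, c in enumerate(model.classes_):
        pos = (y == c)
        if not pos.any() or pos.all():
            skipped.append(c)
            continue
        fpr, tpr, thresholds = _roc_curve(pos.astype(int), scores[:, j])
        curves[c] = (fpr, tpr, thresholds)
        aucs[c] = float(_trapezoid_auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return {"curves": curves, "auc": aucs, "macro_auc": macro, "skipped": skipped}
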