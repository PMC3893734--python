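"""One-vs-rest subtype classifiers: PLS latent scores feeding binary
logistic regression.

Each classifier restricts the expression matrix to its subtype's 10-gene
panel, standardizes genes with training means/sds, extracts k latent
components (k chosen by PRESS + van der Voet when "auto"), and fits a
binary logistic regression on the x-scores by iteratively reweighted least
squares.  The predicted probability of membership is

    p = 1 / (1 + exp(-(b0 + b1 x1 + ... + bk xk)))

with x_a the a-th gene-component score.  Leave-one-out cross-validated
probabilities (full refit of scaling, PLS and LR per held-out sample) are
the primary, over-fitting-resistant output on a training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model_selection
from .expression import ExpressionMatrix
from .pls import PLSModel, fit_pls, project

logger = logging.getLogger(__name__)

#: ridge penalty applied when IRLS diverges (perfect separation)
RIDGE_FALLBACK = 1e-6


@dataclass
class LogisticModel:
    """Intercept and per-component coefficients of the score-space LR."""

    beta0: float
    betas: np.ndarray
    ridged: bool = False  # True when the perfect-separation fallback fired

    def linear_predictor(self, scores: np.ndarray) -> np.ndarray:
        return self.beta0 + np.atleast_2d(scores) @ self.betas

    def probability(self, scores: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(scores)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
        # keep the open-interval contract even when the predictor saturates
        return np.clip(p, 1e-12, 1.0 - 1e-12)


def fit_logistic_irls(scores: np.ndarray, labels: np.ndarray,
                      max_iter: int = 100, tol: float = 1e-10,
                      ridge: float = 0.0) -> LogisticModel:
    """Binary logistic regression on latent scores by Newton/IRLS.

    On divergence (perfect or quasi-separation: unbounded likelihood, the
    coefficients run away), refits with a small ridge penalty
    (``RIDGE_FALLBACK``) on the slope coefficients and logs a notice.
    """
    X = np.column_stack([np.ones(len(labels)), np.atleast_2d(scores)])
    y = np.asarray(labels, dtype=float).ravel()
    beta = np.zeros(X.shape[1])
    penalty = np.zeros(X.shape[1])
    penalty[1:] = ridge
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - penalty * beta
        hess = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return LogisticModel(float(beta[0]), beta[1:], ridged=ridge > 0)
        if np.max(np.abs(beta)) > 1e6 and ridge == 0.0:
            break
    if ridge == 0.0:
        logger.info(
            "IRLS did not converge (likely perfect separation); "
            "refitting with ridge %.0e", RIDGE_FALLBACK,
        )
        return fit_logistic_irls(scores, labels, max_iter, tol,
                                 ridge=RIDGE_FALLBACK)
    return LogisticModel(float(beta[0]), beta[1:], ridged=True)


@dataclass
class SubtypeClassifier:
    """Gene panel + scaling + PLS decomposition + logistic model."""

    subtype_name: str
    panel_genes: list[str]
    train_mean: np.ndarray  # per-panel-gene training mean
    train_sd: np.ndarray  # per-panel-gene training sd (n-1)
    pls: PLSModel
    lr: LogisticModel
    threshold: float = 0.5

    def _scores(self, matrix: ExpressionMatrix) -> np.ndarray:
        idx = matrix.gene_index(self.panel_genes)
        X = matrix.values[idx].T  # samples x genes
        X0 = (X - self.train_mean) / self.train_sd
        return project(self.pls, X0)

    def to_dict(self) -> dict:
        return {
            "subtype_name": self.subtype_name,
            "panel_genes": list(self.panel_genes),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "k": self.pls.k,
            "W": self.pls.W.tolist(),
            "P": self.pls.P.tolist(),
            "C": self.pls.C.tolist(),
            "x_var_explained": self.pls.x_var_explained.tolist(),
            "y_var_explained": self.pls.y_var_explained.tolist(),
            "beta0": self.lr.beta0,
            "betas": self.lr.betas.tolist(),
            "ridged": self.lr.ridged,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeClassifier":
        k = int(d["k"])
        genes = list(d["panel_genes"])
        pls = PLSModel(
            k=k,
            W=np.array(d["W"]),
            P=np.array(d["P"]),
            C=np.array(d["C"]),
            T=np.empty((0, k)),
            U=np.empty((0, k)),
            x_var_explained=np.array(d["x_var_explained"]),
            y_var_explained=np.array(d["y_var_explained"]),
            gene_order=genes,
        )
        lr = LogisticModel(float(d["beta0"]), np.array(d["betas"]),
                           bool(d.get("ridged", False)))
        return cls(d["subtype_name"], genes, np.array(d["train_mean"]),
                   np.array(d["train_sd"]), pls, lr, float(d["threshold"]))


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def fit_classifier(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    panel_genes: list[str],
    k: int | str = "auto",
    subtype_name: str = "",
    threshold: float = 0.5,
    n_folds: int = 7,
    vdv_alpha: float = 0.10,
    n_randomizations: int = 2000,
    seed: int | None = None,
    max_k: int | None = None,
) -> SubtypeClassifier:
    """Fit one one-vs-rest classifier on a labelled training cohort.

    *labels* is a binary vector over samples (1 = member of the subtype).
    With ``k="auto"`` the component count is chosen by split-sample
    cross-validation PRESS followed by van der Voet's test.
    """
    y = np.asarray(labels, dtype=float).ravel()
    if matrix.n_samples != len(y):
        raise ValueError("labels length does not match sample count")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 3:
        raise ValueError(
            f"need at least 3 samples per class (got {n_pos} vs {n_neg})"
        )
    idx = matrix.gene_index(list(panel_genes))
    X = matrix.values[idx].T
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before fitting")
    X0, mean, sd = _standardize_columns(X)
    y0 = y - y.mean()

    if k == "auto":
        kmax = max_k if max_k is not None else min(3, X0.shape[1],
                                                   matrix.n_samples - 2)
        cv = model_selection.split_sample_cv(X0, y0, kmax, n_folds)
        k_use = model_selection.select_components(
            cv, vdv_alpha, n_randomizations, seed
        )
    else:
        k_use = int(k)

    pls = fit_pls(X0, y0, k_use, gene_order=list(panel_genes))
    lr = fit_logistic_irls(pls.T, y)
    return SubtypeClassifier(subtype_name, list(panel_genes), mean, sd,
                             pls, lr, threshold)


def predict_probability(clf: SubtypeClassifier,
                        matrix: ExpressionMatrix) -> np.ndarray:
    """Membership probability per sample via the fitted scores and LR."""
    return np.asarray(clf.lr.probability(clf._scores(matrix))).ravel()


def loocv_probabilities(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    panel_genes: list[str],
    k: int,
    subtype_name: str = "",
) -> np.ndarray:
    """Leave-one-out cross-validated membership probabilities.

    For each sample the scaling, the PLS decomposition (k fixed — not
    re-selected per fold) and the logistic regression are refit on the other
    n-1 samples, and the held-out sample is predicted by that model.
    """
    y = np.asarray(labels, dtype=float).ravel()
    n = matrix.n_samples
    idx = matrix.gene_index(list(panel_genes))
    X = matrix.values[idx].T
    probs = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"leave-one-out fold {i} has a single-class training set"
            )
        X0, mean, sd = _standardize_columns(X[keep])
        pls = fit_pls(X0, y_tr - y_tr.mean(), k)
        lr = fit_logistic_irls(pls.T, y_tr)
        scores = project(pls, (X[i] - mean) / sd)
        probs[i] = float(lr.probability(scores)[0])
    return probs


@dataclass
class ClassifierMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float  # NaN when labels are single-class
    adjusted_r2: float  # Nagelkerke pseudo-R^2
    n_positive: int = 0
    n_negative: int = 0


def classifier_metrics(probabilities: np.ndarray, labels: np.ndarray,
                       threshold: float = 0.5) -> ClassifierMetrics:
    """Confusion metrics at *threshold*, rank-statistic AUC (midranks for
    ties) and Nagelkerke pseudo-R^2 from the probability log-likelihood."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    pred = p > threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")

    if n_pos == 0 or n_neg == 0:
        auc = float("nan")
    else:
        from scipy.stats import rankdata

        ranks = rankdata(p)  # midranks
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    n = len(y)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    prev = y.mean()
    if prev in (0.0, 1.0):
        r2 = float("nan")
    else:
        ll0 = n * (prev * np.log(prev) + (1 - prev) * np.log(1 - prev))
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        r2 = float(cox_snell / (1.0 - np.exp(2.0 * ll0 / n)))
    return ClassifierMetrics(accuracy, sensitivity, specificity, float(auc),
                             r2, n_pos, n_neg)
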