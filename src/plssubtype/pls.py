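"""Single-response partial least squares by NIPALS with X-deflation.

Latent gene components are extracted one at a time: the weight vector of
component *a* is the normalized cross-covariance X'y of the current residual
matrices, x-scores are t = Xw, and both X and y are deflated by the rank-one
approximation t p' (resp. t c) before the next component.  For a single
response each extraction is exact in one pass — no inner iteration is
needed — and successive score vectors are orthogonal by construction.

Notation follows the standard PLS literature: w weights, t x-scores,
p x-loadings, c y-loading, u y-scores.  Weight vectors are normalized to
unit Euclidean length; score vectors are not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NoPredictiveStructureError(ValueError):
    """The response is (numerically) orthogonal to every predictor."""


@dataclass
class PLSModel:
    """Fitted PLS decomposition X0 = T P' + E, y0 = T c' + f.

    All matrices have one column per extracted component; ``gene_order``
    fixes which predictor each row of W and P refers to.
    """

    k: int
    W: np.ndarray  # genes x k, unit-norm weight vectors
    P: np.ndarray  # genes x k, x-loadings
    C: np.ndarray  # k, y-loadings
    T: np.ndarray  # samples x k, x-scores
    U: np.ndarray  # samples x k, y-scores
    x_var_explained: np.ndarray  # per-component fraction of centered SS of X
    y_var_explained: np.ndarray  # per-component fraction of centered SS of y
    gene_order: list[str] = field(default_factory=list)

    @property
    def rotation(self) -> np.ndarray:
        """Deflation-corrected weights R = W (P'W)^-1, so that X0 R = T."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients mapping X0 to the fitted y0."""
        return self.rotation @ self.C


def fit_pls(X0: np.ndarray, y0: np.ndarray, k: int,
            gene_order: list[str] | None = None) -> PLSModel:
    """Extract *k* latent components from centered predictors and response.

    Parameters
    ----------
    X0
        Centered (and usually scaled) predictor matrix, samples x genes.
    y0
        Centered response, one value per sample.
    k
        Number of components; must satisfy ``1 <= k <= min(n, p)``.

    Raises
    ------
    NoPredictiveStructureError
        If at some component the residual response has (numerically) zero
        cross-covariance with every residual predictor.
    """
    X = np.array(X0, dtype=float)
    y = np.asarray(y0, dtype=float).ravel().copy()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X0 and y0 disagree on sample count")
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k={k} outside valid range [1, {min(n, p)}]")

    ss_x = float((X ** 2).sum())
    ss_y = float((y ** 2).sum())
    scale = np.sqrt(ss_x * ss_y) if ss_x * ss_y > 0 else 1.0

    W = np.empty((p, k))
    P = np.empty((p, k))
    C = np.empty(k)
    T = np.empty((n, k))
    U = np.empty((n, k))
    xve = np.empty(k)
    yve = np.empty(k)

    for a in range(k):
        cov = X.T @ y
        nrm = float(np.linalg.norm(cov))
        if nrm <= 1e-12 * max(scale, 1.0):
            raise NoPredictiveStructureError(
                f"no predictive structure at component {a + 1}: "
                "response orthogonal to all predictors"
            )
        w = cov / nrm
        # sign convention: largest-magnitude weight entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = X @ w
        tt = float(t @ t)
        p_a = X.T @ t / tt
        c_a = float(t @ y) / tt
        W[:, a], P[:, a], C[a], T[:, a] = w, p_a, c_a, t
        U[:, a] = y  # y-scores: residual response (q = 1 for one column)
        X -= np.outer(t, p_a)
        y = y - t * c_a
        xve[a] = tt * float(p_a @ p_a) / ss_x if ss_x > 0 else 0.0
        yve[a] = tt * c_a ** 2 / ss_y if ss_y > 0 else 0.0

    return PLSModel(k, W, P, C, T, U, xve, yve,
                    list(gene_order) if gene_order else [])


def project(model: PLSModel, new_X0: np.ndarray,
            gene_order: list[str] | None = None) -> np.ndarray:
    """Score new centered/scaled samples on the model's latent components.

    Uses the deflation-corrected rotation so that projecting the training
    matrix reproduces the training scores.  If *gene_order* is given it must
    match the model's training order.
    """
    if gene_order is not None and model.gene_order:
        if list(gene_order) != list(model.gene_order):
            missing = [g for g in model.gene_order if g not in set(gene_order)]
            raise KeyError(
                "gene order mismatch with fitted model"
                + (f"; missing: {', '.join(missing)}" if missing else "")
            )
    new_X0 = np.atleast_2d(np.asarray(new_X0, dtype=float))
    if new_X0.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} predictors, got {new_X0.shape[1]}"
        )
    return new_X0 @ model.rotation


def variance_explained(model: PLSModel) -> dict[str, np.ndarray]:
    """Per-component and cumulative fractions of X- and y-variance removed."""
    return {
        "x": model.x_var_explained.copy(),
        "y": model.y_var_explained.copy(),
        "x_cumulative": np.cumsum(model.x_var_explained),
        "y_cumulative": np.cumsum(model.y_var_explained),
    }
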