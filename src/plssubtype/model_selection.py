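"""Choose the number of latent components: cross-validated PRESS + van der
Voet's randomization test.

The candidate with minimal predicted residual sum of squares (PRESS) is the
reference; the selected model is the *smallest* candidate whose
cross-validated squared residuals are not significantly worse than the
reference under a paired sign-flip randomization test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import NoPredictiveStructureError, fit_pls, project


@dataclass
class CVResult:
    """Split-sample cross-validation summary over candidate component counts."""

    k_candidates: list[int]
    press: np.ndarray  # PRESS per candidate
    residuals: np.ndarray  # samples x candidates, cross-validated residuals
    k_min_press: int
    p_values: dict[int, float] = field(default_factory=dict)
    k_selected: int | None = None


def split_sample_cv(X0: np.ndarray, y0: np.ndarray, max_k: int,
                    n_folds: int = 7) -> CVResult:
    """Systematic split-sample CV: observation i goes to fold ``i % n_folds``.

    For each fold a PLS model is refit on the remaining observations and the
    held-out responses predicted with 1..max_k components;
    ``PRESS(k) = sum_i (y_i - yhat_i^(k))^2``.
    """
    X0 = np.asarray(X0, dtype=float)
    y0 = np.asarray(y0, dtype=float).ravel()
    n = len(y0)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n_folds > n:
        raise ValueError("more folds than observations")
    folds = np.arange(n) % n_folds
    min_train = min(int((folds != f).sum()) for f in range(n_folds))
    if not 1 <= max_k <= min(min_train, X0.shape[1]):
        raise ValueError(
            f"max_k={max_k} infeasible for fold training size {min_train}"
        )

    residuals = np.full((n, max_k), np.nan)
    for f in range(n_folds):
        train = folds != f
        test = ~train
        y_tr = y0[train]
        if np.all(y_tr == y_tr[0]):
            warnings.warn(
                f"fold {f}: training response is constant "
                "(one class lost entirely)", stacklevel=2
            )
        # a fold may exhaust the predictive structure before max_k
        # components; later candidates then predict no better than the last
        # extractable one
        k_fit = max_k
        while True:
            try:
                model = fit_pls(X0[train], y_tr, k_fit)
                break
            except NoPredictiveStructureError:
                if k_fit == 1:
                    raise
                k_fit -= 1
        scores = project(model, X0[test])
        # cumulative prediction over components: yhat^(k) = sum_{a<=k} t_a c_a
        yhat = np.cumsum(scores * model.C, axis=1)
        if k_fit < max_k:
            yhat = np.column_stack(
                [yhat] + [yhat[:, -1]] * (max_k - k_fit))
        residuals[test, :] = y0[test, None] - yhat

    press = (residuals ** 2).sum(axis=0)
    k_candidates = list(range(1, max_k + 1))
    k_min = k_candidates[int(np.argmin(press))]
    return CVResult(k_candidates, press, residuals, k_min)


def van_der_voet_test(residuals_k: np.ndarray, residuals_ref: np.ndarray,
                      n_randomizations: int = 2000,
                      seed: int | None = None) -> float:
    """Paired sign-flip randomization p-value comparing squared residuals.

    Statistic ``C = sum_i (r_ik^2 - r_iref^2)``; the null distribution flips
    the sign of each paired difference independently.  All ``2^n`` sign
    patterns are enumerated when n <= 20 (exact p, no smoothing); otherwise
    Monte Carlo with add-one smoothing and the given *seed*.
    """
    r_k = np.asarray(residuals_k, dtype=float).ravel()
    r_ref = np.asarray(residuals_ref, dtype=float).ravel()
    if r_k.shape != r_ref.shape:
        raise ValueError("paired residual vectors must have equal length")
    d = r_k ** 2 - r_ref ** 2
    if np.all(d == 0):
        return 1.0
    c_obs = abs(float(d.sum()))
    n = len(d)
    if n <= 20:
        count = 0
        total = 1 << n
        chunk = 1 << min(n, 16)
        patterns = np.arange(chunk)[:, None] >> np.arange(min(n, 16)) & 1
        signs_low = 1.0 - 2.0 * patterns  # chunk x min(n,16)
        for hi in range(total // chunk):
            hi_bits = hi >> np.arange(max(n - 16, 0)) & 1
            hi_signs = 1.0 - 2.0 * hi_bits
            base = float(hi_signs @ d[16:]) if n > 16 else 0.0
            c_star = signs_low @ d[: min(n, 16)] + base
            count += int((np.abs(c_star) >= c_obs - 1e-12 * max(c_obs, 1)).sum())
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_randomizations, n))
    c_star = signs @ d
    count = int((np.abs(c_star) >= c_obs - 1e-12 * max(c_obs, 1)).sum())
    return (count + 1) / (n_randomizations + 1)


def select_components(cv: CVResult, alpha: float = 0.10,
                      n_randomizations: int = 2000,
                      seed: int | None = None) -> int:
    """Smallest candidate not significantly worse than the PRESS minimizer.

    Fills ``cv.p_values`` and ``cv.k_selected`` in place and returns the
    selected component count; the PRESS minimizer itself is always
    admissible (p = 1 by construction).
    """
    ref_idx = cv.k_candidates.index(cv.k_min_press)
    r_ref = cv.residuals[:, ref_idx]
    for i, k in enumerate(cv.k_candidates):
        cv.p_values[k] = van_der_voet_test(
            cv.residuals[:, i], r_ref, n_randomizations, seed
        )
    for k in cv.k_candidates:
        if k > cv.k_min_press:
            break
        if cv.p_values[k] >= alpha:
            cv.k_selected = k
            return k
    cv.k_selected = cv.k_min_press
    return cv.k_min_press


def cv_report_rows(cv: CVResult) -> list[dict]:
    """Rows for a TSV report: candidate k, PRESS, p-value, selected flag."""
    return [
        {
            "k": k,
            "press": float(cv.press[i]),
            "p_value": cv.p_values.get(k, float("nan")),
            "selected": k == cv.k_selected,
        }
        for i, k in enumerate(cv.k_candidates)
    ]
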