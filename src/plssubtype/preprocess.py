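"""Turn raw expression tables into the matrices the classifiers consume.

Three steps: collapse multiple probesets per gene to the most variable one
(inter-quartile range across arrays), standardize each gene to mean 0 / sd 1
across samples, and fill missing entries by an expectation-maximization loop
around a low-rank reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


def _row_iqr(values: np.ndarray) -> np.ndarray:
    """Per-row IQR ignoring NaN, using linear-interpolation quantiles.

    Rows with no observed value get NaN (ineligible for collapse).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q75 = np.nanpercentile(values, 75, axis=1)
        q25 = np.nanpercentile(values, 25, axis=1)
    return q75 - q25


def collapse_by_iqr(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Keep, for each gene, the probeset with the largest IQR across samples.

    ``probe_to_gene`` must cover every row of *matrix* (rows are probesets).
    Genes measured by a single probeset pass through unchanged.  An IQR tie
    keeps the first probeset in input order and logs a warning.
    """
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("cannot collapse an empty matrix")
    probes = matrix.probeset_ids if matrix.probeset_ids is not None else matrix.gene_ids
    unmapped = [p for p in probes if p not in probe_to_gene]
    if unmapped:
        raise KeyError(f"probesets without a gene mapping: {', '.join(unmapped[:5])}")

    iqr = _row_iqr(matrix.values)
    chosen: dict[str, int] = {}
    gene_order: list[str] = []
    for row, probe in enumerate(probes):
        gene = probe_to_gene[probe]
        if np.isnan(iqr[row]):
            logger.warning("probeset %s has no observed values; ineligible", probe)
            continue
        if gene not in chosen:
            chosen[gene] = row
            gene_order.append(gene)
        elif iqr[row] > iqr[chosen[gene]]:
            chosen[gene] = row
        elif iqr[row] == iqr[chosen[gene]]:
            logger.warning(
                "IQR tie for gene %s between %s and %s; keeping first",
                gene, probes[chosen[gene]], probe,
            )
    missing_genes = {probe_to_gene[p] for p in probes} - set(chosen)
    if missing_genes:
        raise ValueError(
            f"genes with only fully-missing probesets: {', '.join(sorted(missing_genes))}"
        )
    rows = [chosen[g] for g in gene_order]
    return ExpressionMatrix(
        gene_order,
        list(matrix.sample_ids),
        matrix.values[rows],
        probeset_ids=[probes[r] for r in rows],
    )


@dataclass
class StandardizeResult:
    matrix: ExpressionMatrix
    zero_variance_genes: list[str]


def standardize_genes(
    matrix: ExpressionMatrix, center_only: bool = False
) -> StandardizeResult:
    """Center each gene row; unless *center_only*, also scale to unit sd (n-1).

    Zero-variance rows are centered only and reported in the result; no
    missing values are allowed (impute first).
    """
    values = matrix.values
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute before standardizing")
    centered = values - values.mean(axis=1, keepdims=True)
    zero_var: list[str] = []
    if not center_only:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        flat = (sd[:, 0] == 0) | np.isnan(sd[:, 0])
        zero_var = [g for g, z in zip(matrix.gene_ids, flat) if z]
        if zero_var:
            logger.warning("%d zero-variance genes centered only", len(zero_var))
        sd[flat] = 1.0
        centered = centered / sd
    out = ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), centered, matrix.probeset_ids
    )
    return StandardizeResult(out, zero_var)


@dataclass
class ImputeResult:
    matrix: ExpressionMatrix
    converged: bool
    n_iter: int
    max_change: float


def impute_em(
    matrix: ExpressionMatrix,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 100,
    response: np.ndarray | None = None,
) -> ImputeResult:
    """Fill missing entries by EM around a low-rank model of the gene rows.

    Missing entries start at the gene's mean over observed samples, then are
    iteratively replaced by the reconstruction of a rank-``n_components``
    model fitted to the completed matrix, until the largest absolute change
    falls below *tol* or *max_iter* is reached.  Observed entries are never
    altered.  When *response* (one value per sample) is given the
    reconstruction is the x-part of a partial-least-squares fit; otherwise a
    truncated SVD (principal-component reconstruction) is used.
    """
    values = matrix.values
    mask = np.isnan(values)
    if not mask.any():
        return ImputeResult(matrix.copy(), True, 0, 0.0)
    fully_missing = mask.all(axis=1)
    if fully_missing.any():
        bad = [g for g, b in zip(matrix.gene_ids, fully_missing) if b]
        raise ValueError(f"variables with no observed value: {', '.join(bad)}")

    work = values.copy()
    row_mean = np.nanmean(values, axis=1)
    work[mask] = np.broadcast_to(row_mean[:, None], work.shape)[mask]

    converged = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        center = work.mean(axis=1, keepdims=True)
        centered = work - center
        recon = _low_rank_reconstruction(centered.T, n_components, response).T + center
        change = float(np.max(np.abs(recon[mask] - work[mask])))
        work[mask] = recon[mask]
        if change < tol:
            converged = True
            break
    out = ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), work, matrix.probeset_ids
    )
    return ImputeResult(out, converged, it, change)


def _low_rank_reconstruction(
    X: np.ndarray, n_components: int, response: np.ndarray | None
) -> np.ndarray:
    """Rank-k reconstruction of a samples x variables matrix."""
    k = min(n_components, min(X.shape))
    if response is not None:
        from .pls import fit_pls

        y = np.asarray(response, dtype=float)
        model = fit_pls(X, y - y.mean(), k)
        return model.T @ model.P.T
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    return (u[:, :k] * s[:k]) @ vt[:k]
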