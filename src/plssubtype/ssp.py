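"""Centroid-based single-sample prediction (SSP).

The comparator method: each subtype is represented by the per-gene mean
expression of its training samples (the centroid), and a new sample is
assigned to the subtype whose centroid it is most Spearman-correlated with,
or left Unclassified when every correlation falls below the threshold
(default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .assembly import SUBTYPES, UNCLASSIFIED
from .expression import ExpressionMatrix

RHO_THRESHOLD = 0.1


@dataclass
class CentroidSet:
    """Per-subtype mean expression over the signature genes."""

    subtype_names: list[str]
    gene_ids: list[str]
    centroids: np.ndarray  # subtypes x genes

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (len(self.subtype_names), len(self.gene_ids)):
            raise ValueError("centroid matrix shape mismatch")
        if np.isnan(self.centroids).any():
            raise ValueError("centroids contain missing entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in centroid set")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.centroids.T, index=self.gene_ids,
                            columns=self.subtype_names)

    @classmethod
    def read_tsv(cls, path) -> "CentroidSet":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.columns), [str(g) for g in frame.index],
                   frame.to_numpy(dtype=float).T)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_centroids(matrix: ExpressionMatrix, labels,
                    subtype_names: list[str] | None = None) -> CentroidSet:
    """Per-gene arithmetic mean within each subtype."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("labels length does not match sample count")
    names = subtype_names or [s for s in SUBTYPES if s in set(labels)]
    if not names:
        names = sorted(set(labels))
    cents = np.empty((len(names), matrix.n_genes))
    for i, name in enumerate(names):
        members = labels == name
        if not members.any():
            raise ValueError(f"subtype {name!r} has zero samples")
        cents[i] = matrix.values[:, members].mean(axis=1)
    return CentroidSet(list(names), list(matrix.gene_ids), cents)


@dataclass
class SSPCall:
    sample_id: str
    correlations: dict[str, float]
    label: str


def ssp_assign(sample_vector: np.ndarray, centroids: CentroidSet,
               rho_threshold: float = RHO_THRESHOLD,
               sample_id: str = "") -> SSPCall:
    """Assign one sample to the centroid with maximal Spearman rho.

    The sample vector must be aligned to ``centroids.gene_ids``.  Assigned
    iff the maximal rho reaches the threshold (an all-below-threshold sample
    is Unclassified); ties on the maximum go to the earlier subtype with a
    warning.  A constant sample vector has undefined rank correlation and is
    returned Unclassified with a warning.
    """
    x = np.asarray(sample_vector, dtype=float).ravel()
    if len(x) != len(centroids.gene_ids):
        raise ValueError("sample vector not aligned to centroid genes")
    if len(x) < 3:
        raise ValueError("need at least 3 genes for rank correlation")
    if np.all(x == x[0]):
        warnings.warn(f"constant sample vector {sample_id!r}: "
                      "rank correlation undefined", stacklevel=2)
        return SSPCall(sample_id, {s: float("nan") for s in centroids.subtype_names},
                       UNCLASSIFIED)
    rhos = {}
    for i, name in enumerate(centroids.subtype_names):
        rho = spearmanr(x, centroids.centroids[i]).statistic
        rhos[name] = float(rho)
    vals = np.array([rhos[s] for s in centroids.subtype_names])
    best = int(np.nanargmax(vals))
    if (vals == vals[best]).sum() > 1:
        warnings.warn(f"tied maximal correlation for sample {sample_id!r}; "
                      "keeping canonical order", stacklevel=2)
    label = centroids.subtype_names[best] if vals[best] >= rho_threshold \
        else UNCLASSIFIED
    return SSPCall(sample_id, rhos, label)


def ssp_cohort(matrix: ExpressionMatrix, centroids: CentroidSet,
               rho_threshold: float = RHO_THRESHOLD) -> list[SSPCall]:
    """SSP calls for every sample of a cohort (genes aligned by name)."""
    idx = matrix.gene_index(list(centroids.gene_ids))
    sub = matrix.values[idx]
    return [
        ssp_assign(sub[:, j], centroids, rho_threshold, matrix.sample_ids[j])
        for j in range(matrix.n_samples)
    ]
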