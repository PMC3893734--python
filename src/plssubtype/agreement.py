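"""Cross-tabulation and weighted Cohen's kappa.

Agreement between two call sets (e.g. centroid SSP vs the PLS classifier)
is summarized by a confusion table over an ordered category list and by
weighted Cohen's kappa.  Linear (Cicchetti-Allison) weights
``w_ij = 1 - |i - j| / (R - 1)`` are the default; quadratic and unweighted
schemes are available.  The standard error is the Fleiss-Cohen-Everitt
large-sample formula and the 95% CI is the Wald interval truncated to
[-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def drop(self, labels) -> "ConfusionTable":
        """Remove the given labels from both axes (where present)."""
        labels = set(labels)
        keep_r = [i for i, l in enumerate(self.row_labels) if l not in labels]
        keep_c = [j for j, l in enumerate(self.col_labels) if l not in labels]
        return ConfusionTable(
            [self.row_labels[i] for i in keep_r],
            [self.col_labels[j] for j in keep_c],
            self.counts[np.ix_(keep_r, keep_c)],
        )

    def squared(self) -> "ConfusionTable":
        """Embed into the square table over the union of row/col labels,
        rows first, zero-filling missing cells."""
        labels = list(self.row_labels) + [
            l for l in self.col_labels if l not in self.row_labels
        ]
        out = np.zeros((len(labels), len(labels)))
        ri = {l: i for i, l in enumerate(labels)}
        for i, rl in enumerate(self.row_labels):
            for j, cl in enumerate(self.col_labels):
                out[ri[rl], ri[cl]] = self.counts[i, j]
        return ConfusionTable(labels, labels, out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.astype(int), index=self.row_labels,
                            columns=self.col_labels)

    @classmethod
    def read_tsv(cls, path) -> "ConfusionTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(r) for r in frame.index],
                   [str(c) for c in frame.columns],
                   frame.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def cross_tabulate(calls_a, calls_b, label_order: list[str],
                   drop_labels=None) -> ConfusionTable:
    """Square confusion table of two aligned call sequences.

    *calls_a* index the rows, *calls_b* the columns; both are dicts
    sample -> label or equal-length sequences over the same samples.
    Labels in *drop_labels* (e.g. ``{"Unclassified"}``) are removed from
    both axes after tabulation.
    """
    if isinstance(calls_a, dict) or isinstance(calls_b, dict):
        if not (isinstance(calls_a, dict) and isinstance(calls_b, dict)):
            raise TypeError("both call sets must be dicts or both sequences")
        only_a = set(calls_a) - set(calls_b)
        only_b = set(calls_b) - set(calls_a)
        if only_a or only_b:
            raise ValueError(
                f"call sets disagree on samples (only in a: {sorted(only_a)[:3]}, "
                f"only in b: {sorted(only_b)[:3]})"
            )
        samples = list(calls_a)
        a = [calls_a[s] for s in samples]
        b = [calls_b[s] for s in samples]
    else:
        a, b = list(calls_a), list(calls_b)
        if len(a) != len(b):
            raise ValueError("call sets have different lengths")
    unknown = (set(a) | set(b)) - set(label_order)
    if unknown:
        raise ValueError(f"labels outside label_order: {sorted(unknown)}")
    counts = np.zeros((len(label_order), len(label_order)))
    index = {l: i for i, l in enumerate(label_order)}
    for la, lb in zip(a, b):
        counts[index[la], index[lb]] += 1
    table = ConfusionTable(list(label_order), list(label_order), counts)
    if drop_labels:
        table = table.drop(drop_labels)
    return table


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    weight_scheme: str
    n: int


def _weights(r: int, scheme: str) -> np.ndarray:
    i, j = np.indices((r, r))
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (r - 1) if r > 1 else np.ones((1, 1))
    if scheme == "quadratic":
        return 1.0 - (i - j) ** 2 / (r - 1) ** 2 if r > 1 else np.ones((1, 1))
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(table: ConfusionTable, scheme: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa with large-sample SE and 95% Wald CI.

    kappa = (Po_w - Pe_w) / (1 - Pe_w), where Po_w is the weighted observed
    agreement and Pe_w the weighted chance agreement from the marginal
    products.  Requires a square table with identically ordered categories.
    """
    if table.row_labels != table.col_labels:
        raise ValueError("weighted kappa requires a square, identically "
                         "ordered table (see ConfusionTable.squared)")
    n = table.total
    if n <= 0:
        raise ValueError("empty table")
    P = table.counts / n
    r = len(table.row_labels)
    w = _weights(r, scheme)
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    po = float((w * P).sum())
    pe = float((w * np.outer(p_row, p_col)).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ZeroDivisionError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt asymptotic variance of weighted kappa
    wbar_row = w @ p_col  # average weight of row category i
    wbar_col = w.T @ p_row
    term = (w * (1 - pe)
            - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)) ** 2
    var = (float((P * term).sum()) - (po * pe - 2 * pe + po) ** 2) \
        / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = max(kappa - 1.96 * se, -1.0)
    ci_high = min(kappa + 1.96 * se, 1.0)
    return KappaResult(float(kappa), se, ci_low, ci_high, scheme, int(round(n)))
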