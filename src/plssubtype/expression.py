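"""Gene-expression matrix container and tab-delimited I/O.

The universal input of the package: a genes x samples matrix of log-scale
expression values with gene symbols (or, pre-collapse, platform probeset
identifiers) as row names and sample identifiers as column names.  Missing
entries are represented as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: missing-value codes accepted in input files
NA_CODES = ["", "NA", "NaN", "nan", "null"]


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    gene_ids
        Row identifiers: gene symbols, or probeset ids before collapsing.
    sample_ids
        Column identifiers, unique.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; NaN marks
        a missing entry.
    probeset_ids
        Optional platform probeset identifiers (pre-collapse state).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probeset_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: list[str]) -> np.ndarray:
        """Row indices of *genes*, erroring on any gene absent from the matrix."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not present in matrix: {', '.join(missing)}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in keep],
            self.values[:, keep],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            list(self.probeset_ids) if self.probeset_ids is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        index = self.probeset_ids if self.probeset_ids is not None else self.gene_ids
        return pd.DataFrame(self.values, index=index, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(dtype=float),
        )

    @classmethod
    def read_tsv(cls, path, orientation: str = "genes_in_rows") -> "ExpressionMatrix":
        """Read a tab-delimited matrix: first column row ids, header of column ids."""
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=NA_CODES, keep_default_na=False
        )
        if orientation == "samples_in_rows":
            frame = frame.T
        elif orientation != "genes_in_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls.from_frame(frame)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probeset -> gene TSV (header optional, detected)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("probe map must have two columns: probeset, gene")
    first = frame.iloc[0]
    if first.str.lower().isin(["probeset", "probe", "probe_id", "probeset_id"]).any():
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def read_labels(path) -> pd.Series:
    """Read a two-column sample -> label TSV into a Series indexed by sample."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = frame.iloc[0]
    if first.str.lower().isin(["sample", "sample_id", "id"]).any():
        frame = frame.iloc[1:]
    return pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values)
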