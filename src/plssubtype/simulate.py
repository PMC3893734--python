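"""Synthetic expression cohorts with subtype-centroid structure, plus the
packaged gene panels and printed confusion tables.

The generator emulates the structural assumption behind centroid-based
subtyping: each subtype shifts the mean of its own signature genes, all
other variation is independent Gaussian noise.  Gene g of a sample from
subtype s takes the value

    shift(g, s) + Normal(0, noise_sd)

where shift is ``effect_size`` (in sd units) for genes on subtype s's own
panel, an optional cross-effect for genes on other panels, and 0 for
background genes.  Entries may then be masked missing uniformly at random.
Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .agreement import ConfusionTable
from .assembly import SUBTYPES, UNCLASSIFIED
from .expression import ExpressionMatrix

#: training-prototype cohort composition (samples per subtype, canonical order)
PROTOTYPE_COUNTS = (57, 35, 23, 12, 12)


@dataclass
class GenePanel:
    """Ordered 10-gene panel of one subtype, with the published reference
    weight vector (stored verbatim; not renormalized)."""

    subtype_name: str
    gene_ids: list[str]
    reference_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate gene in panel")
        if self.reference_weights is not None:
            self.reference_weights = np.asarray(self.reference_weights, float)
            if len(self.reference_weights) != len(self.gene_ids):
                raise ValueError("weights do not match genes")


@dataclass
class SimulationSpec:
    """Conditions of one synthetic cohort.

    Defaults mirror the prototype training cohort: 57/35/23/12/12 samples
    per subtype, a 2-sd mean shift on a subtype's own panel genes, unit
    Gaussian noise, no background genes and no missingness.
    """

    seed: int
    n_per_subtype: tuple = PROTOTYPE_COUNTS
    panels: list[GenePanel] | None = None
    background_genes: int = 0
    effect_size: float = 2.0
    cross_effects: dict | None = None  # (subtype, panel_subtype) -> shift
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.panels is None:
            self.panels = load_pam50_panels()
        if len(self.n_per_subtype) != len(self.panels):
            raise ValueError("n_per_subtype must give one count per panel")


def generate_cohort(spec: SimulationSpec) -> tuple[ExpressionMatrix, list[str]]:
    """Draw one cohort; returns the genes x samples matrix and true labels."""
    rng = np.random.default_rng(spec.seed)
    gene_ids: list[str] = []
    for panel in spec.panels:
        for g in panel.gene_ids:
            if g not in gene_ids:  # panels may share genes
                gene_ids.append(g)
    gene_ids += [f"BG{i + 1:04d}" for i in range(spec.background_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    labels: list[str] = []
    for panel, n in zip(spec.panels, spec.n_per_subtype):
        labels += [panel.subtype_name] * int(n)
    n_samples = len(labels)
    n_genes = len(gene_ids)

    mean = np.zeros((n_genes, n_samples))
    for j, lab in enumerate(labels):
        for panel in spec.panels:
            if panel.subtype_name == lab:
                shift = spec.effect_size
            elif spec.cross_effects:
                shift = float(spec.cross_effects.get(
                    (lab, panel.subtype_name), 0.0))
            else:
                shift = 0.0
            if shift:
                for g in panel.gene_ids:
                    mean[gene_index[g], j] += shift

    values = mean + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))
    if spec.missing_rate > 0:
        mask = rng.random((n_genes, n_samples)) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


def load_pam50_panels() -> list[GenePanel]:
    """The five published 10-gene panels with their printed weight vectors."""
    path = resources.files("plssubtype.data") / "pam50_panels.tsv"
    frame = pd.read_csv(path, sep="\t")
    panels = []
    for subtype in SUBTYPES:
        block = frame[frame["subtype"] == subtype]
        panels.append(GenePanel(subtype, list(block["gene"]),
                                block["weight"].to_numpy(float)))
    return panels


def load_printed_confusions() -> tuple[ConfusionTable, ConfusionTable]:
    """The packaged training (5x6) and validation (6x6) cross-tabulations
    of centroid SSP calls (rows) against the PLS classifier (columns)."""
    data = resources.files("plssubtype.data")
    training = ConfusionTable.read_tsv(data / "table2_confusion.tsv")
    validation = ConfusionTable.read_tsv(data / "table4_confusion.tsv")
    return training, validation
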