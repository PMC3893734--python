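"""Combine five one-vs-rest classifiers into a single subtype call.

Standard mode: a sample is called for the subtype with the highest
cross-validated probability provided that probability exceeds the 0.5
threshold; the call is flagged ambiguous when more than one classifier
exceeds the threshold, and Unclassified when none does.  Forced mode
categorizes every sample into the argmax subtype as long as the highest
probability exceeds 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical subtype order used for argmax tie-breaks and confusion tables
SUBTYPES = [
    "Basal-like",
    "HER2-enriched",
    "Luminal-A",
    "Luminal-B",
    "Normal breast-like",
]
UNCLASSIFIED = "Unclassified"

FORCED_THRESHOLD = 0.1


@dataclass
class SubtypeCall:
    sample_id: str
    probabilities: dict[str, float]
    label: str
    ambiguous: bool
    mode: str = "standard"


def assemble_call(probabilities: dict[str, float], threshold: float = 0.5,
                  mode: str = "standard", sample_id: str = "",
                  forced_threshold: float = FORCED_THRESHOLD) -> SubtypeCall:
    """Turn five per-subtype probabilities into one labelled call.

    Strict inequalities throughout: a probability must exceed (not merely
    reach) the threshold to count as a positive prediction.  Exact argmax
    ties go to the earlier subtype in canonical order, flagged ambiguous.
    """
    missing = [s for s in SUBTYPES if s not in probabilities]
    if missing:
        raise KeyError(f"missing subtype probabilities: {', '.join(missing)}")
    probs = np.array([probabilities[s] for s in SUBTYPES], dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    best = int(np.argmax(probs))  # first max in canonical order
    tied = int((probs == probs[best]).sum()) > 1
    positives = int((probs > threshold).sum())
    if mode == "standard":
        if positives == 0:
            return SubtypeCall(sample_id, dict(probabilities), UNCLASSIFIED,
                               False, mode)
        return SubtypeCall(sample_id, dict(probabilities), SUBTYPES[best],
                           positives > 1 or tied, mode)
    if mode == "forced":
        if probs[best] <= forced_threshold:
            return SubtypeCall(sample_id, dict(probabilities), UNCLASSIFIED,
                               False, mode)
        return SubtypeCall(sample_id, dict(probabilities), SUBTYPES[best],
                           positives > 1 or tied, mode)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CohortCalls:
    calls: list[SubtypeCall]
    n_ambiguous: int = 0
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        self.n_ambiguous = sum(c.ambiguous for c in self.calls)
        self.n_unclassified = sum(c.label == UNCLASSIFIED for c in self.calls)

    def labels(self) -> list[str]:
        return [c.label for c in self.calls]

    def summary(self) -> dict:
        counts = {s: 0 for s in SUBTYPES + [UNCLASSIFIED]}
        for c in self.calls:
            counts[c.label] += 1
        return {
            "n": len(self.calls),
            "counts": counts,
            "n_ambiguous": self.n_ambiguous,
            "n_unclassified": self.n_unclassified,
        }


def classify_cohort(matrix, classifiers: dict, labels=None,
                    use_loocv: bool = False, mode: str = "standard",
                    threshold: float | None = None,
                    forced_threshold: float = FORCED_THRESHOLD) -> CohortCalls:
    """Call every sample of a cohort with the five fitted classifiers.

    On a training cohort pass ``use_loocv=True`` together with the training
    *labels* (subtype name per sample): each classifier's probabilities are
    then leave-one-out cross-validated.  On an external cohort the fitted
    models predict directly.
    """
    from .classifier import loocv_probabilities, predict_probability

    missing = [s for s in SUBTYPES if s not in classifiers]
    if missing:
        raise KeyError(f"missing classifiers for: {', '.join(missing)}")
    prob_matrix = {}
    for name in SUBTYPES:
        clf = classifiers[name]
        if use_loocv:
            if labels is None:
                raise ValueError("use_loocv requires the training labels")
            binary = (np.asarray(labels) == name).astype(float)
            prob_matrix[name] = loocv_probabilities(
                matrix, binary, clf.panel_genes, clf.pls.k, name
            )
        else:
            prob_matrix[name] = predict_probability(clf, matrix)
    thr = threshold if threshold is not None else classifiers[SUBTYPES[0]].threshold
    calls = [
        assemble_call(
            {s: float(prob_matrix[s][i]) for s in SUBTYPES},
            threshold=thr, mode=mode, sample_id=matrix.sample_ids[i],
            forced_threshold=forced_threshold,
        )
        for i in range(matrix.n_samples)
    ]
    return CohortCalls(calls)
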