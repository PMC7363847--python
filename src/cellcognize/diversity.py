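"""Community profiles, probability-based similarity scores, diversity summaries.

Per-event probability vectors are condensed into a class-attribution
profile: counts, relative abundances, and per-class statistics of the
*winning* probability (the probability of the class each event was
assigned to).  The mean winning probability of a query population,
relative to that of the true standard's own cells, defines the
classification similarity score.  Profiles feed the ecological
summaries: richness above an abundance threshold, Shannon entropy
(natural log), and pairwise Bray-Curtis dissimilarities on counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _entropy

from .ann import ClassificationResult

__all__ = [
    "ClassAttributionProfile",
    "DiversitySummary",
    "attribution_profile",
    "classification_similarity_score",
    "chance_accuracy",
    "diversity_summary",
]


@dataclass
class ClassAttributionProfile:
    """Summary of one classification run over a sample.

    ``mean_probability`` is NaN for classes with no attributed events.
    ``probability_histogram`` has one row per class, binned on [0, 1];
    each row sums to that class's count.
    """

    class_counts: pd.Series
    relative_abundance: pd.Series
    mean_probability: pd.Series
    probability_histogram: pd.DataFrame
    bin_edges: np.ndarray

    @property
    def class_labels(self) -> list[str]:
        return list(self.class_counts.index)


def attribution_profile(
    result: ClassificationResult, bins: int = 50
) -> ClassAttributionProfile:
    """Condense per-event assignments into a class-attribution profile."""
    if result.n_events == 0:
        raise ValueError("cannot profile an empty classification result")
    labels = result.class_labels
    counts = result.class_counts.astype(float)
    rel = counts / counts.sum()
    win = result.winning_probability
    edges = np.linspace(0.0, 1.0, bins + 1)
    mean_p = pd.Series(np.nan, index=labels, dtype=float)
    hist = pd.DataFrame(
        np.zeros((len(labels), bins)), index=labels,
        columns=[f"bin_{i}" for i in range(bins)],
    )
    for i, lab in enumerate(labels):
        mask = result.assigned_idx == i
        if mask.any():
            mean_p[lab] = float(win[mask].mean())
            h, _ = np.histogram(win[mask], bins=edges)
            hist.loc[lab] = h
    return ClassAttributionProfile(
        class_counts=counts,
        relative_abundance=rel,
        mean_probability=mean_p,
        probability_histogram=hist,
        bin_edges=edges,
    )


def classification_similarity_score(
    attributed_mean_p: float, standard_mean_p: float
) -> float:
    """Similarity (%) of a query population to a standard class.

    The ratio of the query cells' mean winning probability in a class
    to the mean winning probability of the true standard's own cells in
    that class, times 100.  Returned at full precision; round to the
    nearest whole percent for reporting.  100% means the query is
    classified as confidently as the standard itself.
    """
    if not 0 < attributed_mean_p <= 1:
        raise ValueError("attributed_mean_p must be in (0, 1]")
    if not 0 < standard_mean_p <= 1:
        raise ValueError("standard_mean_p must be in (0, 1]")
    return 100.0 * attributed_mean_p / standard_mean_p


def chance_accuracy(k: int) -> float:
    """Expected accuracy (%) of random assignment over ``k`` classes: 100/k."""
    if k < 1:
        raise ValueError("class count must be >= 1")
    return 100.0 / k


@dataclass
class DiversitySummary:
    """Richness, Shannon entropy and Bray-Curtis dissimilarities over profiles."""

    richness: pd.Series
    shannon: pd.Series
    pairwise_bray_curtis: pd.DataFrame
    richness_threshold: float


def diversity_summary(
    profiles: Sequence[ClassAttributionProfile],
    richness_threshold: float = 0.0005,
    sample_ids: Sequence[str] | None = None,
) -> DiversitySummary:
    """Ecological summaries over a set of class-attribution profiles.

    Richness counts classes whose relative abundance strictly exceeds
    ``richness_threshold`` (default 0.05%).  Shannon entropy H =
    -sum(p ln p) is in nats, with 0 ln 0 taken as 0.  Bray-Curtis
    dissimilarity is computed on counts, so profile pairs with no
    shared classes score 1 and identical profiles score 0.
    """
    if not profiles:
        raise ValueError("diversity of an empty profile set is undefined")
    labels = profiles[0].class_labels
    for p in profiles[1:]:
        if p.class_labels != labels:
            raise ValueError("profiles must share class label ordering")
    ids = list(sample_ids) if sample_ids is not None else [
        f"profile_{i}" for i in range(len(profiles))
    ]
    counts = np.vstack([p.class_counts.to_numpy(dtype=float) for p in profiles])
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("diversity of an empty profile is undefined")
    rel = counts / counts.sum(axis=1, keepdims=True)
    richness = (rel > richness_threshold).sum(axis=1)
    shannon = np.array([_entropy(row) for row in rel])  # natural log, ignores zeros
    if len(profiles) > 1:
        bc = squareform(pdist(counts, metric="braycurtis"))
    else:
        bc = np.zeros((1, 1))
    return DiversitySummary(
        richness=pd.Series(richness, index=ids),
        shannon=pd.Series(shannon, index=ids),
        pairwise_bray_curtis=pd.DataFrame(bc, index=ids, columns=ids),
        richness_threshold=richness_threshold,
    )
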