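"""Fisher-score and Hellinger-distance feature weights.

Two classical filter-style feature rankings used as comparison methods
for the improved-MI weighting.  The Fisher score is the multi-class
criterion: between-class scatter of the class means over pooled
within-class variance.  The Hellinger weight histograms the (min-max
normalised) feature per class on equal-width bins and averages the
pairwise Hellinger distance between class distributions; it lies in
[0, 1].  Both are reconstructions of the standard forms from the
feature-selection literature.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .data_model import ExpressionMatrix, LabelVector
from .weighting import WeightVector, minmax_normalize

__all__ = ["fisher_score", "hellinger_score", "weight_all_baseline"]

_EPS = 1e-12  # guards zero within-class variance


def fisher_score(x: np.ndarray, labels: LabelVector) -> float:
    """Multi-class Fisher criterion of one feature.

    F = sum_c n_c (mu_c - mu)^2 / (sum_c n_c sigma_c^2 + eps) with
    population class variances.  0 for a constant feature; large when
    class means separate well relative to within-class spread.
    """
    x = np.asarray(x, dtype=float)
    if len(labels) != x.size:
        raise ValueError("labels length does not match feature length")
    if labels.n_classes < 2:
        raise ValueError("Fisher score needs at least 2 classes")
    mu = x.mean()
    between = 0.0
    within = 0.0
    codes = labels.codes()
    for c in range(labels.n_classes):
        xc = x[codes == c]
        n_c = xc.size
        between += n_c * (xc.mean() - mu) ** 2
        within += n_c * xc.var()  # population variance
    return float(between / (within + _EPS))


def hellinger_score(x: np.ndarray, labels: LabelVector, bins: int = 10) -> float:
    """Mean pairwise Hellinger distance between per-class histograms.

    The feature is min-max normalised, each class binned into ``bins``
    equal-width bins on [0, 1], and H(p, q) = sqrt(1 - sum_b sqrt(p_b q_b))
    averaged over unordered class pairs.  Result in [0, 1]; identical
    class distributions give 0, disjoint supports give 1.
    """
    x = np.asarray(x, dtype=float)
    if len(labels) != x.size:
        raise ValueError("labels length does not match feature length")
    if labels.n_classes < 2:
        raise ValueError("Hellinger score needs at least 2 classes")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    xn = minmax_normalize(x)
    edges = np.linspace(0.0, 1.0, bins + 1)
    codes = labels.codes()
    hists = []
    for c in range(labels.n_classes):
        counts, _ = np.histogram(xn[codes == c], bins=edges)
        hists.append(counts / counts.sum())
    dists = []
    for p, q in combinations(hists, 2):
        bc = np.sqrt(p * q).sum()
        dists.append(np.sqrt(max(0.0, 1.0 - bc)))
    return float(np.mean(dists))


def weight_all_baseline(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    method: str,
    *,
    bins: int = 10,
) -> WeightVector:
    """Apply a baseline score to every feature; same ranking contract as MI."""
    if method not in ("fisher", "hellinger"):
        raise ValueError(f"unknown baseline method {method!r}")
    weights = np.empty(matrix.n_features)
    for i in range(matrix.n_features):
        try:
            if method == "fisher":
                weights[i] = fisher_score(matrix.values[i], labels)
            else:
                weights[i] = hellinger_score(matrix.values[i], labels, bins=bins)
        except Exception as exc:
            raise RuntimeError(
                f"{method} weighting failed for feature "
                f"{matrix.feature_ids[i]!r}: {exc}"
            ) from exc
    return WeightVector(list(matrix.feature_ids), weights, method=method)
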