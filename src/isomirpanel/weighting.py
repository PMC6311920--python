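"""Kernel-density "improved" mutual information between a continuous
feature and a discrete class label.

Classical plug-in MI estimators need both variables continuous (KDE) or
both discrete (contingency tables).  Expression values are continuous
while subtype labels are categorical, so the estimator used here mixes a
Gaussian kernel over the (min-max normalised) feature with the 0/1
discrete metric d(y_i, y_j) over labels:

    f(x_i)      = 1/(sqrt(2*pi)*n) * sum_j exp(-(x_i - x_j)^2 / 2)
    f(y_i)      = 1/(sqrt(2*pi)*n) * sum_j exp(-d(y_i, y_j) / 2)
    f(x_i, y_i) = 1/(2*pi*n)       * sum_k exp(-D_k / 2),
                  D_k = sqrt((x_i - x_k)^2 + d(y_k, y_i))

    I(x, Y) = 1/n * sum_i log[ f(x_i, y_i) / (f(x_i) * f(y_i)) ]

Note the asymmetry: the marginal kernels use squared distances while the
joint kernel exponentiates the *root* of the combined distance.  Both
forms are implemented exactly as written; for a constant feature the
joint and product terms cancel analytically and the weight is 0.

The weight of a feature measures how informative it is for the class
labels; features are ranked by weight (descending) to build candidate
biomarker panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix, LabelVector

__all__ = [
    "DensityEstimates",
    "WeightVector",
    "minmax_normalize",
    "estimate_densities",
    "mi_weight",
    "weight_all",
]

logger = logging.getLogger(__name__)

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_2PI = 2.0 * math.pi


@dataclass
class DensityEstimates:
    """Per-sample marginal and joint kernel density values for one feature."""

    f_x: np.ndarray
    f_y: np.ndarray
    f_xy: np.ndarray
    distance: np.ndarray  # D[i, k] = sqrt((x_i - x_k)^2 + d(y_k, y_i))


@dataclass
class WeightVector:
    """Per-feature weights plus the deterministic descending ranking.

    Ties are broken by ascending feature index, so identical rows always
    rank in their input order.
    """

    feature_ids: list[str]
    weights: np.ndarray
    method: str = "mi"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_ids) != self.weights.size:
            raise ValueError("feature_ids and weights length mismatch")
        # stable sort on -w: ties keep ascending feature index
        self.ranking = np.argsort(-self.weights, kind="stable")

    def top(self, n: int) -> list[str]:
        """IDs of the top-n features by weight."""
        if not 0 < n <= len(self.feature_ids):
            raise ValueError(f"n must be in 1..{len(self.feature_ids)}, got {n}")
        return [self.feature_ids[i] for i in self.ranking[:n]]

    def ranked_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.ranking]


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] by (x - min) / (max - min).

    A constant vector maps to all zeros (a warning is logged); this is
    the degenerate case of a feature carrying no information.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalise an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("min-max normalisation of a constant vector -> all zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def estimate_densities(
    x: np.ndarray,
    labels: LabelVector,
    *,
    bandwidth: float = 1.0,
    label_distance: np.ndarray | None = None,
) -> DensityEstimates:
    """Evaluate the three kernel density estimates at every sample.

    ``x`` is expected on the [0, 1] scale (see :func:`minmax_normalize`).
    ``bandwidth`` rescales x-distances as (x_i - x_j)/h inside every
    kernel; the default h=1 is the printed form.  ``label_distance`` may
    pass a precomputed 0/1 distance matrix to avoid recomputation when
    sweeping many features against the same labels.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if len(labels) != n:
        raise ValueError(f"labels length {len(labels)} != feature length {n}")
    dmat = labels.distance_matrix() if label_distance is None else label_distance
    dx = (x[:, None] - x[None, :]) / bandwidth
    sq = dx * dx
    f_x = np.exp(-sq / 2.0).sum(axis=1) / (_SQRT_2PI * n)
    f_y = np.exp(-dmat / 2.0).sum(axis=1) / (_SQRT_2PI * n)
    distance = np.sqrt(sq + dmat)
    f_xy = np.exp(-distance / 2.0).sum(axis=1) / (_2PI * n)
    return DensityEstimates(f_x=f_x, f_y=f_y, f_xy=f_xy, distance=distance)


def _log(v: np.ndarray, base: str) -> np.ndarray:
    return np.log(v) if base == "e" else np.log2(v)


def mi_weight(
    x: np.ndarray,
    labels: LabelVector,
    *,
    log_base: str = "e",
    bandwidth: float = 1.0,
    normalize: bool = True,
    label_distance: np.ndarray | None = None,
    f_y: np.ndarray | None = None,
) -> float:
    """Improved-MI weight of one feature against the labels.

    The raw feature is min-max normalised first (``normalize=False``
    skips this for already-scaled input).  The estimator is a plug-in
    average of log density ratios and may be slightly negative for
    uninformative features; a constant feature scores exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to estimate a weight")
    if log_base not in ("e", "2"):
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    if normalize:
        x = minmax_normalize(x)
    dens = estimate_densities(
        x, labels, bandwidth=bandwidth, label_distance=label_distance
    )
    fy = dens.f_y if f_y is None else f_y
    ratio = dens.f_xy / (dens.f_x * fy)
    return float(_log(ratio, log_base).mean())


def weight_all(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    *,
    log_base: str = "e",
    bandwidth: float = 1.0,
) -> WeightVector:
    """Improved-MI weight of every feature, with the deterministic ranking.

    The 0/1 label distance matrix and the label marginal density are
    shared across features; cost is O(m * n^2) overall.
    """
    if len(labels) != matrix.n_samples:
        raise ValueError(
            f"labels cover {len(labels)} samples but matrix has {matrix.n_samples}"
        )
    if labels.n_classes < 2:
        raise ValueError("need at least 2 distinct classes to weight features")
    n = matrix.n_samples
    dmat = labels.distance_matrix()
    f_y = np.exp(-dmat / 2.0).sum(axis=1) / (_SQRT_2PI * n)
    weights = np.empty(matrix.n_features)
    for i in range(matrix.n_features):
        try:
            weights[i] = mi_weight(
                matrix.values[i],
                labels,
                log_base=log_base,
                bandwidth=bandwidth,
                label_distance=dmat,
                f_y=f_y,
            )
        except Exception as exc:
            raise RuntimeError(
                f"weighting failed for feature {matrix.feature_ids[i]!r}: {exc}"
            ) from exc
    return WeightVector(list(matrix.feature_ids), weights, method="mi")
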