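"""Removal of lowly expressed isomiRs by a chi-square null model.

Most isomiRs in a quantification run are sequencing noise: their total
expression across all samples is tiny, and the distribution of totals is
exponential-like with most mass below 1 RPM.  Instead of a hard cutoff,
a "soft" threshold is derived from a null hypothesis on the totals: with
q features and totals TE = {te_1..te_q}, the significance threshold is

    theta = q * mean(TE) / chi2_quantile(1 - alpha/2; df=q)

and features with total expression below theta are removed.  At
alpha = 0.05 the denominator is the upper-2.5% chi-square critical value
with q degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ExpressionMatrix

__all__ = [
    "FilterResult",
    "total_expression",
    "chi2_threshold",
    "filter_low_expression",
    "te_histogram",
]


@dataclass
class FilterResult:
    """Outcome of the low-expression filter.

    ``te`` holds the per-feature totals in the input's row order;
    ``kept_ids`` are exactly the features with ``te >= theta``.
    """

    te: np.ndarray
    te_mean: float
    alpha: float
    theta: float
    kept_ids: list[str]
    removed_ids: list[str]

    @property
    def q(self) -> int:
        return len(self.te)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def total_expression(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-feature total expression: te_tau = sum over samples of x_tau^a."""
    if matrix.n_features == 0:
        raise ValueError("empty expression matrix")
    return matrix.values.sum(axis=1)


def chi2_threshold(te: np.ndarray, alpha: float = 0.05) -> float:
    """theta = q * mean(TE) / chi2 quantile at probability 1 - alpha/2, df=q."""
    te = np.asarray(te, dtype=float)
    q = te.size
    if q == 0:
        raise ValueError("need at least one feature to compute a threshold")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    quantile = stats.chi2.ppf(1.0 - alpha / 2.0, df=q)
    return float(q * te.mean() / quantile)


def filter_low_expression(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> tuple[FilterResult, ExpressionMatrix]:
    """Drop features whose total expression falls below the theta threshold.

    Row order of the surviving features is preserved.  Raises if the
    filter would remove every feature (a sign the input is miscalibrated
    or alpha is too small).
    """
    te = total_expression(matrix)
    theta = chi2_threshold(te, alpha)
    keep = te >= theta
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    removed_ids = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if not kept_ids:
        raise ValueError(
            "low-expression filter removed every feature; "
            "check the input is counts/RPM or use a larger alpha"
        )
    result = FilterResult(
        te=te,
        te_mean=float(te.mean()),
        alpha=alpha,
        theta=theta,
        kept_ids=kept_ids,
        removed_ids=removed_ids,
    )
    filtered = ExpressionMatrix(
        matrix.values[keep], kept_ids, list(matrix.sample_ids), matrix.unit
    )
    return result, filtered


def te_histogram(
    te: np.ndarray, bin_width: float = 1.0, max_te: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of total expression with fixed-width bins (reporting only).

    Returns ``(edges, ratio)`` where ``ratio`` is the fraction of all
    features falling in each bin.  ``max_te`` truncates the plotted
    range; features beyond it are still counted in the denominator.
    """
    te = np.asarray(te, dtype=float)
    hi = float(te.max()) if max_te is None else max_te
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(te, bins=edges)
    return edges, counts / te.size
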