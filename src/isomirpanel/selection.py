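"""Top-N biomarker panel evaluation and plateau-based panel sizing.

Candidate panels are the top-N features of a weight ranking.  Each panel
is scored by stratified 5-fold cross-validation of a multiclass RBF-SVM:
within each fold the training split is min-max scaled and SMOTE-balanced
(subtype cohorts are heavily imbalanced), the untouched test split is
scored with one-vs-rest decision values, and performance is the
macro-averaged one-vs-rest ROC AUC.  The chosen panel size is the
smallest N beyond which the AUC curve stops improving by more than a
tolerance epsilon (the "plateau" rule).

SMOTE is implemented here directly: each minority class is oversampled
to the majority count by interpolating a random class member toward one
of its k nearest same-class neighbours with a uniform factor in [0, 1].
By default it runs inside training folds only, so synthetic samples
never leak into test splits; ``smote_before_cv=True`` reproduces the
alternative order of balancing the whole dataset first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .baselines import weight_all_baseline
from .data_model import ExpressionMatrix, LabelVector
from .lowexpr import FilterResult, filter_low_expression
from .weighting import WeightVector, weight_all

__all__ = [
    "SelectionResult",
    "PipelineResult",
    "smote_balance",
    "evaluate_topn",
    "select_plateau",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """AUC curve over panel sizes and the plateau-chosen panel."""

    grid: list[int]
    auc: np.ndarray
    auc_sd: np.ndarray
    chosen_n: int
    panel: list[str]
    epsilon: float
    seed: int
    method: str = "mi"
    plateau_found: bool = True


@dataclass
class PipelineResult:
    """Everything the filter -> weight -> select pipeline produced."""

    filter_result: FilterResult
    weights: WeightVector
    selection: SelectionResult
    config: dict = field(default_factory=dict)


def smote_balance(
    x: np.ndarray,
    labels: LabelVector,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, LabelVector]:
    """Oversample minority classes to the majority count (SMOTE).

    ``x`` is samples x features.  For each minority class, synthetic
    samples are drawn as ``base + u * (neighbour - base)`` with ``u``
    uniform in [0, 1] and the neighbour one of the base sample's k
    nearest same-class neighbours (Euclidean); k is capped at class
    size - 1.  Original samples are retained and synthetic rows are
    appended, so an already-balanced input is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(labels):
        raise ValueError("x must be samples x features matching the labels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = labels.class_counts()
    target = max(counts.values())
    y = labels.labels.astype(str)
    new_x = [x]
    new_y = [y]
    for cls in labels.classes:
        n_c = counts[cls]
        deficit = target - n_c
        if deficit == 0:
            continue
        if n_c < 2:
            raise ValueError(
                f"class {cls!r} has a single sample and cannot be SMOTE-"
                "oversampled; merge it with another class or remove it"
            )
        xc = x[y == cls]
        k_eff = min(k, n_c - 1)
        # k_eff+1 because each sample is its own nearest neighbour
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(xc)
        _, idx = nn.kneighbors(xc)
        base = rng.integers(0, n_c, size=deficit)
        pick = rng.integers(1, k_eff + 1, size=deficit)  # skip self at col 0
        u = rng.uniform(0.0, 1.0, size=deficit)
        neigh = idx[base, pick]
        synth = xc[base] + u[:, None] * (xc[neigh] - xc[base])
        new_x.append(synth)
        new_y.append(np.full(deficit, cls, dtype=object))
    if len(new_x) == 1:
        return x, labels
    return np.vstack(new_x), LabelVector(np.concatenate(new_y))


def _macro_auc(y_true: np.ndarray, decision: np.ndarray, classes: list[str]) -> float:
    """Unweighted mean of per-class one-vs-rest ROC AUCs."""
    if decision.ndim == 1:  # binary SVC: decision for classes[1]
        decision = np.column_stack([-decision, decision])
    aucs = []
    for j, cls in enumerate(classes):
        pos = y_true == cls
        if pos.all() or not pos.any():
            continue  # class absent from this split on one side
        aucs.append(roc_auc_score(pos, decision[:, j]))
    if not aucs:
        raise ValueError("no class with both positives and negatives in test split")
    return float(np.mean(aucs))


def evaluate_topn(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    weights: WeightVector,
    grid: list[int],
    seed: int = 0,
    *,
    n_folds: int = 5,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    smote_k: int = 5,
    smote_before_cv: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of cross-validated macro-AUC for each panel size in grid.

    Deterministic given ``seed``: fold assignment and SMOTE draws derive
    from it.  The same folds are reused for every N so the curve varies
    only through the feature panel.
    """
    grid = [int(n) for n in grid]
    if not grid:
        raise ValueError("empty panel-size grid")
    if min(grid) <= 0:
        raise ValueError(f"panel sizes must be positive, got {min(grid)}")
    if max(grid) > matrix.n_features:
        raise ValueError(
            f"largest panel size {max(grid)} exceeds feature count {matrix.n_features}"
        )
    min_class = min(labels.class_counts().values())
    if min_class < n_folds:
        raise ValueError(
            f"smallest class has {min_class} samples; need >= {n_folds} "
            f"for stratified {n_folds}-fold CV"
        )
    ranked = weights.ranking
    x_all = matrix.values.T[:, ranked]  # samples x features, best first
    y = labels.labels.astype(str)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x_all, y))
    ss = np.random.SeedSequence(seed)
    fold_rngs = [np.random.default_rng(s) for s in ss.spawn(n_folds * (1 + len(grid)))]
    means = np.empty(len(grid))
    sds = np.empty(len(grid))
    for gi, n_top in enumerate(grid):
        fold_aucs = []
        for fi, (train, test) in enumerate(splits):
            rng = fold_rngs[gi * n_folds + fi]
            x_tr, x_te = x_all[train, :n_top], x_all[test, :n_top]
            y_tr, y_te = y[train], y[test]
            scaler = MinMaxScaler().fit(x_tr)
            x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)
            if smote_before_cv:
                # balancing was applied upstream; nothing to do per fold
                bal_x, bal_y = x_tr, LabelVector(y_tr)
            else:
                bal_x, bal_y = smote_balance(x_tr, LabelVector(y_tr), k=smote_k, seed=rng)
            clf = SVC(
                C=svm_c, kernel="rbf", gamma=svm_gamma,
                decision_function_shape="ovr",
            )
            clf.fit(bal_x, bal_y.labels.astype(str))
            dec = clf.decision_function(x_te)
            fold_aucs.append(_macro_auc(y_te, dec, list(clf.classes_)))
        means[gi] = np.mean(fold_aucs)
        sds[gi] = np.std(fold_aucs)
    return means, sds


def select_plateau(
    grid: list[int], auc: np.ndarray, epsilon: float = 0.005
) -> tuple[int, bool]:
    """Smallest N after which no later panel improves the AUC by >= epsilon.

    Returns ``(chosen_n, plateau_found)``.  A point qualifies when every
    later grid point improves on it by less than epsilon; if no point
    with successors qualifies, the argmax-AUC N is returned with
    ``plateau_found=False`` and a logged warning.
    """
    auc = np.asarray(auc, dtype=float)
    if len(grid) != auc.size:
        raise ValueError("grid and auc length mismatch")
    if list(grid) != sorted(set(int(n) for n in grid)):
        raise ValueError("grid must be strictly ascending")
    for i in range(len(grid) - 1):
        if auc[i + 1 :].max() - auc[i] < epsilon:
            return int(grid[i]), True
    best = int(grid[int(np.argmax(auc))])
    logger.warning(
        "AUC still improving by >= %.3g at every panel size; "
        "falling back to argmax N=%d", epsilon, best,
    )
    return best, False


def run_pipeline(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    *,
    alpha: float = 0.05,
    method: str = "mi",
    log_base: str = "e",
    bandwidth: float = 1.0,
    hellinger_bins: int = 10,
    grid: list[int] | None = None,
    epsilon: float = 0.005,
    seed: int = 0,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    smote_k: int = 5,
    smote_before_cv: bool = False,
) -> PipelineResult:
    """Filter -> weight -> top-N evaluation -> plateau selection.

    ``method`` picks the feature weighting: ``mi`` (improved mutual
    information), ``fisher`` or ``hellinger``.  The default grid is
    panel sizes 1..50, clipped to the post-filter feature count.
    Fully reproducible from (inputs, parameters, seed).
    """
    if labels.sample_ids is not None:
        labels = labels.reorder(matrix.sample_ids)
    try:
        filter_result, filtered = filter_low_expression(matrix, alpha=alpha)
    except ValueError as exc:
        raise RuntimeError(f"low-expression filter stage failed: {exc}") from exc
    try:
        if method == "mi":
            weights = weight_all(
                filtered, labels, log_base=log_base, bandwidth=bandwidth
            )
        else:
            weights = weight_all_baseline(
                filtered, labels, method, bins=hellinger_bins
            )
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(f"weighting stage ({method}) failed: {exc}") from exc
    if grid is None:
        grid = list(range(1, 51))
    grid = sorted({int(n) for n in grid if int(n) <= filtered.n_features})
    if not grid:
        raise RuntimeError(
            "selection stage failed: no panel size in the grid is <= the "
            f"post-filter feature count {filtered.n_features}"
        )
    eval_matrix, eval_labels = filtered, labels
    if smote_before_cv:
        bal_x, eval_labels = smote_balance(
            filtered.values.T, labels, k=smote_k, seed=seed
        )
        eval_matrix = ExpressionMatrix(
            bal_x.T, list(filtered.feature_ids),
            [f"s{i}" for i in range(bal_x.shape[0])], filtered.unit,
        )
    try:
        auc, auc_sd = evaluate_topn(
            eval_matrix, eval_labels, weights, grid, seed=seed,
            svm_c=svm_c, svm_gamma=svm_gamma, smote_k=smote_k,
            smote_before_cv=smote_before_cv,
        )
    except ValueError as exc:
        raise RuntimeError(f"panel evaluation stage failed: {exc}") from exc
    chosen_n, plateau_found = select_plateau(grid, auc, epsilon=epsilon)
    selection = SelectionResult(
        grid=grid, auc=auc, auc_sd=auc_sd, chosen_n=chosen_n,
        panel=weights.top(chosen_n), epsilon=epsilon, seed=seed,
        method=method, plateau_found=plateau_found,
    )
    config = dict(
        alpha=alpha, method=method, log_base=log_base, bandwidth=bandwidth,
        hellinger_bins=hellinger_bins, grid=grid, epsilon=epsilon, seed=seed,
        svm_c=svm_c, svm_gamma=svm_gamma, smote_k=smote_k,
        smote_before_cv=smote_before_cv,
    )
    return PipelineResult(filter_result, weights, selection, config)
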