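"""Cross-validated evaluation: accuracy, ROC/AUC, PR/AUPR, and the
DBN-vs-no-DBN ablation.

The protocol is stratified 10-fold cross-validation.  For each fold the full
pipeline — featurisation, DBN pretraining (train folds only), ensemble
fitting — is re-run from scratch on the training folds and scored on the
held-out fold; test-fold vote-fraction scores are pooled across folds for a
single ROC and PR curve per run.  Per-fold seeds are derived from the master
seed and the fold index alone, so training-side models never depend on
test-fold contents.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .config import PipelineConfig, derive_seed
from .dbn import encode, train_dbn
from .ensemble import fit_ensemble, predict_ensemble
from .features import featurize_batch
from .io import PeptideRecord


@dataclass
class CVResult:
    """Everything a cross-validation run measured."""

    fold_assignments: np.ndarray
    per_fold: list[dict]
    pooled_accuracy: float
    mean_fold_accuracy: float
    auc: float
    aupr: float
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_points: tuple[np.ndarray, np.ndarray]  # (recall, precision)
    labels: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    seed: int
    use_dbn: bool


def kfold_split(
    labels: np.ndarray, k: int = 10, stratified: bool = True, seed: int = 0
) -> np.ndarray:
    """Per-record fold index in 0..k-1; stratified by class by default."""
    labels = np.asarray(labels, dtype=int).ravel()
    n = labels.size
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    if stratified:
        if np.unique(labels).size < 2:
            raise ValueError("stratified split needs both classes present")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignments[test_idx] = fold
    return assignments


def roc_pr_curves(labels: np.ndarray, scores: np.ndarray) -> dict:
    """ROC and PR curves with AUC and AUPR.

    The threshold sweep places one threshold per distinct score (equal
    scores are grouped), so heavily tied vote-fraction scores are handled
    consistently; AUC is then the trapezoidal area, equal to the normalised
    Mann-Whitney U statistic, and AUPR is the step-wise integral of
    precision over recall.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("ROC/PR need at least one positive and one negative")
    fpr, tpr, roc_thresh = roc_curve(labels, scores)
    precision, recall, pr_thresh = precision_recall_curve(labels, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thresh,
        "auc": float(roc_auc_score(labels, scores)),
        "precision": precision,
        "recall": recall,
        "pr_thresholds": pr_thresh,
        "aupr": float(average_precision_score(labels, scores)),
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "tp": int(((y_true == 1) & (y_pred == 1)).sum()),
        "fp": int(((y_true == 0) & (y_pred == 1)).sum()),
        "tn": int(((y_true == 0) & (y_pred == 0)).sum()),
        "fn": int(((y_true == 1) & (y_pred == 0)).sum()),
    }


def fit_fold_models(
    X56: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    config: PipelineConfig,
    fold: int,
):
    """Train the fold's DBN (optional) and ensemble on the training rows only.

    Seeds depend only on (master seed, fold index), never on data content,
    so the fitted models are bitwise independent of held-out rows.
    """
    X_train = X56[train_idx]
    dbn = None
    if config.use_dbn:
        dbn = train_dbn(
            X_train,
            layer_sizes=config.dbn.layer_sizes,
            epochs=config.dbn.epochs,
            learning_rate=config.dbn.learning_rate,
            cd_steps=config.dbn.cd_steps,
            batch_size=config.dbn.batch_size,
            seed=derive_seed(config.seed, "dbn", fold),
        )
        E_train = encode(dbn, X_train)
    else:
        E_train = X_train
    ens_config = replace(
        config.ensemble, seed=derive_seed(config.seed, "ensemble", fold)
    )
    ens = fit_ensemble(
        E_train,
        y[train_idx],
        config=ens_config,
        kernel=config.kernel,
        max_iter=config.rvm.max_iter,
        tol=config.rvm.tol,
    )
    return dbn, ens


def _fit_and_score_fold(
    X56: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    fold: int,
) -> tuple[np.ndarray, np.ndarray]:
    dbn, ens = fit_fold_models(X56, y, train_idx, config, fold)
    X_test = X56[test_idx]
    E_test = encode(dbn, X_test) if dbn is not None else X_test
    return predict_ensemble(ens, E_test)


def cross_validate(
    records: list[PeptideRecord], config: PipelineConfig
) -> CVResult:
    """Run the full pipeline under k-fold cross-validation.

    Per-fold accuracy uses majority-vote labels; AUC/AUPR are computed once
    on the pooled held-out vote fractions.
    """
    y = np.array([r.label for r in records])
    if any(r.label is None for r in records):
        raise ValueError("all records need labels for cross-validation")
    X56 = featurize_batch(records)
    folds = kfold_split(
        y, k=config.cv.k, stratified=config.cv.stratified,
        seed=derive_seed(config.seed, "cv"),
    )
    n = len(records)
    pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    per_fold: list[dict] = []
    for fold in range(config.cv.k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        labels_f, scores_f = _fit_and_score_fold(
            X56, y, train_idx, test_idx, config, fold
        )
        pred[test_idx] = labels_f
        scores[test_idx] = scores_f
        stats = _confusion(y[test_idx], labels_f)
        stats["accuracy"] = float((labels_f == y[test_idx]).mean())
        stats["n"] = int(test_idx.size)
        per_fold.append(stats)
    curves = roc_pr_curves(y, scores)
    return CVResult(
        fold_assignments=folds,
        per_fold=per_fold,
        pooled_accuracy=float((pred == y).mean()),
        mean_fold_accuracy=float(np.mean([f["accuracy"] for f in per_fold])),
        auc=curves["auc"],
        aupr=curves["aupr"],
        roc_points=(curves["fpr"], curves["tpr"]),
        pr_points=(curves["recall"], curves["precision"]),
        labels=y,
        scores=scores,
        predictions=pred,
        seed=config.seed,
        use_dbn=config.use_dbn,
    )


def ablation_no_dbn(
    records: list[PeptideRecord], config: PipelineConfig
) -> tuple[CVResult, CVResult]:
    """Paired comparison: DBN-encoded pipeline vs raw 56-d features.

    Both arms share the master seed, hence identical fold assignments; only
    the encoding step differs.
    """
    with_dbn = cross_validate(records, replace(config, use_dbn=True))
    without_dbn = cross_validate(records, replace(config, use_dbn=False))
    assert np.array_equal(
        with_dbn.fold_assignments, without_dbn.fold_assignments
    ), "ablation arms must share fold assignments"
    return with_dbn, without_dbn


def plot_roc_pr(results: dict[str, CVResult], out_roc, out_pr) -> None:
    """Render one ROC figure and one PR figure overlaying the named runs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, res in results.items():
        fpr, tpr = res.roc_points
        ax.plot(fpr, tpr, label=f"{name} (AUC={res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.savefig(out_roc, dpi=150, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, res in results.items():
        recall, precision = res.pr_points
        ax.step(recall, precision, where="post", label=f"{name} (AUPR={res.aupr:.3f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend()
    fig.savefig(out_pr, dpi=150, bbox_inches="tight")
    plt.close(fig)
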