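"""Imbalance-aware evaluation: confusion metrics, AUC, repeated stratified
cross-validation of the full pipeline, and grid search.

The headline metrics treat the minority class as positive:

    Pre = TP/(TP+FP)      Sen = TP/(TP+FN)      Spe = TN/(TN+FP)
    F   = 2*Sen*Pre/(Sen+Pre)                   G-mean = sqrt(Sen*Spe)

AUC is computed as the Mann-Whitney pair statistic (probability that a
random minority sample outscores a random majority sample, ties counted
half), which equals the trapezoidal area under the ROC curve.

``run_pipeline_cv`` evaluates the full method with strict fold hygiene:
standardization statistics, the embedding network, and the oversampler are
all fit on the training fold only; test folds contain only original rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import Dataset, standardize
from .embedding import EmbeddingConfig, embed, train_embedding
from .fsvm import FSVM
from .oversampling import oversample_to_balance

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CVConfig",
    "PipelineParams",
    "confusion",
    "metric_report",
    "auc",
    "stratified_folds",
    "run_pipeline_cv",
    "grid_search",
    "C_GRID",
    "SIGMA_GRID",
    "MARGIN_GRID",
    "DIM_GRID",
]

# canonical hyper-parameter grids for the method
C_GRID = [10.0**k for k in range(-3, 5)]
SIGMA_GRID = [2.0**k for k in range(-5, 5)]
MARGIN_GRID = [round(0.1 * k, 1) for k in range(1, 10)]
DIM_GRID = [2, 4, 6, 8, 10, 12]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Quadrant counts with the minority class (+1) as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
    )


def auc(scores, y_true) -> float:
    """Mann-Whitney AUC: P(minority score > majority score), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true == 1
    neg = y_true == -1
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricReport:
    precision: float
    sensitivity: float
    specificity: float
    f_measure: float
    g_mean: float
    auc: float

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_measure": self.f_measure,
            "g_mean": self.g_mean,
            "auc": self.auc,
        }


def metric_report(counts: ConfusionCounts, scores=None, y_true=None) -> MetricReport:
    """All confusion-derived metrics plus (optionally) score-based AUC.

    Zero-denominator conventions: Pre = 0 when tp+fp = 0; F = 0 when
    Pre+Sen = 0; Sen/Spe = 0 when their class is absent.  AUC is NaN unless
    ``scores`` and ``y_true`` are supplied.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    spe = tn / (tn + fp) if tn + fp > 0 else 0.0
    f = 2 * sen * pre / (sen + pre) if sen + pre > 0 else 0.0
    g = float(np.sqrt(sen * spe))
    a = auc(scores, y_true) if scores is not None and y_true is not None else float("nan")
    return MetricReport(
        precision=pre, sensitivity=sen, specificity=spe, f_measure=f, g_mean=g, auc=a
    )


def stratified_folds(y, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each sample to one of k folds, class-balanced by round-robin.

    Within each class, indices are shuffled and dealt to folds in turn, so
    per-fold class counts differ by at most one from proportionality.
    Deterministic for a given generator state.
    """
    y = np.asarray(y)
    assignment = np.empty(len(y), dtype=int)
    n_min = int(np.sum(y == 1))
    if n_min < k:
        raise ValueError(
            f"minority class has {n_min} samples < {k} folds; use a smaller k"
        )
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    runs: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PipelineParams:
    """Everything needed to run the pipeline on one training fold.

    ``use_embedding=False`` classifies the standardized raw features;
    ``oversample=False`` skips minority synthesis; ``membership=None``
    uses s == 1 (plain SVM).  The ablation switches exist so the same CV
    machinery scores the full method and its stripped-down baselines on
    identical folds.
    """

    C: float = 10.0
    sigma: float = 1.0
    embed_dim: int = 8
    margin: float = 0.2
    epochs: int = 200
    triplets_per_epoch: int = 128
    learning_rate: float = 1e-2
    activation: str = "gumbel"
    last_layer_activated: bool = True
    use_embedding: bool = True
    oversample: bool = True
    membership: str | None = "ir"


@dataclass
class CVResult:
    folds: pd.DataFrame  # one row per (run, fold) with all metrics
    mean: pd.Series
    std: pd.Series

    def cell(self, metric: str, decimals: int = 3) -> str:
        """Human-readable "mean +/- std" cell for one metric."""
        return f"{self.mean[metric]:.{decimals}f} ± {self.std[metric]:.{decimals}f}"


def _stage_seed(base: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(base) % (2**31), *[int(x) for x in parts]])
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_and_score_fold(train_ds, test_ds, params: PipelineParams, seed: int):
    Xtr, Xte, _, _ = standardize(train_ds.X, test_ds.X)
    ytr, yte = train_ds.y, test_ds.y

    if params.use_embedding:
        config = EmbeddingConfig(
            embed_dim=params.embed_dim,
            margin=params.margin,
            epochs=params.epochs,
            triplets_per_epoch=params.triplets_per_epoch,
            learning_rate=params.learning_rate,
            seed=_stage_seed(seed, 1),
            activation=params.activation,
            last_layer_activated=params.last_layer_activated,
        )
        net, _ = train_embedding(Xtr, ytr, config)
        Ztr = embed(net, Xtr)
        Zte = embed(net, Xte)
    else:
        Ztr, Zte = Xtr, Xte

    s = None
    if params.membership == "ir":
        # IR of the pre-oversampling training fold: after balancing, the raw
        # ratio would be 1 and the fuzzy weighting would vanish
        ir = np.sum(ytr == -1) / np.sum(ytr == 1)

    if params.oversample:
        rng = np.random.default_rng(_stage_seed(seed, 2))
        Ztr, ytr, _report = oversample_to_balance(Ztr, ytr, rng)
    if params.membership == "ir":
        s = np.where(ytr == 1, ir, 1.0)

    model = FSVM(C=params.C, sigma=params.sigma, membership=None)
    model.fit(Ztr, ytr, s=s)
    scores = model.decision_function(Zte)
    preds = model.predict(Zte)
    return metric_report(confusion(yte, preds), scores, yte)


def run_pipeline_cv(dataset: Dataset, params: PipelineParams, cv: CVConfig) -> CVResult:
    """Repeated stratified k-fold CV of the full pipeline.

    For each of ``runs`` independent repetitions the data is split into
    ``folds`` stratified folds; per fold, standardization, embedding
    training and oversampling are fit on the training part only, the FSVM
    is trained, and the held-out fold is scored.  Returns all fold-level
    metric rows plus their mean and standard deviation.
    """
    rows = []
    for run in range(cv.runs):
        rng = np.random.default_rng(_stage_seed(cv.seed, 100 + run))
        assignment = stratified_folds(dataset.y, cv.folds, rng)
        for fold in range(cv.folds):
            test_mask = assignment == fold
            train_ds = Dataset(
                X=dataset.X[~test_mask], y=dataset.y[~test_mask], source=dataset.source
            )
            test_ds = Dataset(
                X=dataset.X[test_mask], y=dataset.y[test_mask], source=dataset.source
            )
            report = _fit_and_score_fold(
                train_ds, test_ds, params, _stage_seed(cv.seed, run, fold)
            )
            rows.append({"run": run, "fold": fold, "n_test": int(test_mask.sum()),
                         **report.as_dict()})
    df = pd.DataFrame(rows)
    metrics = ["precision", "sensitivity", "specificity", "f_measure", "g_mean", "auc"]
    return CVResult(folds=df, mean=df[metrics].mean(), std=df[metrics].std(ddof=1))


@dataclass
class GridSearchResult:
    best_params: PipelineParams
    best_score: float
    table: pd.DataFrame


def grid_search(
    dataset: Dataset,
    grids: dict[str, list],
    cv: CVConfig,
    base: PipelineParams | None = None,
    metric: str = "g_mean",
) -> GridSearchResult:
    """Exhaustive search over the cartesian product of ``grids``.

    Each grid point is scored by mean CV value of ``metric`` (G-mean by
    default); ties resolve to the first point in deterministic grid order.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("all grids must be non-empty")
    base = base or PipelineParams()
    keys = list(grids)
    records = []
    best_score = -np.inf
    best_params = None
    for combo in itertools.product(*(grids[k] for k in keys)):
        params = replace(base, **dict(zip(keys, combo)))
        result = run_pipeline_cv(dataset, params, cv)
        score = float(result.mean[metric])
        records.append({**dict(zip(keys, combo)), metric: score})
        if score > best_score:
            best_score = score
            best_params = params
    return GridSearchResult(
        best_params=best_params, best_score=best_score, table=pd.DataFrame(records)
    )
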