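"""End-to-end genotype-phenotype mapping pipelines and cross-validation.

Five methods share one harness:

* ``pls``        — ordinary PLS1 (the data treated as a single block);
* ``mbpls``      — multiblock PLS on the supplied partition, no selection;
* ``bip-mbpls``  — mbPLS with blocks retained by BIP > 1, then VIP > 1
                   variable selection within the retained blocks;
* ``bwip-mbpls`` — as above with BwIP as the block statistic;
* ``grouplasso`` — the group-lasso baseline with a CV-chosen penalty.

The component count is chosen by K-fold cross-validation minimizing the
held-out RMSE and is re-chosen after each filtering stage, since dropping
blocks or variables changes the effective dimensionality.  Folds are
stratified by response quantile (small-n stability) and fully determined by
the seed.  Scaling is refit inside every training fold, so no information
from held-out samples leaks into preprocessing.

Reported errors follow the calibration/validation convention: the
calibrated RMSE is computed on the full training data under the final
model, while the validated RMSE wraps the *entire* pipeline (component
choice, block selection, variable selection, refits) inside a fresh CV loop
so that selection optimism does not contaminate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import grouplasso as gl
from . import importance as imp
from . import mbpls
from .blocking import BlockPartition
from .io import Dataset, apply_scaling, autoscale, invert_scaling

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "CVReport",
    "rmse",
    "stratified_folds",
    "cross_validate_components",
    "run_pipeline",
]

METHODS = ("pls", "mbpls", "bip-mbpls", "bwip-mbpls", "grouplasso")


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class PipelineConfig:
    """Configuration shared by all pipeline methods."""

    method: str = "bwip-mbpls"
    folds: int = 10
    max_components: int = 10
    block_threshold: float = 1.0
    vip_threshold: float = 1.0
    loading_threshold: float = 0.2
    variable_rule: str = "vip"  # or "loading"
    literal_bwip: bool = False
    iterative: bool = False
    n_lambda: int = 30
    group_weights: str = "size"
    seed: int = 0
    validate: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


@dataclass
class CVReport:
    """Per-component-count CV errors and the chosen count."""

    r_grid: np.ndarray
    mean_rmse: np.ndarray
    fold_rmse: np.ndarray  # (folds, len(r_grid))
    chosen_r: int


@dataclass
class PipelineResult:
    """Fitted pipeline: selections, final model, calibration/validation errors."""

    method: str
    chosen_components: int
    component_trace: list[int]
    selected_blocks: list[int]
    selected_variable_ids: list[str]
    model: object  # MbplsModel or GroupLassoModel-based predictor
    calibrated_rmse: float
    validated_rmse: float | None
    fold_rmse: list[float] = field(default_factory=list)
    cv_report: CVReport | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, ds: Dataset) -> np.ndarray:
        """Predict new samples (original response units)."""
        return self.model.predict_dataset(ds)


def stratified_folds(y, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign samples to folds, stratifying by response quantile.

    Samples are ranked by y, cut into consecutive rank chunks of size
    ``n_folds``, and fold labels are shuffled within each chunk, so every
    fold spans the response range even at small n.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} samples")
    order = np.argsort(y, kind="stable")
    fold_ids = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        chunk = order[start : start + n_folds]
        ids = rng.permutation(n_folds)[: chunk.size]
        fold_ids[chunk] = ids
    counts = np.bincount(fold_ids, minlength=n_folds)
    if np.any(counts == 0):  # tiny n with many folds: repair round-robin
        fold_ids = np.empty(n, dtype=int)
        fold_ids[order] = np.arange(n) % n_folds
    return fold_ids


class _MbplsPredictor:
    """Final mbPLS model plus the variable subset it was trained on."""

    def __init__(self, model: mbpls.MbplsModel, variable_ids: list[str]):
        self.model = model
        self.variable_ids = list(variable_ids)

    def predict_dataset(self, ds: Dataset) -> np.ndarray:
        sub = _subset_by_ids(ds, self.variable_ids)
        return mbpls.predict(self.model, sub)


class _GroupLassoPredictor:
    def __init__(self, model, params, variable_ids):
        self.model = model
        self.params = params
        self.variable_ids = list(variable_ids)

    def predict_dataset(self, ds: Dataset) -> np.ndarray:
        sub = _subset_by_ids(ds, self.variable_ids)
        Xs = (sub.X - self.params.x_mean) / self.params.x_sd
        return invert_scaling(Xs @ self.model.beta, self.params, which="y")


def _subset_by_ids(ds: Dataset, ids: list[str]) -> Dataset:
    if list(ds.variable_ids) == list(ids):
        return ds
    pos = {v: j for j, v in enumerate(ds.variable_ids)}
    missing = [v for v in ids if v not in pos]
    if missing:
        raise ValueError(f"new data lacks trained variables: {missing[:10]}")
    return ds.select_variables([pos[v] for v in ids])


def _effective_max_components(config: PipelineConfig, n: int, p: int) -> int:
    n_val = int(np.ceil(n / config.folds))
    return max(1, min(config.max_components, n - n_val - 1, p))


def cross_validate_components(
    ds: Dataset, partition: BlockPartition, config: PipelineConfig
) -> CVReport:
    """Choose the component count minimizing mean held-out RMSE.

    One model with the maximal feasible R is fitted per training fold and
    evaluated at every truncation 1..R on the held-out fold; ties in the
    mean curve go to the smaller count.
    """
    if ds.y is None:
        raise ValueError("dataset has no response")
    r_max = _effective_max_components(config, ds.n, ds.p)
    rng = np.random.default_rng(config.seed)
    fold_ids = stratified_folds(ds.y, config.folds, rng)
    fold_rmse = np.full((config.folds, r_max), np.nan)
    for k in range(config.folds):
        tr_idx = np.flatnonzero(fold_ids != k)
        va_idx = np.flatnonzero(fold_ids == k)
        if tr_idx.size < 2:
            raise ValueError("a training fold has fewer than 2 samples")
        train = ds.select_samples(tr_idx)
        val = ds.select_samples(va_idx)
        train_s, params = autoscale(train)
        model = mbpls.fit_mbpls(
            train_s,
            partition,
            mbpls.FitOptions(n_components=r_max),
            scaling=params,
        )
        preds = mbpls.predict_components(model, val)  # (n_val, R_eff + 1)
        for r in range(1, r_max + 1):
            col = min(r, model.n_components)  # unavailable components add nothing
            fold_rmse[k, r - 1] = rmse(val.y, preds[:, col])
    mean_rmse = fold_rmse.mean(axis=0)
    chosen = int(np.argmin(mean_rmse)) + 1  # argmin takes the first (smallest R) tie
    return CVReport(
        r_grid=np.arange(1, r_max + 1),
        mean_rmse=mean_rmse,
        fold_rmse=fold_rmse,
        chosen_r=chosen,
    )


def _fit_scaled_mbpls(
    ds: Dataset, partition: BlockPartition, n_components: int
) -> mbpls.MbplsModel:
    scaled, params = autoscale(ds)
    return mbpls.fit_mbpls(
        scaled,
        partition,
        mbpls.FitOptions(n_components=n_components),
        scaling=params,
    )


def _sub_partition(partition: BlockPartition, variable_idx: np.ndarray) -> BlockPartition:
    """Restrict a partition to a variable subset, relabelling blocks 1..C'."""
    labels = partition.labels[variable_idx]
    present = np.unique(labels)
    remap = {int(old): i + 1 for i, old in enumerate(present)}
    return BlockPartition(
        labels=np.array([remap[int(v)] for v in labels], dtype=int)
    ), [int(b) for b in present]


def _fit_pipeline(
    ds: Dataset, partition: BlockPartition, config: PipelineConfig
) -> PipelineResult:
    """Fit the configured method on the full given data (no outer validation)."""
    if config.method == "grouplasso":
        return _fit_grouplasso(ds, partition, config)

    if config.method == "pls":
        partition = BlockPartition.single_block(ds.p)

    trace: list[int] = []
    cv0 = cross_validate_components(ds, partition, config)
    trace.append(cv0.chosen_r)
    model = _fit_scaled_mbpls(ds, partition, cv0.chosen_r)
    selected_blocks = list(range(1, partition.n_blocks + 1))
    selected_ids = list(ds.variable_ids)
    work_ds, work_part = ds, partition
    extras: dict = {}

    if config.method in ("bip-mbpls", "bwip-mbpls"):
        rule = "bip" if config.method == "bip-mbpls" else "bwip"
        # stage 1: block selection (optionally iterated to a fixed point)
        orig_labels = list(range(1, partition.n_blocks + 1))
        for _ in range(10 if config.iterative else 1):
            report = imp.compute_importance(
                model,
                literal_bwip=config.literal_bwip,
                block_threshold=config.block_threshold,
                vip_threshold=config.vip_threshold,
                loading_threshold=config.loading_threshold,
            )
            kept_local = imp.select_blocks(report, rule=rule)
            if len(kept_local) == work_part.n_blocks:
                break
            keep_idx = np.flatnonzero(np.isin(work_part.labels, kept_local))
            orig_labels = [orig_labels[b - 1] for b in kept_local]
            work_ds = work_ds.select_variables(keep_idx)
            work_part, _ = _sub_partition(work_part, keep_idx)
            cv1 = cross_validate_components(work_ds, work_part, config)
            trace.append(cv1.chosen_r)
            model = _fit_scaled_mbpls(work_ds, work_part, cv1.chosen_r)
            if not config.iterative:
                break
        selected_blocks = orig_labels
        extras["bip"] = report.bip.tolist()
        extras["bwip"] = report.bwip.tolist()
        # stage 2: within-block variable selection
        report = imp.compute_importance(
            model,
            literal_bwip=config.literal_bwip,
            block_threshold=config.block_threshold,
            vip_threshold=config.vip_threshold,
            loading_threshold=config.loading_threshold,
        )
        var_idx = np.array(
            imp.select_variables(report, rule=config.variable_rule), dtype=int
        )
        if var_idx.size < work_ds.p:
            work_ds = work_ds.select_variables(var_idx)
            work_part, _ = _sub_partition(work_part, var_idx)
            cv2 = cross_validate_components(work_ds, work_part, config)
            trace.append(cv2.chosen_r)
            model = _fit_scaled_mbpls(work_ds, work_part, cv2.chosen_r)
        selected_ids = list(work_ds.variable_ids)

    predictor = _MbplsPredictor(model, selected_ids)
    calibrated = rmse(ds.y, predictor.predict_dataset(ds))
    return PipelineResult(
        method=config.method,
        chosen_components=trace[-1],
        component_trace=trace,
        selected_blocks=selected_blocks,
        selected_variable_ids=selected_ids,
        model=predictor,
        calibrated_rmse=calibrated,
        validated_rmse=None,
        cv_report=cv0,
        extras=extras,
    )


def _fit_grouplasso(
    ds: Dataset, partition: BlockPartition, config: PipelineConfig
) -> PipelineResult:
    # the CV curve is insensitive to solver precision well below the fold
    # noise, so the path runs at a relaxed tolerance; the final fit is tight
    lam, grid, curve = gl.lambda_path_cv(
        ds,
        partition,
        folds=config.folds,
        n_lambda=config.n_lambda,
        seed=config.seed,
        group_weights=config.group_weights,
        tol=1e-5,
        max_iter=3000,
    )
    scaled, params = autoscale(ds)
    model = gl.fit_group_lasso(
        scaled, partition, lam, group_weights=config.group_weights
    )
    predictor = _GroupLassoPredictor(model, params, ds.variable_ids)
    active = np.flatnonzero(model.beta != 0)
    return PipelineResult(
        method="grouplasso",
        chosen_components=0,
        component_trace=[],
        selected_blocks=model.active_blocks,
        selected_variable_ids=[ds.variable_ids[j] for j in active],
        model=predictor,
        calibrated_rmse=rmse(ds.y, predictor.predict_dataset(ds)),
        validated_rmse=None,
        extras={"lambda": lam, "lambda_grid": grid.tolist(), "cv_rmse": curve.tolist()},
    )


def run_pipeline(
    ds: Dataset, partition: BlockPartition, config: PipelineConfig
) -> PipelineResult:
    """Run the full pipeline; optionally wrap it in CV for a validated RMSE.

    The validated RMSE re-runs every stage (component choice, block and
    variable selection, refits) inside each outer training fold, so the
    estimate carries no selection optimism.  Set ``config.validate=False``
    to skip the outer loop (e.g. when an independent test set exists).
    """
    result = _fit_pipeline(ds, partition, config)
    if not config.validate:
        return result
    rng = np.random.default_rng(config.seed + 1_000_003)
    fold_ids = stratified_folds(ds.y, config.folds, rng)
    fold_errors: list[float] = []
    inner = replace(config, validate=False)
    for k in range(config.folds):
        train = ds.select_samples(np.flatnonzero(fold_ids != k))
        val = ds.select_samples(np.flatnonzero(fold_ids == k))
        fit_k = _fit_pipeline(train, partition, inner)
        fold_errors.append(rmse(val.y, fit_k.predict(val)))
    result.validated_rmse = float(np.mean(fold_errors))
    result.fold_rmse = [float(e) for e in fold_errors]
    return result
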