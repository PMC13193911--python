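"""Leakage-resistant validation for clustered lesion-level survival models.

Patients — not lesions — are the unit of splitting and resampling: all
targets of one patient land in the same fold of every cross-validation plan,
and the cluster bootstrap resamples whole patients so correlated lesions
travel together.  Encoders, hyperparameter choices and censoring
distributions are always fitted on the training side of a split.

Hyperparameters are tuned by an inner grouped grid search maximizing the mean
inner-fold concordance; the outer loop reports the concordance index and the
integrated Brier score on held-out patients, with the censoring distribution
estimated from the outer-training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import CohortTable
from .forest import Hyperparams, SurvivalForest, fit_forest, predict_risk, predict_survival
from .metrics import (
    UndefinedMetricError,
    harrell_cindex,
    integrated_brier,
    km_censoring,
)
from .preprocessing import EncoderState, FeatureMatrix, PredictorSpec, fit_encoder, transform

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "CVResult",
    "FoldDegeneracyError",
    "grouped_kfold",
    "cross_validate",
    "repeated_cv_interval",
    "cluster_bootstrap_ci",
    "permutation_importance",
    "grouped_permutation_importance",
]


class FoldDegeneracyError(ValueError):
    """An outer-training split carries no observed events."""


@dataclass
class FoldPlan:
    """K patient-level folds plus the derived per-row index sets."""

    folds: list[list[str]]  # patient ids per fold
    row_indices: list[np.ndarray]  # validation row indices per fold

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            if not f:
                raise ValueError("empty fold in plan")
            for pid in f:
                if pid in seen:
                    raise ValueError(f"patient {pid} appears in more than one fold")
                seen.add(pid)

    @property
    def K(self) -> int:
        return len(self.folds)


def grouped_kfold(patient_ids: Sequence[str], K: int, seed: int) -> FoldPlan:
    """Deal distinct patients into K near-equal folds after a seeded shuffle.

    ``patient_ids`` is the per-row patient column; all rows of a patient end
    up in that patient's single fold.
    """
    patient_ids = list(patient_ids)
    distinct = list(dict.fromkeys(patient_ids))  # order of first appearance
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > len(distinct):
        raise ValueError(
            f"K={K} exceeds the number of distinct patients ({len(distinct)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(distinct))
    shuffled = [distinct[i] for i in order]
    folds = [list(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), K)]
    rows_by_pid: dict[str, list[int]] = {}
    for i, pid in enumerate(patient_ids):
        rows_by_pid.setdefault(pid, []).append(i)
    row_indices = [
        np.array(sorted(i for pid in fold for i in rows_by_pid[pid]), dtype=int)
        for fold in folds
    ]
    return FoldPlan(folds, row_indices)


@dataclass
class CVResult:
    """Grouped cross-validation output with its audit trail."""

    fold_cindex: list[float]
    fold_ibs: list[float]
    pooled_cindex: float
    pooled_ibs: float
    tuned_hyperparams: list[Hyperparams]
    seeds: dict[str, int]
    tau: float
    ci: Optional[dict] = None  # {"metric": ..., "lower": ..., "upper": ..., "method": ...}

    def as_dict(self) -> dict:
        return {
            "fold_cindex": self.fold_cindex,
            "fold_ibs": self.fold_ibs,
            "pooled_cindex": self.pooled_cindex,
            "pooled_ibs": self.pooled_ibs,
            "tuned_hyperparams": [vars(h) for h in self.tuned_hyperparams],
            "seeds": self.seeds,
            "tau": self.tau,
            "ci": self.ci,
        }


def _fit_and_score(
    cohort: CohortTable,
    train_rows: np.ndarray,
    val_rows: np.ndarray,
    hp: Hyperparams,
    tau: float,
    spec: Optional[Sequence[PredictorSpec]],
) -> tuple[float, float]:
    """Fit encoder+forest on ``train_rows``, score C-index and IBS on ``val_rows``."""
    train = cohort.subset(train_rows)
    val = cohort.subset(val_rows)
    enc = fit_encoder(train, spec)
    fm_train = transform(enc, train)
    fm_val = transform(enc, val)
    forest = fit_forest(fm_train, hp)
    risks = predict_risk(forest, fm_val)
    cidx = harrell_cindex(fm_val.time, fm_val.event, risks)
    G = km_censoring(fm_train.time, fm_train.event)
    curves = predict_survival(forest, fm_val)
    ibs = integrated_brier(curves, fm_val.time, fm_val.event, G, tau)
    return cidx, ibs


def cross_validate(
    cohort: CohortTable,
    grid: Sequence[Hyperparams],
    K_outer: int = 5,
    K_inner: int = 3,
    tau: float = 18.0,
    seed: int = 0,
    spec: Optional[Sequence[PredictorSpec]] = None,
) -> CVResult:
    """Patient-level grouped CV with inner-loop hyperparameter tuning.

    Per outer fold the encoder, the censoring distribution and the selected
    hyperparameters are functions of the outer-training rows only; metrics
    are computed on the held-out patients.  Pooled estimates are fold means.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    pids = cohort.patient_ids
    plan = grouped_kfold(pids, K_outer, seed)
    all_rows = np.arange(len(cohort))

    # degeneracy is checked for every fold up front so the error does not
    # depend on fold evaluation order
    for k in range(plan.K):
        if cohort.subset(np.setdiff1d(all_rows, plan.row_indices[k])).n_events == 0:
            raise FoldDegeneracyError(
                f"outer-training split of fold {k} has zero events"
            )

    fold_c: list[float] = []
    fold_ibs: list[float] = []
    tuned: list[Hyperparams] = []
    for k in range(plan.K):
        val_rows = plan.row_indices[k]
        train_rows = np.setdiff1d(all_rows, val_rows)
        train = cohort.subset(train_rows)
        # inner grouped grid search on the outer-training patients
        if len(grid) == 1:
            best_hp = grid[0]
        else:
            inner_seed = seed + 1009 * (k + 1)
            inner_plan = grouped_kfold(train.patient_ids, K_inner, inner_seed)
            inner_all = np.arange(len(train))
            scores: list[float] = []
            for hp in grid:
                inner_scores = []
                for j in range(inner_plan.K):
                    iv = inner_plan.row_indices[j]
                    it = np.setdiff1d(inner_all, iv)
                    if cohort.subset(train_rows[it]).n_events == 0:
                        continue
                    try:
                        c, _ = _fit_and_score(train, it, iv, hp, tau, spec)
                    except (UndefinedMetricError, ValueError):
                        continue
                    inner_scores.append(c)
                scores.append(float(np.mean(inner_scores)) if inner_scores else -np.inf)
            best_hp = grid[int(np.argmax(scores))]  # first best wins ties
        tuned.append(best_hp)
        cidx, ibs = _fit_and_score(cohort, train_rows, val_rows, best_hp, tau, spec)
        fold_c.append(cidx)
        fold_ibs.append(ibs)

    return CVResult(
        fold_cindex=fold_c,
        fold_ibs=fold_ibs,
        pooled_cindex=float(np.mean(fold_c)),
        pooled_ibs=float(np.mean(fold_ibs)),
        tuned_hyperparams=tuned,
        seeds={"outer": seed},
        tau=tau,
    )


def repeated_cv_interval(
    cohort: CohortTable,
    grid: Sequence[Hyperparams],
    n_repeats: int = 10,
    level: float = 0.95,
    seed: int = 0,
    **cv_kwargs,
) -> dict:
    """Spread of pooled C-index over repeated grouped CV with distinct seeds.

    Returns a percentile interval tagged ``repeated_grouped_cv`` — the
    alternative to the cluster bootstrap for quantifying uncertainty.
    """
    estimates = []
    for r in range(n_repeats):
        res = cross_validate(cohort, grid, seed=seed + 7919 * r, **cv_kwargs)
        estimates.append(res.pooled_cindex)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return {
        "metric": "pooled_cindex",
        "estimates": estimates,
        "lower": float(lo),
        "upper": float(hi),
        "level": level,
        "method": "repeated_grouped_cv",
    }


def cluster_bootstrap_ci(
    cohort: CohortTable,
    metric: Callable[[CohortTable], float],
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile interval from patient-level bootstrap resampling.

    Patients are drawn with replacement and all their lesions travel
    together; resampled patients are relabeled so repeated draws stay
    distinct clusters.  Replicates where the metric is undefined are dropped
    with a logged count.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    by_pid: dict[str, list] = {}
    for r in cohort:
        by_pid.setdefault(r.patient_id, []).append(r)
    pids = list(by_pid)

    values = []
    dropped = 0
    for b in range(B):
        draw = rng.choice(len(pids), size=len(pids), replace=True)
        records = []
        for j, pi in enumerate(draw):
            for r in by_pid[pids[pi]]:
                records.append(r.replace(patient_id=f"{r.patient_id}#{j}"))
        rep = CohortTable(records, provenance=f"bootstrap[{b}]")
        try:
            values.append(float(metric(rep)))
        except (UndefinedMetricError, ValueError):
            dropped += 1
    if dropped:
        logger.warning("cluster bootstrap: %d/%d replicates undefined, dropped", dropped, B)
    if not values:
        raise UndefinedMetricError("metric undefined on every bootstrap replicate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return {
        "lower": float(lo),
        "upper": float(hi),
        "level": level,
        "n_effective": len(values),
        "n_dropped": dropped,
        "method": "cluster_bootstrap_percentile",
    }


def grouped_permutation_importance(
    cohort: CohortTable,
    hp: Hyperparams,
    K: int = 5,
    R: int = 10,
    seed: int = 0,
    spec: Optional[Sequence[PredictorSpec]] = None,
) -> dict[str, float]:
    """Permutation importance averaged over patient-level grouped folds.

    Each fold refits encoder and forest on its training patients and permutes
    encoded columns within the held-out block; the reported delta per feature
    is the mean over folds in which the validation C-index was defined.
    Features dropped by some fold's encoder contribute only where present.
    """
    plan = grouped_kfold(cohort.patient_ids, K, seed)
    all_rows = np.arange(len(cohort))
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for k in range(plan.K):
        val_rows = plan.row_indices[k]
        train_rows = np.setdiff1d(all_rows, val_rows)
        train = cohort.subset(train_rows)
        if train.n_events == 0:
            continue
        enc = fit_encoder(train, spec)
        forest = fit_forest(transform(enc, train), hp)
        fm_val = transform(enc, cohort.subset(val_rows))
        try:
            deltas = permutation_importance(
                forest, fm_val, R=R, seed=seed + 31 * (k + 1)
            )
        except UndefinedMetricError:
            continue
        for col, d in deltas.items():
            sums[col] = sums.get(col, 0.0) + d
            counts[col] = counts.get(col, 0) + 1
    return {col: sums[col] / counts[col] for col in sums}


def permutation_importance(
    forest: SurvivalForest,
    fm_val: FeatureMatrix,
    R: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean decrease in validation C-index when each encoded column is permuted.

    The permutation happens within the validation block only; the model is
    never refitted.  A constant column is invariant under permutation and
    scores a delta of exactly zero.
    """
    rng = np.random.default_rng(seed)
    baseline = harrell_cindex(fm_val.time, fm_val.event, predict_risk(forest, fm_val))
    deltas: dict[str, float] = {}
    for j, col in enumerate(fm_val.columns):
        if np.all(fm_val.X[:, j] == fm_val.X[0, j]):
            deltas[col] = 0.0  # permuting a constant column is the identity
            continue
        permuted_scores = []
        for _ in range(R):
            Xp = fm_val.X.copy()
            Xp[:, j] = Xp[rng.permutation(fm_val.n), j]
            permuted_scores.append(
                harrell_cindex(fm_val.time, fm_val.event, predict_risk(forest, Xp))
            )
        deltas[col] = baseline - float(np.mean(permuted_scores))
    return deltas
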