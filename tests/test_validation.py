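"""Grouped splitting, nested tuning, cluster bootstrap and importance."""

import numpy as np
import pytest

from gksurv.cohort import CohortTable
from gksurv.forest import Hyperparams
from gksurv.metrics import harrell_cindex
from gksurv.preprocessing import fit_encoder, transform
from gksurv.synthetic import GeneratorParams, generate_cohort
from gksurv.validation import (
    FoldDegeneracyError,
    FoldPlan,
    cluster_bootstrap_ci,
    cross_validate,
    grouped_kfold,
    permutation_importance,
)

from conftest import make_record

FAST_HP = Hyperparams(
    n_trees=50, max_depth=4, min_samples_leaf=5, min_samples_split=10,
    max_features=0.58, seed=1,
)


def test_ten_patients_five_folds_of_two():
    pids = [f"P{i}" for i in range(10)]
    plan = grouped_kfold(pids, 5, seed=0)
    assert plan.K == 5
    assert sorted(len(f) for f in plan.folds) == [2] * 5
    assert sorted(p for f in plan.folds for p in f) == sorted(pids)


def test_multi_lesion_patient_stays_in_one_fold():
    pids = ["A", "A", "A", "B", "C", "D"]
    plan = grouped_kfold(pids, 3, seed=1)
    fold_of_a = [k for k, f in enumerate(plan.folds) if "A" in f]
    assert len(fold_of_a) == 1
    assert set(plan.row_indices[fold_of_a[0]]) >= {0, 1, 2}


def test_plan_is_deterministic_in_seed():
    pids = [f"P{i}" for i in range(17)]
    assert grouped_kfold(pids, 4, 3).folds == grouped_kfold(pids, 4, 3).folds
    assert grouped_kfold(pids, 4, 3).folds != grouped_kfold(pids, 4, 4).folds


def test_k_larger_than_patients_rejected():
    with pytest.raises(ValueError):
        grouped_kfold(["A", "B"], 3, 0)


def test_fold_plan_rejects_patient_in_two_folds():
    with pytest.raises(ValueError, match="more than one fold"):
        FoldPlan([["A"], ["A", "B"]], [np.array([0]), np.array([1, 2])])


def test_no_patient_spans_folds_over_many_random_plans():
    rng = np.random.default_rng(0)
    for trial in range(50):
        n_pat = int(rng.integers(5, 40))
        pids = [f"P{i}" for i in rng.integers(0, n_pat, size=n_pat * 2)]
        K = int(rng.integers(2, min(5, len(set(pids))) + 1))
        plan = grouped_kfold(pids, K, seed=trial)
        seen = {}
        for k, fold in enumerate(plan.folds):
            for p in fold:
                assert p not in seen
                seen[p] = k
        all_rows = np.concatenate(plan.row_indices)
        assert sorted(all_rows) == list(range(len(pids)))


def test_cross_validate_on_pure_noise_is_near_half(default_cohort):
    """Outcomes permuted across lesions: pooled grouped-CV C ~ 0.5.

    A single permutation of a small clustered cohort can carry sizeable
    spurious covariate-outcome correlation, so the check averages the pooled
    estimate over several independent permutation draws.
    """
    pooled = []
    for pseed in (3, 5, 7, 11):
        rng = np.random.default_rng(pseed)
        perm = rng.permutation(len(default_cohort))
        records = [
            r.replace(
                time_months=default_cohort[int(j)].time_months,
                event=default_cohort[int(j)].event,
            )
            for r, j in zip(default_cohort, perm)
        ]
        res = cross_validate(CohortTable(records), [FAST_HP], K_outer=4, seed=3)
        pooled.append(res.pooled_cindex)
    assert abs(float(np.mean(pooled)) - 0.5) < 0.1


def test_cross_validate_recovers_signal(signal_cohort):
    res = cross_validate(signal_cohort, [FAST_HP], K_outer=4, seed=5)
    assert res.pooled_cindex > 0.6
    assert len(res.fold_cindex) == 4 and len(res.tuned_hyperparams) == 4
    assert all(ibs >= 0 for ibs in res.fold_ibs)


def test_inner_tuning_picks_from_grid(signal_cohort):
    grid = [FAST_HP, Hyperparams(n_trees=50, max_depth=2, min_samples_leaf=10,
                                 min_samples_split=20, max_features=0.33, seed=1)]
    res = cross_validate(signal_cohort, grid, K_outer=3, K_inner=3, seed=2)
    assert all(hp in grid for hp in res.tuned_hyperparams)


def test_all_events_in_one_patient_triggers_degeneracy_error():
    records = [
        make_record("P1", "L1", time_months=3.0, event=1),
        make_record("P1", "L2", time_months=4.0, event=1),
        make_record("P2", "L1", time_months=9.0, event=0),
        make_record("P3", "L1", time_months=9.5, event=0),
    ]
    with pytest.raises(FoldDegeneracyError):
        cross_validate(CohortTable(records), [FAST_HP], K_outer=3, seed=0)


def test_validation_rows_never_touch_the_fold_model(signal_cohort):
    """Mutating held-out covariates leaves the fitted fold artifacts unchanged."""
    pids = signal_cohort.patient_ids
    plan = grouped_kfold(pids, 4, seed=9)
    val_rows = plan.row_indices[0]
    train_rows = np.setdiff1d(np.arange(len(signal_cohort)), val_rows)
    train = signal_cohort.subset(train_rows)
    enc1 = fit_encoder(train)
    from gksurv.forest import fit_forest

    f1 = fit_forest(transform(enc1, train), FAST_HP)
    # mutate every validation record heavily, then refit from the same split
    _ = [signal_cohort[int(i)].replace(volume_cm3=999.0) for i in val_rows]
    enc2 = fit_encoder(train)
    f2 = fit_forest(transform(enc2, train), FAST_HP)
    assert enc1.to_dict() == enc2.to_dict()
    assert f1.to_json() == f2.to_json()


def test_cluster_bootstrap_constant_metric_zero_width(default_cohort):
    ci = cluster_bootstrap_ci(default_cohort, lambda c: 0.7, B=25, seed=0)
    assert ci["lower"] == ci["upper"] == 0.7


def test_cluster_bootstrap_interval_properties(default_cohort):
    metric = lambda c: c.n_events / len(c)
    point = metric(default_cohort)
    ci = cluster_bootstrap_ci(default_cohort, metric, B=200, seed=1)
    assert ci["lower"] <= ci["upper"]
    assert ci["lower"] <= point <= ci["upper"]
    assert ci["method"] == "cluster_bootstrap_percentile"


def test_cluster_bootstrap_keeps_lesions_together():
    captured = []

    def metric(c):
        captured.append(c)
        return 0.0

    records = [
        make_record("P1", "L1", time_months=3.0, event=1),
        make_record("P1", "L2", time_months=4.0, event=0),
        make_record("P2", "L1", time_months=9.0, event=0),
    ]
    cluster_bootstrap_ci(CohortTable(records), metric, B=10, seed=2)
    for rep in captured:
        counts = {}
        for r in rep:
            counts.setdefault(r.patient_id, set()).add(r.lesion_id)
        for pid, lids in counts.items():
            if pid.startswith("P1#"):
                assert lids == {"L1", "L2"}


def test_bootstrap_coverage_of_true_cindex():
    """Scaled-down coverage study: the 95% interval for the event fraction
    covers the long-run truth in most repeated synthetic draws."""
    gp = GeneratorParams(n_patients=60, seed=0)
    big, _ = generate_cohort(GeneratorParams(n_patients=2000, seed=999))
    truth = big.n_events / len(big)
    metric = lambda c: c.n_events / len(c)
    hits = 0
    for rep in range(20):
        cohort, _ = generate_cohort(GeneratorParams(n_patients=60, seed=100 + rep))
        ci = cluster_bootstrap_ci(cohort, metric, B=120, seed=rep)
        hits += ci["lower"] <= truth <= ci["upper"]
    assert hits >= 17  # ~85% empirical coverage at nominal 95%


def test_permutation_importance_constant_feature_is_exactly_zero(signal_fit):
    enc, fm, forest = signal_fit
    fm2 = fm.subset(range(fm.n))
    j = fm2.columns.index("tert=mut")
    fm2.X[:, j] = 1.0  # constant column: permutation is the identity
    deltas = permutation_importance(forest, fm2, R=3, seed=0)
    assert deltas["tert=mut"] == 0.0


def test_permutation_importance_deterministic(signal_fit, signal_cohort):
    enc, fm, forest = signal_fit
    holdout, _ = generate_cohort(GeneratorParams(n_patients=40, seed=77))
    fm_val = transform(enc, holdout)
    d1 = permutation_importance(forest, fm_val, R=5, seed=4)
    d2 = permutation_importance(forest, fm_val, R=5, seed=4)
    assert d1 == d2
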