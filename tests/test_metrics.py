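"""Metric oracles: exhaustive pair enumeration, hand product-limit tables,
manual IPCW expansions, and cross-checks against independent libraries."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from gksurv.curves import SurvivalCurve
from gksurv.metrics import (
    StepFunction,
    UndefinedMetricError,
    WeightSingularityError,
    brier_score,
    harrell_cindex,
    integrated_brier,
    km_censoring,
)


# --- independent oracles -------------------------------------------------

def cindex_oracle(times, events, risks):
    """Plain-loop Harrell concordance: comparable iff t_i < t_j and i failed."""
    conc = comp = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if events[i] == 1 and times[i] < times[j]:
                comp += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    conc += 0.5
    return conc / comp


def brier_oracle(t, surv_at_t, times, events, G):
    total = 0.0
    for s, ti, ei in zip(surv_at_t, times, events):
        if ti <= t and ei == 1:
            total += s**2 / G.left_limit(ti)
        elif ti > t:
            total += (1 - s) ** 2 / G(t)
    return total / len(times)


# --- Harrell C ------------------------------------------------------------

def test_single_concordant_pair():
    assert harrell_cindex([5, 10], [1, 1], [2, 1]) == 1.0


def test_all_tied_risks_give_half():
    assert harrell_cindex([5, 10, 15], [1, 1, 0], [3, 3, 3]) == 0.5


def test_tied_event_times_not_comparable():
    with pytest.raises(UndefinedMetricError):
        harrell_cindex([7, 7], [1, 1], [2, 1])


def test_all_censored_undefined():
    with pytest.raises(UndefinedMetricError):
        harrell_cindex([5, 10], [0, 0], [2, 1])


def test_cindex_matches_exhaustive_enumeration_on_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(5, 31))
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        risks = np.round(rng.normal(size=n), 1)  # rounded to force ties
        if not ((events == 1) & (times[:, None] < times[None, :]).any(1)).any():
            continue
        assert harrell_cindex(times, events, risks) == pytest.approx(
            cindex_oracle(times, events, risks)
        )


def test_cindex_agrees_with_scikit_survival_on_tie_free_data():
    sksurv_metrics = pytest.importorskip("sksurv.metrics")
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = 40
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        risks = rng.normal(size=n)
        if events.sum() == 0:
            continue
        ours = harrell_cindex(times, events, risks)
        theirs = sksurv_metrics.concordance_index_censored(
            events.astype(bool), times, risks
        )[0]
        assert ours == pytest.approx(theirs)


def test_cindex_invariant_under_monotone_risk_transform():
    rng = np.random.default_rng(2)
    times = rng.exponential(10, 25)
    events = rng.integers(0, 2, 25)
    events[0] = 1
    risks = rng.normal(size=25)
    a = harrell_cindex(times, events, risks)
    b = harrell_cindex(times, events, np.exp(3 * risks))
    assert a == pytest.approx(b)


# --- censoring KM ---------------------------------------------------------

def test_no_censoring_gives_identity():
    G = km_censoring([1, 2, 3], [1, 1, 1])
    assert G(0) == 1.0 and G(5) == 1.0


def test_two_subject_hand_product_limit():
    G = km_censoring([1, 2], [0, 1])
    assert G(0.5) == 1.0
    assert G(1) == pytest.approx(0.5)
    assert G(10) == pytest.approx(0.5)


def test_six_subject_hand_km_table():
    # censorings at 2 (n=5) and 5 (n=2): G = (1-1/5)*(1-1/2) after 5
    times = [1, 2, 3, 4, 5, 6]
    events = [1, 0, 1, 1, 0, 1]
    G = km_censoring(times, events)
    assert G(1.5) == 1.0
    assert G(2) == pytest.approx(4 / 5)
    assert G(4.9) == pytest.approx(4 / 5)
    assert G(5) == pytest.approx(4 / 5 * 1 / 2)


def test_km_matches_lifelines_on_random_fixture():
    rng = np.random.default_rng(3)
    times = rng.exponential(10, 50)
    events = rng.integers(0, 2, 50)
    G = km_censoring(times, events)
    kmf = KaplanMeierFitter().fit(times, 1 - events)
    for t in np.linspace(0.1, 25, 40):
        assert G(t) == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0])
        )


def test_left_limit_excludes_jump_at_t():
    G = StepFunction(np.array([2.0, 4.0]), np.array([0.5, 0.25]))
    assert G.left_limit(2.0) == 1.0
    assert G(2.0) == 0.5
    assert G.left_limit(3.0) == 0.5


# --- Brier score ----------------------------------------------------------

def _const_curves(n, s):
    return [SurvivalCurve(np.array([0.0]), np.array([s])) for _ in range(n)]


def test_perfect_prediction_zero_brier():
    times = np.array([2.0, 8.0, 9.0])
    events = np.array([1, 0, 0])
    curves = [
        SurvivalCurve(np.array([2.0]), np.array([0.0])),
        _const_curves(1, 1.0)[0],
        _const_curves(1, 1.0)[0],
    ]
    G = StepFunction(np.array([]), np.array([]))  # no censoring: G == 1
    assert brier_score(5.0, curves, times, events, G) == 0.0


def test_constant_half_predictor_scores_quarter():
    times = np.array([2.0, 8.0, 9.0, 12.0])
    events = np.array([1, 1, 1, 1])
    G = StepFunction(np.array([]), np.array([]))
    assert brier_score(5.0, _const_curves(4, 0.5), times, events, G) == pytest.approx(0.25)


def test_censored_eight_subject_fixture_matches_hand_expansion():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    events = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    G = km_censoring(times, events)
    rng = np.random.default_rng(4)
    s_vals = rng.uniform(0.2, 0.9, 8)
    curves = [SurvivalCurve(np.array([1e-9]), np.array([s])) for s in s_vals]
    t = 4.5
    assert brier_score(t, curves, times, events, G) == pytest.approx(
        brier_oracle(t, s_vals, times, events, G)
    )


def test_brier_with_no_censoring_equals_unweighted_mse():
    rng = np.random.default_rng(5)
    n = 30
    times = rng.exponential(10, n)
    events = np.ones(n, dtype=int)
    s_vals = rng.uniform(size=n)
    curves = [SurvivalCurve(np.array([1e-9]), np.array([s])) for s in s_vals]
    G = StepFunction(np.array([]), np.array([]))
    t = 8.0
    outcome = (times > t).astype(float)
    mse = float(np.mean((outcome - s_vals) ** 2))
    assert brier_score(t, curves, times, events, G) == pytest.approx(mse)


def test_brier_matches_scikit_survival_on_censored_fixture():
    sksurv_metrics = pytest.importorskip("sksurv.metrics")
    from sksurv.util import Surv

    rng = np.random.default_rng(6)
    n = 60
    times = rng.exponential(10, n)
    events = rng.integers(0, 2, n)
    s_vals = rng.uniform(0.1, 0.95, n)
    curves = [SurvivalCurve(np.array([1e-9]), np.array([s])) for s in s_vals]
    G = km_censoring(times, events)
    y = Surv.from_arrays(events.astype(bool), times)
    t = float(np.quantile(times, 0.4))
    _, theirs = sksurv_metrics.brier_score(y, y, s_vals[:, None], [t])
    ours = brier_score(t, curves, times, events, G)
    assert ours == pytest.approx(float(theirs[0]), rel=1e-9)


def test_weight_singularity_is_reported():
    # everyone censored by time 3: G(3) == 0 and a later survivor needs it
    times = np.array([1.0, 2.0, 3.0, 10.0])
    events = np.array([0, 0, 0, 1])
    G = km_censoring(times[:3], events[:3])
    curves = _const_curves(4, 0.5)
    with pytest.raises(WeightSingularityError):
        brier_score(5.0, curves, times, events, G)


# --- integrated Brier -----------------------------------------------------

def test_constant_bs_integrates_to_itself():
    times = np.array([2.0, 8.0, 9.0, 12.0])
    events = np.array([1, 1, 1, 1])
    G = StepFunction(np.array([]), np.array([]))
    curves = _const_curves(4, 0.5)
    # BS(t) = mean((1[T>t]-0.5)^2) = 0.25 for every t
    assert integrated_brier(curves, times, events, G, tau=1.5) == pytest.approx(0.25)


def test_quadrature_grid_refinement_converges():
    rng = np.random.default_rng(7)
    n = 40
    times = rng.exponential(10, n)
    events = rng.integers(0, 2, n)
    grid_t = np.sort(rng.uniform(0.5, 15, 12))
    curves = []
    for _ in range(n):
        s = np.sort(rng.uniform(0.2, 1.0, grid_t.size))[::-1]
        curves.append(SurvivalCurve(grid_t, s))
    G = km_censoring(times, events)
    tau = 15.0
    coarse = np.linspace(0, tau, 400)
    fine = np.linspace(0, tau, 800)
    a = integrated_brier(curves, times, events, G, tau, grid=coarse)
    b = integrated_brier(curves, times, events, G, tau, grid=fine)
    assert abs(a - b) < 5e-4


def test_ibs_nonnegative_and_deterministic(signal_cohort, signal_fit):
    from gksurv.forest import predict_survival

    enc, fm, forest = signal_fit
    G = km_censoring(fm.time, fm.event)
    curves = predict_survival(forest, fm)
    a = integrated_brier(curves, fm.time, fm.event, G, 18.0)
    b = integrated_brier(curves, fm.time, fm.event, G, 18.0)
    assert a == b and a >= 0.0
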