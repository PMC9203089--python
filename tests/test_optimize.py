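import numpy as np
import pandas as pd
import pytest

from biliphone import (
    CohortFeatures,
    cross_validate_stage2,
    default_roi_set,
    optimize_rois_stage1,
    pattern_search,
    roi_objective,
    stage1_spec,
    stage2_spec,
    stratified_split,
)
from biliphone.exceptions import InvalidParameterError, StratificationError
from biliphone.glm import GammaGLMRegressor
from biliphone.optimize import _lower_median


def cohort_table(tsb_values):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:03d}" for i in range(len(tsb_values))],
            "tsb_mg_dl": tsb_values,
        }
    )


@pytest.fixture(scope="module")
def thirty_seven_patients():
    """A 37-patient TSB table populating every clinical stratum."""
    rng = np.random.default_rng(100)
    tsb = np.concatenate(
        [
            rng.uniform(1.0, 3.4, 8),
            rng.uniform(3.6, 5.0, 4),
            rng.uniform(5.1, 6.4, 6),
            rng.uniform(6.6, 10.0, 9),
            rng.uniform(10.1, 15.0, 7),
            rng.uniform(15.1, 24.0, 3),
        ]
    )
    assert tsb.size == 37
    return cohort_table(tsb)


def test_stage1_split_sizes(thirty_seven_patients):
    """8 train (2 per clinical bin) and 7 test (2/2/2/1)."""
    train, test = stratified_split(thirty_seven_patients, stage1_spec(), seed=5)
    assert len(train) == 8 and len(test) == 7
    assert not set(train) & set(test)
    tsb = thirty_seven_patients.set_index("patient_id")["tsb_mg_dl"]
    for lo, hi in [(0, 5), (5, 10), (10, 15), (15, 25)]:
        in_bin = [(lo < tsb[p] <= hi) for p in train]
        assert sum(in_bin) == 2


def test_stage2_split_sizes(thirty_seven_patients):
    """5-patient test set (1 per bin), remaining 32 train."""
    train, test = stratified_split(thirty_seven_patients, stage2_spec(), seed=5)
    assert len(test) == 5 and len(train) == 32
    assert not set(train) & set(test)


def test_split_is_deterministic(thirty_seven_patients):
    a = stratified_split(thirty_seven_patients, stage1_spec(), seed=7)
    b = stratified_split(thirty_seven_patients, stage1_spec(), seed=7)
    assert a == b


def test_underpopulated_bin_is_named():
    patients = cohort_table([1.0, 2.0, 6.0, 7.0, 8.0, 9.0, 12.0, 13.0, 14.0, 16.0])
    with pytest.raises(StratificationError, match=r"\(0(\.0)?, 5(\.0)?\]"):
        stratified_split(patients, stage1_spec(), seed=1)


# ---------------------------------------------------------------------------
# pattern search
# ---------------------------------------------------------------------------


def test_pattern_search_finds_quadratic_minimum():
    """1-parameter quadratic: converges to the dense-grid minimizer."""
    target = 0.37

    def f(x):
        return float((x[0] - target) ** 2)

    res = pattern_search(
        f, np.array([0.9]), np.array([0.0]), np.array([1.0]),
        budget=500, mesh_tolerance=1e-5,
    )
    grid = np.linspace(0, 1, 100001)
    best_grid = grid[np.argmin((grid - target) ** 2)]
    assert res.best[0] == pytest.approx(best_grid, abs=1e-3)
    assert res.objective <= f(np.array([0.9]))


def test_stationary_start_returns_unchanged():
    def f(x):
        return float(np.sum(x**2))

    res = pattern_search(
        f, np.zeros(3), -np.ones(3), np.ones(3), budget=200
    )
    assert np.allclose(res.best, 0.0)


def test_budget_one_never_increases_objective():
    def f(x):
        return float(np.sum((x - 0.5) ** 2))

    x0 = np.array([0.1, 0.9])
    res = pattern_search(f, x0, np.zeros(2), np.ones(2), budget=1)
    assert res.objective <= f(x0)
    assert res.n_evaluations <= 1


def test_accepted_trace_is_non_increasing():
    def f(x):
        return float(np.sum((x - 0.3) ** 2))

    res = pattern_search(f, np.array([0.9, 0.1]), np.zeros(2), np.ones(2), budget=300)
    assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))
    assert res.objective == res.trace[-1]


def test_infeasible_start_rejected():
    with pytest.raises(InvalidParameterError):
        pattern_search(lambda x: np.inf, np.zeros(1), np.zeros(1), np.ones(1))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def test_objective_matches_external_sse_recomputation(recovery_cohort):
    patients, cohort, _truth = recovery_cohort
    rois = default_roi_set()
    train = list(patients["patient_id"][:40])
    evals = list(patients["patient_id"][40:])
    sse = roi_objective(rois, cohort, train, evals)
    X_train = cohort.features(rois, train)
    X_eval = cohort.features(rois, evals)
    model = GammaGLMRegressor(strict=False).fit(
        X_train, cohort.tsb[cohort.rows(train)]
    )
    pred = model.predict(X_eval)
    expected = float(np.sum((pred - cohort.tsb[cohort.rows(evals)]) ** 2))
    assert sse == pytest.approx(expected, rel=1e-10)


def test_degenerate_roi_returns_barrier(recovery_cohort):
    patients, cohort, _truth = recovery_cohort
    rois = default_roi_set()
    vec = rois.to_vector()
    vec[0] = 200.0  # radius far outside the bounds and the FOV
    bad = rois.with_vector(vec)
    ids = list(patients["patient_id"])
    assert roi_objective(bad, cohort, ids[:40], ids[40:]) == np.inf


def test_interpolation_limit_gives_near_zero_sse(recovery_cohort):
    """eval set == train set with n < p: the GLM interpolates."""
    patients, cohort, _truth = recovery_cohort
    rois = default_roi_set()
    ids = list(patients["patient_id"][:8])
    assert roi_objective(rois, cohort, ids, ids) == pytest.approx(0.0, abs=1e-4)


# ---------------------------------------------------------------------------
# stage 1 / stage 2 drivers
# ---------------------------------------------------------------------------


def test_lower_median_convention():
    assert _lower_median(np.array([3.0, 9.0, 5.0])) == 5.0
    assert _lower_median(np.array([1.0, 2.0, 3.0, 4.0])) == 2.0


def test_single_resample_median_equals_the_optimum(recovery_cohort):
    patients, cohort, _truth = recovery_cohort
    init = default_roi_set()
    result = optimize_rois_stage1(cohort, init, n_resamples=1, budget=20, seed=4)
    only = result.table[result.table["resample"] == 0]
    assert len(only) == 9
    for j, roi in enumerate(result.median_rois.rois):
        row = only[only["roi"] == j].iloc[0]
        assert roi.radius == pytest.approx(row["radius_mm"])
        assert roi.theta == pytest.approx(row["theta_deg"])


def test_stage1_replay_is_deterministic(recovery_cohort):
    _patients, cohort, _truth = recovery_cohort
    init = default_roi_set()
    a = optimize_rois_stage1(cohort, init, n_resamples=3, budget=20, seed=8)
    b = optimize_rois_stage1(cohort, init, n_resamples=3, budget=20, seed=8)
    assert a.median_rois == b.median_rois
    pd.testing.assert_frame_equal(a.table, b.table)


def test_stage2_splits_and_median_predictions(recovery_cohort):
    patients, cohort, _truth = recovery_cohort
    cv = cross_validate_stage2(
        cohort, default_roi_set(), n_iterations=200, seed=12
    )
    df = cv.to_frame(patients)
    appearances = df["n_test_appearances"].to_numpy()
    assert appearances.sum() == 200 * 5
    assert np.all(df["median_prediction"].dropna() > 0)
    # the reported median is the median of the recorded predictions
    pid = df.iloc[0]["patient_id"]
    assert cv.median_prediction[pid] == pytest.approx(
        np.median(cv.per_patient_predictions[pid])
    )


def test_stage2_replay_is_deterministic(recovery_cohort):
    _patients, cohort, _truth = recovery_cohort
    a = cross_validate_stage2(cohort, default_roi_set(), n_iterations=50, seed=3)
    b = cross_validate_stage2(cohort, default_roi_set(), n_iterations=50, seed=3)
    assert a.median_prediction == b.median_prediction
    assert a.per_patient_predictions == b.per_patient_predictions
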