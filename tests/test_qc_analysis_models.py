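import numpy as np
import pandas as pd
import pytest

import surfqc as sq
from surfqc.errors import DesignError, StrategyError
from surfqc.qc_analysis import Strategy
from surfqc.synthetic import CohortSimParams, simulate_cohort

QOALA = sq.QCMetricSpec("qoala_t", "higher_better")


@pytest.fixture(scope="module")
def cohort_truth(recovery_cohort):
    return recovery_cohort


def test_metric_correlation_matrix_structure(cohort_truth):
    cohort, _ = cohort_truth
    metrics = [sq.FSQC_METRIC, sq.EULER_METRIC, sq.QCMetricSpec("motion_qc"), QOALA]
    mat = sq.metric_correlation_matrix(cohort, metrics)
    np.testing.assert_allclose(np.diag(mat), 1.0)
    np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
    # shared latent quality: all correlations non-zero, signs follow direction
    off = mat.loc["fsqc", ["euler", "motion_qc"]]
    assert (off > 0.2).all()
    assert mat.loc["fsqc", "qoala_t"] < -0.2
    assert mat.attrs["direction"]["qoala_t"] == "higher_better"


def test_global_quality_correlations(cohort_truth):
    cohort, _ = cohort_truth
    res = sq.global_quality_correlations(cohort, sq.FSQC_METRIC)
    assert res.attrs["bonferroni_level"] == pytest.approx(0.05 / 6)
    assert len(res) == 6
    assert res["significant"].any()
    # monotone dependence gives rho 1 and a flag
    cohort2, _ = cohort_truth
    df = cohort2.df.copy()
    df["perfect"] = df["fsqc"] ** 3
    table = sq.CohortTable(df, cohort2.schema)
    res2 = sq.global_quality_correlations(table, sq.FSQC_METRIC, ["perfect", "nonexistent"])
    assert res2["rho"].iloc[0] == pytest.approx(1.0)
    assert res2.attrs["skipped"] == ["nonexistent"]


def test_demographic_model_recovers_age_and_diagnosis_direction(cohort_truth):
    cohort, _ = cohort_truth
    res = sq.demographic_quality_model(cohort, sq.FSQC_METRIC)
    effects = res.effects.set_index("term")
    assert effects.loc["age", "estimate"] < 0  # younger participants: worse quality
    assert effects.loc["age", "p"] < 1e-4
    assert effects.loc["diagnosis", "estimate"] > 0
    assert np.isfinite(effects.loc["diagnosis", "cohens_d"])
    assert np.isnan(effects.loc["age", "cohens_d"])
    assert "mixedlm" in res.summary()


def test_regional_recovery_and_null_flags(cohort_truth):
    cohort, truth = cohort_truth
    res = sq.regional_quality_associations(cohort, sq.FSQC_METRIC, "CT")
    merged = res.effects.merge(truth, on="region")
    err = (merged["partial_r"] - merged["implied_partial_r"]).abs()
    assert err.max() < 0.08
    strong = merged[merged["implied_partial_r"].abs() >= 0.1]
    assert (
        np.sign(strong["partial_r"]) == np.sign(strong["implied_partial_r"])
    ).mean() >= 0.95
    assert (merged["q"] >= merged["p"] - 1e-12).all()
    assert (np.sign(merged["partial_r"]) == np.sign(merged["t"])).all()


def test_direction_flip_negates_partial_r(cohort_truth):
    cohort, _ = cohort_truth
    res_worse = sq.regional_quality_associations(cohort, sq.FSQC_METRIC, "CT")
    flipped = sq.QCMetricSpec("fsqc", "higher_better")
    res_better = sq.regional_quality_associations(cohort, flipped, "CT")
    np.testing.assert_allclose(
        res_better.effects["partial_r"].to_numpy(),
        -res_worse.effects["partial_r"].to_numpy(),
        atol=1e-9,
    )


def test_duplicating_rows_keeps_r_shrinks_p():
    target = np.array([-0.15, 0.0, 0.12])
    params = CohortSimParams(n=400, n_regions=3, target_partial_r=target, seed=6)
    cohort, _ = simulate_cohort(params)
    res1 = sq.regional_quality_associations(cohort, sq.FSQC_METRIC, "CT")
    doubled = cohort.df.loc[cohort.df.index.repeat(2)].reset_index(drop=True)
    doubled["subject_id"] = [f"d{i}" for i in range(len(doubled))]
    cohort2 = sq.CohortTable(doubled, cohort.schema)
    res2 = sq.regional_quality_associations(cohort2, sq.FSQC_METRIC, "CT")
    np.testing.assert_allclose(
        res2.effects["partial_r"], res1.effects["partial_r"], atol=0.01
    )
    nontrivial = res1.effects["p"] > 1e-12
    assert (
        res2.effects.loc[nontrivial, "p"].to_numpy()
        <= res1.effects.loc[nontrivial, "p"].to_numpy() + 1e-12
    ).all()


def test_results_exports(tmp_path, cohort_truth):
    cohort, _ = cohort_truth
    res = sq.regional_quality_associations(cohort, sq.FSQC_METRIC, "CT")
    res.to_csv(tmp_path / "all.csv")
    res.to_csv(tmp_path / "sig.csv", thresholded=True)
    full = pd.read_csv(tmp_path / "all.csv")
    sig = pd.read_csv(tmp_path / "sig.csv")
    assert len(sig) == res.n_significant <= len(full)
    lo, hi = res.partial_r_range()
    assert lo <= hi
    assert "regions pass" in res.summary()


# -- threshold sweep --------------------------------------------------------


def test_sweep_identity_when_cutoff_retains_everyone(cohort_truth):
    cohort, _ = cohort_truth
    base = sq.regional_quality_associations(cohort, sq.FSQC_METRIC, "CT")
    sweep = sq.threshold_sweep(cohort, sq.FSQC_METRIC, [4.0], "CT")
    point = sweep.points.iloc[0]
    assert point["n_retained"] == len(cohort)
    np.testing.assert_allclose(
        sweep.per_cutoff[4.0].effects["partial_r"], base.effects["partial_r"], atol=1e-12
    )


def test_sweep_retained_counts_non_increasing(cohort_truth):
    cohort, _ = cohort_truth
    sweep = sq.threshold_sweep(cohort, sq.FSQC_METRIC, [3.0, 2.5, 2.0, 1.5], "CT")
    n_ret = sweep.points["n_retained"].to_numpy()
    assert (np.diff(n_ret) <= 0).all()


def test_sweep_flags_emptying_cutoff(cohort_truth):
    cohort, _ = cohort_truth
    sweep = sq.threshold_sweep(cohort, sq.FSQC_METRIC, [1.0001], "CT")
    assert bool(sweep.points["flagged"].iloc[0])


# -- case-control -----------------------------------------------------------


def test_case_control_threshold_retaining_all_equals_none(cohort_truth):
    cohort, _ = cohort_truth
    none = sq.case_control_comparison(cohort, "CT", Strategy("none"))
    thr = sq.case_control_comparison(
        cohort, "CT", Strategy("threshold", threshold_metric=sq.FSQC_METRIC, cutoff=4.0)
    )
    np.testing.assert_allclose(
        thr.effects["cohens_d"], none.effects["cohens_d"], atol=1e-12
    )


def test_case_control_constant_covariate_degrades_to_none(cohort_truth):
    cohort, _ = cohort_truth
    df = cohort.df.copy()
    df["flatq"] = 2.0
    table = sq.CohortTable(df, cohort.schema)
    none = sq.case_control_comparison(table, "CT", Strategy("none"))
    cov = sq.case_control_comparison(
        table, "CT", Strategy("covariate", covariate_metric=sq.QCMetricSpec("flatq"))
    )
    np.testing.assert_allclose(cov.effects["cohens_d"], none.effects["cohens_d"], atol=1e-12)


def test_case_control_true_effect_recovered_under_all_strategies():
    delta = np.array([0.3 * 0.15, 0.0, 0.0, 0.0])  # +0.3 residual SD in region 0
    params = CohortSimParams(
        n=1500, n_regions=4, target_partial_r=np.zeros(4), delta_dx=delta,
        beta_dx=0.0, seed=14,
    )
    cohort, _ = simulate_cohort(params)
    strategies = [
        Strategy("none"),
        Strategy("covariate", covariate_metric=sq.FSQC_METRIC),
        Strategy("threshold", threshold_metric=sq.FSQC_METRIC, cutoff=2.5),
        Strategy(
            "hybrid", threshold_metric=sq.FSQC_METRIC, cutoff=2.5,
            covariate_metric=sq.EULER_METRIC,
        ),
    ]
    for st in strategies:
        res = sq.case_control_comparison(cohort, "CT", st)
        d = res.effects.set_index("region")["cohens_d"]
        assert d["CT_region000"] == pytest.approx(0.3, abs=0.1)
        assert d[["CT_region001", "CT_region002", "CT_region003"]].abs().max() < 0.12


def test_case_control_emptied_group_raises():
    params = CohortSimParams(n=300, n_regions=2, target_partial_r=np.zeros(2),
                             beta_dx=3.0, seed=2)
    cohort, _ = simulate_cohort(params)
    # cases all pushed to fsqc >= mu + 3 - eps; a tight cutoff removes them all
    with pytest.raises(StrategyError):
        sq.case_control_comparison(
            cohort, "CT",
            Strategy("threshold", threshold_metric=sq.FSQC_METRIC, cutoff=1.05),
        )


# -- interaction ------------------------------------------------------------


def test_interaction_sign_recovered():
    hits = 0
    reps = 5
    for seed in range(reps):
        params = CohortSimParams(
            n=1500, n_regions=2, quality_slopes=np.array([-0.06, -0.06]), seed=seed
        )
        cohort, _ = simulate_cohort(params)
        df = cohort.df.copy()
        # make the quality slope steeper in cases: add extra -0.04 * fsqc_c * dx
        fsqc_c = df["fsqc"] - df["fsqc"].mean()
        df["CT_region000"] = df["CT_region000"] - 0.04 * fsqc_c * df["diagnosis"]
        table = sq.CohortTable(df, cohort.schema)
        eff = sq.quality_diagnosis_interaction(table, sq.FSQC_METRIC, "CT")
        est = eff.set_index("region")["estimate"]
        hits += est["CT_region000"] < 0
    assert hits >= 4  # sign recovered in nearly all replicates


def test_interaction_null_calibration_and_columns():
    params = CohortSimParams(n=800, n_regions=10, target_partial_r=np.full(10, -0.2), seed=8)
    cohort, _ = simulate_cohort(params)
    eff = sq.quality_diagnosis_interaction(cohort, sq.FSQC_METRIC, "CT")
    assert eff["significant"].mean() <= 0.2  # no injected interaction
    assert {"estimate", "t", "p", "q", "significant"} <= set(eff.columns)


def test_interaction_constant_metric_raises(cohort_truth):
    cohort, _ = cohort_truth
    df = cohort.df.copy()
    df["flatq"] = 1.0
    table = sq.CohortTable(df, cohort.schema)
    with pytest.raises(DesignError):
        sq.quality_diagnosis_interaction(table, sq.QCMetricSpec("flatq"), "CT")
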