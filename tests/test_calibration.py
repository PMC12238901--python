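"""Cohort splitting, OLS fitting, VIF screening and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from d3cr.calibration import (
    MODE_PREDICTORS,
    SplitSpec,
    calibrate,
    design_matrix,
    fit_ols,
    split_cohort,
    stepwise_select,
    vif,
)
from d3cr.config import COEF_D3CR_HT_WT, COEF_MV_HT_WT
from d3cr.synthetic import CohortParams, generate_cohort, make_stepwise_cohort


# ---------------------------------------------------------------- splitting
def test_split_exact_sizes_and_partition():
    df = pd.DataFrame({"x": range(10)})
    tr, va = split_cohort(df, SplitSpec(train_fraction=0.5, seed=3))
    assert len(tr) == 5 and len(va) == 5
    assert sorted(pd.concat([tr, va])["x"]) == list(range(10))
    assert set(tr["x"]).isdisjoint(set(va["x"]))


def test_split_is_reproducible():
    df = pd.DataFrame({"x": range(10)})
    spec = SplitSpec(train_fraction=0.8, seed=42)
    a = split_cohort(df, spec)[0]["x"].tolist()
    b = split_cohort(df, spec)[0]["x"].tolist()
    assert a == b


def test_split_bernoulli_supports_observed_cohort_sizes():
    """Per-case Bernoulli assignment fluctuates around n*f.

    A 451-record cohort split 'approximately 80/20' case-by-case can
    realise 367/84 (0.73 SD above expectation); the exact method cannot.
    """
    df = pd.DataFrame({"x": range(451)})
    sizes = np.array(
        [len(split_cohort(df, SplitSpec(seed=s, method="bernoulli"))[0])
         for s in range(400)]
    )
    mean, sd = 451 * 0.8, np.sqrt(451 * 0.8 * 0.2)
    assert abs(sizes.mean() - mean) < 3 * sd / np.sqrt(400)
    assert mean - 3 * sd <= 367 <= mean + 3 * sd  # the observed split is typical
    tr, va = split_cohort(df, SplitSpec(seed=0, method="exact"))
    assert (len(tr), len(va)) == (361, 90)  # round(451*0.8)


def test_split_membership_frequency_matches_fraction():
    df = pd.DataFrame({"x": range(20)})
    counts = np.zeros(20)
    n_seeds = 300
    for s in range(n_seeds):
        tr, _ = split_cohort(df, SplitSpec(train_fraction=0.8, seed=s))
        counts[tr["x"].to_numpy()] += 1
    freq = counts / n_seeds
    se = np.sqrt(0.8 * 0.2 / n_seeds)
    assert np.all(np.abs(freq - 0.8) < 4 * se)


def test_split_rejects_degenerate_inputs():
    df = pd.DataFrame({"x": range(5)})
    with pytest.raises(ValueError):
        split_cohort(df, SplitSpec(train_fraction=0.8, seed=0))
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=1.0)


# ---------------------------------------------------------------------- OLS
def test_fit_ols_exact_line():
    df = pd.DataFrame({"x": np.linspace(0, 10, 30)})
    df["y"] = 2.0 * df["x"] + 1.0
    m = fit_ols(df, ["x"], "y")
    assert m.params["x"] == pytest.approx(2.0, abs=1e-10)
    assert m.intercept == pytest.approx(1.0, abs=1e-10)
    assert m.adj_r2 == pytest.approx(1.0, abs=1e-10)


def test_fit_ols_null_predictor(rng):
    df = pd.DataFrame({"x": rng.normal(size=500), "y": rng.normal(size=500)})
    m = fit_ols(df, ["x"], "y")
    assert abs(m.params["x"]) < 0.15
    assert m.p_value("x") > 0.01


def test_fit_ols_residuals_orthogonal_to_predictors(training_cohort):
    m = fit_ols(training_cohort, ["pool_g", "weight_kg", "height_m"],
                "mri_volume_l")
    X = training_cohort[["pool_g", "weight_kg", "height_m"]].to_numpy()
    fitted = X @ [m.params["pool_g"], m.params["weight_kg"], m.params["height_m"]]
    resid = training_cohort["mri_volume_l"].to_numpy() - fitted - m.intercept
    scale = len(resid) * training_cohort["mri_volume_l"].std()
    for j in range(X.shape[1]):
        assert abs(resid @ X[:, j]) / scale < 1e-8


def test_fit_ols_adjusted_r2_identity(rng):
    """adj R^2 = 1 - (1-R^2)(n-1)/(n-k-1), checked long-hand."""
    n, k = 40, 3
    X = rng.normal(size=(n, k))
    y = X @ [1.0, -0.5, 0.2] + rng.normal(size=n)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["y"] = y
    m = fit_ols(df, ["a", "b", "c"], "y")
    assert m.adj_r2 == pytest.approx(
        1 - (1 - m.r2) * (n - 1) / (n - k - 1), rel=1e-10
    )


def test_fit_ols_ethnicity_uses_chinese_reference(training_cohort):
    m = fit_ols(training_cohort, ["pool_g", "ethnicity"], "mri_volume_l")
    names = [t[0] for t in m.terms]
    assert "ethnicity_Chinese" not in names
    assert {"ethnicity_Malay", "ethnicity_Indian", "ethnicity_Other"} <= set(names)


def test_fit_ols_rank_deficiency_names_terms():
    df = pd.DataFrame({"x": np.arange(20.0)})
    df["x2"] = df["x"] * 2.0
    df["y"] = df["x"] + 1.0
    with pytest.raises(ValueError, match="collinear"):
        fit_ols(df, ["x", "x2"], "y")


# ---------------------------------------------------------------------- VIF
def test_vif_orthogonal_predictors_are_one():
    df = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1, 1, -1],
                       "b": [1, 1, -1, -1, 1, 1, -1, -1]})
    df["y"] = 0.0
    v = vif(df, ["a", "b"])
    assert v["a"] == pytest.approx(1.0, abs=1e-10)
    assert v["b"] == pytest.approx(1.0, abs=1e-10)


def test_vif_flags_near_duplicate(rng):
    x = rng.normal(size=200)
    df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-3, 200)})
    v = vif(df, ["a", "b"])
    assert v["a"] > 3 and v["b"] > 3


def test_vif_cross_checked_against_statsmodels(rng):
    """Dual route: auxiliary-regression VIF vs statsmodels' implementation."""
    n = 300
    z = rng.normal(size=n)
    df = pd.DataFrame({
        "a": z + rng.normal(size=n),
        "b": 0.5 * z + rng.normal(size=n),
        "c": rng.normal(size=n),
    })
    ours = vif(df, ["a", "b", "c"])
    X = np.column_stack([np.ones(n), df["a"], df["b"], df["c"]])
    for j, name in enumerate(["a", "b", "c"], start=1):
        assert ours[name] == pytest.approx(
            variance_inflation_factor(X, j), rel=1e-8
        )


def test_vif_below_threshold_on_default_cohort(training_cohort):
    v = vif(training_cohort, ["pool_g", "weight_kg", "height_m"])
    assert all(x < 3 for x in v.values())


# ----------------------------------------------------------------- stepwise
def test_stepwise_single_strong_candidate(rng):
    df = pd.DataFrame({"x": rng.normal(size=200)})
    df["y"] = 3 * df["x"] + rng.normal(size=200)
    m = stepwise_select(df, ["x"], "y")
    assert [t[0] for t in m.terms] == ["x"]


def test_stepwise_pure_noise_gives_intercept_only(rng):
    df = pd.DataFrame({"x": rng.normal(size=2000), "y": rng.normal(size=2000)})
    m = stepwise_select(df, ["x"], "y")
    assert m.terms == ()
    assert m.intercept == pytest.approx(df["y"].mean())


def test_stepwise_entry_one_gives_full_model(training_cohort):
    cands = ["pool_g", "age_y", "height_m", "weight_kg"]
    m = stepwise_select(training_cohort, cands, "mri_volume_l",
                        entry_p=1.0 - 1e-12, removal_p=1.0)
    assert set(t[0] for t in m.terms) == set(cands)


def test_stepwise_entry_zero_gives_intercept_only(training_cohort):
    m = stepwise_select(training_cohort, ["pool_g", "height_m"],
                        "mri_volume_l", entry_p=0.0)
    assert m.terms == ()


def test_stepwise_excludes_borderline_age_and_ethnicity():
    """A borderline age effect (p ~= 0.08 by construction) and null
    ethnicity indicators drop out at entry p = 0.05, leaving pool, height
    and weight -- the progression from the full candidate set to the final
    three-term model."""
    cohort = make_stepwise_cohort(n=367, seed=0)
    full = fit_ols(cohort, ["pool_g", "age_y", "ethnicity", "height_m",
                            "weight_kg"], "mri_volume_l")
    assert full.p_value("age_y") == pytest.approx(0.076, abs=1e-6)
    assert full.p_value("ethnicity_Indian") == pytest.approx(0.317, abs=1e-6)
    assert full.p_value("ethnicity_Malay") == pytest.approx(0.942, abs=1e-6)
    audit: list[str] = []
    m = stepwise_select(cohort, ["pool_g", "age_y", "ethnicity", "height_m",
                                 "weight_kg"], "mri_volume_l", audit=audit)
    assert set(t[0] for t in m.terms) == {"pool_g", "height_m", "weight_kg"}
    assert audit, "audit log must record the steps"


# ---------------------------------------------------------------- calibrate
def test_calibrate_recovers_noiseless_generating_equations(training_cohort):
    df = training_cohort.copy()
    df["mri_volume_l"] = (
        0.032 * df["pool_g"] + 0.030 * df["weight_kg"]
        + 4.336 * df["height_m"] - 4.134
    )
    coef, model = calibrate(df, mode="d3cr_ht_wt")
    assert coef.beta_pool == pytest.approx(0.032, abs=1e-10)
    assert coef.beta_weight == pytest.approx(0.030, abs=1e-10)
    assert coef.beta_height == pytest.approx(4.336, abs=1e-9)
    assert coef.intercept == pytest.approx(-4.134, abs=1e-8)
    assert model.adj_r2 == pytest.approx(1.0, abs=1e-10)

    df["mri_volume_l"] = 0.045 * df["weight_kg"] + 6.266 * df["height_m"] - 5.438
    coef, _ = calibrate(df, mode="mv_ht_wt")
    assert coef.beta_pool == 0.0
    assert coef.beta_weight == pytest.approx(0.045, abs=1e-10)
    assert coef.beta_height == pytest.approx(6.266, abs=1e-9)
    assert coef.intercept == pytest.approx(-5.438, abs=1e-8)


def test_calibrate_round_trip_reproduces_fitted_values(training_cohort):
    coef, model = calibrate(training_cohort, mode="d3cr_ht_wt")
    pred = training_cohort.apply(
        lambda r: coef.predict(r.pool_g, r.weight_kg, r.height_m), axis=1
    )
    resid = training_cohort["mri_volume_l"] - pred
    # residuals must average zero and be orthogonal to the design
    assert abs(resid.mean()) < 1e-8


def test_calibrate_drops_missing_reference(training_cohort):
    df = training_cohort.copy()
    df.loc[df.index[:25], "mri_volume_l"] = np.nan
    _, model = calibrate(df, mode="d3cr_ht_wt")
    assert model.n == len(df) - 25
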