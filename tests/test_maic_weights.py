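"""Eligibility harmonization, design construction, exact-balance weighting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crosstrial as ct
from crosstrial.covariates import feature
from crosstrial.maic_weights import ConvergenceError


@pytest.fixture(scope="module")
def raw_410():
    """410 patients: 15 with ECOG 2, one with a missing baseline value."""
    cfg = ct.ipd_trial_config(seed=21, n_per_arm=205)
    df = ct.simulate_trial(cfg)
    df["ecog"] = np.where(np.arange(len(df)) < 15, 2, np.where(df["ecog"] == 2, 1, df["ecog"]))
    df.loc[20, "prior_chemo"] = np.nan  # index 20 has ecog 1 here
    return df


def test_eligibility_accounting(raw_410):
    retained, counts = ct.apply_eligibility(raw_410)
    assert counts == {
        "total": 410,
        "excluded_ecog": 15,
        "excluded_missing": 1,
        "retained": 394,
    }
    assert len(retained) == 394
    assert not (retained["ecog"] == 2).any()


def test_eligibility_identity_cases(raw_410):
    no_rules, counts = ct.apply_eligibility(
        raw_410, excluded_ecog_levels=(), drop_missing=False
    )
    assert len(no_rules) == 410 and counts["retained"] == 410

    clean = raw_410.dropna(subset=["prior_chemo"])
    clean = clean[clean["ecog"] != 2]
    kept, counts = ct.apply_eligibility(clean)
    assert counts["excluded_ecog"] == 0 and counts["excluded_missing"] == 0


def test_eligibility_all_excluded_errors(raw_410):
    with pytest.raises(ValueError, match="every patient"):
        ct.apply_eligibility(raw_410, excluded_ecog_levels=(0, 1, 2))


def test_build_design_median_becomes_half_target(ipd_394):
    records, _ = ipd_394
    margins = ct.TargetMargins([ct.MarginEntry("age", "median", 56.5)])
    X, targets = ct.build_design(records, margins)
    assert list(X.columns) == ["age_gt_median"]
    assert targets["age_gt_median"] == 0.5
    assert set(X["age_gt_median"].unique()) <= {0.0, 1.0}
    pd.testing.assert_series_equal(
        X["age_gt_median"],
        (records["age"] > 56.5).astype(float),
        check_names=False,
    )


def test_build_design_categorical_reference_level(ipd_394):
    records, _ = ipd_394
    margins = ct.TargetMargins(
        [
            ct.MarginEntry("n_sites_2", "proportion", 0.337),
            ct.MarginEntry("n_sites_ge3", "proportion", 0.349),
        ]
    )
    X, targets = ct.build_design(records, margins)
    assert list(X.columns) == ["n_sites_2", "n_sites_ge3"]
    assert targets.tolist() == [0.337, 0.349]
    # one-site patients are the omitted reference level: both indicators 0
    one_site = records["n_disease_sites"] == "1"
    assert (X.loc[one_site.to_numpy()].sum(axis=1) == 0).all()


def test_build_design_unknown_covariate_named_in_error(ipd_394):
    records, _ = ipd_394
    margins = ct.TargetMargins([ct.MarginEntry("karnofsky", "proportion", 0.5)])
    with pytest.raises(KeyError, match="karnofsky"):
        ct.build_design(records, margins)


def test_weights_null_match_is_uniform(ipd_394):
    records, _ = ipd_394
    X = pd.DataFrame({"ecog0": feature(records, "ecog0")})
    wv = ct.estimate_weights(X, pd.Series({"ecog0": X["ecog0"].mean()}))
    assert np.allclose(wv.coefficients, 0.0, atol=1e-8)
    assert np.allclose(wv.weights, 1.0, atol=1e-8)
    assert wv.ess == pytest.approx(len(records))


def test_weights_closed_form_four_patients():
    """Binary covariate {1,1,1,0}, target 0.5: the moment equation forces
    w(x=1)/w(x=0) = 1/3 and an exactly matched weighted mean."""
    X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 0.0]})
    wv = ct.estimate_weights(X, pd.Series({"x": 0.5}))
    w = wv.weights
    assert w[0] == pytest.approx(w[1]) == pytest.approx(w[2])
    assert w[0] / w[3] == pytest.approx(1 / 3, abs=1e-8)
    assert (w @ X["x"]) / w.sum() == pytest.approx(0.5, abs=1e-10)


def test_weights_agree_with_bisection_oracle():
    """One covariate, six patients: Newton solution matches a bisection root
    of the scalar moment equation to 1e-6."""
    x = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
    target = 0.4
    xc = x - target

    def moment(a):
        return float(np.sum(xc * np.exp(a * xc)))

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if moment(lo) * moment(mid) <= 0:
            hi = mid
        else:
            lo = mid
    a_oracle = (lo + hi) / 2

    wv = ct.estimate_weights(pd.DataFrame({"x": x}), pd.Series({"x": target}))
    assert wv.coefficients["x"] == pytest.approx(a_oracle, abs=1e-6)


def test_exact_balance_at_reported_margins(ipd_394):
    """Weighting the pre-match sample to the comparator's reported margins
    reproduces every target to numerical exactness."""
    records, _ = ipd_394
    margins = ct.TargetMargins.from_dict(dict(ct.COMPARATOR_MARGINS), comparator_n=171)
    X, targets = ct.build_design(records, margins)
    wv = ct.estimate_weights(X, targets)
    post = (wv.weights @ X.to_numpy()) / wv.weights.sum()
    assert np.max(np.abs(post - targets.to_numpy())) <= 1e-8
    assert wv.ess < len(records)


def test_infeasible_target_raises_separation_error():
    """A target outside the convex hull of the sample (here, a positive
    proportion for a covariate nobody has) cannot be matched."""
    X = pd.DataFrame({"x": np.zeros(12)})
    with pytest.raises(ConvergenceError, match="infeasible|separation"):
        ct.estimate_weights(X, pd.Series({"x": 0.5}))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ess_at_most_n_equality_iff_uniform(seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x": rng.integers(0, 2, 40).astype(float)})
    target = float(np.clip(X["x"].mean() + rng.uniform(-0.15, 0.15), 0.05, 0.95))
    wv = ct.estimate_weights(X, pd.Series({"x": target}))
    assert wv.ess <= wv.n + 1e-9
    uniform = np.allclose(wv.weights, wv.weights[0])
    assert (wv.ess == pytest.approx(wv.n)) == uniform


def test_weight_rescaling_leaves_estimates_unchanged(ipd_394):
    records, _ = ipd_394
    margins = ct.TargetMargins.from_dict(dict(ct.COMPARATOR_MARGINS), comparator_n=171)
    X, targets = ct.build_design(records, margins)
    wv = ct.estimate_weights(X, targets)
    sample = ct.SurvivalSample.from_arrays(
        records["os_time"], records["os_event"], records["arm"], wv.weights
    )
    scaled = ct.SurvivalSample.from_arrays(
        records["os_time"], records["os_event"], records["arm"], wv.weights * 17.3
    )
    r1 = ct.weighted_cox(sample, "placebo")
    r2 = ct.weighted_cox(scaled, "placebo")
    assert r1.effect == pytest.approx(r2.effect, rel=1e-9)
    k1 = ct.weighted_km(sample, "active")
    k2 = ct.weighted_km(scaled, "active")
    assert np.allclose(k1.survival, k2.survival)


def test_balance_test_flags_reported_imbalance(ipd_394):
    """An ECOG-0 rate of 68.8% in 394 patients against a reported 55.0% in
    171 is a significant difference, and the chi-square statistic matches a
    hand-built contingency table."""
    records, _ = ipd_394
    margins = ct.TargetMargins(
        [ct.MarginEntry("ecog0", "proportion", 0.550)], comparator_n=171
    )
    report = ct.balance_tests(records, margins)
    row = report.loc["ecog0"]
    assert row["significant"]

    p1 = feature(records, "ecog0").mean()
    n1, n2 = len(records), 171
    table = np.array(
        [
            [p1 * n1, (1 - p1) * n1],
            [0.55 * n2, 0.45 * n2],
        ]
    )
    chi2_oracle = stats.chi2_contingency(table, correction=False)[0]
    assert row["statistic"] == pytest.approx(chi2_oracle, rel=1e-9)


def test_balance_test_no_flags_when_identical(ipd_394):
    """Margins summarized from the sample itself show no significant
    differences (the continuous test is location-approximate, so it is
    checked against the sample mean rather than the skewed median)."""
    records, _ = ipd_394
    margins = ct.margins_from_records(records)
    entries = [
        e if e.kind == "proportion" else ct.MarginEntry(e.name, e.kind, float(records[e.name].mean()))
        for e in margins
    ]
    report = ct.balance_tests(
        records, ct.TargetMargins(entries, comparator_n=len(records))
    )
    assert not report["significant"].any()
    assert (report.loc[report["kind"] == "proportion", "statistic"] == 0).all()


def test_balance_test_requires_comparator_n(ipd_394):
    records, _ = ipd_394
    margins = ct.TargetMargins([ct.MarginEntry("ecog0", "proportion", 0.5)])
    with pytest.raises(ValueError, match="sample size"):
        ct.balance_tests(records, margins)
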