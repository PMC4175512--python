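"""Bucher combination, NNT, unanchored and negative-control comparisons."""

import numpy as np
import pandas as pd
import pytest

import crosstrial as ct


class TestSeFromCi:
    @pytest.mark.parametrize(
        "hr, lo, hi, expected",
        [
            (0.38, 0.29, 0.49, np.log(0.49 / 0.29) / (2 * 1.959964)),
            (0.42, 0.26, 0.66, np.log(0.66 / 0.26) / (2 * 1.959964)),
            (1.0, 0.5, 2.0, np.log(4.0) / (2 * 1.959964)),
        ],
    )
    def test_back_calculation(self, hr, lo, hi, expected):
        effect = ct.PublishedEffect(hr, lo, hi)
        assert ct.se_from_ci(effect) == pytest.approx(expected, abs=1e-12)

    def test_printed_values(self):
        assert ct.se_from_ci(ct.PublishedEffect(0.38, 0.29, 0.49)) == pytest.approx(
            0.1338, abs=5e-4
        )
        assert ct.se_from_ci(ct.PublishedEffect(0.42, 0.26, 0.66)) == pytest.approx(
            0.2376, abs=5e-4
        )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ct.PublishedEffect(0.5, -0.1, 0.9)
        with pytest.raises(ValueError):
            ct.PublishedEffect(0.5, 0.6, 0.9)


class TestBucher:
    def test_published_pfs_inputs_reproduce_printed_row(self):
        """HRs 0.38 (0.29-0.49) vs 0.42 (0.26-0.66) combine to 0.90 with a
        lower CI bound of 0.53."""
        ab = ct.PublishedEffect(0.38, 0.29, 0.49, endpoint="pfs")
        cb = ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="pfs")
        res = ct.bucher(ab, cb)
        assert round(res.effect, 2) == 0.90
        assert round(res.ci_lower, 2) == 0.53
        assert res.p_value > 0.05

    def test_identical_inputs_null(self):
        e = ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="pfs")
        res = ct.bucher(e, e)
        assert res.effect == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_ratio_of_point_estimates(self):
        ab = ct.PublishedEffect(0.35, 0.24, 0.52, endpoint="pfs")
        cb = ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="pfs")
        res = ct.bucher(ab, cb)
        assert res.effect == pytest.approx(0.35 / 0.42, rel=1e-12)

    def test_reciprocal_transitivity(self):
        ab = ct.PublishedEffect(0.38, 0.29, 0.49, endpoint="pfs")
        cb = ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="pfs")
        fwd = ct.bucher(ab, cb)
        rev = ct.bucher(cb, ab)
        assert fwd.effect * rev.effect == pytest.approx(1.0, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_endpoint_mismatch_rejected(self):
        ab = ct.PublishedEffect(0.38, 0.29, 0.49, endpoint="pfs")
        cb = ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="os")
        with pytest.raises(ValueError, match="endpoint"):
            ct.bucher(ab, cb)

    def test_accepts_fitted_result(self, ipd_394):
        records, _ = ipd_394
        sample = ct.SurvivalSample.from_arrays(
            records["pfs_time"], records["pfs_event"], records["arm"], endpoint="pfs"
        )
        within = ct.weighted_cox(sample, "placebo", kind="anchored")
        res = ct.bucher(within, ct.PublishedEffect(0.42, 0.26, 0.66, endpoint="pfs"))
        assert res.effect == pytest.approx(within.effect / 0.42, rel=1e-9)
        assert res.log_se > within.log_se


class TestNNT:
    def test_printed_one_and_two_year_values(self):
        one_year = ct.nnt_from_probabilities(0.82, 0.70, 12.0)
        two_year = ct.nnt_from_probabilities(0.65, 0.54, 24.0)
        assert round(one_year.nnt, 1) == 8.3
        assert round(two_year.nnt, 1) == 9.1

    def test_equal_survival_non_finite(self):
        res = ct.nnt_from_probabilities(0.6, 0.6, 12.0)
        assert not res.finite
        assert not np.isfinite(res.nnt)

    def test_harm_direction_flagged(self):
        res = ct.nnt_from_probabilities(0.5, 0.62, 12.0)
        assert res.harm
        assert res.nnt == pytest.approx(-1 / 0.12, rel=1e-9)

    def test_from_curves_with_extrapolation_flag(self, toy_survival):
        sample = ct.SurvivalSample(toy_survival)
        km = ct.weighted_km(sample, "a")
        res = ct.nnt_at(km, km, 50.0)
        assert res.extrapolated
        assert not res.finite


@pytest.fixture(scope="module")
def pseudo_placebo_os(comparator_aggregate):
    _, agg, _ = comparator_aggregate
    return ct.reconstruct_pseudo_ipd(
        agg.km_curves[("placebo", "os")],
        agg.at_risk[("placebo", "os")],
        total_events=agg.event_counts[("placebo", "os")],
    )


class TestPooledComparisons:
    def test_missing_weights_rejected(self, ipd_394, pseudo_placebo_os):
        records, _ = ipd_394
        act = records[records["arm"] == "active"]
        with pytest.raises(ValueError, match="weights"):
            ct.unanchored_active_comparison(
                act["os_time"], act["os_event"], None, pseudo_placebo_os
            )

    def test_identical_laws_hr_near_one(self):
        """Pseudo-IPD arm reconstructed from the IPD arm's own KM compares at
        HR ~ 1 against that arm."""
        rng = np.random.default_rng(4)
        n = 300
        t = np.minimum(rng.exponential(18, n), 36.0)
        e = (rng.exponential(18, n) <= 36.0)[:n]  # noqa: simple admin censor
        t = np.minimum(rng.exponential(18, n), 36.0)
        e = t < 36.0
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.arange(0.0, 37.0, 1.0)
        s = kmf.survival_function_at_times(grid).to_numpy()
        s[0] = 1.0
        curve = ct.DigitizedCurve(grid, np.minimum.accumulate(s))
        rg = np.arange(0.0, 37.0, 6.0)
        table = ct.AtRiskTable(rg, np.array([(t >= x).sum() for x in rg]))
        pseudo = ct.reconstruct_pseudo_ipd(curve, table)
        res = ct.unanchored_active_comparison(t, e.astype(int), np.ones(n), pseudo)
        assert res.ci_lower <= 1.0 <= res.ci_upper
        assert res.effect == pytest.approx(1.0, abs=0.1)

    def test_weight_scale_invariance_of_pooled_fit(self, ipd_394, pseudo_placebo_os):
        records, _ = ipd_394
        act = records[records["arm"] == "active"]
        w = np.linspace(0.5, 2.0, len(act))
        r1 = ct.unanchored_active_comparison(
            act["os_time"], act["os_event"], w, pseudo_placebo_os
        )
        r2 = ct.unanchored_active_comparison(
            act["os_time"], act["os_event"], w * 3.21, pseudo_placebo_os
        )
        assert r1.effect == pytest.approx(r2.effect, rel=1e-8)

    def test_external_control_feeds_nnt(self, ipd_394, pseudo_placebo_os):
        records, _ = ipd_394
        act = records[records["arm"] == "active"]
        res, km_a, km_c = ct.external_control_comparison(
            act["os_time"], act["os_event"], np.ones(len(act)), pseudo_placebo_os
        )
        assert res.kind == "external_control"
        nnt = ct.nnt_at(km_a, km_c, 12.0)
        assert nnt.surv_active == km_a.survival_at(12.0)[0]
        assert nnt.surv_control == km_c.survival_at(12.0)[0]

    def test_negative_control_labeled_and_noted(self, ipd_394, comparator_aggregate):
        records, _ = ipd_394
        _, agg, _ = comparator_aggregate
        pseudo = ct.reconstruct_pseudo_ipd(
            agg.km_curves[("placebo", "pfs")], agg.at_risk[("placebo", "pfs")]
        )
        plc = records[records["arm"] == "placebo"]
        res = ct.negative_control(
            plc["pfs_time"], plc["pfs_event"], np.ones(len(plc)), pseudo
        )
        assert res.kind == "negative_control"
        assert any("residual" in n for n in res.notes)

    def test_negative_control_shifts_with_unmeasured_imbalance(self):
        """A prognostic covariate enriched in one trial but not matched on
        moves the placebo-PFS hazard ratio in the induced direction."""
        rng = np.random.default_rng(19)
        n = 2500
        base = 0.12

        def placebo_arm(p_frail):
            frail = rng.random(n) < p_frail
            rate = base * np.exp(0.8 * frail)
            t = rng.exponential(1 / rate)
            return np.minimum(t, 30.0), (t <= 30.0).astype(int), frail

        t_ipd, e_ipd, _ = placebo_arm(0.7)  # IPD trial enriched for frailty
        t_cmp, e_cmp, _ = placebo_arm(0.2)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t_cmp, e_cmp)
        grid = np.arange(0.0, 31.0, 1.0)
        s = kmf.survival_function_at_times(grid).to_numpy()
        s[0] = 1.0
        curve = ct.DigitizedCurve(grid, np.minimum.accumulate(s))
        rg = np.arange(0.0, 31.0, 6.0)
        table = ct.AtRiskTable(rg, np.array([(t_cmp >= x).sum() for x in rg]))
        pseudo = ct.reconstruct_pseudo_ipd(curve, table)
        res = ct.negative_control(t_ipd, e_ipd, np.ones(n), pseudo)
        assert res.effect > 1.1  # frailer IPD placebo progresses faster
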