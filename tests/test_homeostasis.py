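"""Homeostasis (1/H) and discharge power-law estimators."""
import numpy as np
import pandas as pd
import pytest

from streamstoich.homeostasis import (
    InsufficientDataError,
    fit_homeostasis,
    fit_homeostasis_by_tp_bin,
    fit_power_law,
    per_site_homeostasis,
    regress_b_on_landuse,
    site_power_laws,
)


class TestFitHomeostasis:
    def test_constant_particulate_ratio_is_strictly_homeostatic(self, rng):
        """Static particle N:P across any dissolved supply: slope exactly 0."""
        dissolved = rng.lognormal(3, 1, 50)
        fit = fit_homeostasis(dissolved, np.full(50, 4.0))
        assert fit.slope_inv_h == 0.0
        assert fit.intercept_log_c == pytest.approx(np.log10(4.0))

    def test_proportional_tracking_is_plastic_limit(self, rng):
        dissolved = rng.lognormal(3, 1, 50)
        fit = fit_homeostasis(dissolved, dissolved)
        assert fit.slope_inv_h == 1.0
        assert fit.intercept_log_c == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_dissolved_ratio_rejected(self):
        with pytest.raises(ValueError, match="degenerate dissolved"):
            fit_homeostasis([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_slope_recovery_by_simulation(self):
        """OLS consistency: mean slope over seeds ~ true 0.096."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            logx = rng.normal(np.log10(55), 0.6, 5000)
            logy = 0.434 + 0.096 * logx + rng.normal(0, 0.3, 5000)
            fit = fit_homeostasis(10.0**logx, 10.0**logy)
            slopes.append(fit.slope_inv_h)
        assert abs(np.mean(slopes) - 0.096) < 0.005

    def test_slope_invariant_to_dissolved_rescaling(self, rng):
        """Multiplying dissolved ratios by k leaves 1/H unchanged and shifts
        the intercept by slope * log10 k."""
        x = rng.lognormal(3, 1, 200)
        y = 10 ** (0.4 + 0.1 * np.log10(x) + rng.normal(0, 0.2, 200))
        base = fit_homeostasis(x, y)
        scaled = fit_homeostasis(1000.0 * x, y)
        assert scaled.slope_inv_h == pytest.approx(base.slope_inv_h, abs=1e-10)
        assert scaled.intercept_log_c == pytest.approx(
            base.intercept_log_c - base.slope_inv_h * 3.0, abs=1e-9
        )


class TestTpBins:
    def make_frame(self, rng, n_per_bin, slope_low, slope_high):
        rows = []
        for tp, slope, n in ((0.01, slope_low, n_per_bin), (0.3, slope_high, n_per_bin)):
            logx = rng.normal(1.5, 0.5, n)
            logy = 0.4 + slope * logx + rng.normal(0, 0.2, n)
            rows.append(pd.DataFrame({"TP": tp, "np_dissolved": 10.0**logx,
                                      "np_particulate": 10.0**logy}))
        return pd.concat(rows, ignore_index=True)

    def test_bin_slopes_recovered(self, rng):
        frame = self.make_frame(rng, 2000, 0.0, -0.04)
        fits = fit_homeostasis_by_tp_bin(frame)
        assert abs(fits["tp_lt_0.025"].slope_inv_h - 0.0) < 0.02
        assert abs(fits["tp_gt_0.1"].slope_inv_h - (-0.04)) < 0.02

    def test_middle_band_and_boundaries_excluded(self, rng):
        frame = self.make_frame(rng, 50, 0.1, 0.1)
        frame["TP"] = 0.05  # everything in the excluded middle band
        with pytest.warns(UserWarning):
            fits = fit_homeostasis_by_tp_bin(frame)
        assert fits["tp_lt_0.025"] is None and fits["tp_gt_0.1"] is None
        frame["TP"] = 0.025  # boundary: strict < keeps the low bin empty
        with pytest.warns(UserWarning):
            fits = fit_homeostasis_by_tp_bin(frame)
        assert fits["tp_lt_0.025"] is None


class TestPerSite:
    def test_eligibility_is_strictly_greater(self, rng):
        def site(name, n):
            x = rng.lognormal(3, 0.5, n)
            return pd.DataFrame({"site_id": name, "np_dissolved": x,
                                 "np_particulate": np.full(n, 3.0),
                                 "np_total": x / 2})

        frame = pd.concat([site("exactly100", 100), site("eligible", 101)],
                          ignore_index=True)
        fits, ineligible = per_site_homeostasis(frame, min_n=100)
        assert ineligible == ["exactly100"]
        row = fits.set_index("site_id").loc["eligible"]
        assert row["inv_h"] == 0.0  # constant particulate ratio
        assert row["pn_pp_median"] == pytest.approx(3.0)

    def test_site_slope_ranking_recovered(self):
        """A panel of sites with true slopes spanning -1..0.3 is recovered in
        rank order."""
        rng = np.random.default_rng(7)
        true_slopes = np.linspace(-1.0, 0.3, 13)
        frames = []
        for i, slope in enumerate(true_slopes):
            logx = rng.normal(1.5, 0.5, 150)
            logy = 0.4 + slope * logx + rng.normal(0, 0.25, 150)
            frames.append(pd.DataFrame({"site_id": f"s{i:02d}",
                                        "np_dissolved": 10.0**logx,
                                        "np_particulate": 10.0**logy}))
        fits, _ = per_site_homeostasis(pd.concat(frames, ignore_index=True), min_n=100)
        fits = fits.sort_values("site_id")
        rho = pd.Series(fits["inv_h"].to_numpy()).corr(
            pd.Series(true_slopes), method="spearman"
        )
        assert rho > 0.9


class TestPowerLaw:
    def test_constant_ratio_is_chemostatic(self, rng):
        q = rng.lognormal(5, 1, 40)
        fit = fit_power_law(q, np.full(40, 7.2))
        assert fit.b_exp == 0.0
        assert fit.a_coeff == pytest.approx(7.2)

    def test_exact_power_law_recovered(self, rng):
        q = rng.lognormal(5, 1, 40)
        fit = fit_power_law(q, 2.0 * q)
        assert fit.b_exp == pytest.approx(1.0, abs=1e-10)
        assert fit.a_coeff == pytest.approx(2.0, abs=1e-9)

    def test_eligibility_strictly_more_than_ten(self, rng):
        q = rng.lognormal(5, 1, 10)
        with pytest.raises(InsufficientDataError):
            fit_power_law(q, 2.0 * q)

    def test_exponent_recovery_by_simulation(self):
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            logq = rng.normal(3, 0.8, 50)
            lognp = 1.0 - 0.3 * logq + rng.normal(0, 0.2, 50)
            estimates.append(fit_power_law(10.0**logq, 10.0**lognp).b_exp)
        assert abs(np.mean(estimates) + 0.3) < 0.03

    def test_exponent_invariant_to_discharge_units(self, rng):
        q = rng.lognormal(5, 1, 40)
        ratio = 10 ** (0.5 - 0.2 * np.log10(q) + rng.normal(0, 0.1, 40))
        lps = fit_power_law(q, ratio)
        m3s = fit_power_law(q / 1000.0, ratio)
        assert m3s.b_exp == pytest.approx(lps.b_exp, abs=1e-10)


class TestBLanduseRegression:
    @pytest.fixture
    def landuse(self, rng):
        n = 30
        return pd.DataFrame({"site_id": [f"s{i}" for i in range(n)],
                             "p_cro": rng.uniform(0, 0.5, n),
                             "p_hay": rng.uniform(0, 0.2, n),
                             "p_urb": rng.uniform(0, 0.4, n),
                             "p_for": rng.uniform(0, 0.5, n)})

    def test_identical_exponents_give_zero_slope(self, landuse):
        fits = pd.DataFrame({"site_id": landuse["site_id"], "ratio_kind": "total",
                             "b_exp": 0.1})
        out = regress_b_on_landuse(fits, landuse)
        assert (out["slope"] == 0.0).all()

    def test_linear_dependence_on_agriculture_recovered(self, landuse):
        ag = landuse["p_cro"] + landuse["p_hay"]
        fits = pd.DataFrame({"site_id": landuse["site_id"], "ratio_kind": "total",
                             "b_exp": 0.4 * ag})
        out = regress_b_on_landuse(fits, landuse).set_index("predictor")
        assert out.loc["agriculture", "slope"] == pytest.approx(0.4)
        assert out.loc["agriculture", "p_value"] < 1e-12

    def test_too_few_sites_rejected(self, landuse):
        fits = pd.DataFrame({"site_id": landuse["site_id"][:5], "ratio_kind": "total",
                             "b_exp": 0.1})
        with pytest.raises(InsufficientDataError):
            regress_b_on_landuse(fits, landuse)


def test_site_power_laws_reports_ineligible(rng):
    frames = []
    for name, n in (("big", 30), ("small", 8)):
        q = rng.lognormal(5, 1, n)
        frames.append(pd.DataFrame({"site_id": name, "discharge_lps": q,
                                    "np_total": 2 * q}))
    fits, ineligible = site_power_laws(pd.concat(frames, ignore_index=True),
                                       "np_total", "total")
    assert list(fits["site_id"]) == ["big"]
    assert ineligible == ["small"]
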