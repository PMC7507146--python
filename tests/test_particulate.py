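"""DIN computation, organic-share estimation, bootstrap particulate derivation."""
import numpy as np
import pandas as pd
import pytest

from streamstoich.particulate import (
    DomProportionDistribution,
    add_din,
    bootstrap_particulate,
    check_dom_vs_landuse,
    compute_din,
    derive_particulates,
    estimate_dom_proportions,
    filter_inconsistent,
)


class TestComputeDin:
    def test_zero_components(self):
        din, partial = compute_din(0.0, 0.0, 0.0)
        assert din == 0.0 and not partial

    def test_sum_arithmetic(self):
        din, partial = compute_din(0.01, 0.02, 0.50)
        assert din == pytest.approx(0.53) and not partial

    def test_missing_component_treated_as_zero_and_flagged(self):
        din, partial = compute_din(np.nan, 0.02, 0.50)
        assert din == pytest.approx(0.52) and partial
        # strict oracle: any missing component poisons the sum
        din_strict, _ = compute_din(np.nan, 0.02, 0.50, strict=True)
        assert np.isnan(din_strict)

    def test_all_missing_gives_missing(self):
        din, partial = compute_din(np.nan, np.nan, np.nan)
        assert np.isnan(din) and not partial

    def test_add_din_vectorized_matches_scalar(self):
        frame = pd.DataFrame(
            {"NH3N": [0.01, np.nan], "NO3NO2N": [0.5, 0.3], "site_id": ["a", "b"]}
        )
        out = add_din(frame)
        assert out["din"].tolist() == pytest.approx([0.51, 0.3])
        assert out["din_partial"].tolist() == [True, True]  # NH4N column absent


class TestDomProportions:
    def make_pairs(self, tn, tdn, din):
        return pd.DataFrame({"TN": tn, "TDN": tdn, "din": din})

    def test_proportion_arithmetic(self):
        frame = self.make_pairs([1.0] * 10, [0.8] * 10, [0.6] * 10)
        dist = estimate_dom_proportions(frame, "N")
        assert np.allclose(dist.proportions, 0.5)
        assert dist.n_source_pairs == 10

    def test_out_of_bounds_proportions_excluded(self):
        frame = self.make_pairs([1.0] * 11, [0.8] * 10 + [1.2], [0.6] * 11)
        dist = estimate_dom_proportions(frame, "N")
        assert dist.proportions.size == 10
        assert dist.n_excluded == 1

    def test_insufficient_pairs_is_error(self):
        frame = self.make_pairs([1.0] * 5, [0.8] * 5, [0.6] * 5)
        with pytest.raises(ValueError, match="insufficient pairs"):
            estimate_dom_proportions(frame, "N")

    def test_beta_shares_recovered(self, rng):
        """Pairs built with Beta(2,5) organic shares: retained mean ~ 2/7."""
        n = 1000
        p = rng.beta(2, 5, n)
        din = rng.lognormal(0, 0.5, n)
        residual = rng.lognormal(-1, 0.5, n)
        frame = self.make_pairs(din + residual, din + p * residual, din)
        dist = estimate_dom_proportions(frame, "N")
        assert dist.proportions.size == n
        assert abs(dist.proportions.mean() - 2 / 7) < 0.03


class TestBootstrapParticulate:
    def test_zero_residual_degenerate(self, rng):
        dist = DomProportionDistribution("N", np.full(20, 0.3), 20)
        assert bootstrap_particulate(0.0, dist, rng=rng) == 0.0

    def test_point_mass_distribution_collapses_iqr(self, rng):
        dist = DomProportionDistribution("N", np.full(50, 0.4), 50)
        assert bootstrap_particulate(1.0, dist, rng=rng) == pytest.approx(0.6)

    def test_two_point_distribution_envelope(self, rng):
        """Candidates are residual*(1-p), p in {0.2, 0.4}: support is [0.6, 0.8]."""
        dist = DomProportionDistribution("N", np.tile([0.2, 0.4], 25), 50)
        draws = np.array([bootstrap_particulate(1.0, dist, 200, rng) for _ in range(500)])
        assert draws.min() >= 0.6
        assert draws.max() <= 0.8

    def test_unusable_distribution_rejected(self, rng):
        dist = DomProportionDistribution("N", np.full(5, 0.4), 5)
        with pytest.raises(ValueError, match="unusable"):
            bootstrap_particulate(1.0, dist, rng=rng)

    def test_mass_near_one_produces_missing(self, rng):
        """Shares ~1 push candidates to ~0; tiny IQR draws can go non-positive."""
        dist = DomProportionDistribution("N", np.ones(20), 20)
        assert np.isnan(bootstrap_particulate(1.0, dist, rng=rng))


class TestDeriveTable:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "site_id": ["A", "A", "B"],
                "date": pd.to_datetime(["2005-01-01", "2005-02-01", "2005-01-01"]),
                "TN": [1.0, 2.0, 1.5],
                "din": [0.4, 0.8, 0.9],
                "TP": [0.1, 0.2, 0.15],
                "DIP": [0.03, 0.05, 0.04],
            }
        )

    def test_envelope_and_reproducibility(self, table):
        dist_n = DomProportionDistribution("N", np.tile([0.2, 0.4], 10), 20)
        dist_p = DomProportionDistribution("P", np.tile([0.1, 0.5], 10), 20)
        out1, report = derive_particulates(table, dist_n, dist_p, n_boot=200, seed=3)
        out2, _ = derive_particulates(table, dist_n, dist_p, n_boot=200, seed=3)
        pd.testing.assert_frame_equal(out1, out2)
        residual_n = table["TN"] - table["din"]
        assert ((out1["pn"] >= 0.6 * residual_n) & (out1["pn"] <= 0.8 * residual_n)).all()
        assert report["pn_n"] == 3 and report["pn_missing"] == 0


class TestFilterInconsistent:
    def test_retain_and_remove(self):
        frame = pd.DataFrame({"TN": [1.0, 1.0], "din": [0.5, 1.2],
                              "TP": [0.1, 0.1], "DIP": [0.05, 0.05],
                              "site_id": ["a", "b"]})
        kept, report = filter_inconsistent(frame)
        assert list(kept["site_id"]) == ["a"]
        assert report.set_index("analyte").loc["DIN", "n_removed"] == 1

    def test_toy_table_fractions(self):
        """10 rows, 2 DIN violations and 1 DIP violation: fractions 0.2 and 0.1."""
        tn = [1.0] * 10
        din = [0.5] * 8 + [1.5, 2.0]
        tp = [0.10] * 10
        dip = [0.20] + [0.05] * 9
        frame = pd.DataFrame({"TN": tn, "din": din, "TP": tp, "DIP": dip})
        kept, report = filter_inconsistent(frame)
        assert len(kept) == 7
        rep = report.set_index("analyte")
        assert rep.loc["DIN", "fraction"] == pytest.approx(0.2)
        assert rep.loc["DIP", "fraction"] == pytest.approx(0.1)


class TestDomLanduseCheck:
    @pytest.fixture
    def landuse(self, rng):
        n = 20
        return pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "p_cro": rng.uniform(0, 0.4, n),
                "p_hay": rng.uniform(0, 0.3, n),
                "p_urb": rng.uniform(0, 0.4, n),
                "p_for": rng.uniform(0, 0.5, n),
            }
        )

    def test_identical_proportions_give_flat_regression(self, landuse):
        props = pd.Series(0.5, index=landuse["site_id"])
        out = check_dom_vs_landuse(props, landuse)
        assert (out["slope"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()

    def test_exact_linear_dependence_recovered(self, landuse):
        props = pd.Series(
            (0.2 + 0.5 * landuse["p_urb"]).to_numpy(), index=landuse["site_id"]
        )
        out = check_dom_vs_landuse(props, landuse).set_index("predictor")
        assert out.loc["p_urb", "slope"] == pytest.approx(0.5)
        assert out.loc["p_urb", "p_value"] < 1e-12

    def test_degenerate_predictor_flagged(self, landuse, rng):
        landuse = landuse.assign(p_hay=0.1)
        props = pd.Series(rng.uniform(0, 1, len(landuse)), index=landuse["site_id"])
        out = check_dom_vs_landuse(props, landuse).set_index("predictor")
        assert out.loc["p_hay", "degenerate"]
        assert np.isnan(out.loc["p_hay", "slope"])

    def test_too_few_sites_rejected(self, landuse):
        props = pd.Series(0.5, index=landuse["site_id"][:2])
        with pytest.raises(ValueError, match=">= 3 sites"):
            check_dom_vs_landuse(props, landuse)
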