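"""Tests for the synthetic-data generator and its file round trips."""

import numpy as np
import pytest
from scipy.special import logit

import ipm_demog as ipm
from ipm_demog import io as ipm_io
from ipm_demog.synthetic import ScenarioPreset, draw_yearly_params


class TestDrawYearlyParams:
    def test_zero_spread_returns_preset_means(self):
        preset = ipm.northwest_like(sd_logit_phi_ad=0.0, sd_log_brood=0.0,
                                    sd_logit_egg_period=0.0,
                                    sd_logit_chick_period=0.0, sd_log_rho=0.0)
        params = draw_yearly_params(preset, seed=1)
        assert np.allclose(params.phi_ad, 0.46)
        assert np.allclose(params.brood_size, 5.78)
        assert np.allclose(params.phi_egg_daily ** 13, 0.71)
        assert np.allclose(params.phi_chick_daily ** 13, 0.76)
        assert np.allclose(params.rho, 0.39)

    def test_reproducible_under_seed(self):
        preset = ipm.southeast_like()
        a = draw_yearly_params(preset, seed=5)
        b = draw_yearly_params(preset, seed=5)
        assert np.array_equal(a.phi_ad, b.phi_ad)
        assert np.array_equal(a.rho, b.rho)

    def test_transformed_scale_mean(self):
        # law of large numbers on the logit scale over ~10^4 drawn years
        preset = ipm.northwest_like(T=10_001, missing_years=())
        params = draw_yearly_params(preset, seed=3)
        z = logit(params.phi_ad)
        se = z.std(ddof=1) / np.sqrt(len(z))
        assert z.mean() == pytest.approx(logit(0.46), abs=3 * se)

    def test_explicit_yearly_paths_override(self):
        path = np.linspace(0.3, 0.6, 18)
        preset = ipm.northwest_like(yearly_phi_ad=path)
        params = draw_yearly_params(preset, seed=1)
        assert np.array_equal(params.phi_ad, path)


class TestSimulateRegion:
    def test_counts_equal_latent_in_noise_free_limit(self):
        preset = ipm.northwest_like(T=10, sigma_obs=1e-12, missing_years=())
        res = ipm.simulate_region(preset, seed=4)
        obs = res.observed.counts
        assert np.allclose(obs, res.latent.N, rtol=1e-9)

    def test_extinction_is_flagged_not_raised(self):
        K = 9
        preset = ScenarioPreset(T=10, yearly_phi_ad=np.zeros(K),
                                yearly_brood=np.full(K, 5.0),
                                yearly_egg_period=np.full(K, 0.7),
                                yearly_chick_period=np.full(K, 0.7),
                                yearly_rho=np.zeros(K), missing_years=())
        res = ipm.simulate_region(preset, seed=1)
        assert res.extinct
        assert (res.latent.N[1:] == 0).all()

    def test_latent_identity(self):
        res = ipm.simulate_region(ipm.northwest_like(T=8), seed=2)
        assert np.array_equal(res.latent.N[1:], res.latent.N_a + res.latent.N_r)

    def test_missing_year_is_nan(self):
        res = ipm.simulate_region(ipm.northwest_like(), seed=2)
        assert np.isnan(res.observed.counts[7])
        assert np.isfinite(np.delete(res.observed.counts, 7)).all()

    def test_realised_nest_hazard_matches_daily_rate(self):
        # zero-spread preset: pooled egg-stage failures/exposure ~ 1 - phi_daily
        preset = ipm.northwest_like(T=10, n_nests_per_year=400,
                                    sd_logit_egg_period=0.0, missing_years=())
        res = ipm.simulate_region(preset, seed=6)
        nests = res.observed.nests
        surv = np.where(nests["egg_survived"] == 1, nests["egg_days"],
                        nests["egg_days"] - 1).sum()
        fails = (nests["egg_survived"] == 0).sum()
        haz = fails / (surv + fails)
        true_haz = 1 - res.params.phi_egg_daily[0]
        se = np.sqrt(true_haz * (1 - true_haz) / (surv + fails))
        assert haz == pytest.approx(true_haz, abs=4 * se)

    def test_realised_recapture_rate(self):
        preset = ipm.northwest_like(T=10, n_releases_per_year=500, missing_years=())
        res = ipm.simulate_region(preset, seed=8)
        # individuals released at occasion 0: survivors to occasion 1 are not
        # directly observable, so check the marginal: P(seen at occ f+1)
        # = phi_f * p
        h = res.observed.histories
        first0 = h.enc[h.first == 0]
        frac = first0[:, 1].mean()
        expect = res.params.phi_ad[0] * res.params.p_recapture
        se = np.sqrt(expect * (1 - expect) / len(first0))
        assert frac == pytest.approx(expect, abs=4 * se)

    def test_count_log_residual_sd(self):
        preset = ipm.northwest_like(T=120, missing_years=(),
                                    sd_logit_phi_ad=0.05, sd_log_rho=0.05)
        res = ipm.simulate_region(preset, seed=11)
        ok = res.observed.counts > 0
        resid = np.log(res.observed.counts[ok]) - np.log(res.latent.N[ok])
        assert resid.std(ddof=1) == pytest.approx(0.10, abs=0.03)

    def test_implied_fpba_matches_formula(self):
        # aggregate Mayfield + mean-brood estimate reproduces B*fe^ep*fc^yp
        preset = ipm.northwest_like(T=12, n_nests_per_year=600,
                                    sd_logit_egg_period=0.0,
                                    sd_logit_chick_period=0.0, sd_log_brood=0.0,
                                    missing_years=())
        res = ipm.simulate_region(preset, seed=13)
        nests = res.observed.nests
        egg_surv = np.where(nests["egg_survived"] == 1, nests["egg_days"],
                            nests["egg_days"] - 1).sum()
        egg_tot = egg_surv + (nests["egg_survived"] == 0).sum()
        fe = egg_surv / egg_tot
        hatched = nests[nests["egg_survived"] == 1]
        ch_surv = np.where(hatched["chick_survived"] == 1, hatched["chick_days"],
                           hatched["chick_days"] - 1).sum()
        ch_tot = ch_surv + (hatched["chick_survived"] == 0).sum()
        fc = ch_surv / ch_tot
        brood = hatched["brood"].mean()
        implied = brood * fe ** 13 * fc ** 13
        truth = res.params.fpba[0]
        assert implied == pytest.approx(truth, rel=0.06)


class TestRecoveryPresets:
    def test_expected_pattern(self):
        nw, se = ipm.recovery_presets()
        lam_nw = nw.yearly_phi_ad + 0.5 * np.asarray(nw.yearly_brood) * \
            np.asarray(nw.yearly_egg_period) * np.asarray(nw.yearly_chick_period) * \
            np.asarray(nw.yearly_rho)
        lam_se = se.yearly_phi_ad + 0.5 * np.asarray(se.yearly_brood) * \
            np.asarray(se.yearly_egg_period) * np.asarray(se.yearly_chick_period) * \
            np.asarray(se.yearly_rho)
        # both decline through the dip; only the northwest recovers fully
        assert (np.cumprod(lam_se)[-1]) < 1.0
        assert (np.cumprod(lam_nw)[-1]) > 1.0


class TestIO:
    def test_scenario_round_trip(self, tmp_path):
        res = ipm.simulate_region(ipm.northwest_like(T=6), seed=5)
        ipm_io.write_scenario(res.observed, tmp_path, truth=res)
        back = ipm_io.read_scenario(tmp_path)
        np.testing.assert_allclose(back.counts, res.observed.counts)
        assert np.array_equal(back.years, res.observed.years)
        assert np.array_equal(back.histories.enc, res.observed.histories.enc)
        assert np.array_equal(back.histories.first, res.observed.histories.first)
        cols = ["year", "brood", "egg_days", "egg_survived", "chick_days",
                "chick_survived"]
        assert back.nests[cols].equals(
            res.observed.nests[cols].astype(back.nests[cols].dtypes))

    def test_missing_counts_serialise_as_empty_fields(self, tmp_path):
        res = ipm.simulate_region(ipm.northwest_like(T=9, missing_years=(4,)), seed=5)
        ipm_io.write_scenario(res.observed, tmp_path)
        lines = (tmp_path / "counts.csv").read_text().strip().splitlines()
        missing_line = lines[1 + 4]
        assert missing_line.endswith(",")       # empty field, not a zero
        assert ",0" not in missing_line

    def test_truth_file_contains_generating_params(self, tmp_path):
        res = ipm.simulate_region(ipm.northwest_like(T=6), seed=5)
        ipm_io.write_scenario(res.observed, tmp_path, truth=res)
        truth = ipm_io.read_truth_yaml(tmp_path / "truth.yaml")
        for key in ("phi_ad", "brood_size", "phi_egg_daily", "phi_chick_daily",
                    "rho", "sigma_obs", "p_recapture", "ep", "yp"):
            assert key in truth["params"]
        for key in ("phi_ad_mean", "sd_logit_phi_ad", "T", "N0",
                    "n_nests_per_year", "n_releases_per_year"):
            assert key in truth["preset"]
        assert np.allclose(truth["params"]["phi_ad"], res.params.phi_ad)

    def test_inp_reader(self, tmp_path):
        path = tmp_path / "hist.inp"
        path.write_text(
            "/* ringing site A */\n"
            "1100 2;\n"
            "1010 1; /* trailing comment */\n"
            "0011 3;\n")
        h = ipm_io.read_inp(path, region="A")
        assert len(h) == 6
        assert h.n_occasions == 4
        assert (h.first == [0, 0, 0, 2, 2, 2]).sum() == 6

    def test_inp_requires_terminal_semicolon(self, tmp_path):
        path = tmp_path / "bad.inp"
        path.write_text("1100 2;\n1010 1\n")
        with pytest.raises(ValueError):
            ipm_io.read_inp(path)
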