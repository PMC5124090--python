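"""Unit and property tests for the demographic process and likelihood kernels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import ipm_demog as ipm
from ipm_demog.model_core import (
    CaptureHistorySet,
    NestRecord,
    PriorSpec,
    build_m_array,
    latent_process_loglik,
    nests_to_frame,
    ztpoisson_logpmf,
)
from conftest import enum_history_loglik


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------

class TestProductivity:
    @pytest.mark.parametrize("brood,fe,fc,ep,yp,expected", [
        (6.0, 1.0, 1.0, 13, 13, 6.0),                      # perfect survival
        (6.0, 0.5 ** (1 / 13), 0.5 ** (1 / 13), 13, 13, 1.5),  # half per stage
        (5.78, 0.71 ** (1 / 13), 0.76 ** (1 / 13), 13, 13, 5.78 * 0.71 * 0.76),
    ])
    def test_worked_examples(self, brood, fe, fc, ep, yp, expected):
        assert ipm.productivity_fpba(brood, fe, fc, ep, yp) == pytest.approx(expected)

    def test_period_survival_magnitude(self):
        # stage survivals of 0.71/0.76 with brood 5.78 give ~3.1 fledglings
        assert ipm.productivity_fpba(
            5.78, 0.71 ** (1 / 13), 0.76 ** (1 / 13)) == pytest.approx(3.119, abs=5e-3)

    def test_zero_survival_kills_productivity(self):
        assert ipm.productivity_fpba(6.0, 0.0, 0.9, 13, 13) == 0.0

    @pytest.mark.parametrize("kwargs", [
        dict(brood_size=-1.0, phi_egg_daily=0.9, phi_chick_daily=0.9),
        dict(brood_size=5.0, phi_egg_daily=1.2, phi_chick_daily=0.9),
        dict(brood_size=5.0, phi_egg_daily=0.9, phi_chick_daily=-0.1),
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ipm.productivity_fpba(**kwargs)

    def test_rejects_negative_exposure(self):
        with pytest.raises(ValueError):
            ipm.productivity_fpba(5.0, 0.9, 0.9, ep=-1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(phi=st.floats(0.01, 0.999), a=st.integers(0, 20), b=st.integers(0, 20))
    def test_exposure_splitting_invariance(self, phi, a, b):
        # surviving a+b days equals surviving a then b days
        whole = ipm.productivity_fpba(1.0, phi, 1.0, ep=a + b, yp=1)
        split = (ipm.productivity_fpba(1.0, phi, 1.0, ep=a, yp=1)
                 * ipm.productivity_fpba(1.0, phi, 1.0, ep=b, yp=1))
        assert whole == pytest.approx(split, rel=1e-12)


# ---------------------------------------------------------------------------
# population step
# ---------------------------------------------------------------------------

class TestStepPopulation:
    def test_extinction_is_absorbing(self):
        rng = np.random.default_rng(0)
        assert ipm.step_population(0, 0.5, 3.0, 0.4, rng) == (0, 0)

    def test_pure_survival(self):
        rng = np.random.default_rng(0)
        n_a, n_r = ipm.step_population(1000, 1.0, 0.0, 0.4, rng)
        assert (n_a, n_r) == (1000, 0)

    def test_mean_growth_matches_closed_form(self):
        # E[lambda] = phi + 0.5 * F * rho at modest replicate count
        rng = np.random.default_rng(42)
        reps = 20_000
        n_a, n_r = ipm.step_population(np.full(reps, 1000), 0.45, 3.0, 0.40, rng)
        lam = (n_a + n_r) / 1000.0
        se = lam.std(ddof=1) / np.sqrt(reps)
        assert lam.mean() == pytest.approx(1.05, abs=3 * se)

    def test_rejects_bad_args(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ipm.step_population(-1, 0.5, 3.0, 0.4, rng)
        with pytest.raises(ValueError):
            ipm.step_population(10, 1.5, 3.0, 0.4, rng)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

class TestObservation:
    def test_matches_lognormal_density(self):
        expected = stats.lognorm.logpdf(1100.0, s=0.1, scale=1000.0)
        assert ipm.observation_loglik(1100.0, 1000, 0.1) == pytest.approx(expected)

    def test_missing_contributes_zero(self):
        assert ipm.observation_loglik(np.nan, 500, 0.1) == 0.0

    def test_mode_at_truth(self):
        at_truth = ipm.observation_loglik(1000.0, 1000, 0.01)
        off = ipm.observation_loglik(1010.0, 1000, 0.01)
        assert at_truth > off

    def test_zero_latent_with_observed_count(self):
        assert ipm.observation_loglik(10.0, 0, 0.1) == -np.inf

    def test_vectorised_sum(self):
        y = np.array([900.0, np.nan, 1100.0])
        n = np.array([1000, 1000, 1000])
        single = (ipm.observation_loglik(900.0, 1000, 0.1)
                  + ipm.observation_loglik(1100.0, 1000, 0.1))
        assert ipm.observation_loglik(y, n, 0.1) == pytest.approx(single)


# ---------------------------------------------------------------------------
# CJS
# ---------------------------------------------------------------------------

class TestCJS:
    def test_survive_then_recapture(self):
        h = CaptureHistorySet.from_strings(["11"])
        assert ipm.cjs_loglik(h, [0.5], 0.5) == pytest.approx(np.log(0.25))

    def test_released_never_seen(self):
        h = CaptureHistorySet.from_strings(["10"])
        assert ipm.cjs_loglik(h, [0.5], 0.5) == pytest.approx(np.log(0.75))

    @pytest.mark.parametrize("T", [2, 3, 4])
    def test_matches_fate_enumeration(self, T):
        rng = np.random.default_rng(T)
        phi = rng.uniform(0.15, 0.95, size=T - 1)
        p = rng.uniform(0.1, 0.9)
        for bits in itertools.product([0, 1], repeat=T):
            if sum(bits) == 0:
                continue
            h = CaptureHistorySet.from_strings(["".join(map(str, bits))])
            impl = ipm.cjs_loglik(h, phi, p)
            oracle = enum_history_loglik(bits, phi, p)
            assert impl == pytest.approx(oracle, abs=1e-10)

    def test_additive_over_histories(self):
        phi, p = [0.6, 0.4, 0.5], 0.3
        singles = sum(ipm.cjs_loglik(CaptureHistorySet.from_strings([s]), phi, p)
                      for s in ["1010", "1100", "0110"])
        joint = ipm.cjs_loglik(
            CaptureHistorySet.from_strings(["1010", "1100", "0110"]), phi, p)
        assert joint == pytest.approx(singles)

    def test_rejects_invalid_first_encounter(self):
        with pytest.raises(ValueError):
            ipm.CaptureHistory(region="r", first_occasion=1,
                               encounters=np.array([0, 0, 1]))

    def test_rejects_wrong_phi_length(self):
        h = CaptureHistorySet.from_strings(["110"])
        with pytest.raises(ValueError):
            ipm.cjs_loglik(h, [0.5], 0.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=4).filter(lambda b: sum(b) > 0),
           st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    def test_enumeration_property(self, bits, phi_val, p):
        phi = np.full(3, phi_val)
        h = CaptureHistorySet.from_strings(["".join(map(str, bits))])
        assert ipm.cjs_loglik(h, phi, p) == pytest.approx(
            enum_history_loglik(bits, phi, p), abs=1e-10)


# ---------------------------------------------------------------------------
# nest survival (Mayfield)
# ---------------------------------------------------------------------------

def _nest(year, brood, egg_days, egg_ok, chick_days, chick_ok):
    return NestRecord(region="r", year=year, brood=brood, egg_days=egg_days,
                      egg_survived=egg_ok, chick_days=chick_days,
                      chick_survived=chick_ok)


class TestNestLoglik:
    def test_certain_survival_contributes_zero(self):
        recs = [_nest(2000, 5, 10, True, 0, True)]
        # chick stage with zero exposure days adds nothing either
        assert ipm.nest_loglik(recs, [1.0], [0.9], [2000]) == 0.0

    def test_failure_day_formula(self):
        # 3 survived egg days then a failure day at phi = 0.9
        recs = [_nest(2000, 0, 4, False, 0, False)]
        expected = 3 * np.log(0.9) + np.log(0.1)
        assert ipm.nest_loglik(recs, [0.9], [0.5], [2000]) == pytest.approx(expected)

    def test_mle_equals_mayfield_closed_form(self):
        preset = ipm.northwest_like(T=4, n_nests_per_year=400)
        res = ipm.simulate_region(preset, seed=3)
        nests = res.observed.nests
        seasons = res.observed.years[:-1]
        surv = np.where(nests["egg_survived"] == 1, nests["egg_days"],
                        nests["egg_days"] - 1).sum()
        fails = (nests["egg_survived"] == 0).sum()
        closed = surv / (surv + fails)

        def nll(phi):
            return -ipm.nest_loglik(nests, np.full(3, phi), np.full(3, 0.9), seasons)

        opt = optimize.minimize_scalar(nll, bounds=(1e-6, 1 - 1e-6), method="bounded",
                                       options={"xatol": 1e-10})
        assert opt.x == pytest.approx(closed, abs=1e-6)

    def test_rejects_failure_without_exposure(self):
        with pytest.raises(ValueError):
            _nest(2000, 0, 0, False, 0, False)


class TestBroodLoglik:
    def test_empty_records(self):
        assert ipm.brood_loglik(nests_to_frame([]), [5.0], [2000]) == 0.0

    def test_matches_ztpoisson_pmf(self):
        recs = [_nest(2000, 5, 13, True, 13, True)]
        expected = float(ztpoisson_logpmf(5, 5.0))
        by_hand = 5 * np.log(5) - 5 - np.log(1 - np.exp(-5.0)) - np.log(120)
        assert expected == pytest.approx(by_hand)
        assert ipm.brood_loglik(recs, [5.0], [2000]) == pytest.approx(expected)

    def test_mle_at_truncation_corrected_mean(self):
        # all broods equal k: the ZTP rate MLE satisfies mu/(1-e^-mu) = k
        recs = [_nest(2000, 4, 13, True, 13, True) for _ in range(50)]

        def nll(mu):
            return -ipm.brood_loglik(recs, [mu], [2000])

        opt = optimize.minimize_scalar(nll, bounds=(0.1, 9.9), method="bounded",
                                       options={"xatol": 1e-10})
        implied_mean = opt.x / (1 - np.exp(-opt.x))
        assert implied_mean == pytest.approx(4.0, abs=1e-5)

    def test_rejects_non_integer_broods(self):
        df = nests_to_frame([_nest(2000, 5, 13, True, 13, True)]).astype({"brood": float})
        df.loc[0, "brood"] = 4.5
        with pytest.raises(ValueError):
            ipm.brood_loglik(df, [5.0], [2000])


# ---------------------------------------------------------------------------
# joint posterior kernel
# ---------------------------------------------------------------------------

@pytest.fixture()
def small_dataset():
    res = ipm.simulate_region(
        ipm.northwest_like(T=5, n_nests_per_year=10, n_releases_per_year=15,
                           missing_years=()), seed=9)
    return res


class TestJointLoglik:
    def test_additivity_over_components(self, small_dataset):
        res = small_dataset
        data, params, latent = res.observed, res.params, res.latent
        priors = PriorSpec()
        seasons = data.years[:-1]
        total = (ipm.observation_loglik(data.counts, latent.N, params.sigma_obs)
                 + latent_process_loglik(latent, params)
                 + ipm.cjs_loglik(data.histories, params.phi_ad, params.p_recapture)
                 + ipm.nest_loglik(data.nests, params.phi_egg_daily,
                                   params.phi_chick_daily, seasons)
                 + ipm.brood_loglik(data.nests, params.brood_size, seasons)
                 + priors.logpdf(params))
        assert ipm.joint_loglik(data, params, latent, priors) == pytest.approx(total)

    def test_support_violation_is_minus_inf(self, small_dataset):
        res = small_dataset
        latent = res.latent
        bad_Na = latent.N_a.copy()
        bad_Na[1] = latent.N[1] + 50     # more survivors than last year's birds
        bad = ipm.LatentTrajectory(
            N=np.concatenate([latent.N[:2], [bad_Na[1] + latent.N_r[1]],
                              latent.N[3:]]),
            N_a=bad_Na, N_r=latent.N_r)
        assert ipm.joint_loglik(res.observed, res.params, bad) == -np.inf

    def test_prior_governed_shift(self, small_dataset):
        # moving sigma changes the kernel by the observation + prior deltas
        res = small_dataset
        p1 = res.params
        import dataclasses
        p2 = dataclasses.replace(p1, sigma_obs=p1.sigma_obs * 2)
        priors = PriorSpec()
        d_joint = (ipm.joint_loglik(res.observed, p2, res.latent, priors)
                   - ipm.joint_loglik(res.observed, p1, res.latent, priors))
        d_obs = (ipm.observation_loglik(res.observed.counts, res.latent.N, p2.sigma_obs)
                 - ipm.observation_loglik(res.observed.counts, res.latent.N, p1.sigma_obs))
        d_prior = (stats.halfnorm.logpdf(p2.sigma_obs)
                   - stats.halfnorm.logpdf(p1.sigma_obs))
        assert d_joint == pytest.approx(d_obs + d_prior)

    def test_out_of_prior_support(self, small_dataset):
        res = small_dataset
        import dataclasses
        p2 = dataclasses.replace(res.params, rho=res.params.rho + 10.0)
        assert ipm.joint_loglik(res.observed, p2, res.latent) == -np.inf


def test_m_array_totals():
    h = CaptureHistorySet.from_strings(["1010", "1100", "0110", "0011", "1000"])
    m = build_m_array(h)
    assert m["M"] == m["m"].sum() == 4
    assert (m["R"] - m["m"].sum(axis=1) == m["never"]).all()
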