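"""Shared fixtures: tiny simulated datasets, small fits, constructed draws."""

from __future__ import annotations

import numpy as np
import pytest

import ipm_demog as ipm
from ipm_demog.inference import PosteriorDraws


def enum_history_loglik(enc, phi, p):
    """Brute-force CJS oracle: sum over all latent death times.

    ``enc`` is a 0/1 vector; the probability of the history conditions on
    the first capture and marginalises the occasion after which the bird
    died (or survived past the study).
    """
    enc = np.asarray(enc, dtype=int)
    T = len(enc)
    occ = np.flatnonzero(enc)
    f = occ[0]
    total = 0.0
    for d in range(f, T):          # d = last occasion alive
        pr = 1.0
        for t in range(f, d):
            pr *= phi[t]
        if d < T - 1:
            pr *= 1.0 - phi[d]
        ok = True
        for t in range(f + 1, T):
            if t <= d:
                pr *= p if enc[t] else (1.0 - p)
            elif enc[t]:
                ok = False
                break
        if ok:
            total += pr
    return np.log(total)


def make_draws(rng, n_draws=500, T=19, lam=None, rho=None, phi_ad=None,
               brood=None, years0=1994, n_chains=2) -> PosteriorDraws:
    """Constructed posterior-draw container with controllable structure.

    Any yearly matrix not supplied is filled with mildly noisy defaults;
    ``lam`` (per-draw growth rates) is realised through the stored N path
    so that the container's internal consistency (lambda = N_t/N_{t-1})
    holds by construction.
    """
    K = T - 1
    if lam is None:
        lam = 1.0 + 0.05 * rng.standard_normal((n_draws, K))
    lam = np.asarray(lam, dtype=float)
    N = np.empty((n_draws, T))
    N[:, 0] = 1000.0
    for t in range(K):
        N[:, t + 1] = N[:, t] * lam[:, t]
    if phi_ad is None:
        phi_ad = np.clip(0.45 + 0.05 * rng.standard_normal((n_draws, K)), 0.01, 0.99)
    if brood is None:
        brood = np.clip(5.8 + 0.2 * rng.standard_normal((n_draws, K)), 0.1, 9.9)
    if rho is None:
        rho = np.clip(0.4 + 0.05 * rng.standard_normal((n_draws, K)), 0.01, 4.99)
    fe = np.clip(0.97 + 0.005 * rng.standard_normal((n_draws, K)), 0.5, 0.999)
    fc = np.clip(0.98 + 0.005 * rng.standard_normal((n_draws, K)), 0.5, 0.999)
    per = max(1, n_draws // n_chains)
    chain = np.minimum(np.arange(n_draws) // per, n_chains - 1)
    draw = np.arange(n_draws) - chain * per
    return PosteriorDraws(
        phi_ad=np.asarray(phi_ad, dtype=float), brood=np.asarray(brood, dtype=float),
        phi_egg=fe, phi_chick=fc, rho=np.asarray(rho, dtype=float),
        sigma_obs=np.full(n_draws, 0.1), p_recapture=np.full(n_draws, 0.3),
        N=N, chain=chain, draw=draw,
        years=np.arange(years0, years0 + T),
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated region (8 years) with one masked count year."""
    preset = ipm.northwest_like(T=8, n_nests_per_year=40, n_releases_per_year=60,
                                missing_years=(3,))
    return ipm.simulate_region(preset, seed=2024)


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """Cheap MCMC fit of the small region, reused across tests."""
    cfg = ipm.FitConfig(n_chains=2, n_iter=2000, n_burnin=1000, thin=4,
                        seed=7, n_sweeps=4)
    return ipm.fit_ipm(tiny_sim.observed, cfg)
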