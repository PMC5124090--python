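"""Metropolis-within-Gibbs engine for the integrated population model.

The data are first reduced to sufficient statistics — an m-array for the
CJS stream, per-season exposure-day and brood totals for the nest stream
— and the MCMC loop then runs in a numba-compiled kernel.

Two structural choices make the chain mix well:

* The recruitment scaling ``rho_t`` is integrated out analytically
  during sampling (collapsed Gibbs).  With a Uniform(0, R) prior and a
  single Poisson term, the marginal recruitment pmf is
  ``P(N_r; c) = gammainc(N_r + 1, R c) / (R c)`` with
  ``c = 0.5 N F`` — otherwise the exact Gibbs draw of ``rho`` and the
  random walk on ``N_r`` pin each other to a narrow ridge and the pair
  diffuses very slowly.  Each retained draw then samples ``rho_t`` from
  its exact full conditional (a Gamma truncated at the prior bound), so
  retained draws come from the full joint posterior.
* The observation s.d. uses an inverse-gamma independence proposal
  matching its full conditional up to the half-normal prior factor, so
  it decorrelates from the latent path in one step.

Remaining blocks are random walks on transformed scales: per-interval
adult survival (CJS likelihood with a backward-recursion chi term plus
the binomial latent-survival term), recapture probability, per-season
daily egg/chick survival and brood rate, and single-coordinate integer
walks on the latent (N_a, N_r) pairs, swept several times per iteration
because the latent path is the stiffest part of the posterior.  Several
blocks carry ridge-breaking companion proposals, each mixed 50/50 with
a plain variant so acceptance stays healthy when the companion is
blocked: survival updates can transfer ~N*dphi birds between survivors
and recruits, productivity updates can scale next year's recruits, and
the latent sweep includes independence refreshes of N_a (binomial
normal approximation) and N_r (exact draw from the marginal recruitment
pmf) plus a tail-shift move sliding the trajectory from a random year
onward.  All discretised-normal proposals enter the Hastings ratio
exactly.  Proposal scales adapt toward target acceptance rates during
burn-in only and are frozen afterwards, preserving detailed balance in
retained draws.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model_core import (
    FEMALE_FRACTION,
    ObservedData,
    PriorSpec,
    build_m_array,
    cjs_marray_loglik,
    nest_sufficient_stats,
)

_ADAPT_EVERY = 50
_TARGET = 0.44
HALF = FEMALE_FRACTION


def _interp_log_counts(counts: np.ndarray) -> np.ndarray:
    """Observed counts with missing years filled by log-scale interpolation."""
    t = np.arange(len(counts))
    obs = np.isfinite(counts)
    return np.exp(np.interp(t, t[obs], np.log(counts[obs])))


# ---------------------------------------------------------------------------
# numba helpers
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gammainc_p(a, x):
    """Regularised lower incomplete gamma P(a, x) (series / continued fraction)."""
    if x <= 0.0:
        return 0.0
    if x < a + 1.0:
        ap = a
        s = 1.0 / a
        delta = s
        for _ in range(1000):
            ap += 1.0
            delta *= x / ap
            s += delta
            if abs(delta) < abs(s) * 1e-14:
                break
        return s * math.exp(-x + a * math.log(x) - math.lgamma(a))
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1e300
    d = 1.0 / b
    h = d
    for i in range(1, 1000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        de = d * c
        h *= de
        if abs(de - 1.0) < 1e-14:
            break
    q = math.exp(-x + a * math.log(x) - math.lgamma(a)) * h
    return 1.0 - q


@njit(cache=False)
def _bin_lp(k, n, p):
    if k < 0 or k > n:
        return -np.inf
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
            + k * math.log(p) + (n - k) * math.log1p(-p))


@njit(cache=False)
def _marg_rec_lp(k, cbase, rho_max):
    """Recruitment log pmf with rho integrated out against its uniform prior."""
    if k < 0:
        return -np.inf
    if cbase <= 0.0:
        return 0.0 if k == 0 else -np.inf
    z = rho_max * cbase
    p = _gammainc_p(k + 1.0, z)
    if p <= 0.0:
        return -np.inf
    return math.log(p) - math.log(z)


@njit(cache=False)
def _ndisc_lp(d, mu, sd):
    """Log pmf of a rounded (integer-discretised) normal draw."""
    rt2 = 1.4142135623730951
    pr = 0.5 * (math.erf((d + 0.5 - mu) / (sd * rt2))
                - math.erf((d - 0.5 - mu) / (sd * rt2)))
    if pr <= 0.0:
        return -np.inf
    return math.log(pr)


@njit(cache=False)
def _rate_move_terms(rng, ratio, t, c, Nr, Na, N, F, phi,
                     obs_mask, logy, sg, rho_max, T):
    """Recruit-coupled part of a productivity-rate proposal.

    A proposal scaling the per-attempt productivity by ``ratio`` also
    scales next year's recruits (discretised-normal step centred on
    ``N_r (ratio - 1)``), so the pair moves along the flat recruitment
    ridge instead of pinning each other.  Returns (valid, recruit step,
    log-ratio contribution), where the contribution covers the marginal
    recruitment change, the observation and downstream-year terms touched
    by the recruit change, and the exact proposal correction.
    """
    nr0 = Nr[c, t]
    cb0 = HALF * N[c, t] * F[c, t]
    coupled = rng.random() >= 0.5
    if coupled:
        mu_f = nr0 * (ratio - 1.0)
        sd_f = max(1.0, math.sqrt(abs(mu_f)))
        dnr = int(math.floor(mu_f + sd_f * rng.standard_normal() + 0.5))
    else:
        # plain variant of the mixture: rate moves alone; keeps acceptance
        # healthy where the recruit transfer is blocked (e.g. N_r near 0)
        dnr = 0
        mu_f = 0.0
        sd_f = 1.0
    nr1 = nr0 + dnr
    if nr1 < 0:
        return False, 0, 0.0
    j = t + 1
    n0 = N[c, j]
    n1 = n0 + dnr
    dll = (_marg_rec_lp(nr1, cb0 * ratio, rho_max)
           - _marg_rec_lp(nr0, cb0, rho_max))
    if dnr != 0:
        if obs_mask[j]:
            if n1 <= 0:
                return False, 0, 0.0
            r1 = logy[j] - math.log(n1)
            r0 = logy[j] - math.log(n0)
            dll += -0.5 * (r1 * r1 - r0 * r0) / (sg * sg)
        if j < T - 1:
            phn = phi[c, j]
            k2 = HALF * F[c, j]
            dll += (_bin_lp(Na[c, j], n1, phn) - _bin_lp(Na[c, j], n0, phn)
                    + _marg_rec_lp(Nr[c, j], k2 * n1, rho_max)
                    - _marg_rec_lp(Nr[c, j], k2 * n0, rho_max))
    if coupled:
        mu_r = nr1 * (1.0 / ratio - 1.0)
        sd_r = max(1.0, math.sqrt(abs(mu_r)))
        dll += _ndisc_lp(-dnr, mu_r, sd_r) - _ndisc_lp(dnr, mu_f, sd_f)
    return True, dnr, dll


@njit(cache=False)
def _cjs_ll(phi, c, p, w, never, M, A):
    """CJS log likelihood for chain ``c`` from m-array statistics."""
    K = phi.shape[1]
    ll = M * math.log(p) + A * math.log1p(-p)
    chi = 1.0
    chi_part = 0.0
    for i in range(K - 1, -1, -1):
        f = phi[c, i]
        chi = (1.0 - f) + f * (1.0 - p) * chi
        if never[i] > 0:
            chi_part += never[i] * math.log(chi)
        ll += w[i] * math.log(f)
    return ll + chi_part


@njit(cache=False)
def _trunc_gamma(rng, shape, rate, upper):
    """Gamma(shape, rate) truncated to (0, upper): rejection with an
    inverse-CDF (bisection) fallback for low acceptance rates."""
    for _ in range(50):
        g = rng.standard_gamma(shape) / rate
        if g < upper:
            return max(g, 1e-12)
    # mass below the bound is small: invert P(shape, rate*x) = u numerically
    z_hi = rate * upper
    u = rng.random() * _gammainc_p(shape, z_hi)
    lo, hi = 0.0, z_hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _gammainc_p(shape, mid) < u:
            lo = mid
        else:
            hi = mid
    return max(0.5 * (lo + hi) / rate, 1e-12)


@njit(cache=False)
def _run_kernel(rng, n_iter, n_burnin, thin, n_sweeps,
                logy, obs_mask, egg_s, egg_f, chick_s, chick_f,
                n_brood, sum_brood, w, never, M, A, has_cjs,
                ep, yp, brood_max, rho_max, sigma_prior,
                phi, p, fe, fc, B, sigma, Na, Nr, N,
                out_phi, out_fe, out_fc, out_B, out_rho,
                out_N, out_Na, out_Nr, out_sigma, out_p):
    C, K = phi.shape
    T = K + 1

    F = np.empty((C, K))
    for c in range(C):
        for t in range(K):
            F[c, t] = B[c, t] * fe[c, t] ** ep * fc[c, t] ** yp

    cur_cjs = np.zeros(C)
    if has_cjs:
        for c in range(C):
            cur_cjs[c] = _cjs_ll(phi, c, p[c], w, never, M, A)

    n_obs = 0
    for j in range(T):
        if obs_mask[j]:
            n_obs += 1

    s_phi = np.full(K, 0.2)
    s_fe = np.full(K, 0.3)
    s_fc = np.full(K, 0.3)
    s_B = np.full(K, 0.1)
    s_na = np.full(K, 25.0)
    s_nr = np.full(K, 25.0)
    s_p = 0.1
    s_tail = 25.0
    a_phi = np.zeros(K)
    a_fe = np.zeros(K)
    a_fc = np.zeros(K)
    a_B = np.zeros(K)
    a_na = np.zeros(K)
    a_nr = np.zeros(K)
    a_p = 0.0
    a_tail = 0.0
    n_prop = 0.0
    tmpN = np.empty(T, dtype=np.int64)
    tmpNa = np.empty(K, dtype=np.int64)
    tmpNr = np.empty(K, dtype=np.int64)

    k_out = 0
    for it in range(n_iter):
        n_prop += C
        for c in range(C):
            # --- adult survival, year at a time ----------------------------
            # joint with a survivor/recruit transfer: delta ~ N_t * dphi birds
            # move between N_a and N_r so total N (hence the observation and
            # downstream terms) is untouched; the discretised-normal transfer
            # is corrected exactly in the Hastings ratio.  Without the
            # transfer the sharp binomial at large N pins phi to a ridge.
            for t in range(K):
                f0 = phi[c, t]
                z = math.log(f0 / (1.0 - f0)) + s_phi[t] * rng.standard_normal()
                f1 = min(max(1.0 / (1.0 + math.exp(-z)), 1e-12), 1.0 - 1e-12)
                nt = N[c, t]
                na0 = Na[c, t]
                nr0 = Nr[c, t]
                ndisc_corr = 0.0
                if rng.random() < 0.5:
                    # plain variant of the mixture (no bird transfer)
                    delta = 0
                else:
                    mu = nt * (f1 - f0)
                    sd1 = max(1.0, math.sqrt(nt * f1 * (1.0 - f1)))
                    sd0 = max(1.0, math.sqrt(nt * f0 * (1.0 - f0)))
                    delta = int(math.floor(mu + sd1 * rng.standard_normal() + 0.5))
                    if delta + na0 < 0 or delta + na0 > nt or nr0 - delta < 0:
                        continue
                    ndisc_corr = _ndisc_lp(-delta, -mu, sd0) - _ndisc_lp(delta, mu, sd1)
                na1 = na0 + delta
                nr1 = nr0 - delta
                phi[c, t] = f1
                new_cjs = _cjs_ll(phi, c, p[c], w, never, M, A) if has_cjs else 0.0
                cb = HALF * nt * F[c, t]
                d = (new_cjs - cur_cjs[c]
                     + _bin_lp(na1, nt, f1) - _bin_lp(na0, nt, f0)
                     + _marg_rec_lp(nr1, cb, rho_max) - _marg_rec_lp(nr0, cb, rho_max)
                     + math.log(f1 * (1.0 - f1)) - math.log(f0 * (1.0 - f0))
                     + ndisc_corr)
                if math.log(rng.random()) < d:
                    cur_cjs[c] = new_cjs
                    Na[c, t] = na1
                    Nr[c, t] = nr1
                    a_phi[t] += 1.0
                else:
                    phi[c, t] = f0

            # --- recapture probability -------------------------------------
            if has_cjs:
                p0 = p[c]
                z = math.log(p0 / (1.0 - p0)) + s_p * rng.standard_normal()
                p1 = min(max(1.0 / (1.0 + math.exp(-z)), 1e-12), 1.0 - 1e-12)
                new_cjs = _cjs_ll(phi, c, p1, w, never, M, A)
                d = (new_cjs - cur_cjs[c]
                     + math.log(p1 * (1.0 - p1)) - math.log(p0 * (1.0 - p0)))
                if math.log(rng.random()) < d:
                    p[c] = p1
                    cur_cjs[c] = new_cjs
                    a_p += 1.0

            # --- daily nest survival and brood rate ------------------------
            # each rate proposal carries a recruit-scaling step (see
            # _rate_move_terms), so productivity and next year's recruits
            # travel the flat recruitment ridge together
            for t in range(K):
                f0 = fe[c, t]
                z = math.log(f0 / (1.0 - f0)) + s_fe[t] * rng.standard_normal()
                f1 = min(max(1.0 / (1.0 + math.exp(-z)), 1e-12), 1.0 - 1e-12)
                ratio = (f1 / f0) ** ep
                ok, dnr, extra = _rate_move_terms(
                    rng, ratio, t, c, Nr, Na, N, F, phi,
                    obs_mask, logy, sigma[c], rho_max, T)
                if ok:
                    d = (egg_s[t] * (math.log(f1) - math.log(f0))
                         + egg_f[t] * (math.log1p(-f1) - math.log1p(-f0))
                         + extra
                         + math.log(f1 * (1.0 - f1)) - math.log(f0 * (1.0 - f0)))
                    if math.log(rng.random()) < d:
                        fe[c, t] = f1
                        F[c, t] *= ratio
                        Nr[c, t] += dnr
                        N[c, t + 1] += dnr
                        a_fe[t] += 1.0

                f0 = fc[c, t]
                z = math.log(f0 / (1.0 - f0)) + s_fc[t] * rng.standard_normal()
                f1 = min(max(1.0 / (1.0 + math.exp(-z)), 1e-12), 1.0 - 1e-12)
                ratio = (f1 / f0) ** yp
                ok, dnr, extra = _rate_move_terms(
                    rng, ratio, t, c, Nr, Na, N, F, phi,
                    obs_mask, logy, sigma[c], rho_max, T)
                if ok:
                    d = (chick_s[t] * (math.log(f1) - math.log(f0))
                         + chick_f[t] * (math.log1p(-f1) - math.log1p(-f0))
                         + extra
                         + math.log(f1 * (1.0 - f1)) - math.log(f0 * (1.0 - f0)))
                    if math.log(rng.random()) < d:
                        fc[c, t] = f1
                        F[c, t] *= ratio
                        Nr[c, t] += dnr
                        N[c, t + 1] += dnr
                        a_fc[t] += 1.0

                b0 = B[c, t]
                b1 = b0 * math.exp(s_B[t] * rng.standard_normal())
                if b1 >= brood_max:
                    continue
                dlog = math.log(b1) - math.log(b0)
                ratio = b1 / b0
                ok, dnr, extra = _rate_move_terms(
                    rng, ratio, t, c, Nr, Na, N, F, phi,
                    obs_mask, logy, sigma[c], rho_max, T)
                if ok:
                    d = (sum_brood[t] * dlog - n_brood[t] * (b1 - b0)
                         - n_brood[t] * (math.log(-math.expm1(-b1))
                                         - math.log(-math.expm1(-b0)))
                         + extra
                         + dlog)
                    if math.log(rng.random()) < d:
                        B[c, t] = b1
                        F[c, t] *= ratio
                        Nr[c, t] += dnr
                        N[c, t + 1] += dnr
                        a_B[t] += 1.0

        # --- latent states and sigma: several sweeps -----------------------
        # the random-walk moves (0, 1) run every sweep; the independence
        # refreshes (2, 3) are ridge-breakers and run once per iteration
        for _s in range(n_sweeps):
            n_moves = 4 if _s == 0 else 2
            for c in range(C):
                sg2 = sigma[c] * sigma[c]
                for j in range(1, T):
                    t = j - 1
                    nprev = N[c, j - 1]
                    ph = phi[c, t]
                    c1 = HALF * nprev * F[c, t]
                    for move in range(n_moves):
                        na0 = Na[c, t]
                        nr0 = Nr[c, t]
                        n0 = na0 + nr0
                        qcorr = 0.0
                        if move == 0:
                            step = int(math.floor(s_na[t] * rng.standard_normal() + 0.5))
                            na1 = na0 + step
                            nr1 = nr0
                        elif move == 1:
                            step = int(math.floor(s_nr[t] * rng.standard_normal() + 0.5))
                            na1 = na0
                            nr1 = nr0 + step
                        elif move == 3:
                            # recruit refresh: exact draw from the marginal
                            # recruitment pmf (rho' uniform, then Poisson),
                            # whose Hastings terms cancel the recruitment
                            # likelihood — acceptance is governed solely by
                            # the observation and downstream terms
                            rho_p = rho_max * rng.random()
                            nr1 = rng.poisson(c1 * rho_p)
                            na1 = na0
                            step = nr1 - nr0
                            qcorr = (_marg_rec_lp(nr0, c1, rho_max)
                                     - _marg_rec_lp(nr1, c1, rho_max))
                        else:
                            # survivor refresh: independence draw from the
                            # binomial's normal approximation, Hastings-
                            # corrected; jumps straight across the
                            # (phi, N_a) ridge when the year is unanchored
                            mu_a = nprev * ph
                            sd_a = max(1.0, math.sqrt(nprev * ph * (1.0 - ph)))
                            na1 = int(math.floor(mu_a + sd_a * rng.standard_normal() + 0.5))
                            nr1 = nr0
                            step = na1 - na0
                            qcorr = (_ndisc_lp(na0, mu_a, sd_a)
                                     - _ndisc_lp(na1, mu_a, sd_a))
                        if step == 0:
                            continue
                        if na1 < 0 or nr1 < 0 or na1 > nprev:
                            continue
                        n1 = na1 + nr1
                        d = (qcorr
                             + _bin_lp(na1, nprev, ph) - _bin_lp(na0, nprev, ph)
                             + _marg_rec_lp(nr1, c1, rho_max)
                             - _marg_rec_lp(nr0, c1, rho_max))
                        if obs_mask[j]:
                            if n1 == 0:
                                continue
                            r1 = logy[j] - math.log(n1)
                            r0 = logy[j] - math.log(n0)
                            d += -0.5 * (r1 * r1 - r0 * r0) / sg2
                        if j < T - 1:
                            phn = phi[c, j]
                            k2 = HALF * F[c, j]
                            d += (_bin_lp(Na[c, j], n1, phn) - _bin_lp(Na[c, j], n0, phn)
                                  + _marg_rec_lp(Nr[c, j], k2 * n1, rho_max)
                                  - _marg_rec_lp(Nr[c, j], k2 * n0, rho_max))
                        if math.log(rng.random()) < d:
                            Na[c, t] = na1
                            Nr[c, t] = nr1
                            N[c, j] = n1
                            if move == 0:
                                a_na[t] += 1.0 / n_sweeps
                            elif move == 1:
                                a_nr[t] += 1.0 / n_sweeps

                # tail shift: slide the whole trajectory from a random year
                # onward, recruits absorbing the initial step and adults
                # tracking it through each survival transition.  The cascade
                # steps are discretised normals whose centres flip sign and
                # scales are even in the previous step, so the proposal is
                # symmetric and the Hastings ratio is 1.
                j0 = 1 + int(rng.random() * (T - 1))
                if j0 > T - 1:
                    j0 = T - 1
                d0 = int(math.floor(s_tail * rng.standard_normal() + 0.5))
                if d0 != 0:
                    for jj in range(T):
                        tmpN[jj] = N[c, jj]
                    for tt in range(K):
                        tmpNa[tt] = Na[c, tt]
                        tmpNr[tt] = Nr[c, tt]
                    tmpNr[j0 - 1] += d0
                    tmpN[j0] += d0
                    ok = tmpNr[j0 - 1] >= 0
                    dprev = d0
                    if ok:
                        for k in range(j0 + 1, T):
                            center = phi[c, k - 1] * dprev
                            sd = max(1.0, math.sqrt(abs(center)))
                            dk = int(math.floor(center + sd * rng.standard_normal() + 0.5))
                            tmpNa[k - 1] += dk
                            tmpN[k] += dk
                            if tmpNa[k - 1] < 0:
                                ok = False
                                break
                            dprev = dk
                    if ok:
                        ll = 0.0
                        for k in range(j0, T):
                            tt = k - 1
                            ph = phi[c, tt]
                            ll += (_bin_lp(tmpNa[tt], tmpN[k - 1], ph)
                                   - _bin_lp(Na[c, tt], N[c, k - 1], ph)
                                   + _marg_rec_lp(tmpNr[tt], HALF * tmpN[k - 1] * F[c, tt], rho_max)
                                   - _marg_rec_lp(Nr[c, tt], HALF * N[c, k - 1] * F[c, tt], rho_max))
                            if obs_mask[k]:
                                if tmpN[k] <= 0:
                                    ll = -np.inf
                                    break
                                r1 = logy[k] - math.log(tmpN[k])
                                r0 = logy[k] - math.log(N[c, k])
                                ll += -0.5 * (r1 * r1 - r0 * r0) / sg2
                        if math.log(rng.random()) < ll:
                            for jj in range(j0, T):
                                N[c, jj] = tmpN[jj]
                            for tt in range(j0 - 1, K):
                                Na[c, tt] = tmpNa[tt]
                                Nr[c, tt] = tmpNr[tt]
                            a_tail += 1.0 / n_sweeps

                # observation s.d.: inverse-gamma independence proposal
                # matching the full conditional up to the half-normal prior
                if n_obs >= 3:
                    sse = 0.0
                    for j in range(T):
                        if obs_mask[j]:
                            r = logy[j] - math.log(N[c, j])
                            sse += r * r
                    alpha = 0.5 * (n_obs - 1.0)
                    x1 = 0.5 * sse / max(rng.standard_gamma(alpha), 1e-300)
                    x1 = max(x1, 1e-16)
                    x0 = sigma[c] * sigma[c]
                    if math.log(rng.random()) < -(x1 - x0) / (2.0 * sigma_prior * sigma_prior):
                        sigma[c] = math.sqrt(x1)

        # --- adaptation during burn-in -------------------------------------
        if it < n_burnin and (it + 1) % _ADAPT_EVERY == 0:
            for t in range(K):
                s_phi[t] = min(max(s_phi[t] * math.exp(a_phi[t] / n_prop - _TARGET), 1e-3), 50.0)
                s_fe[t] = min(max(s_fe[t] * math.exp(a_fe[t] / n_prop - _TARGET), 1e-3), 50.0)
                s_fc[t] = min(max(s_fc[t] * math.exp(a_fc[t] / n_prop - _TARGET), 1e-3), 50.0)
                s_B[t] = min(max(s_B[t] * math.exp(a_B[t] / n_prop - _TARGET), 1e-3), 50.0)
                s_na[t] = min(max(s_na[t] * math.exp(a_na[t] / n_prop - _TARGET), 1.0), 1e5)
                s_nr[t] = min(max(s_nr[t] * math.exp(a_nr[t] / n_prop - _TARGET), 1.0), 1e5)
                a_phi[t] = 0.0
                a_fe[t] = 0.0
                a_fc[t] = 0.0
                a_B[t] = 0.0
                a_na[t] = 0.0
                a_nr[t] = 0.0
            s_p = min(max(s_p * math.exp(a_p / n_prop - _TARGET), 1e-3), 50.0)
            s_tail = min(max(s_tail * math.exp(a_tail / n_prop - 0.25), 1.0), 1e5)
            a_p = 0.0
            a_tail = 0.0
            n_prop = 0.0

        # --- record (rho drawn from its exact full conditional) ------------
        if it >= n_burnin and (it - n_burnin) % thin == thin - 1:
            for c in range(C):
                for t in range(K):
                    out_phi[c, k_out, t] = phi[c, t]
                    out_fe[c, k_out, t] = fe[c, t]
                    out_fc[c, k_out, t] = fc[c, t]
                    out_B[c, k_out, t] = B[c, t]
                    out_Na[c, k_out, t] = Na[c, t]
                    out_Nr[c, k_out, t] = Nr[c, t]
                    cbase = HALF * N[c, t] * F[c, t]
                    if cbase > 0.0:
                        out_rho[c, k_out, t] = _trunc_gamma(rng, Nr[c, t] + 1.0,
                                                            cbase, rho_max)
                    else:
                        out_rho[c, k_out, t] = max(rho_max * rng.random(), 1e-12)
                for j in range(T):
                    out_N[c, k_out, j] = N[c, j]
                out_sigma[c, k_out] = sigma[c]
                out_p[c, k_out] = p[c]
            k_out += 1


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class MwGSampler:
    def __init__(self, data: ObservedData, priors: PriorSpec, n_chains: int,
                 ep: int, yp: int, initial_n: int, n_sweeps: int = 10):
        self.C = n_chains
        self.T = data.n_years
        self.K = self.T - 1
        self.ep, self.yp = ep, yp
        self.N0 = int(initial_n)
        self.priors = priors
        self.n_sweeps = n_sweeps
        self.obs_mask = np.isfinite(data.counts)
        self.logy = np.where(self.obs_mask,
                             np.log(np.where(self.obs_mask, data.counts, 1.0)), 0.0)
        self.n_obs = int(self.obs_mask.sum())
        ss = nest_sufficient_stats(data.nests, data.years[:-1])
        self.egg_s, self.egg_f = ss["egg_surv"], ss["egg_fail"]
        self.chick_s, self.chick_f = ss["chick_surv"], ss["chick_fail"]
        self.n_brood, self.sum_brood = ss["n_brood"], ss["sum_brood"]
        self.has_cjs = len(data.histories) > 0
        if self.has_cjs:
            self.marr = build_m_array(data.histories)
            if self.marr["T"] != self.T:
                raise ValueError("capture histories must span the study years")
        else:
            self.marr = {"w": np.zeros(self.K), "never": np.zeros(self.K, dtype=np.int64),
                         "M": 0, "A": 0}
        self.counts = data.counts

    # -- state initialisation -------------------------------------------

    def init_state(self, rng: np.random.Generator):
        """Crude data-based starting values with chain-specific jitter.

        Aggregate Mayfield ratios for the daily nest survivals, the mean
        observed brood for the brood rate, the m-array return rate for
        recapture; latent N starts at the observed counts (log-scale
        interpolation across missing years) with the first year pinned
        at the configured initial size.
        """
        C, K = self.C, self.K
        pr = self.priors

        def logit(x):
            return np.log(x / (1 - x))

        def expit(z):
            return 1.0 / (1.0 + np.exp(-z))

        egg_tot = self.egg_s.sum() + self.egg_f.sum()
        fe0 = np.clip(self.egg_s.sum() / egg_tot, 0.6, 0.995) if egg_tot else 0.9
        chick_tot = self.chick_s.sum() + self.chick_f.sum()
        fc0 = np.clip(self.chick_s.sum() / chick_tot, 0.6, 0.995) if chick_tot else 0.9
        nb = self.n_brood.sum()
        B0 = np.clip(self.sum_brood.sum() / nb, 1.0, pr.brood_max - 0.5) if nb else pr.brood_max / 2
        if self.has_cjs and self.marr["R"].sum() > 0:
            ret = self.marr["M"] / max(1, self.marr["R"].sum())
            p0 = float(np.clip(2.0 * ret, 0.05, 0.95))
        else:
            p0 = 0.5

        def jit(x, s):
            return x + s * rng.standard_normal((C, K))

        st = {}
        st["phi"] = expit(jit(logit(0.5), 0.15))
        st["fe"] = expit(jit(logit(fe0), 0.15))
        st["fc"] = expit(jit(logit(fc0), 0.15))
        st["B"] = np.clip(np.exp(jit(np.log(B0), 0.05)), 0.1, pr.brood_max - 1e-3)
        st["p"] = expit(logit(p0) + 0.15 * rng.standard_normal(C))
        st["sigma"] = np.exp(np.log(0.1) + 0.2 * rng.standard_normal(C))

        n_fill = np.maximum(np.round(_interp_log_counts(self.counts)), 1).astype(np.int64)
        N = np.tile(n_fill, (C, 1))
        N[:, 0] = self.N0
        Na = np.minimum(np.round(st["phi"] * N[:, :-1]),
                        np.minimum(N[:, :-1], N[:, 1:])).astype(np.int64)
        Na = np.maximum(Na, 0)
        Nr = N[:, 1:] - Na
        st["N"], st["Na"], st["Nr"] = N, Na, Nr
        return st

    # -- initial-state validation ----------------------------------------

    def _check_initial(self, st):
        comps = {
            "cjs": (cjs_marray_loglik(st["phi"], st["p"], self.marr)
                    if self.has_cjs else np.zeros(self.C)),
            "nest": ((self.egg_s * np.log(st["fe"]) + self.egg_f * np.log1p(-st["fe"])).sum(-1)
                     + (self.chick_s * np.log(st["fc"])
                        + self.chick_f * np.log1p(-st["fc"])).sum(-1)),
            "brood": (self.sum_brood * np.log(st["B"]) - self.n_brood * st["B"]
                      - self.n_brood * np.log(-np.expm1(-st["B"]))).sum(-1),
            "survival-process": self._bin_ll(st),
            "recruitment-process": self._rec_ll(st),
            "observation": self._obs_ll(st),
        }
        for name, v in comps.items():
            if not np.all(np.isfinite(v)):
                raise RuntimeError(
                    f"non-finite log posterior at initialization in the {name} component")

    def _bin_ll(self, st):
        from scipy.special import gammaln
        N, Na, phi = st["N"], st["Na"], st["phi"]
        Np = N[:, :-1]
        return (gammaln(Np + 1) - gammaln(Na + 1) - gammaln(Np - Na + 1)
                + Na * np.log(phi) + (Np - Na) * np.log1p(-phi)).sum(-1)

    def _rec_ll(self, st):
        from scipy.special import gammainc
        F = st["B"] * st["fe"] ** self.ep * st["fc"] ** self.yp
        z = self.priors.rho_max * HALF * st["N"][:, :-1] * F
        Nr = st["Nr"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(z > 0, np.log(gammainc(Nr + 1, z)) - np.log(z),
                          np.where(Nr == 0, 0.0, -np.inf))
        return ll.sum(-1)

    def _obs_ll(self, st):
        N = st["N"]
        logN = np.log(np.maximum(N, 1))
        dev = np.where(self.obs_mask, (self.logy - logN), 0.0)
        bad = self.obs_mask & (N == 0)
        out = -self.n_obs * np.log(st["sigma"]) - 0.5 * (dev ** 2).sum(-1) / st["sigma"] ** 2
        return np.where(bad.any(-1), -np.inf, out)

    # -- run -------------------------------------------------------------

    def run(self, rng: np.random.Generator, n_iter: int, n_burnin: int, thin: int):
        C, K, T = self.C, self.K, self.T
        st = self.init_state(rng)
        self._check_initial(st)
        keep = (n_iter - n_burnin) // thin
        out = {
            "phi": np.empty((C, keep, K)), "fe": np.empty((C, keep, K)),
            "fc": np.empty((C, keep, K)), "B": np.empty((C, keep, K)),
            "rho": np.empty((C, keep, K)), "N": np.empty((C, keep, T)),
            "Na": np.empty((C, keep, K)), "Nr": np.empty((C, keep, K)),
            "sigma": np.empty((C, keep)), "p": np.empty((C, keep)),
        }
        _run_kernel(
            rng, n_iter, n_burnin, thin, self.n_sweeps,
            self.logy, self.obs_mask, self.egg_s, self.egg_f,
            self.chick_s, self.chick_f, self.n_brood, self.sum_brood,
            np.asarray(self.marr["w"], dtype=np.float64),
            np.asarray(self.marr["never"], dtype=np.float64),
            float(self.marr["M"]), float(self.marr["A"]), self.has_cjs,
            self.ep, self.yp, self.priors.brood_max, self.priors.rho_max,
            self.priors.sigma_scale,
            st["phi"], st["p"], st["fe"], st["fc"], st["B"],
            st["sigma"], st["Na"], st["Nr"], st["N"],
            out["phi"], out["fe"], out["fc"], out["B"], out["rho"],
            out["N"], out["Na"], out["Nr"], out["sigma"], out["p"],
        )
        return out
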