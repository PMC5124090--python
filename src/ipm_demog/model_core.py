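"""Demographic process model, observation model and component likelihoods.

The population model is a female-only state-space model for an annual
breeding passerine.  The number of females in year ``t`` splits into
adults surviving from year ``t-1`` and first-year recruits::

    N_t = N_a,t + N_r,t
    N_a,t ~ Binomial(N_{t-1}, phi_ad,t-1)
    N_r,t ~ Poisson(N_{t-1} * 0.5 * FPBA_{t-1} * rho_{t-1})

where ``FPBA`` (fledglings per breeding attempt) decomposes productivity
into brood size and daily nest survival at the egg and chick stages,

    FPBA = B * phi_egg^ep * phi_chick^yp,

``0.5`` is the female fraction of fledglings, and ``rho`` is a recruitment
scaling factor absorbing unmeasured processes (first-year survival,
dispersal, multiple brooding, the non-breeding fraction).  Observed count
indices are log-normal around the latent population,

    log y_t ~ Normal(log N_t, sigma_obs).

Adult survival is informed by Cormack-Jolly-Seber (CJS) mark-recapture
histories from constant-effort sites; egg- and chick-stage daily survival
by Mayfield-type exposure days from nest records; brood size by a
zero-truncated Poisson on brood counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

FEMALE_FRACTION = 0.5
DEFAULT_EGG_DAYS = 13
DEFAULT_CHICK_DAYS = 13
DEFAULT_N0 = 1000

NEST_COLUMNS = [
    "region", "year", "brood",
    "egg_days", "egg_survived", "chick_days", "chick_survived",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DemographicParams:
    """Per-region demographic rates.

    Yearly vectors are indexed by *transition* (interval t -> t+1, equally
    the breeding season of year t); with T count years there are T-1
    transitions.  ``phi_egg_daily`` / ``phi_chick_daily`` are daily nest
    survival probabilities; the corresponding whole-stage survivals are
    ``phi_egg_daily**ep`` and ``phi_chick_daily**yp``.
    """

    phi_ad: np.ndarray
    brood_size: np.ndarray
    phi_egg_daily: np.ndarray
    phi_chick_daily: np.ndarray
    rho: np.ndarray
    sigma_obs: float
    p_recapture: float
    ep: int = DEFAULT_EGG_DAYS
    yp: int = DEFAULT_CHICK_DAYS

    def __post_init__(self):
        for name in ("phi_ad", "brood_size", "phi_egg_daily", "phi_chick_daily", "rho"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.phi_ad)
        for name in ("brood_size", "phi_egg_daily", "phi_chick_daily", "rho"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have the same length as phi_ad ({k})")
        for name in ("phi_ad", "phi_egg_daily", "phi_chick_daily"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.p_recapture <= 1:
            raise ValueError("p_recapture must lie in [0, 1]")
        if np.any(self.brood_size < 0) or np.any(self.rho < 0):
            raise ValueError("brood_size and rho must be non-negative")
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be non-negative")
        if self.ep < 1 or self.yp < 1:
            raise ValueError("ep and yp must be >= 1")

    @property
    def n_transitions(self) -> int:
        return len(self.phi_ad)

    @property
    def fpba(self) -> np.ndarray:
        """Fledglings per breeding attempt, per transition year."""
        return productivity_fpba(
            self.brood_size, self.phi_egg_daily, self.phi_chick_daily, self.ep, self.yp
        )


@dataclass
class LatentTrajectory:
    """True female population split into survivors and recruits.

    ``N`` has length T; ``N_a``/``N_r`` have length T-1 and refer to years
    2..T (the composition of year 1 is not defined by the model).
    """

    N: np.ndarray
    N_a: np.ndarray
    N_r: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=int)
        self.N_a = np.asarray(self.N_a, dtype=int)
        self.N_r = np.asarray(self.N_r, dtype=int)
        if len(self.N_a) != len(self.N) - 1 or len(self.N_r) != len(self.N) - 1:
            raise ValueError("N_a and N_r must have length len(N) - 1")
        if np.any(self.N < 0) or np.any(self.N_a < 0) or np.any(self.N_r < 0):
            raise ValueError("population sizes must be non-negative")
        if np.any(self.N[1:] != self.N_a + self.N_r):
            raise ValueError("N_t must equal N_a,t + N_r,t")

    @property
    def lam(self) -> np.ndarray:
        """Annual growth rates lambda_t = N_t / N_{t-1}."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.N[1:] / self.N[:-1].astype(float)


@dataclass
class NestRecord:
    """One nest: brood count plus exposure days and fate per stage.

    Exposure days count every observed day at risk *including* the failure
    day for a failed stage; a stage that failed therefore has >= 1 exposure
    day.  ``chick_days`` is 0 when the nest failed at the egg stage, and
    ``brood`` is only meaningful (>= 1) once the chick stage was entered.
    """

    region: str
    year: int
    brood: int
    egg_days: int
    egg_survived: bool
    chick_days: int
    chick_survived: bool

    def __post_init__(self):
        if self.egg_days < 0 or self.chick_days < 0:
            raise ValueError("exposure days must be non-negative")
        if not self.egg_survived and self.chick_days != 0:
            raise ValueError("chick_days must be 0 when the egg stage failed")
        if not self.egg_survived and self.egg_days < 1:
            raise ValueError("a failed egg stage implies >= 1 exposure day")
        if self.egg_survived and not self.chick_survived and self.chick_days < 1:
            raise ValueError("a failed chick stage implies >= 1 exposure day")
        if self.egg_survived and self.brood < 1:
            raise ValueError("brood must be >= 1 when the chick stage is entered")


def nests_to_frame(records: Iterable[NestRecord]) -> pd.DataFrame:
    rows = [
        (r.region, r.year, r.brood, r.egg_days, int(r.egg_survived),
         r.chick_days, int(r.chick_survived))
        for r in records
    ]
    return pd.DataFrame(rows, columns=NEST_COLUMNS)


@dataclass
class CaptureHistory:
    """One individual's encounter history across study occasions."""

    region: str
    first_occasion: int
    encounters: np.ndarray

    def __post_init__(self):
        self.encounters = np.asarray(self.encounters, dtype=np.int8)
        if self.encounters[self.first_occasion] != 1:
            raise ValueError("entry at first_occasion must be 1")
        if np.any(self.encounters[: self.first_occasion] != 0):
            raise ValueError("no encounters allowed before first_occasion")


@dataclass
class CaptureHistorySet:
    """Column-stacked capture histories for one region.

    ``enc`` is an (n_individuals, n_occasions) 0/1 matrix; ``first`` holds
    each individual's release occasion.
    """

    first: np.ndarray
    enc: np.ndarray
    region: str = ""

    def __post_init__(self):
        self.first = np.asarray(self.first, dtype=int)
        self.enc = np.asarray(self.enc, dtype=np.int8)
        if self.enc.ndim != 2 or len(self.first) != self.enc.shape[0]:
            raise ValueError("first and enc shapes are inconsistent")
        n = self.enc.shape[0]
        if n and np.any(self.enc[np.arange(n), self.first] != 1):
            raise ValueError("every history must be 1 at its first occasion")

    @classmethod
    def from_histories(cls, histories: Sequence[CaptureHistory]) -> "CaptureHistorySet":
        enc = np.stack([h.encounters for h in histories])
        first = np.array([h.first_occasion for h in histories])
        region = histories[0].region if histories else ""
        return cls(first=first, enc=enc, region=region)

    @classmethod
    def from_strings(cls, strings: Sequence[str], region: str = "") -> "CaptureHistorySet":
        enc = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
        first = np.argmax(enc == 1, axis=1)
        return cls(first=first, enc=enc, region=region)

    @property
    def n_occasions(self) -> int:
        return self.enc.shape[1]

    def __len__(self) -> int:
        return self.enc.shape[0]


@dataclass
class ObservedData:
    """The three observation streams for one region.

    ``counts`` is a length-T float vector with NaN flagging missing survey
    years (never zero-filled); ``nests`` is a DataFrame in the nest CSV
    dialect; ``histories`` a :class:`CaptureHistorySet` over T occasions.
    """

    counts: np.ndarray
    nests: pd.DataFrame
    histories: CaptureHistorySet
    years: np.ndarray
    region: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if len(self.counts) != len(self.years):
            raise ValueError("counts and years must have equal length")
        if not np.any(np.isfinite(self.counts)):
            raise ValueError("at least one count must be observed")
        obs = self.counts[np.isfinite(self.counts)]
        if np.any(obs <= 0):
            raise ValueError("observed counts must be positive")
        if self.histories is not None and len(self.histories) and \
                self.histories.n_occasions != len(self.years):
            raise ValueError("capture histories must span the study years")
        missing = set(NEST_COLUMNS[1:]) - set(self.nests.columns)
        if missing:
            raise ValueError(f"nest table is missing columns: {sorted(missing)}")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.counts)


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------

def productivity_fpba(brood_size, phi_egg_daily, phi_chick_daily,
                      ep: int = DEFAULT_EGG_DAYS, yp: int = DEFAULT_CHICK_DAYS):
    """Fledglings per breeding attempt: B * phi_egg^ep * phi_chick^yp."""
    brood_size = np.asarray(brood_size, dtype=float)
    phi_egg_daily = np.asarray(phi_egg_daily, dtype=float)
    phi_chick_daily = np.asarray(phi_chick_daily, dtype=float)
    if np.any(brood_size < 0):
        raise ValueError("brood_size must be non-negative")
    for name, v in (("phi_egg_daily", phi_egg_daily), ("phi_chick_daily", phi_chick_daily)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    if ep < 0 or yp < 0:
        raise ValueError("exposure periods must be non-negative")
    out = brood_size * phi_egg_daily ** ep * phi_chick_daily ** yp
    return out if out.ndim else float(out)

def step_population(n_prev, phi_ad, fpba, rho, rng: np.random.Generator):
    """One stochastic transition: binomial adult survival, Poisson recruitment.

    Returns ``(n_a, n_r)`` with ``n_a ~ Binomial(n_prev, phi_ad)`` and
    ``n_r ~ Poisson(n_prev * 0.5 * fpba * rho)`` (female recruits only).
    Accepts scalars or broadcastable arrays.
    """
    n_prev = np.asarray(n_prev)
    if np.any(n_prev < 0):
        raise ValueError("n_prev must be non-negative")
    if np.any((np.asarray(phi_ad) < 0) | (np.asarray(phi_ad) > 1)):
        raise ValueError("phi_ad must lie in [0, 1]")
    if np.any(np.asarray(fpba) < 0) or np.any(np.asarray(rho) < 0):
        raise ValueError("fpba and rho must be non-negative")
    n_a = rng.binomial(n_prev, phi_ad)
    n_r = rng.poisson(n_prev * FEMALE_FRACTION * np.asarray(fpba) * np.asarray(rho))
    return n_a, n_r


def observation_loglik(y, n, sigma_obs: float):
    """Log-normal log density of the observed index given latent abundance.

    Missing observations (NaN) contribute 0; an observed count with a zero
    latent population has no support (-inf).  Vectorised over years.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be non-negative")
    y_b, n_b = np.broadcast_arrays(y, n)
    out = np.zeros(y_b.shape)
    obs = np.isfinite(y_b)
    bad = obs & (n_b < 1)
    ok = obs & ~bad
    out[bad] = -np.inf
    out[ok] = stats.lognorm.logpdf(y_b[ok], s=sigma_obs, scale=n_b[ok])
    return float(np.sum(out))


# --- CJS ----------------------------------------------------------------

def build_m_array(histories: CaptureHistorySet):
    """Reduce capture histories to m-array sufficient statistics.

    Returns a dict with releases ``R[i]`` (every capture at occasion
    i < T-1 is a release), first-recapture counts ``m[i, j]`` and
    never-seen-again counts; plus the aggregates used by the closed-form
    likelihood: total recaptures ``M``, total skipped occasions ``A`` and
    per-interval recapture-path weights ``w``.
    """
    T = histories.n_occasions
    R = np.zeros(T - 1, dtype=int)
    m = np.zeros((T - 1, T), dtype=int)
    for first, enc in zip(histories.first, histories.enc):
        if enc[first] != 1:
            raise ValueError("history must begin with an encounter")
        occ = np.flatnonzero(enc)
        for a, b in zip(occ[:-1], occ[1:]):
            R[a] += 1
            m[a, b] += 1
        if occ[-1] < T - 1:
            R[occ[-1]] += 1
    never = R - m.sum(axis=1)
    ii, jj = np.nonzero(m)
    M = int(m.sum())
    A = int((m[ii, jj] * (jj - ii - 1)).sum())
    w = np.zeros(T - 1)
    for i, j in zip(ii, jj):
        w[i:j] += m[i, j]
    return {"R": R, "m": m, "never": never, "M": M, "A": A, "w": w, "T": T}


def cjs_marray_loglik(phi, p, marr) -> np.ndarray:
    """CJS log likelihood from m-array statistics.

    ``phi`` has shape (..., T-1); ``p`` broadcasts over the leading axes.
    The never-seen-again term uses chi_i = (1-phi_i) + phi_i (1-p) chi_{i+1}
    evaluated in closed form via cumulative products.
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    lead = phi.shape[:-1]
    K = phi.shape[-1]
    p_col = p[..., None] if p.ndim < phi.ndim else p
    a = phi * (1.0 - p_col)
    P = np.cumprod(a, axis=-1)
    P = np.concatenate([np.ones(lead + (1,)), P], axis=-1)      # P[..., i] = prod_{k<i} a_k
    s = P[..., :-1] * (1.0 - phi)
    S = np.flip(np.cumsum(np.flip(s, -1), -1), -1)              # sum_{j>=i} s_j
    chi = (S + P[..., -1:]) / P[..., :-1]
    with np.errstate(divide="ignore"):
        ll = (
            marr["M"] * np.log(p_col[..., 0])
            + marr["A"] * np.log1p(-p_col[..., 0])
            + np.log(phi) @ marr["w"]
            + np.log(chi) @ marr["never"]
        )
    return ll


def cjs_loglik(histories: CaptureHistorySet | Sequence[CaptureHistory],
               phi_ad, p_recapture) -> float:
    """CJS log likelihood of capture histories, conditioning on first release.

    ``phi_ad`` holds per-interval survival probabilities (length
    n_occasions - 1); ``p_recapture`` is the constant per-occasion
    recapture probability.
    """
    if not isinstance(histories, CaptureHistorySet):
        histories = CaptureHistorySet.from_histories(list(histories))
    phi_ad = np.asarray(phi_ad, dtype=float)
    if len(phi_ad) != histories.n_occasions - 1:
        raise ValueError("phi_ad must have length n_occasions - 1")
    marr = build_m_array(histories)
    return float(cjs_marray_loglik(phi_ad, np.asarray(float(p_recapture)), marr))


# --- nests --------------------------------------------------------------

def nest_sufficient_stats(nests: pd.DataFrame, seasons: Sequence[int]):
    """Per-season exposure-day and brood sufficient statistics.

    Returns arrays aligned with ``seasons``: survived exposure days and
    failure days per stage, plus brood counts (number and sum) for nests
    that reached the chick stage.
    """
    K = len(seasons)
    idx = {int(y): t for t, y in enumerate(seasons)}
    out = {k: np.zeros(K) for k in
           ("egg_surv", "egg_fail", "chick_surv", "chick_fail", "n_brood", "sum_brood")}
    if len(nests) == 0:
        return out
    years = nests["year"].astype(int).to_numpy()
    unknown = [y for y in np.unique(years) if y not in idx]
    if unknown:
        raise ValueError(f"nest records outside the study seasons: {unknown}")
    ti = np.array([idx[y] for y in years])
    egg_days = nests["egg_days"].to_numpy(dtype=float)
    egg_ok = nests["egg_survived"].to_numpy(dtype=bool)
    chick_days = nests["chick_days"].to_numpy(dtype=float)
    chick_ok = nests["chick_survived"].to_numpy(dtype=bool)
    if np.any(egg_days < 0) or np.any(chick_days < 0):
        raise ValueError("exposure days must be non-negative")
    if np.any(~egg_ok & (egg_days < 1)):
        raise ValueError("failed egg stage requires >= 1 exposure day")
    if np.any(egg_ok & ~chick_ok & (chick_days < 1)):
        raise ValueError("failed chick stage requires >= 1 exposure day")
    np.add.at(out["egg_surv"], ti, np.where(egg_ok, egg_days, egg_days - 1))
    np.add.at(out["egg_fail"], ti, (~egg_ok).astype(float))
    np.add.at(out["chick_surv"], ti,
              np.where(egg_ok, np.where(chick_ok, chick_days, chick_days - 1), 0.0))
    np.add.at(out["chick_fail"], ti, (egg_ok & ~chick_ok).astype(float))
    hatched = egg_ok
    brood = nests["brood"].to_numpy(dtype=float)
    if np.any(hatched & (brood != np.round(brood))):
        raise ValueError("brood counts must be integers")
    if np.any(hatched & (brood < 1)):
        raise ValueError("brood must be >= 1 for nests entering the chick stage")
    np.add.at(out["n_brood"], ti, hatched.astype(float))
    np.add.at(out["sum_brood"], ti, np.where(hatched, brood, 0.0))
    return out


def _bernoulli_days_loglik(surv_days, fail_days, phi):
    phi = np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = surv_days * np.log(phi) + fail_days * np.log1p(-phi)
    # 0 * log(0) = 0 by convention (no exposure at a degenerate rate)
    term = np.where((surv_days == 0) & (phi == 0), fail_days * np.log1p(-phi), term)
    term = np.where((fail_days == 0) & (phi == 1), surv_days * np.log(phi), term)
    return term


def nest_loglik(nests: pd.DataFrame | Sequence[NestRecord],
                phi_egg_daily, phi_chick_daily, seasons: Sequence[int]) -> float:
    """Mayfield exposure-day log likelihood of nest records.

    Every survived day at a stage contributes ``log(phi)``, a failure
    contributes one ``log(1 - phi)`` day at the stage of failure.
    ``phi_egg_daily``/``phi_chick_daily`` are per-season vectors aligned
    with ``seasons``.
    """
    if not isinstance(nests, pd.DataFrame):
        nests = nests_to_frame(list(nests))
    ss = nest_sufficient_stats(nests, seasons)
    e = _bernoulli_days_loglik(ss["egg_surv"], ss["egg_fail"], phi_egg_daily)
    c = _bernoulli_days_loglik(ss["chick_surv"], ss["chick_fail"], phi_chick_daily)
    return float(np.sum(e) + np.sum(c))


def ztpoisson_logpmf(k, mu):
    """Zero-truncated Poisson log pmf (support k >= 1)."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore"):
        out = k * np.log(mu) - mu - np.log(-np.expm1(-mu)) - gammaln(k + 1)
    return np.where(k >= 1, out, -np.inf)


def brood_loglik(nests: pd.DataFrame | Sequence[NestRecord],
                 brood_mean, seasons: Sequence[int]) -> float:
    """Zero-truncated Poisson log likelihood of observed brood counts.

    ``brood_mean`` is the per-season underlying Poisson rate; only nests
    that reached the chick stage contribute a brood count.
    """
    if not isinstance(nests, pd.DataFrame):
        nests = nests_to_frame(list(nests))
    if len(nests) == 0:
        return 0.0
    hatched = nests[nests["egg_survived"].astype(bool)]
    if len(hatched) == 0:
        return 0.0
    brood = hatched["brood"].to_numpy(dtype=float)
    if np.any(brood != np.round(brood)):
        raise ValueError("brood counts must be integers")
    idx = {int(y): t for t, y in enumerate(seasons)}
    ti = np.array([idx[int(y)] for y in hatched["year"]])
    mu = np.asarray(brood_mean, dtype=float)[ti]
    return float(ztpoisson_logpmf(brood, mu).sum())


# --- process and joint density ------------------------------------------

def binom_logpmf(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
               + k * np.log(p) + (n - k) * np.log1p(-p))
        out = np.where((k == 0) & (p == 0), 0.0 * n, out)
        out = np.where((k == n) & (p == 1), 0.0 * n, out)
    return np.where((k < 0) | (k > n), -np.inf, out)


def poisson_logpmf(k, mu):
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(mu) - mu - gammaln(k + 1)
    out = np.where((mu == 0), np.where(k == 0, 0.0, -np.inf), out)
    return np.where(k < 0, -np.inf, out)


def latent_process_loglik(latent: LatentTrajectory, params: DemographicParams) -> float:
    """Log density of the latent survivor/recruit path given the rates."""
    N_prev = latent.N[:-1]
    fpba = params.fpba
    b = binom_logpmf(latent.N_a, N_prev, params.phi_ad)
    mu = N_prev * FEMALE_FRACTION * fpba * params.rho
    p = poisson_logpmf(latent.N_r, mu)
    return float(np.sum(b) + np.sum(p))


@dataclass
class PriorSpec:
    """Uninformative prior specification.

    Uniform(0,1) on every probability (daily nest survival on the daily
    probability scale), Uniform(0, brood_max) on brood means,
    Uniform(0, rho_max) on rho, half-Normal(0, sigma_scale) on sigma_obs.
    """

    brood_max: float = 10.0
    rho_max: float = 5.0
    sigma_scale: float = 1.0

    def logpdf(self, params: DemographicParams) -> float:
        for v in (params.phi_ad, params.phi_egg_daily, params.phi_chick_daily):
            if np.any((v <= 0) | (v >= 1)):
                return -np.inf
        if not 0 < params.p_recapture < 1:
            return -np.inf
        if np.any((params.brood_size <= 0) | (params.brood_size >= self.brood_max)):
            return -np.inf
        if np.any((params.rho <= 0) | (params.rho >= self.rho_max)):
            return -np.inf
        if params.sigma_obs <= 0:
            return -np.inf
        lp = -np.log(self.brood_max) * params.n_transitions
        lp += -np.log(self.rho_max) * params.n_transitions
        lp += float(stats.halfnorm.logpdf(params.sigma_obs, scale=self.sigma_scale))
        return lp


def joint_loglik(data: ObservedData, params: DemographicParams,
                 latent: LatentTrajectory, priors: PriorSpec | None = None) -> float:
    """Log posterior kernel: data likelihoods + process density + priors."""
    if len(latent.N) != data.n_years:
        raise ValueError("latent trajectory length must match the study years")
    if params.n_transitions != data.n_years - 1:
        raise ValueError("params must cover n_years - 1 transitions")
    priors = priors or PriorSpec()
    lp = priors.logpdf(params)
    if not np.isfinite(lp):
        return -np.inf
    seasons = data.years[:-1]
    ll = observation_loglik(data.counts, latent.N, params.sigma_obs)
    ll += latent_process_loglik(latent, params)
    if len(data.histories):
        ll += cjs_loglik(data.histories, params.phi_ad, params.p_recapture)
    ll += nest_loglik(data.nests, params.phi_egg_daily, params.phi_chick_daily, seasons)
    ll += brood_loglik(data.nests, params.brood_size, seasons)
    return float(ll + lp)
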