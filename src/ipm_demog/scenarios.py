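"""Growth-rate surfaces and counterfactual rate-substitution trajectories.

Two what-if analyses over fitted posteriors:

* :func:`growth_surface` maps expected annual growth
  ``lambda = phi_ad + 0.5 * FPBA * rho_bar`` over the observed
  (survival x productivity) space, holding the recruitment scaling at its
  grand posterior mean across regions and years, with an optional
  stochastic (simulated) mode.
* :func:`substitute_trajectory` re-projects one region's population index
  from a chosen year onward with a single demographic rate (survival or
  productivity) swapped in from a donor region, per paired posterior
  draw, assuming no density-dependent response in the other rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .inference import PosteriorDraws
from .model_core import FEMALE_FRACTION
from .posterior import _pair_draws


@dataclass
class GrowthSurface:
    """Expected (or simulated) growth over the demographic parameter space."""

    phi_grid: np.ndarray
    fpba_grid: np.ndarray
    lambda_surface: np.ndarray
    rho_fixed: float
    points: pd.DataFrame | None = None
    mode: str = "expected"

    def __post_init__(self):
        if self.lambda_surface.shape != (len(self.phi_grid), len(self.fpba_grid)):
            raise ValueError("surface dimensions must match the grids")


def expected_growth(phi_ad, fpba, rho):
    """Closed-form expected annual growth: phi + 0.5 * FPBA * rho."""
    return np.asarray(phi_ad) + FEMALE_FRACTION * np.asarray(fpba) * np.asarray(rho)


def _yearly_mean_points(draws: PosteriorDraws, region_label: str) -> pd.DataFrame:
    return pd.DataFrame({
        "region": region_label,
        "year": draws.transition_labels,
        "phi_ad": draws.phi_ad.mean(0),
        "fpba": draws.fpba.mean(0),
    })


def growth_surface(draws_nw: PosteriorDraws, draws_se: PosteriorDraws,
                   grid_resolution: int = 50, mode: str = "expected",
                   seed=None, n_reps: int = 10_000,
                   n_start: int = 1000) -> GrowthSurface:
    """Annual growth over the union of both regions' observed rate ranges.

    The grid spans the posterior-mean yearly (phi_ad, FPBA) points of both
    regions; ``rho`` is held at its grand posterior mean over regions and
    years.  ``expected`` mode uses the closed form; ``stochastic`` mode
    Monte-Carlo-averages one binomial/Poisson projection step from
    ``n_start`` females per cell.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    pts = pd.concat([
        _yearly_mean_points(draws_nw, draws_nw.region or "northwest"),
        _yearly_mean_points(draws_se, draws_se.region or "southeast"),
    ], ignore_index=True)
    phi_grid = np.linspace(pts["phi_ad"].min(), pts["phi_ad"].max(), grid_resolution)
    fpba_grid = np.linspace(pts["fpba"].min(), pts["fpba"].max(), grid_resolution)
    rho_bar = float(np.concatenate([draws_nw.rho.ravel(), draws_se.rho.ravel()]).mean())
    if mode == "expected":
        surf = expected_growth(phi_grid[:, None], fpba_grid[None, :], rho_bar)
    elif mode == "stochastic":
        rng = np.random.default_rng(seed)
        surf = np.empty((grid_resolution, grid_resolution))
        for i, phi in enumerate(phi_grid):
            n_a = rng.binomial(n_start, phi, size=(n_reps, 1))
            mu = n_start * FEMALE_FRACTION * fpba_grid * rho_bar
            n_r = rng.poisson(np.broadcast_to(mu, (n_reps, len(fpba_grid))))
            surf[i] = (n_a + n_r).mean(0) / n_start
    else:
        raise ValueError("mode must be 'expected' or 'stochastic'")
    return GrowthSurface(phi_grid=phi_grid, fpba_grid=fpba_grid,
                         lambda_surface=surf, rho_fixed=rho_bar,
                         points=pts, mode=mode)


@dataclass
class SubstitutedTrajectory:
    """Baseline and rate-substituted population-index trajectories.

    Indices are the latent population normalised to the first study
    year.  ``baseline_index``/``substituted_index`` are per-year summary
    tables (median and 95% CRI); before ``from_year`` both equal the
    fitted index.  The per-draw index matrices are kept for testing.
    """

    years: np.ndarray
    baseline_index: pd.DataFrame
    substituted_index: pd.DataFrame
    substituted_rate: str
    from_year: int
    baseline_draws: np.ndarray | None = None
    substituted_draws: np.ndarray | None = None

    def __post_init__(self):
        pre = self.years < self.from_year
        b = self.baseline_index["median"].to_numpy()[pre]
        s = self.substituted_index["median"].to_numpy()[pre]
        if not np.allclose(b, s):
            raise ValueError("baseline and substituted must agree before from_year")


def _summary_frame(years, idx):
    return pd.DataFrame({
        "year": years,
        "median": np.median(idx, axis=0),
        "cri_low": np.quantile(idx, 0.025, axis=0),
        "cri_high": np.quantile(idx, 0.975, axis=0),
    })


def _project(N_start, phi, fpba, rho, rng):
    """Per-draw stochastic projection from N_start over phi.shape[1] steps."""
    n, steps = phi.shape
    out = np.empty((n, steps + 1), dtype=np.int64)
    out[:, 0] = N_start
    cur = N_start.astype(np.int64)
    for t in range(steps):
        n_a = rng.binomial(cur, phi[:, t])
        n_r = rng.poisson(cur * FEMALE_FRACTION * fpba[:, t] * rho[:, t])
        cur = n_a + n_r
        out[:, t + 1] = cur
    return out


def substitute_trajectory(draws_target: PosteriorDraws, draws_donor: PosteriorDraws,
                          rate: str, from_year: int, n_start_rule: str = "draw",
                          seed=None) -> SubstitutedTrajectory:
    """Counterfactual re-projection with a donor region's rate swapped in.

    Per paired draw, the target trajectory restarts from its own fitted
    latent N at ``from_year`` (``n_start_rule='draw'``; ``'mean'`` uses
    the posterior-mean N) and is projected with binomial survival and
    Poisson recruitment; the named rate (``'survival'`` -> phi_ad,
    ``'productivity'`` -> FPBA) comes from the donor draw, everything else
    (including rho) from the target draw.  Other rates are assumed not to
    respond (no density dependence).  The baseline applies the identical
    re-projection under the target's own rates.
    """
    if rate not in ("survival", "productivity"):
        raise ValueError("rate must be 'survival' or 'productivity'")
    if not np.array_equal(draws_target.years, draws_donor.years):
        raise ValueError("regions must be fitted over the same year span")
    years = draws_target.years
    if from_year < years[0] or from_year > years[-1]:
        raise ValueError("from_year must fall inside the study span")
    j = int(np.searchsorted(years, from_year))

    tgt_phi, don_phi = _pair_draws(draws_target.phi_ad, draws_donor.phi_ad)
    tgt_fpba, don_fpba = _pair_draws(draws_target.fpba, draws_donor.fpba)
    tgt_rho, _ = _pair_draws(draws_target.rho, draws_donor.rho)
    tgt_N, _ = _pair_draws(draws_target.N, draws_donor.N)

    if n_start_rule == "draw":
        N_start = tgt_N[:, j]
    elif n_start_rule == "mean":
        N_start = np.full(len(tgt_N), tgt_N[:, j].mean())
    else:
        raise ValueError("n_start_rule must be 'draw' or 'mean'")
    N_start = np.round(N_start).astype(np.int64)

    phi_sub = don_phi if rate == "survival" else tgt_phi
    fpba_sub = don_fpba if rate == "productivity" else tgt_fpba

    ss = np.random.SeedSequence(seed)
    rng_b, rng_s = (np.random.default_rng(s) for s in ss.spawn(2))
    base_proj = _project(N_start, tgt_phi[:, j:], tgt_fpba[:, j:], tgt_rho[:, j:], rng_b)
    sub_proj = _project(N_start, phi_sub[:, j:], fpba_sub[:, j:], tgt_rho[:, j:], rng_s)

    # projections cover years j..T-1 (the first entry is the shared N_start)
    norm = tgt_N[:, 0].astype(float)[:, None]
    base_idx = np.concatenate([tgt_N[:, :j], base_proj], axis=1) / norm
    sub_idx = np.concatenate([tgt_N[:, :j], sub_proj], axis=1) / norm

    return SubstitutedTrajectory(
        years=years,
        baseline_index=_summary_frame(years, base_idx),
        substituted_index=_summary_frame(years, sub_idx),
        substituted_rate=rate,
        from_year=from_year,
        baseline_draws=base_idx,
        substituted_draws=sub_idx,
    )


def recovery_test(trajectory: SubstitutedTrajectory, threshold: float = 1.0):
    """Whether the median substituted index reaches the recovery threshold.

    Returns ``(recovered, year)`` with the first year at or after
    ``from_year`` whose median substituted index is >= ``threshold``
    (``year`` is None when recovery never happens).
    """
    med = trajectory.substituted_index["median"].to_numpy()
    years = trajectory.years
    mask = (years >= trajectory.from_year) & (med >= threshold)
    if mask.any():
        return True, int(years[np.argmax(mask)])
    return False, None


def self_substitution_pvalue(trajectory: SubstitutedTrajectory,
                             year: int | None = None) -> float:
    """Mann-Whitney p-value comparing substituted vs baseline index draws.

    Used as the identity check: substituting a region's own rates should
    leave the index distribution unchanged up to Monte-Carlo noise.
    """
    t = -1 if year is None else int(np.searchsorted(trajectory.years, year))
    res = sstats.mannwhitneyu(trajectory.substituted_draws[:, t],
                              trajectory.baseline_draws[:, t])
    return float(res.pvalue)
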