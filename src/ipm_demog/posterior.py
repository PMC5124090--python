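"""Per-draw correlations between growth rates and demographic rates.

For every retained MCMC draw, the Pearson correlation is taken across the
T-1 yearly transitions between the modelled growth rate
``lambda_t = N_t / N_{t-1}`` and a demographic rate aligned to the same
transition (the survival interval t-1 -> t and the breeding season of
year t-1).  The resulting distribution of per-draw correlation
coefficients is summarised by its mean, 95% credible interval and the
probability of a positive correlation.  The same machinery applies to
cross-region comparisons, pairing the two regions' draws by retained-draw
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import RATE_NAMES, PosteriorDraws


@dataclass
class CorrelationSummary:
    """Summary of a per-draw correlation distribution."""

    mean_r: float
    cri: tuple
    p_positive: float
    n_draws: int
    n_years: int
    n_degenerate: int = 0
    rate_name: str = ""

    def __post_init__(self):
        lo, hi = self.cri
        if not (-1 - 1e-9 <= lo <= self.mean_r + 1e-9 and
                self.mean_r <= hi + 1e-9 <= 1 + 1e-9):
            raise ValueError("credible interval must bracket the mean in [-1, 1]")
        if not 0 <= self.p_positive <= 1:
            raise ValueError("p_positive must lie in [0, 1]")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray):
    """Pearson correlation of each row pair; NaN rows flag zero variance.

    Variance is judged relative to the row's magnitude so that a rate
    that is constant up to floating-point round-off still counts as
    degenerate.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    va = (ac ** 2).sum(1)
    vb = (bc ** 2).sum(1)
    ok = (va > 1e-24 * (a ** 2).sum(1)) & (vb > 1e-24 * (b ** 2).sum(1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(1) / np.sqrt(va * vb)
    return np.where(ok, np.clip(r, -1.0, 1.0), np.nan)


def _rowwise_spearman(a: np.ndarray, b: np.ndarray):
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    return _rowwise_pearson(ra, rb)


def _summarise(r: np.ndarray, n_years: int, rate_name: str) -> CorrelationSummary:
    finite = np.isfinite(r)
    n_degenerate = int((~finite).sum())
    r = r[finite]
    if len(r) == 0:
        raise ValueError("correlation undefined in every draw (constant rate)")
    return CorrelationSummary(
        mean_r=float(r.mean()),
        cri=(float(np.quantile(r, 0.025)), float(np.quantile(r, 0.975))),
        p_positive=float((r > 0).mean()),
        n_draws=int(len(r)),
        n_years=int(n_years),
        n_degenerate=n_degenerate,
        rate_name=rate_name,
    )


def growth_rate_correlation(draws: PosteriorDraws, rate_name: str,
                            method: str = "pearson") -> CorrelationSummary:
    """Correlation between yearly growth rates and a demographic rate.

    Computed per MCMC draw over the aligned T-1 transitions, then
    summarised over draws.  Draws in which the rate (or lambda) is
    constant across years have no defined correlation; they are excluded
    and counted in ``n_degenerate``.
    """
    lam = draws.lam
    rate = draws.rate_matrix(rate_name)
    corr = _rowwise_pearson if method == "pearson" else _rowwise_spearman
    r = corr(lam, rate)
    return _summarise(r, n_years=lam.shape[1], rate_name=rate_name)


def _pair_draws(a: np.ndarray, b: np.ndarray):
    """Trim to a common draw count with evenly spaced subsampling."""
    n = min(len(a), len(b))
    ia = np.linspace(0, len(a) - 1, n).round().astype(int)
    ib = np.linspace(0, len(b) - 1, n).round().astype(int)
    return a[ia], b[ib]


def cross_region_correlation(draws_a: PosteriorDraws, draws_b: PosteriorDraws,
                             rate_name: str, method: str = "pearson") -> CorrelationSummary:
    """Between-region correlation of a yearly demographic rate.

    The regions are fitted independently, so draws are paired by retained
    index (the longer set is subsampled evenly if the counts differ); per
    paired draw the correlation is taken across years between region A's
    and region B's rate.
    """
    if not np.array_equal(draws_a.years, draws_b.years):
        raise ValueError("regions must be fitted over the same year span")
    ra, rb = _pair_draws(draws_a.rate_matrix(rate_name),
                         draws_b.rate_matrix(rate_name))
    corr = _rowwise_pearson if method == "pearson" else _rowwise_spearman
    r = corr(ra, rb)
    return _summarise(r, n_years=ra.shape[1], rate_name=rate_name)


def transition_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior-mean rates and growth, one row per aligned transition.

    Documents the alignment convention: ``lambda_t = N_t / N_{t-1}``
    (labelled by the later year t) is paired with the adult survival of
    the interval t-1 -> t and the productivity of breeding season t-1.
    """
    rows = {
        "year": draws.transition_labels,
        "lambda": draws.lam.mean(0),
        "phi_ad": draws.phi_ad.mean(0),
        "fpba": draws.fpba.mean(0),
        "brood": draws.brood.mean(0),
        "phi_egg_period": draws.rate_matrix("phi_egg_period").mean(0),
        "phi_chick_period": draws.rate_matrix("phi_chick_period").mean(0),
        "rho": draws.rho.mean(0),
    }
    return pd.DataFrame(rows)


def correlation_table(draws: PosteriorDraws,
                      rate_names=RATE_NAMES) -> pd.DataFrame:
    """Growth-rate correlation summaries for several rates at once."""
    rows = []
    for name in rate_names:
        s = growth_rate_correlation(draws, name)
        rows.append({"rate": name, "mean_r": s.mean_r, "cri_low": s.cri[0],
                     "cri_high": s.cri[1], "p_positive": s.p_positive,
                     "n_draws": s.n_draws, "n_years": s.n_years,
                     "n_degenerate": s.n_degenerate})
    return pd.DataFrame(rows)
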