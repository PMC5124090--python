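# ipm-demog

Regional integrated population models (IPMs) for migratory songbirds,
built for the question: *when two populations of the same species
diverge — one growing, one declining — which demographic rate is
responsible, and would realistic improvements in it have reversed the
decline?*

The package joins three standard monitoring streams in one Bayesian
state-space likelihood per region:

* annual **count indices** (log-normal observation error around a latent
  female population),
* **capture histories** from constant-effort ringing
  (Cormack–Jolly–Seber likelihood for annual adult survival φ_ad,t),
* **nest records** (Mayfield exposure-day likelihood for daily egg- and
  chick-stage survival, zero-truncated Poisson brood sizes).

The latent population follows

    N_t = N_a,t + N_r,t,   N_a,t ~ Bin(N_{t-1}, φ_ad,t-1),
    N_r,t ~ Poisson(N_{t-1} · 0.5 · B·φ_egg^ep·φ_chick^yp · ρ_{t-1}),

with productivity decomposed into brood size and stage survival (FPBA,
fledglings per breeding attempt), a female fraction of 0.5, and a
recruitment scaling ρ absorbing unmeasured processes (first-year
survival, dispersal, multiple brooding). Survey-gap years are imputed
by the process model. Fitting is by a fast Metropolis-within-Gibbs
sampler (numba kernel, ρ collapsed analytically); convergence is
diagnosed with split Gelman–Rubin R̂.

On top of the fit, the package implements the demographic-attribution
toolkit: per-MCMC-draw correlations between annual growth rates
λ_t = N_t/N_{t-1} and each demographic rate (with 95% CRIs and the
probability of a positive correlation), cross-region rate correlations,
an expected-growth surface λ = φ + 0.5·FPBA·ρ̄ over the observed
(survival × productivity) space, and counterfactual trajectories in
which a declining region is re-projected with a donor region's survival
or productivity swapped in.

Because the underlying national monitoring datasets are not public, the
package ships a first-class synthetic-data generator whose presets
centre on the published regional posterior means for British willow
warblers; everything is validated end-to-end against known truth.

## Worked example

```python
import ipm_demog as ipm

# simulate a stable/increasing region (19 years, 150 nests and
# 200 ringing releases per year, one missing survey year)
res = ipm.simulate_region(ipm.northwest_like(), seed=11)

# fit the IPM (sklearn-style estimator; ~30 s on one CPU)
model = ipm.IntegratedPopulationModel(random_state=5).fit(res.observed)
draws = model.draws_
print(f"max R-hat = {model.max_rhat_:.3f}, converged = {model.converged_}")

s = ipm.growth_rate_correlation(draws, "phi_ad")
print(f"corr(lambda, survival)     = {s.mean_r:.2f} "
      f"({s.cri[0]:.2f}, {s.cri[1]:.2f}), P(r>0) = {s.p_positive:.2f}")
s = ipm.growth_rate_correlation(draws, "fpba")
print(f"corr(lambda, productivity) = {s.mean_r:.2f} "
      f"({s.cri[0]:.2f}, {s.cri[1]:.2f}), P(r>0) = {s.p_positive:.2f}")

print(ipm.impute_missing_counts(draws))
```

prints

```
max R-hat = 1.005, converged = True
corr(lambda, survival)     = -0.27 (-0.59, 0.17), P(r>0) = 0.09
corr(lambda, productivity) = 0.52 (0.24, 0.72), P(r>0) = 1.00
   year      mean          sd  cri_low  cri_high
0  2001  730.4425  231.898699  393.975    1247.0
```

In this simulated realisation, years of high productivity are reliably
years of population growth: the per-draw Pearson correlation between
the 18 yearly growth rates and FPBA averages 0.52 and is positive in
every retained draw, while the survival correlation is weak and
uncertain (which rates drive growth varies between realisations of the
same preset — that is exactly what the correlation machinery measures).
The last table is the posterior for the latent population in the masked
survey year; the generating truth was N = 620, well inside the
interval.

The same pipeline is scriptable from the shell:

```bash
ipm-demog simulate --preset northwest-like --seed 1 --out runs/nw
ipm-demog fit --data runs/nw --out runs/fit_nw --seed 5
ipm-demog analyze --draws runs/fit_nw/draws.csv --out runs/analysis
```

plus `surface`, `substitute` and `report` subcommands for the
growth-rate surface, the counterfactual substitutions and a summary
table of rates, CRIs and growth correlations per region.

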