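# Methods

## The model

`ipm_demog` fits a female-only integrated population model (IPM) per
region. The latent female population in year *t* splits into adults that
survived from the previous year and first-year recruits:

    N_t = N_a,t + N_r,t
    N_a,t ~ Binomial(N_{t-1}, φ_ad,t-1)
    N_r,t ~ Poisson(N_{t-1} · 0.5 · FPBA_{t-1} · ρ_{t-1})

Productivity per breeding attempt decomposes into brood size and daily
nest survival over the egg (incubation) and chick (nestling) stages:

    FPBA = B · φ_egg^ep · φ_chick^yp

The factor 0.5 keeps only female fledglings (equal sex ratio assumed).
ρ is a per-year recruitment scaling that absorbs everything the data
streams cannot measure — first-year survival, dispersal, multiple
brooding, the non-breeding fraction. The first-year population is an
index anchor and is pinned at `initial_n` (default 1000); observed
count indices are log-normal around the latent population,
`log y_t ~ Normal(log N_t, σ)`. Years with no survey contribute no
observation term; their latent N is still propagated by the process
model, which is how the missing survey year is imputed.

Three data streams inform the joint likelihood:

* **Counts** — the log-normal observation terms above.
* **Capture histories** from constant-effort ringing — a
  Cormack–Jolly–Seber (CJS) likelihood conditioning on first release,
  with per-interval adult survival φ_ad,t shared with the process model
  and a single time-constant recapture probability p (constant effort
  motivates constant p). Histories are reduced to m-array sufficient
  statistics; the never-seen-again χ terms use the standard backward
  recursion.
* **Nest records** — Mayfield exposure-day terms: every survived day at
  a stage contributes log φ, a failure contributes one log(1−φ) day at
  the stage of failure. Exposure-day fields count the failure day, so a
  failed stage always has ≥ 1 exposure day. Brood counts (for nests
  reaching the chick stage) follow a zero-truncated Poisson whose rate
  is the brood parameter B; at B ≈ 5.8 the gap between the rate and the
  truncated mean is ≈ 0.3%, far below estimation noise.

Priors are deliberately uninformative: Uniform(0,1) on every probability
(daily nest survival on the daily scale), Uniform(0,10) on B,
Uniform(0,5) on each ρ_t, half-Normal(0,1) on σ. σ is a single constant
per region — a free per-year observation s.d. would not be identifiable
from one count per year. All priors are configurable via `PriorSpec`.

## Sampling

The posterior is sampled by Metropolis-within-Gibbs in a numba-compiled
kernel. Two structural choices matter for mixing:

* **ρ is collapsed out.** With a Uniform(0,R) prior and a single Poisson
  term, the marginal recruitment pmf is
  `P(N_r | c) = P(N_r+1, R·c) / (R·c)` (regularised lower incomplete
  gamma), with `c = 0.5·N·FPBA`. Sampling the collapsed chain removes
  the narrow (ρ, N_r) ridge along which the exact Gibbs draw of ρ and a
  random walk on N_r pin each other. Each retained draw then samples
  ρ_t from its exact full conditional (Gamma truncated at the prior
  bound), so stored draws come from the full joint posterior.
* **σ uses an inverse-gamma independence proposal** matching its full
  conditional up to the half-normal prior factor, decorrelating it from
  the latent path in one step.

The remaining blocks are transformed random walks with several
ridge-breaking companions, all exact MH (discretised-normal proposal
pmfs enter the Hastings ratio):

* φ_ad,t updates optionally transfer ≈ N·Δφ birds between survivors and
  recruits so the sharp binomial at large N does not pin φ;
* nest-survival and brood proposals optionally scale next year's
  recruits along with productivity;
* latent (N_a, N_r) pairs get single-coordinate integer walks with
  separate adapted scales (their conditional widths differ by an order
  of magnitude), an independence "survivor refresh" from the binomial's
  normal approximation, an independence "recruit refresh" drawn exactly
  from the marginal recruitment pmf (ρ′ uniform, then Poisson — its
  Hastings terms cancel the recruitment likelihood), and a "tail shift"
  that slides the whole trajectory from a random year onward with
  survival-guided symmetric cascades.

Every optional companion is a 50/50 mixture with its plain counterpart;
the plain branch keeps acceptance healthy where the companion is blocked
(for example N_r near zero). Latent sweeps run several times per
iteration (default 10; the independence refreshes run on the first
sweep only) because the trajectory is the stiffest part of the
posterior. Proposal scales adapt toward target acceptance rates during
burn-in only and freeze afterwards, so retained draws obey detailed
balance. Boundary-of-support proposals are rejected (equivalent to, and
simpler than, reflective proposals). Transformed proposals are clamped
to [1e−12, 1−1e−12]; the probability mass affected is < 1e−10 and the
stationary density vanishes at the boundary.

Initial values are crude data-based estimates — aggregate Mayfield
ratios for daily nest survival, the mean observed brood, the m-array
return rate for p — with per-chain jitter on the transformed scale, and
latent N at the observed counts (log-scale interpolation across missing
years). Crude-estimate starts avoid the pathological cold start of a
prior-median initialisation (daily nest survival 0.5 implies stage
survival ≈ 1e−4), and the jitter preserves the chain overdispersion that
split R̂ needs.

Defaults are desk scale: 4 chains × 20,000 iterations, 10,000 burn-in,
thinning 10 (4,000 retained draws; ≈ 30 s per region on one CPU).
`paper_scale_config()` gives the heavyweight protocol (10 chains ×
200,000, 100,000 burn-in, thin 50) for overnight runs. Convergence is
judged by split Gelman–Rubin R̂ over every parameter and latent state,
with the conventional threshold R̂ < 1.1; non-convergence warns and
flags, it never raises.

Validation highlights (all in the test suite): the CJS kernel matches
exhaustive latent-fate enumeration to 1e−10 on all 2–4-occasion
histories; the nest-survival MLE equals the closed-form Mayfield
estimator to 1e−6; with essentially no data the sampled parameters
reproduce their priors (means and quantiles); and across 20 replicate
synthetic fits at desk scale, max R̂ < 1.1 with ≈ 95% empirical coverage
of the nominal 95% CRIs for yearly survival and productivity.

## Synthetic data

The generator emulates the model's three streams from known parameters.
Yearly rates receive normal year effects on the logit scale
(probabilities; stage survivals on the whole-stage logit before
conversion to daily rates) or log scale (B, ρ) around preset means.
The two bundled presets centre on the reported posterior means for the
stable/increasing northwest and declining southeast British
willow-warbler populations (φ_ad 0.46/0.43, B 5.78/5.83, stage egg
survival 0.71/0.71, stage chick survival 0.76/0.68, ρ 0.39/0.41);
between-year spreads are loosely calibrated to the reported ranges of
annual variation and are illustrative, not estimates. Default scenario
sizes are 19 years (as in 1994–2012), 150 nests and 200 ringing releases
per year, observation s.d. 0.10, recapture probability 0.30, and one
missing count year at the eighth year (the 2001 survey-gap position).
Stage lengths default to ep = yp = 13 days, consistent with
small-passerine incubation and nestling periods; results are reported on
both the daily and whole-stage scales.

Nest fates are drawn day by day (geometric failure times truncated at
the stage length), so exposure days exercise the Mayfield likelihood
nontrivially. Capture histories are simulated forward per release cohort
with Bernoulli survival and recapture. The generator does not emulate
line-transect detection within counts or within-season ringing-visit
structure — it targets the model's sufficient statistics — so passing
tests demonstrate correct inference *given the model*, not robustness to
the detection artefacts of real survey data.

A deterministic `recovery_presets()` pair reproduces the qualitative
decline-and-recovery pattern used by the counterfactual analysis: both
regions share a survival dip over transitions 5–8 and a subsequent
survival recovery, while the northwest carries persistently higher
productivity (FPBA ≈ 3.4 vs ≈ 2.6). The expectation arithmetic puts the
southeast's final index near 0.45 (far below recovery under any seed),
productivity substitution lifts post-dip growth to ≈ 1.16 per year, and
survival substitution to only ≈ 1.01 — full versus partial recovery.

## Downstream analyses

**Growth-rate correlations.** For every retained draw, the Pearson
correlation is taken across the T−1 transitions between
λ_t = N_t/N_{t−1} and a demographic rate aligned to the same transition
(survival over the interval t−1→t, productivity of breeding season
t−1; transitions are labelled by the later year). The distribution of
per-draw coefficients is summarised by its mean, 2.5/97.5% quantiles and
the fraction positive. Draws in which a rate is constant across years
(correlation undefined) are excluded and counted separately. Pearson is
the default to match the linear presentation convention; Spearman is
available via `method="spearman"`. Stage survivals are correlated on the
whole-stage scale. Cross-region correlations pair the two regions'
independently fitted draws by retained index (any pairing is
exchangeable across independent fits; index pairing is reproducible),
subsampling the longer set evenly when counts differ.

**Growth surface.** Expected annual growth λ = φ + 0.5·FPBA·ρ̄ over a
grid spanning both regions' posterior-mean yearly (φ, FPBA) points, with
ρ̄ held at its grand posterior mean across regions and years. The closed
form is the default (and is exactly monotone in both axes); a stochastic
mode Monte-Carlo-averages one binomial/Poisson projection step per cell,
for checking the closed form and for exhibiting demographic noise.

**Rate substitution.** Counterfactual trajectories re-project the target
region from its fitted latent N at `from_year`, per paired draw, with
either survival or productivity taken from the donor region's draw and
everything else — including ρ_t — from the target draw (no density
dependence is assumed). Re-projection starts from each draw's own latent
N (keeping within-draw coherence; a posterior-mean start is available
via `n_start_rule="mean"`) and is stochastic per draw, honouring
parameter uncertainty. The baseline trend applies the identical
re-projection under the target's own rates, so self-substitution versus
baseline is an exact null — the fitted index summaries remain available
directly from the draws. Indices are normalised to the first study year.
`recovery_test` reports whether and when the median substituted index
reaches a threshold (default 1).

## Numerical choices and edge cases

* The regularised incomplete gamma inside the kernel is a standard
  series/continued-fraction implementation (numba cannot call
  scipy.special), validated against scipy to 3e−13.
* Truncated-Gamma ρ draws use rejection with an inverse-CDF bisection
  fallback; for near-zero rates the conditional is essentially uniform
  and the fallback handles it exactly.
* Extinction is absorbing and is data, not an error: simulation flags
  it, likelihood terms treat N = 0 with the conventions
  Binomial(·|0, φ) = δ₀ and Poisson(·|0) = δ₀, and an observed count at
  a zero latent population has no support.
* A count year is "missing" only as NaN — never zero-filled — in both
  the CSV dialect (empty field) and in memory.
* Split R̂ returns exactly 1.0 for zero-variance (constant) parameters;
  rows that are constant up to floating-point round-off count as
  degenerate in the correlation machinery (relative-variance threshold
  1e−24).

## Known limitations

* The CJS stream uses a single time-constant recapture probability;
  time-varying p is not currently exposed.
* ρ absorbs several biological processes at once; its yearly posterior
  is only as meaningful as that composite.
* The sampler's prior-regime mixing (no data at all) is slow for the
  productivity components — the flat (productivity, recruits) manifold
  is traversed diffusively — which is why the prior-recovery test runs
  longer chains than a data-rich fit needs.
* The generator writes aggregated count indices; site-level structure
  and detectability are out of scope.
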