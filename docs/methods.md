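# Methods

## Experimental layout

`DesignSpec`/`build_design` encode a multi-site randomized complete block
design: each site contains `n_blocks_per_site` blocks (default 3) and each
block contains every combination of the 2×2×2 biocide factorial exactly
once, giving 24 plots per site. Plot order within a block is randomized by
a generator seeded with `(rng_seed, site_index, block_index)`, so a design
is reproducible from its seed and extending the network with more sites
never reshuffles existing blocks. Physical plot geometry (plot size,
walkways, subplots) is not modeled; the plot is the experimental and
observational unit. `encode_treatments` produces the seven factorial model
columns under indicator (0/1) or effect (−1/+1) coding; interaction columns
are elementwise products of the coded mains, so under effect coding a
main-effect coefficient is half the difference between marginal means.

## Biomass generator

`simulate_experiment` draws
`y = fixed cell mean + site + block + plot` with independent Gaussian
effects at the three nested levels. Defaults (baseline 100 g; SDs
372.7 / 7.82 / 15.33 g for site / block-within-site / plot-within-block)
describe baseline biomass variation across a globally distributed network
of grassland-like sites and are the fixed conditions under which all
replication presets run. One observation is drawn per plot, so the plot
draw is simultaneously the observation-level noise and the residual of any
refit; no separate residual is added. Effects are additive in grams
(δ = effect% × β₀/100), not multiplicative on site-specific baselines.
Distributional choice: Gaussian at every level.

Two consequences of this hierarchy matter for everything downstream.
First, with baseline 100 g and site SD 372.7 g, site means (and many
plots) are negative — the generator makes no positivity claim, and any
log-scale analysis of synthetic data needs an additive offset (see the
permutation section). Second, in the balanced layout the site and block
terms cancel exactly from within-block treatment contrasts, so detection
power is governed by the plot SD alone: the standard error of a
main-effect cell contrast is σ_plot·√(2/105) ≈ 2.12 g for 35 sites, and of
a two-way interaction contrast σ_plot·√(4/105) ≈ 2.99 g.

Scenario presets:

* `main_only` — β_i = β_f = β_m = δ, interactions 0.
* `superadditive` — mains δ plus β_fm = δ on the fungicide×molluscicide
  pair (the pair is a convention; `all_pairs=True` injects the synergy on
  all three pairs for sensitivity analysis).
* `compensatory` — mains δ, all pairwise interactions −2δ and the
  three-way +3δ, so that *every* multi-biocide cell equals the baseline
  ("perfect compensation"; the three-way value is the unique choice that
  extends the pairwise no-increase property to the triple cell).

## Mixed-model engine

`fit_lmm` fits the model declared by a `ModelSpec` (response, ordered
fixed terms, nested random intercepts, coding, optional log transform with
offset) under ML or REML and returns estimates, normal-reference Wald
p-values, variance components, the log-likelihood and convergence/boundary
flags.

For the canonical layout — one observation per plot, ≥3 sites, equal-size
complete blocks, random intercepts for site and block-within-site, and
fixed-effect columns that are within-block contrasts plus a constant — the
engine solves the model exactly: under balance GLS equals OLS, and the
covariance matrix diagonalizes into site-mean, block-deviation and
within-block strata with eigenvalues λ_S = σ² + kσ²_b + bkσ²_s,
λ_B = σ² + kσ²_b, λ_W = σ² (k plots per block, b blocks per site). ML and
REML reduce to per-stratum variance estimates (with adjacent-strata pooling
when a component hits its non-negativity boundary), and the log-likelihood
and fixed-effect covariance have closed forms. The applicability conditions
are verified numerically at fit time; any other model (the longitudinal
and context models with plot and calendar-year-within-site intercepts,
unbalanced data, covariates that vary between blocks) is delegated to
statsmodels `MixedLM`, and models without random intercepts to OLS. The
test suite checks that the closed form agrees with `MixedLM` and with
`lme4::lmer` (run through `Rscript`) to optimizer precision on the same
data — estimates, standard errors, variance components and both
log-likelihood conventions. The exact path makes a full+reduced model pair
cost ~2 ms, which is what allows hundreds of thousands of refits in the
Monte-Carlo loops.

`lrt_test` compares nested ML fits: statistic 2Δℓ clamped at zero,
referred to χ² with df equal to the difference in fixed-effect columns.
REML fits are rejected for comparisons. `wald_summary` returns two-sided
p-values from estimate/SE against the standard normal; no
degrees-of-freedom correction (Satterthwaite/Kenward–Roger) is applied —
with ≥600 within-block residual degrees of freedom in the canonical layout
the normal reference is adequate, and the choice is uniform across both
back ends. Significance is α = 0.05 two-sided throughout.

## Power analysis

`estimate_power` repeats, per replicate: simulate a fresh dataset
(redrawing site, block and plot effects from their nominal distributions —
replicate seeds are spawned counter-based from the master seed, so runs
are reproducible and parallelizable), fit the full i*f*m factorial mixed
model by ML with site and block random intercepts, and LRT-drop the tested
column. Main-effect scenarios test the insecticide term (the three mains
are exchangeable under balance); interaction scenarios test
fungicide:molluscicide. The full factorial is always fitted, so
interaction terms are estimable even when truly zero; dropping a single
column from the full model is a *conditional* (cell-contrast) test under
indicator coding. A replicate whose fit does not converge is retried once
with a new draw and then counted as a non-rejection (with the exact solver
this path is never exercised in practice, but the contract is part of the
loop). Power is reported with the exact Clopper–Pearson interval
(beta-quantile form).

Expected magnitudes under the default conditions follow from the contrast
SEs above: e.g. a 5% (5 g) main effect gives z ≈ 2.36 and ~60–66% power; a
10% superadditive pair interaction gives z ≈ 3.34 and ~90% power; the
compensatory 5% scenario has a pairwise coefficient of −2δ = −10 g and
therefore the same ~90% scale. The Monte-Carlo estimates in the acceptance
suite agree with these closed-form predictions, which is the package's
internal consistency check on the whole chain.

## Permutation false-positive analysis

`false_positive_analysis` takes any plot-level biomass table (most recent
year per plot if several are present), and per iteration reassigns the
biomass values uniformly at random *within each (site, block)* — the
multiset per block is preserved, treatments untouched — then refits the
±1-coded log-biomass i*f*m model with site and block random intercepts
(REML) and counts Wald significance per term. Blocked shuffling destroys
any treatment–response association while preserving the design structure,
so each non-intercept term should be flagged in ~α of iterations whatever
the input data; the intercept (mean log biomass, far from zero) is flagged
always. Because the synthetic null network is not positive-valued (site SD
≫ baseline), the replication inputs add a +2000 g offset (≈5.4 site SDs)
before the log; the calibration is invariant to this monotone shift. A
known limit: the counted p-values are parametric, so for inputs whose
within-block distribution is far from Gaussian (e.g. synthetic data with
implausibly large injected effects, ≥3× the residual SD) the per-term rate
drifts mildly above α (~8–9% observed at 50% effects) even though the
permutation itself is exact; at realistic effect sizes (≤20% of baseline)
the rates stay inside the exact binomial 99% band.

## Analysis pipeline

Responses are built from long cover tables: richness (count of species
with positive cover), Shannon diversity H = −Σp ln p in nats over positive
covers (undefined and flagged for empty plots), and functional-group
percentages (unmapped species fall into `other`, logged). The per-site
model is `response ~ block + i*f*m` by OLS (block categorical) for
single-time-point data, or the year-crossed longitudinal variant with
calendar-year and plot intercepts otherwise. The cross-site model is
`response ~ year_since_start * i * f * m` with random intercepts for site,
block-within-site, plot-within-block and calendar-year-within-site;
`year_since_start` is continuous and 0 at baseline (the intercept is the
baseline control mean), `calendar_year` categorical. Components that are
unidentifiable for the data at hand are dropped with a logged warning
(calendar-year intercept with one year; plot intercept and year terms with
one record per plot). The context model standardizes a per-site driver
(mean annual temperature, soil pH, mean control biomass, …) before
crossing it with the treatments; a constant driver is an error, and
standardization is an affine reparameterization that leaves the likelihood
unchanged.

`simplify_model` performs backward elimination of interactions by ML
likelihood-ratio tests: starting from the highest order, the currently
removable term (not contained in any retained higher-order interaction)
with the largest p is dropped while that p exceeds α; main effects are
never removed. Note the marginality consequence: a two-way term is
retained either on its own merit or because the three-way is kept, so its
null retention rate is α + (1−α)α ≈ 0.0975 at α = 0.05, while the
three-way's is α — the acceptance suite asserts exactly these nominal
rates. No multiple-testing correction is applied along the elimination
path. An alternative reporting route keeps the full model with scaled
predictors; `n_groups_recode` supports the number-of-excluded-groups
(0–3) parameterization.

## Community generator

`simulate_community` emulates multi-site, multi-year cover sheets purely
for exercising the pipeline: a global species pool with log-normal
baseline abundances, partial pool overlap between sites, per-site
log-normal deviations of species abundances (so sites differ in
composition, giving real site-level variance in diversity responses), a
multiplicative year trend, and log-normal observation noise per
plot/year/species. Consumer pressure is a multiplicative suppression of
the dominant species fraction on plots where the targeted biocide is *not*
applied, so exclusion releases dominants and lowers evenness — the
qualitative signature the diversity models should detect. Covers are
reported to one decimal with a 0.1% floor, mirroring field convention;
derived biomass is proportional to summed cover. The generator makes no
attempt at temporal autocorrelation, species interactions, damage scores
or realistic rank-abundance shapes, so passing pipeline tests demonstrate
correct model mechanics, not ecological realism.

## Problem sizes and determinism

The replication presets use the canonical 35-site layout for power (300
simulations per scenario) and a 29-site synthetic null network for the
permutation analysis (10,000 iterations in the acceptance script, 1,000 in
the acceptance test); parameter-recovery checks use a 200-site simulation,
and unit tests run on 1–10 sites. All randomness flows from explicit
seeds: designs seed per block, power replicates spawn counter-based child
seeds, and the permutation loop owns a single generator, so every reported
number is bit-reproducible from its seed.
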