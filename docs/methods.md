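# Methods

This note documents the models, estimators, and design choices behind
`beepac`, and what the synthetic generator does and does not emulate.

## Data model and filters

Visitation records are one row per observed interaction (year, date,
transect, bee species, plant species, count); floral plot records hold
open floral units per 2 × 2 m plot; the trait table maps each bee species
to its proboscis length (prementum + glossa, mm). Counts of zero carry no
observation and are dropped with a warning; negative counts, dates that
do not parse as ISO-8601, or dates outside their stated year are hard
errors that name the offending file line.

Two filters precede all analysis. The **core season** filter keeps July
and August only, where interaction frequencies support daily networks.
The **rare-species** filter drops bee species with fewer than
`min_total` individuals across the whole record set (default 20: in
strongly skewed assemblages the retained and excluded species are
separated by a wide gap, so any threshold in that gap selects the same
community; the parameter is exposed).

**Flowering periods** are early (through July 20), middle (July 21 –
August 20), late (from August 21). July 20 itself is assigned to early —
the middle stage explicitly begins July 21 — and both boundaries are
configurable.

## Daily networks and floral density

Visits are pooled across transects within a sampling day into a bee ×
plant count matrix; species with no interaction that day are absent (no
zero rows or columns — a species not seen is missing, not zero). Floral
density for a day is the mean of per-plot floral-unit totals across all
plots surveyed that date, restricted to plant species visited at least
once anywhere in the record set (the whole multi-year set by default;
per-year scope is a caller choice, since `visited_plants` takes any
record subset). Plots where no visited species flowered contribute zero
to the mean rather than being dropped.

## Müller's PAC index

For counts `a_ik` (bee i on plant k), `d_ij = Σ_k (a_ik/Σ_l a_il) ·
(a_jk/Σ_m a_mk)`. The first factor is the share of target i's diet on
plant k; the second is acting j's share of all bee visits k receives.
The diagonal is included: `d_ii` is the intraspecific index. Rows sum to
1 by algebraic identity, which the tests assert on random matrices along
with equivalence (to 1e-12) against a literal triple-loop evaluation of
the double sum. The interspecific index of an acting species is its
column mean excluding the diagonal — its average potential effect on the
other species present that day; it is undefined (absent, not zero) in a
single-species network. Computation is vectorized (`P Q^T` with
row-normalized `P` and column-normalized `Q`) in double precision, with
no smoothing or pseudo-counts.

## Mass-action abundance

Raw capture counts are the row sums of the same matrix the PAC index is
computed from, so using them as an abundance covariate would regress the
index on part of itself. Under mass action, `F_ij = x_i · x_j · c_ij`;
taking logs over the observed (nonzero) links gives the additive model
`log F_ij = μ + r_i + s_j + ε_ij`, fit by least squares with sum-to-zero
constraints; `x_i ∝ exp(r_i)` normalized to sum 1 per side and day, and
`c_ij = F_ij/(x_i x_j)` on observed links (the free overall scale is
absorbed into `c`, so the decomposition reproduces `F` exactly on
observed links by construction). Zeros are unobserved links, never
log(0). A disconnected bipartite graph is fit per connected component
with a warning, because relative scaling across components is not
identified; a singleton component contributes zero effects by centering.
This is the minimal deterministic estimator consistent with the
mass-action assumption; it recovers `x` exactly (to 1e-9) whenever `F`
is multiplicative with constant preference, and recovers abundance ranks
under Poisson noise when species abundances are separated the way
strongly skewed bumblebee communities are. Estimation is per daily
network, matching the models' "abundance on the census date" covariate.

## Chao2 completeness

Distinct (bee, plant) links play the role of species and sampling days
the role of incidence units, pooled within a year. The bias-corrected
form `S_est = S_obs + ((m−1)/m) · Q1(Q1−1)/(2(Q2+1))` is the default
because it is defined when Q2 = 0; the classic `Q1²/(2Q2)` form is
available when Q2 > 0. Completeness is `S_obs/S_est ∈ (0, 1]`. The
effort association is a two-sided Spearman rank correlation between
per-year transect counts and completeness; it raises on constant inputs
(rho undefined) and requires at least three years.

## Competition mixed models

One row per (network day, species present that day), inner-joining the
PAC indices, the mass-action abundances, per-day floral density, and
proboscis length; a retained species without a trait entry is an error
naming the species. Two Gaussian linear mixed models share the fixed
structure

```
response ~ abundance_lz * floral_density_lz + proboscis_z
           + C(year) + C(flowering_period)
```

with a random intercept per bee species, the interspecific model taking
the acting species' mean column index as response and the intraspecific
model the diagonal. Reference levels are the first study year and the
early period.

Numerical and inferential choices:

- **Transforms.** Floral density and abundance are log- then
  z-transformed, proboscis z-transformed, over the rows entering the
  model (not per year). The z-score uses the population standard
  deviation (ddof=0, numpy's default; selectable). Non-positive values
  or constant vectors are errors.
- **REML by default.** The species variance component is estimated from
  few groups (~7 species); plain ML shrinks it toward zero and deflates
  the standard errors of species-level covariates such as proboscis
  length, costing nominal 2-SE coverage in simulation. REML (the
  standard default for Gaussian mixed models) restores it. ML remains
  available (`reml=False`, CLI `--ml`) for likelihood comparisons across
  fixed-effect structures, which this pipeline does not perform.
- **Optimization.** A chain of optimizers (L-BFGS, BFGS, Powell,
  Nelder–Mead) is tried in turn, because the species variance can sit on
  the boundary where some Hessians are singular; a boundary fit with
  non-finite standard errors is flagged via `converged=False`, never
  silently.
- **VIF.** Computed on the main-effects design only; the interaction is
  excluded because it is collinear with its own components by
  construction. Each dummy/continuous column is regressed on the rest
  (`VIF = 1/(1−R²)`); a rank-deficient design raises. The conventional
  screening threshold of 3 is reported, not enforced.
- **Wald χ² tests.** Per model term, `χ² = b'V⁻¹b` on the term's
  coefficient block with its fitted covariance; categorical terms are
  tested jointly, single-df terms reduce to z², and the intercept is
  excluded. With a single interaction and no other marginality, this
  coincides with Type-II tests.
- **Partial residuals.** Component-plus-residual values per observation,
  and predicted curves over the term's range at the 10th/50th/90th
  quantiles of transformed floral density, other covariates at their
  reference level or mean (zero, since covariates are centered).
- No multiple-testing correction is applied to the marginal p-values.

## Synthetic generator

`generate_community` emulates a five-year alpine-meadow survey: weekly
sampling days per year (5, 9, 9, 8, 7 — 38 days total) starting July 1;
14 bee species with log-normal relative abundances (σ = 2.0, so the top
species is expected to take roughly half of all visits, matching the
skew of real bumblebee assemblages); 50 plant species with log-normal
base abundances and per-species Gaussian bloom windows; a seasonal
floral curve peaking near July 19 (width 18 days) with an extra
exponential decline (0.02/day) after the peak, scaled to 150 open floral
units per 4 m² at peak; 30 transects per day with 5 plots each and 8
expected visits per transect. Visit counts per (bee, plant, transect)
are Poisson with mean proportional to `x_bee · w_plant(day) · c`, where
`c` is a Gaussian proboscis–corolla matching kernel (width 3 mm) plus a
floor of 0.2 so short-tongued generalists still visit open flowers
broadly. Every latent parameter is returned in a truth bundle.

What it does **not** emulate: between-year turnover in plant community
composition (bloom windows repeat every year, so link persistence is
higher than in real surveys), overdispersion beyond Poisson, weather
gaps, observer effects, spatial structure among transects, and colony
dynamics. Passing tests therefore demonstrate correctness of the
estimators under the mass-action data-generating assumptions, not
robustness to all field realities.

`generate_competition_scenario` plants known regression coefficients
directly into the model-ready table: covariates are drawn with bounded
(log-uniform) tails — a seasonal density curve with log-uniform day
noise and per-(day, species) log-uniform abundances — precisely so the
planted linear predictor provably stays inside the index bounds [0, 1]
at the default effect sizes (intercept 0.45; abundance +0.07; density
+0.01; proboscis +0.08; interaction −0.02; late period +0.05; species
random-intercept sd 0.05, clipped at ±2 sd; residual sd 0.10; 38 days ×
7 species = 266 rows). A configuration whose linear predictor leaves
[0, 1] raises rather than clipping. Generating raw visitation whose
downstream PAC indices follow an exact prescribed linear model is not
tractable, so planting effects at the table level is what gives the
mixed models a recovery target with known truth; the full
records-to-model path is exercised separately on mass-action communities.

## Problem sizes

The test suite and the reproduction script use: ~110 random networks
(≤6 bees × ≤8 plants) for the PAC oracle; 100 replicates for Poisson
rank recovery; 50 replicates of 266-row tables (two mixed-model fits
each) for coefficient recovery; and a 3-year, 6-species community for
end-to-end determinism. These sizes make every check rerun in seconds
while keeping the Monte-Carlo rates stable to a few percent.

## Known limitations

- Mass-action abundances are relative within a day; cross-day or
  absolute comparisons require an external calibration the method does
  not provide.
- With few species groups, Wald inference on species-level covariates is
  approximate even under REML; a parametric bootstrap would be the next
  step if exact coverage mattered.
- The disconnected-component abundance fit leaves cross-component scale
  arbitrary; downstream models should treat such days with care (the
  pipeline only warns).
- The Chao2 estimator assumes incidence exchangeability across sampling
  days within a year; strong phenological turnover violates this and
  biases completeness upward.
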