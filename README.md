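# beepac

Quantifying the potential for interspecific and intraspecific competition
among bumblebees that share floral resources, from quantitative
plant–pollinator visitation networks.

## The problem and the approach

Bumblebee species foraging in the same meadow compete indirectly: when two
species visit the same plants, each one's use of a shared plant reduces
what the other can obtain. `beepac` implements a complete analysis
pipeline for multi-year visitation surveys (daily walk transects recording
which bee visited which plant, floral counts in fixed plots, and a species
trait table of proboscis lengths):

1. **Daily bipartite networks** — visits pooled across transects into a
   bee × plant count matrix `a` per sampling day, restricted to the
   July–August core season with rarely caught species removed.
2. **Müller's potential apparent competition (PAC) index** — for each
   daily network,

   ```
   d_ij = Σ_k (a_ik / Σ_l a_il) · (a_jk / Σ_m a_mk)
   ```

   the potential effect of acting species *j* on target species *i*
   through shared plants *k*. Rows sum to 1. The column mean excluding the
   diagonal is the acting species' **interspecific** index; the diagonal
   `d_ii` is the **intraspecific** index (how much a species monopolizes
   its own plants).
3. **Mass-action abundance** — raw capture counts are row sums of the same
   matrix the PAC index uses, so they cannot serve as an abundance
   covariate. Instead, assuming `F_ij = x_i · x_j · c_ij`, a log-linear
   least-squares decomposition over observed links recovers effective
   relative abundances `x` free of that circularity.
4. **Chao2 sampling completeness** — per year,
   `S_est = S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1))` over link incidences
   across sampling days, plus a Spearman test of completeness against
   sampling effort.
5. **Gaussian mixed models** — interspecific and intraspecific indices
   regressed on abundance (log-z), floral density (log-z), proboscis
   length (z), year, flowering period and the abundance × density
   interaction, with a species random intercept (REML by default); VIF
   screening, per-term Wald χ² tests, and partial-residual outputs at the
   10th/50th/90th floral-density quantiles.

A fully parameterized synthetic generator (`beepac.synthetic`) draws
multi-year communities under the mass-action model with proboscis–corolla
trait matching and a seasonal floral curve, so the entire pipeline is
testable end to end against known ground truth.

## Worked example

`examples/05_competition_models.py` plants known effects in a model-ready
table (abundance +0.07, abundance × density −0.02, proboscis +0.08) and
refits them:

```
266 (day, species) rows; planted coefficients:
{'intercept': 0.45, 'abundance': 0.07, 'density': 0.01, 'proboscis': 0.08,
 'interaction': -0.02, 'period_middle': 0.01, 'period_late': 0.05}

interspecific model (response: mean PAC effect of acting species):
                          term  estimate  std_error  z_value  p_value
                     Intercept    0.4373     0.0215  20.3416   0.0000
                  abundance_lz    0.0653     0.0059  11.1393   0.0000
abundance_lz:floral_density_lz   -0.0148     0.0054  -2.7126   0.0067
                   proboscis_z    0.0744     0.0138   5.3812   0.0000
```

The estimates straddle the planted values well within two standard
errors: potential competition rises with the acting species' abundance,
and the negative interaction means the abundance effect is strongest when
floral density is low. Each script in `examples/` demonstrates one
capability (survey summaries, the hand-checkable 2×2 PAC example, exact
mass-action recovery, Chao2 completeness, the models, the full pipeline).

The same pipeline runs from the shell:

```bash
beepac all --seed 11 --outdir out/        # simulate + every stage
beepac pac --visits out/visits.csv --outdir out/
```

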