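# Methods

## The recruitment model

A site's annual seed crop is partitioned into exclusive fate pathways:
one per seed disperser (seeds swallowed and defecated away from the
parent), plus two reserved pathways, `spat_out` (handled, pulp removed,
dropped near the parent) and `undispersed` (fallen with pulp under the
crown).  Pathway *s* receives a fraction *P_s* of the crop (fractions sum
to 1 — every seed has exactly one fate), germinates with probability
*G_s*, and deposits seeds according to a binned distance kernel *D_sm*.
One-year survival *T_m* is defined on the four experimental distance
classes (5, 15, 30, 50 m).  Recruitment success is

RS = 100 · Σ_s P_s G_s Σ_m D_sm T_m   (percent of the crop alive at one year).

All internal arithmetic is double precision; rounding (RS to 2 decimals,
deltas to 1) happens only in the reporting layer.

Key structural choices:

- **Distance-class mapping.** A kernel bin belongs to the survival class
  whose station is nearest to the bin midpoint (boundaries 10, 22.5,
  40 m).  Distances beyond 50 m clamp to the 50 m class, so long-distance
  dispersal earns no modelled benefit past the experiment's range; this
  deliberately bounds the advantage of the far-dispersing muriqui.  The
  mapping is a `ClassMap` value and can be reconfigured.
- **Non-dispersed pathways** carry a degenerate kernel with all mass in
  the first (0–5 m) bin; their survival is the 5 m value, the nearest
  measured station to the crown.  Spat-out seeds use the
  pulp-removed germination rate, undispersed seeds the with-pulp rate —
  spitting is exactly pulp removal, and the two control treatments of the
  germination experiment provide exactly these rates.
- **Shares vs contributions.** A pathway's contribution is its summand of
  RS (same percent scale); its share is contribution/RS.  Shares are
  undefined (an explicit error, never silent zeros) when RS = 0.

A per-seed Monte-Carlo oracle (`monte_carlo_oracle`) draws each seed's
fate, germination, landing bin and survival; it exists purely as an
independent check of the analytic sum and is tested to agree within
sampling error.

## Estimators

- **Fate profiles** pool raw fruit counts across trees and sessions.  The
  recruitment equation needs crop-level probabilities, so pooling is
  effort-weighted, not tree-averaged.  Dropped fruits are merged into
  `undispersed`.
- **Germination** is the pooled germinated/sown fraction per treatment,
  with per-block mean and SD reported (bar-plot convention: counts out of
  5 seeds, 10 blocks in the field design).  The design-based one-way
  randomized-block ANOVA partitions SS into block/treatment/residual on
  the per-block counts treated as continuous, F with (t−1, (t−1)(b−1))
  df.  Incomplete or unbalanced layouts are a hard error — silently
  dropping cells would bias the blocks.
- **Kernels** are 5 m half-open histograms ([a, b); an observation on an
  edge belongs to the upper bin — fixed so histograms are bit-exact).
  The smooth fit is a cubic smoothing spline through bin-midpoint
  frequencies (penalty chosen by generalized cross-validation when
  "auto"), clipped at zero and renormalized to unit mass; fewer than 4
  occupied bins falls back to the histogram with a warning.  The
  bootstrap envelope resamples distances with replacement, re-bins and
  re-smooths each replicate, and takes pointwise quantiles (defaults:
  1000 replicates, 2.5/97.5%; neither is a fidelity claim — both are
  explicit knobs).
- **Escape curves** are pooled binomial fractions per distance class;
  a class with no data is an error, never an imputation.  Years pool by
  default, with per-year curves available.
- **Distance trend.** Survival counts are regressed on distance with a
  Poisson log link, log(seeds placed) offset, and tree indicator (fixed
  effect) adjustments.  A mixed model with by-tree random slopes would be
  the textbook choice for these data; the fixed-effects version is used
  because the model's consumer is the design-based escape curve — the
  trend test is secondary inference — and because the Poisson working
  variance is conservative for binomial proportions (the type-I error of
  the Wald test sits below the nominal 5%, verified by simulation).
- **Camera traps** yield visits per 100 trap-days with station effort
  counted once per station regardless of how many species a station
  reports.  No detectability modelling: the rates are raw relative
  frequencies.

## Scenario engine

Cumulative losses follow the body-size order (muriqui → howler →
jacutinga).  Removal without compensation reallocates the lost pathway's
crop share to `undispersed` (unhandled fruits fall with pulp).  Removal
therefore commutes, and mass is conserved in every cell.  With
compensation, the whole removal profile is replaced by the fate profile
observed in a community lacking the lost disperser(s) — the moderately
defaunated site supplies the no-muriqui profile, the defaunated site the
no-muriqui-no-howler profile.  Only removal fractions are rewired; the
remaining dispersers keep their intact-site germination and kernels.  A
loss step with no observed source community (e.g. jacutinga-only loss)
appears as an uncompensated cell flagged `compensation_available=False`.

Predator scenarios substitute escape curves: "complete" uses the curve of
the site with the most complete predator assemblage (the moderately
defaunated site), "no_peccaries" the defaunated site's curve, and
"no_peccaries_no_agoutis" the intact site's curve (its predator community
is the most depleted, with small granivorous rodents released).  The
mapping is configuration, not code.  Every grid cell's RS is computed by
the model-core function on the cell's fully constructed model; the two
delta conventions (vs the complete-predator full-assemblage baseline, and
vs each scenario's own baseline) are computed from those RS values only.

## Synthetic data

The generator emulates the five record tables with the statistical
structure the estimators assume:

- multinomial seed fates per fruit, split over ≥ 3 focal trees;
- binomial germination with a normal block effect on the logit scale
  (SD 0.5), shared across treatments within a block — the additive
  structure the block ANOVA targets, kept on the logit scale so
  probabilities stay in [0, 1];
- distances from a log-normal kernel matched to the target mean ± SD by
  method of moments (gamma available); log-normal because the field
  distributions are right-skewed on positive support;
- survival binomial with log-linear distance effect (mirroring the
  log-link trend test) and a log-normal tree effect (SD 0.15), truncated
  to [0, 1];
- Poisson camera-trap visits per station.

Default parameters are the study conditions: removal fractions
muriqui/howler/jacutinga = .41/.41/.01 (intact), .47/.16 (moderate), .41
(defaunated), matching the observed 83/63/41% swallowed totals; kernel
moments 59.7 ± 35.7, 9.7 ± 3.4, 10.5 ± 7.3 m; survival designs of 60
seeds × 4 distances per site-year; 10 blocks × 5 seeds per germination
treatment; ~400 trap-days per site.  Where the field values are not
published at component level, the defaults are fixed plausible choices:
spat-out/undispersed splits (.07/.10, .12/.25, .09/.50), germination
probabilities (.80/.75/.50 defecated, .45 without pulp, .35 with pulp —
primates enhance germination, the bird does not), escape curves (intact:
baseline .11, flat — heavy mortality at all distances under rodent
release; moderate: .18 with +.015/m log slope; defaunated: .20 with
+.012/m), and rodent visitation 70/5/25 per 100 trap-days (the ~14-fold
intact-vs-moderate release).  These defaults yield truth RS of 7.8, 10.9
and 8.7% — the qualitative gradient pattern (lowest recruitment where
predators are most depleted, highest at the moderately defaunated site)
rather than the exact field percentages, which depend on unpublished
per-site component values.

What the generator does **not** emulate: spatial tree maps and
autocorrelated seed shadows, phenology, observer effects in focal
sampling, overdispersion beyond the block/tree random effects,
cause-specific mortality, and multi-year seedling dynamics.  Passing
recovery tests therefore show that the estimators invert the generator's
assumed structure at the stated sample sizes — not that field data meet
those assumptions.

## Numerical and testing notes

- Probability-sum invariants are enforced at 1e-9; histogram mass
  conservation is exact.
- Germination estimates recover the logit-normal *marginal* rate, which
  sits slightly below the conditional parameter (≈ 0.01 at SD 0.5); the
  truth model uses the conditional value, a documented ≈ 0.2–0.3-point
  systematic on recovered RS, well inside the 1-point recovery budget.
  Likewise the log-normal tree effect inflates marginal survival by
  exp(σ²/2) ≈ 1.1%.
- End-to-end recovery is tested at 2 × 10⁴ fruits/site, 5 × 10³
  distances/disperser, 250 germination blocks and 500 seeds per distance
  class and year (20 trees, 2 years): at these sizes the RS sampling SD
  is ≈ 0.4–0.5 points, so the 1-point criterion is a ≈ 2σ bound.  At the
  field-scale design (60 seeds/class/year, 10 blocks) the shared
  tree/block effects leave ≈ 2-point RS sampling noise — the field-scale
  pipeline test therefore uses a 3σ (6-point) sanity bound.
- The smoothing-spline limit of large penalties is the least-squares
  straight line; for uniform histograms this is the global constant.
- Ties at class boundaries go to the upper class (searchsorted,
  right-closed), consistent with the half-open bin convention.

## Known limitations

- Distance is the only spatial variable; there are no seed-shadow maps.
- Beyond-50 m survival is clamped to the 50 m value.
- The trend test's tree adjustments are fixed effects, not random
  slopes; its p-values are conservative for binomial data.
- Compensation rewires only removal fractions; any behavioural change in
  gut passage or movement of the remaining dispersers is out of scope.
- Visitation rates are raw indices; no occupancy or detectability model.
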