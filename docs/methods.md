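# Methods

This note documents the statistical machinery, its assumptions, the
synthetic data-generating process, numerical choices, and known
limitations.

## Curation model

A *survey* is the unit of observation: a unique site × depth-zone ×
year (or fossil age) combination.  Replicates within a survey are
combined by logical OR (a species is present at the site if any
replicate recorded it; absent if scored absent somewhere and present
nowhere; unscored otherwise).  OR is the only aggregation consistent
with presence/absence semantics at the site level.

**Time bins.**  Eleven ordered bins: Late Pleistocene
(131,000–12,000 ybp), Holocene (9,100 ybp–1499 AD), 1500–1959, then
decadal and 4–6-year bins to 2005–2011 (bins narrow after 1980
because survey effort exploded after the *Diadema* die-off).  Fossil
ages are years before 1950 (radiocarbon convention).  Two
conventions collide in the sources for the year 2000 (1995–2000 vs
2000–2004); the package defaults to 1995–2000 and exposes the
alternative as `year2000_with_older=False`.  Ages falling in the
12,000–9,100 ybp gap between the two fossil bins are flagged
unassignable rather than silently binned; the shared 1500 AD
endpoint resolves to the 1500–1959 bin.

**Reef zones.**  Crest ≤ 6 m, midslope 6–20 m (boundary tie goes to
the crest; the crest cutoff moves to 10 m for offshore high-clarity
sites); backreef, reef flat and reef pavement are excluded outright;
deeper than 20 m is excluded.  Without a depth, *A. palmata*
dominance or high wave exposure implies crest and *A. cervicornis*
dominance implies midslope; with neither, the record is excluded
with a logged reason — never guessed.

**Taxonomy.**  Fourteen canonical species groups.  The shipped alias
CSV implements the historical synonymies (undifferentiated
*Porites* → branching *Porites*; *Montastraea* spp. and
*M. annularis* → *Orbicella*; *Diploria labyrinthiformis* and
*Pseudodiploria* spp. → *Pseudodiploria*; etc.) and is user-editable
without code changes.

## Life-history guilds

Competitive (*A. cervicornis*, *A. palmata*, optionally *Millepora*),
stress-tolerant (7 domed taxa) and weedy (4 brooding taxa); the
generalist strategy exists in the type system but has no members and
no model.  *Millepora* is a hydrozoan outside the classical guild
analyses; a flag includes or excludes it from the competitive guild
so both model variants can be compared.

Growth-rate classes are rank-fraction terciles: with minimum-rank
r among n rates, r/n ≤ 1/3 is slow, ≤ 2/3 moderate, else fast.
Minimum ranks implement the tie-to-slower rule and make the
classification scale-invariant.  Interpolated empirical percentiles
at 33⅓/66⅔ were rejected because they cannot reproduce the published
class labels for the 14 shipped rates (they place the 5.0 mm/yr rate
in the slow class); rank-fraction terciles reproduce all published
labels except *Orbicella* (7.9 mm/yr computes as fast), whose
published "moderate" label is honored in the shipped trait table and
the discrepancy is asserted in the tests.

## Occurrence model

For response row *i* (survey × member species; successes y_i out of
n_i trials, n_i = 1 for presence/absence rows):

    y_i | u_{c(i)} ~ Binomial(n_i, logit⁻¹(x_i'β + u_{c(i)})),
    u_c ~ N(0, σ_u²)

x_i encodes time bin, species and their interaction in treatment
coding with the Pleistocene and the alphabetically first species as
references, so baseline contrasts read directly off β.  The country
intercept absorbs uneven geographic sampling.  Empty bin × species
cells drop their interaction columns; completely separated cells
(response constant at 0 or 1) are detected, their Wald inference is
suppressed, and contrasts involving them are skipped.

**Likelihood.**  The marginal likelihood integrates u_c per country.
`n_nodes = 1` (default) is the Laplace approximation — matching the
default of the standard GLMM toolchain — and `n_nodes > 1` uses
adaptive Gauss–Hermite quadrature centered and scaled at the
conditional mode.  Log-likelihoods are in Bernoulli form (no binomial
coefficients), so aggregating rows that share a design row and
country — done internally for speed — leaves the value unchanged.
The AGQ value at 25 nodes agrees with brute-force fixed-grid
integration to < 1e-6 (tested), and σ_u → 0 reduces to the ordinary
binomial GLM to < 1e-4 on all coefficients (tested against
statsmodels).

**Optimization.**  L-BFGS-B on (β, log σ_u) with an analytic gradient
of the Laplace objective (envelope identity at the inner mode plus
the implicit derivative of the log-determinant term; verified against
finite differences).  Inner modes by damped Newton (tolerance 1e-11,
≤ 100 iterations); outer tolerances ftol 1e-12 / gtol 1e-6, iteration
budget 500; starting values from the fixed-effects GLM with
σ_u = 0.5.  σ_u is bounded in [e⁻⁸, e⁴]; after convergence the σ_u = 0
boundary is checked explicitly and adopted if it attains a higher
likelihood.  The Wald covariance is the pseudo-inverse of the
numerical (central-difference) observed information in (β, log σ_u);
the pseudo-inverse leaves separated directions with zero variance,
which downstream code treats as suppressed.

**Marginal means and contrasts.**  Cell estimates are the link-scale
linear predictors at u = 0, ±1.96 SE, inverse-logit transformed.
Guild curves average member-species link predictions with equal
weight before back-transforming (a guild-presence model — presence of
any member — is available as a config switch; the equal-weight
average is the default because it is the direct summary of the fitted
species curves).  All pairwise bin contrasts within one taxon/guild
form a family; the familywise adjusted p is P(max|Z| ≥ |z|) under the
multivariate normal with the contrast correlation matrix, evaluated
by seeded Monte Carlo (100,000 draws; the seed derives
deterministically from the family label; a family of one contrast is
computed exactly and equals the unadjusted two-sided z-test).
Benjamini–Hochberg is reserved for cross-family collections such as
the dissimilarity bin-pair tests.

**Trend summaries.**  Overall change = first-vs-last bin contrast;
earliest significant change vs the Pleistocene baseline; peak = bin
with maximum fitted proportion; earliest post-peak bin significantly
below the peak.  α = 0.05 throughout, on Tukey-adjusted p-values.

## Residual diagnostics

Simulation-based scaled residuals: draw `n_sim` (default 1,000)
complete response vectors from the fitted model, re-drawing country
intercepts each simulation; the residual of an observation is its
randomized empirical quantile among its simulations,
(#below + U·#tied)/n_sim with U ~ Uniform(0,1) from a dedicated,
logged RNG stream — exactly 0 or 1 only when the observation falls
outside the simulated range.  Under a correct model residuals are
Uniform(0,1).  Pooled tests: exact Kolmogorov–Smirnov against
Uniform(0,1); a dispersion test comparing var(y − μ̂) with the
simulated variance distribution (two-sided simulated p, add-one
convention) — the variance-ratio form standard to simulated-residual
frameworks, since the source protocol does not define its statistic
precisely; and a binomial test of the count of residuals at exactly
0/1 against the per-row expectation 2/(n_sim + 1).

Calibration is verified with data simulated *at true parameters*
(200 countries × 2 Bernoulli rows, σ_u = 0.5, two bins) so the
observed vector is exchangeable with the simulations.  Cluster size
matters here: residuals within a country share its realized
intercept (intra-class correlation ≈ 0.1 at σ_u = 0.5), and the
pooled KS test assumes independence, so large clusters make it
over-reject even though each residual is marginally uniform — a
known property of simulation-based residuals with re-simulated
random effects.  Two rows per country keep the variance inflation
below ~10%, so the experiment measures the calibration of the
residual construction itself; diagnostics on strongly clustered
fits should be read with that caveat.  Power is verified with
beta-binomial
responses (ρ = 0.3, 7 trials — a guild-complement count per survey),
because overdispersion is not identifiable on pure Bernoulli rows.

## Dissimilarity and homogenization

Jaccard dissimilarity 1 − |A∩B|/|A∪B| over the 14 species groups;
pairs with an empty union are skipped (the index is undefined on two
empty communities), and the metric axioms are verified exhaustively
on a reduced 6-species alphabet.  Within each bin: all site pairs
within a country (countries need ≥ 2 sites; a single site yields no
pair), country means, then the equal-weight grand mean.  Bootstrap:
resample the n country means with replacement n times, B = 1,000
replicates; the interval is the 5th/95th empirical quantiles — a
nominally 90% interval, implemented exactly as the source protocol
prints it, with 2.5/97.5 available via `quantiles=(2.5, 97.5)`.
Permutation tests between bins act on country means (the unit of the
equal-weighting rationale; site-level permutation would re-weight
large countries), with a Welch t statistic for robustness to unequal
country counts, B = 1,000 reassignments, add-one p-values, and BH
adjustment over all C(bins, 2) pairs within a zone.

## Synthetic scenario

The generator draws presence as
Bernoulli(logit⁻¹(logit(anchor_{s,t}) + u_c + a_site)) with one RNG
stream per (country, bin) derived from the master seed, then applies
species-wise missing-completely-at-random unscoring (the real
database's uneven species scoring has no documented mechanism, so
MCAR is the default).  Ground truth (marginal occurrence
probabilities by Gauss–Hermite integration over u_c + a_site, guild
averages, peak bins) is returned alongside the records.

The default scenario encodes the reconstructed three-phase pattern:
Acropora high and stable through 1500–1959, collapsing in the
1960s bin; *Millepora*, stress-tolerant and weedy taxa rising from
the 1970s, peaking 1985–1994, then plateauing or declining; end
states span the observed modern mix of a few very common and several
rare taxa.  Its scale — 24 countries, 10 sites/country/bin before
1980 and 20 after (~4,100 surveys per zone), country intercept SD
0.5 — was fixed by a design-stage power analysis so that the
scenario's advertised signals (the 1960s competitive drop and the
final-vs-baseline homogenization contrast, ~0.12 against
country-mean scatter ~0.08) are recoverable in the large majority of
replicates, as the generator's contract requires.  Between-site
heterogeneity is a site-level logit intercept shared across species:
SD 1.1 in the historical bin, declining to 0.35 by the final bins
(the homogenization signal) and additionally halved in the two
fossil bins (time-averaging makes fossil assemblages more uniform,
reproducing their depressed dissimilarity).

What the generator does *not* emulate: detection differences between
fossil and modern data types beyond the variance effects above,
spatial autocorrelation within countries, non-random missingness,
abundance, and any ecological dynamics (disease, bleaching) — only
the observation record's statistical structure.  Passing recovery
tests therefore demonstrate that the pipeline extracts the patterns
the model family assumes, not that those assumptions hold for any
particular real dataset.

## Problem sizes and numerical conventions

The test suite uses the full default scenario for end-to-end
recovery (20 replicates) and deliberately small designs elsewhere
(30-survey likelihood oracles; 200 recovery fits of 550 rows;
200 calibration replicates at 480 rows with 250 simulations;
500 bootstrap and 1,000 permutation null replicates), chosen as the
smallest sizes at which the Monte-Carlo tolerances asserted are
meaningful.  Add-one conventions are used for all simulated p-values
(never exactly zero); Tukey Monte-Carlo p-values are floored at the
unadjusted p; percentage outputs in the trend table are rounded to
whole percent.

## Known limitations

* One random-effect level (country); no crossed or nested effects,
  no non-logit links, no Bayesian estimation.
* Laplace (1-node) likelihood has the usual small-cluster bias for
  binary data; raise `n_nodes` when clusters are small.
* Wald intervals on the logit scale; profile-likelihood intervals
  are not implemented.
* Paleo water-depth estimation is a pass-through (records carry the
  depth they were given); georeferencing and map rendering are out
  of scope.
* Externally compiled survey databases are supported through the
  documented CSV dialects but none is bundled; all shipped results
  are synthetic-scenario outputs.
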