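# reefchrono

Reconstructing 131,000 years of Caribbean reef-coral community change
from presence/absence survey records.

Caribbean reefs shifted, within a few mid-20th-century decades, from
communities dominated by fast-growing, branching, *competitive*
*Acropora* corals to communities of formerly subdominant
*stress-tolerant* and *weedy* scleractinians (plus the hydrozoan
*Millepora*).  Tracking that shift across fossil, historical and
modern surveys requires (i) aggressive harmonization of heterogeneous
occurrence records, (ii) occupancy-style trend models that respect
uneven geographic sampling, and (iii) a beta-diversity analysis that
asks whether communities within countries have *homogenized* over
time.  `reefchrono` implements that full pipeline as a tested,
reusable library plus CLI, with a synthetic-data generator (known
ground truth) standing in for the compiled survey database.

## What it computes

**Harmonization.**  Raw survey records (site, country, calendar year
or fossil age, depth/habitat, raw taxon names) are mapped onto 14
canonical species groups (synonym table shipped as editable CSV),
pooled into 11 ordered time bins from the Late Pleistocene
(~131,000–12,000 ybp) to 2005–2011, assigned to reef-crest (≈0–6 m)
or midslope (≈6–20 m) zones by deterministic depth/habitat/Acropora
rules, and reduced to one presence/absence row per survey (replicates
OR-combined).

**Occurrence trends.**  For each life-history guild *g* with member
species *s*, presence of species *s* at survey *i* in country *c* and
time bin *t* is modelled as a binomial GLMM

    y_i | u_c ~ Bernoulli( logit⁻¹( β_{t(i), s(i)} + u_c ) ),
    u_c ~ N(0, σ_u²),

with bin × species fixed effects (treatment coding, Pleistocene
baseline) and a country random intercept, fit by maximum likelihood
via the Laplace approximation or adaptive Gauss–Hermite quadrature
(the likelihood code is validated against brute-force numerical
integration).  Fitted per-bin occurrence proportions with 95% Wald
intervals, Tukey-style familywise-adjusted all-pairwise bin
contrasts, and a trend table (overall change, earliest significant
departure from the Pleistocene baseline, peak bin, earliest
significant decline from peak) follow.  Model adequacy is checked
with simulation-based scaled residuals (uniformity, dispersion and
outlier tests, 1,000 simulations by default).

**Homogenization.**  Within each time bin, Jaccard dissimilarity
(1 − |A∩B|/|A∪B|) is computed between all site pairs within each
country; country means are averaged with equal weight into a per-bin
grand mean (so heavily surveyed countries don't dominate), with
bootstrap 5th/95th-quantile intervals and permutation tests (1,000
iterations) for all bin pairs, Benjamini–Hochberg adjusted.

## Worked example

```python
from reefchrono import RunConfig, run_pipeline

report = run_pipeline(RunConfig(output_dir="out", seed=1))
print(report["_trends"].set_index("label").loc[
    ["competitive", "stress_tolerant", "weedy"],
    ["start_pct", "end_pct", "earliest_sig_change_vs_pleistocene", "peak_bin"],
])
```

On the default synthetic scenario (seed 1, reef crest, ~4,100
surveys, 24 countries) this prints:

```
                 start_pct  end_pct earliest_sig_change_vs_pleistocene    peak_bin
label
competitive             48       34                         B1960_1969    HOLOCENE
stress_tolerant         19       45                         B1970_1979  B1990_1994
weedy                   12       58                         B1960_1969  B1990_1994
```

i.e. the competitive guild (here including *Millepora*, whose own
rise masks part of the *Acropora* collapse) first departs
significantly from the Pleistocene baseline in the 1960s bin, while
stress-tolerant and weedy occurrence roughly doubles-to-quintuples,
peaking in the early 1990s — the three-phase pattern the generator
encodes.  The dissimilarity series
(`report["_dissimilarity"].table`) declines from a 1500–1959
baseline grand mean of 0.695 to 0.565 in 2005–2011
(Benjamini–Hochberg adjusted permutation p ≈ 0.003): communities
homogenized.

The same analyses are available from the shell:

```bash
reefchrono simulate --seed 1 --out surveys.csv
reefchrono trends --zone crest --millepora include --nodes 1 --input surveys.csv
reefchrono homogenization --zone crest --bootstrap 1000 --permutations 1000 --input surveys.csv
reefchrono run-all --zone crest --seed 1 --out results_dir
```

## Layout

| module | role |
| --- | --- |
| `taxa`, `binning`, `records`, `ingest` | harmonization: species groups, time bins, reef zones, replicate aggregation, CSV/YAML I/O |
| `life_history` | trait table, growth-rate terciles, guild assignment |
| `glmm`, `trends` | binomial mixed model (Laplace/AGQ), marginal means, Tukey contrasts, trend summaries |
| `diagnostics` | simulation-based scaled residuals and GOF tests |
| `dissimilarity` | Jaccard, country-equalized means, bootstrap, permutation tests, BH |
| `synthetic` | scenario generator with ground truth |
| `pipeline`, `cli` | orchestration and the `reefchrono` command |

See `docs/methods.md` for the statistical details and design choices.
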