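# Methods

## The statistical model

For one probe in one tissue the package fits, by ordinary least squares,

    beta_i = b0 + b1 * age_i + c' * z_i + e_i,

where `beta_i` is the methylation fraction of sample `i` (in [0, 1]),
`age_i` is chronological age in years entered untransformed, and `z_i` are
covariates. The age coefficient `b1` (beta units per year) is reported
together with its standard error and a two-sided P value from the t
distribution with `n_used − k` degrees of freedom. The percent convention
throughout is that the beta scale × 100 is "%", so an effect of x %/10yr
corresponds to `b1 = x / 1000` per year, and `slope_per_decade_pct` is
exactly `1000 × slope_per_year`.

A probe is called a **gain-aDMP** when `slope_per_decade_pct ≥ 2` and the
Bonferroni-adjusted P value `min(1, p·m)` is ≤ 0.05, with `m` the number of
probes actually tested in that tissue; **loss-aDMPs** use `≤ −2`. Both
thresholds are inclusive by default (a `strict_inequality` flag switches to
strict comparison); the inclusive reading was chosen because the effect-size
criterion is stated as "≥ 2%/10 years" in the catalogue this package
models, and boundary behaviour should be explicit rather than accidental.
Two calling modes exist: `dual` (both cut-offs) and `effect_only` (slope
cut-off alone), the latter removing the influence of per-tissue statistical
power. By construction `effect_only` calls are a superset of `dual` calls at
the same slope threshold, and calling is monotone in both cut-offs.

Design-matrix conventions: binary covariates enter as 0/1, categorical
covariates (e.g. a study/batch label) as reference-coded indicators, and
cell-fraction covariates as given, dropping the last column when they form a
simplex (sum to 1) to preserve full rank. A rank-deficient design raises an
error naming a collinear column rather than silently pseudo-inverting.
Missing betas are handled complete-case per probe; samples missing a
covariate are dropped globally with a logged count. A probe whose usable
sample count falls below `k + 2` (k = design columns) is marked `untested`
and excluded from the Bonferroni family `m` — the family is per analysis,
not a fixed array-wide constant, so family-wise error control refers to the
tests actually performed. Fits with numerically zero residual variance
(constant or exactly linear response, e.g. after clipping saturation) report
`se = 0, p = 0` as an explicit degenerate-fit convention.

The mass-fitting path solves all probes sharing a missingness pattern in one
batched pseudo-inverse solve; the test suite verifies it against an
independent route (explicit normal equations plus the t survival function,
and statsmodels OLS) to 1e-8 relative on random problems.

## Specificity statistics

Gain and loss aDMPs are stratified throughout (a probe gaining in one tissue
and losing in another appears in both direction tables, flagged
`discordant`). For each direction, the specificity table maps every probe
called in ≥ 1 tissue to the set of tissues where it passed the criteria;
`percent_tissue_specific` is the share with a singleton tissue set, reported
half-up to one decimal (full precision retained internally). The overlap
matrix counts pairwise intersections off-diagonal; the diagonal counts
probes unique against **all** other tissues, matching the "unique" notion of
the sharing analysis rather than a pairwise one. The relaxed-significance
check asks, for every (aDMP, non-calling tissue) pair with a testable fit,
whether the raw P is below 0.001 with a same-sign slope — a weak-shared-
effect probe will light up here without passing the full criteria. Region
aggregation (CpG islands, nearest genes) takes the union of member-probe
tissue sets, so a region's sharing can only be as large or larger than any
member probe's; probes untested in a tissue count as "not called" there for
specificity but are excluded from relaxed-check denominators.

## Annotation and enrichment

Coordinates are 0-based half-open internally; BED inputs are taken as such
and 1-based probe-manifest positions are shifted on ingestion. CGI classes
partition probes into `island` (inside a merged island), `shore` (within
2 000 bp of an island boundary coordinate, inclusive at exactly 2 000 bp)
and `non_CGI`. Chromatin states come from a 15-label segmentation
(TssA, TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, ZNF/Rpts, Het, TssBiv,
BivFlnk, EnhBiv, ReprPC, ReprPCWk, Quies) that must tile each tissue's
genome; a probe exactly on a boundary belongs to the interval beginning
there. The EZH2 flag is overlap with any interval of a single union track
(binding observed in any cell type), not a per-tissue annotation. Nearest
genes minimise the distance to the closer of the gene's two ends (the
5'/3' labels depend on strand but the minimum does not); ties break to the
smaller distance then the lexicographically smaller gene id, making the
mapping deterministic.

Enrichment of an aDMP set in a category uses the 2×2 table over the
tested-probe background of that tissue — aDMPs of the opposite direction
remain in the background (the natural "all tested probes" universe). The
odds ratio is `(a·d)/(b·c)`, with +0.5 added to every cell only when some
cell is zero; the test statistic is the 1-df Pearson chi-squared on the raw
counts without continuity correction, matching a plain chi-squared test
while remaining defined on sparse tables. Within a 15-state profile the
significance flag is Bonferroni-corrected over the 15 tests (raw P always
reported); single-category tests flag at p ≤ 0.05. Tables with an empty or
universal category are flagged degenerate instead of producing an infinite
odds ratio. The joint CGI × EZH2 analysis restricts the background to
probes carrying at least one of the two annotations and contrasts the
doubly-annotated stratum against each single-annotation stratum and their
union, asking whether the two enrichments are one underlying signal.

## The synthetic-data generator

The generator emulates the structure of a multi-tissue 450k compendium —
seven tissues with unequal sample sizes (96–1202 in the default cohort:
brain 380, buccal 96, liver 147, kidney 171, subcutaneous fat 648,
monocytes 1202, T-helper cells 214) and unequal age ranges (buccal 1–28 up
to brain 0–97), with a female-only fat cohort, a multi-batch liver cohort
and cell-fraction covariates for the blood-derived tissues.

**Genome.** Probes are laid on a few chromosomes with 300–5000 bp gaps.
CpG islands are realised as runs of consecutive probes totalling an exact
target fraction (default 0.30, the array's CGI bias), so island/shore
geometry is meaningful; islands are EZH2-bound with probability 0.5 against
a 5% background, making the CGI∩EZH2 stratum about 15% of probes.
Segmentations tile each chromosome per tissue with state runs (weights
favouring quiescent/weak states). Everything derives from one seed and is
bit-identical across runs.

**Effects.** Planted effects have slope magnitudes drawn uniformly from a
configured %/10yr range (default 2–8), a direction, and a sharing class —
tissue-specific, k-shared (k uniform in 2..T−1) or universal (same-sign
slope in all tissues, the ELOVL2-like pattern; at least one universal gain
is planted whenever its proportion is positive). Sharing proportions are
realised exactly by largest-remainder rounding; the defaults (gain
0.85/0.13/0.02, loss 0.974/0.026/0) mirror the observed catalogue. Placement
is annotation-biased: gain effects prefer CGI∩EZH2 probes and loss effects
enhancer-state non-CGI probes of their home tissue, with configurable odds
(default 5). The in-category count is drawn from Fisher's noncentral
hypergeometric distribution so the realised placement odds ratio
concentrates at the configured value — sequential weighted sampling would
systematically undershoot it.

**Cohorts.** Ages are uniform within each tissue's range (real cohorts are
not uniform; uniformity maximises design clarity for recovery tests).
Baseline levels per probe follow the 450k bimodality by CGI class
(islands low, non-CGI high; truncated to [0.1, 0.9] so planted effects stay
recoverable), and are shared across tissues. The observation model is
additive Gaussian on the beta scale with clipping to [0, 1] (a logit-normal
residual is available as an option, default off); clipping bias near the
boundaries is accepted. By default a planted probe sits at its drawn level
at the tissue's mid-cohort age (the intercept is `level − slope·age_mid`),
which keeps multi-decade effects inside the unit interval; `effect_anchor =
"zero"` makes the level the literal age-0 intercept. Covariate effects
(sex, batch, cell fractions) are additive with small per-probe coefficients
(defaults 0.005–0.01 beta units). Missingness is completely at random,
capped so every probe retains ≥ 90% of samples. Probes are simulated
independently; the local co-methylation of neighbouring CpGs in real arrays
is **not** emulated, so passing recovery tests demonstrates correctness of
the statistics, not robustness to spatially correlated noise, batch
structure beyond the modelled covariates, or array normalisation artefacts.

## Orchestration and reproducibility

The pipeline runs simulate (optional) → call (dual, plus optional
effect-only and equal-N variants) → specificity → annotate/enrich → report,
writing every stage's tables before the next begins; the report is
recomputable from the persisted TSVs. One global seed fans out to per-stage
seeds via a fixed SHA-256 schedule (all derived seeds < 2³¹), so stages are
individually reproducible and a rerun with the same config and seed yields
a byte-identical report. Equal-N subsampling derives its stream from
(seed, tissue label), making selections deterministic per tissue and
order-independent.

## Problem sizes used in verification

The automated checks run at desk scale, chosen to give the assertions
adequate statistical resolution: 1 000 random problems for OLS oracle
equivalence (1e-8 relative); 40 pure-null replicates of 5 000 probes at
n = 100 for P-value uniformity (pooled Kolmogorov–Smirnov, α = 0.01) and
family-wise error control (≥ 95% clean replicates minus 3σ binomial
tolerance); 20 seeded replicates at n = 300, residual sd 0.03 and planted
slopes ≥ 3%/10yr for sensitivity (≥ 0.90, zero false calls) and for
recovery of planted specific fractions (0.85, 0.97) and placement odds
ratios (2 and 5, recovered within the 20-seed interquartile range); and
10 000 random probes for interval-machinery oracle equivalence. The
acceptance script reuses these conditions at single-replicate scale plus a
5-replicate median for the odds ratios.

## Known limitations

- No normalisation, batch correction, cell-type deconvolution or nonlinear
  age models: covariates are taken as provided and age enters linearly.
- Independent-probe simulation (above) understates the effective
  correlation of real epigenome-wide statistics.
- The Bonferroni family is per tissue after missingness filtering; analyses
  pooling tissues should correct accordingly.
- Enrichment P values are asymptotic (chi-squared); for very sparse tables
  an exact test would be preferable, but the package keeps the plain
  chi-squared to match the analysis it reimplements.
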