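# Methods

## Data model and replicate pooling

Observations enter as long-format rows (region, meadow, time, replicate,
species, count). Counts are validated as non-negative integers and a
duplicated (meadow, time, replicate, species) key is an error rather
than an implicit sum, because a duplicate almost always indicates a
data-entry problem. All meadows share one declared, ordered time axis;
when it is not given explicitly it is the numerically sorted set of
observed times (order of first appearance for non-numeric labels).

Replicate quadrats collected at the same time are pooled by **summing
counts**, which is the union on the incidence scale. The field protocol
being emulated collects five 0.0625 m² quadrats per time; a single
composition vector per time is what the multiple-site statistics
consume, and summation is the only pooling rule that preserves every
detected species. Conversion to densities
(`counts / (n_replicates × area)`) is available but off by default:
presence/absence and Bray–Curtis ratios are invariant to that constant
factor, so standardization matters only for reporting abundances per m².

Presence defaults to *strictly positive abundance*; counts are integers
and no detection limit is modelled. An explicit threshold switches to
`abundance ≥ threshold`. A time with no observations is kept as an empty
assemblage (with a warning) rather than silently dropped — removing it
would change T and, with it, every pairwise sum; an empty time
legitimately contributes nestedness. A meadow needs at least two
non-empty times to be partitioned at all.

## Multiple-site dissimilarity

The incidence statistics are the multiple-site Sørensen family: the sums
`Σ_{i<j} min(b_ij, b_ji)`, `Σ_{i<j} max(b_ij, b_ji)` and
`Σ_i S_i − S_T` are accumulated as exact integers and divided only once,
so the additive identity β_SNE = β_SOR − β_SIM is exact by construction
and the results are bit-stable across platforms. At T = 2 the statistics
reduce to the pairwise Sørensen and Simpson dissimilarities, which the
tests assert.

On abundances, the pairwise Bray–Curtis dissimilarity is
`1 − 2Σ_k min(x_ik, x_jk) / Σ_k (x_ik + x_jk)`. (The similarity ratio
`Σmin/Σ(x_i+x_j)` — which equals 0.5 for identical assemblages — is
sometimes printed as if it were the dissimilarity; values "close to 1"
meaning "high temporal variability" requires the form used here.) The
multiple-site generalization mirrors the incidence construction with
shared abundance `A_ij = Σ_k min(x_ik, x_jk)` and exclusive abundances
`B_ij = Σ_k x_ik − A_ij`:

    BC_total = (Σmin B + Σmax B) / (2 ΣA + Σmin B + Σmax B)
    BC_bal   = Σmin B / (ΣA + Σmin B)
    BC_gra   = BC_total − BC_bal

`BC_bal` captures balanced variation (substitution of individuals of
some species by others), `BC_gra` unidirectional abundance gradients.
Note the `2ΣA` in the total's denominator: it is what makes the T = 2
case collapse to the pairwise index, the abundance analogue of the
`2(Σ S_i − S_T)` term on the incidence side.

A comparison of two entirely empty assemblages is defined as 0 with a
warning (keeping pipelines total); a series whose every time is empty is
an error, since no meaningful statistic exists.

## Driver analysis

Each meadow is one observation. Habitat-structure predictors enter as
temporal coefficients of variation (sample SD with n−1 denominator over
the mean, × 100; an error when the mean is non-positive), climate
predictors as temporal means — variability of the habitat, level of the
climate.

*Screening.* Spearman ρ is computed for every predictor pair; while any
retained pair has ρ² > 0.6 (|ρ| > 0.775), the member lower in a
user-supplied priority order is dropped. The default priority — leaf
biomass, cover, shoot density, epiphytic load, SST, PAR — encodes
"habitat structure before climate"; which member of a correlated pair is
more biologically meaningful is inherently a judgement call, so it is
explicit configuration rather than something inferred from data.
Constant columns are dropped with a warning (ρ undefined).

*Fitting.* Models are Gaussian with identity link — ordinary least
squares — even though the responses live in [0, 1]: with nine sites the
responses sit well inside the interval, OLS supports the adjusted R²,
F and Breusch–Pagan summaries this analysis reports, and it is the
convention for these dissimilarity summaries. A logit-link
quasi-binomial family is available behind `family="quasibinomial"` for
responses near the boundary. The reported per-term statistic is the OLS
t statistic (labelled `stat`); with n = 9 a normal-approximation z would
be inappropriate.

*Selection.* AICc uses k = slopes + intercept + dispersion, i.e.
k = p + 2, with correction `2k(k+1)/(n−k−1)` (infinite when n ≤ k + 1,
which simply ranks such models last). Every subset of the retained
predictors up to `max_size = 5` plus the intercept-only model is fitted;
Akaike weights are `exp(−Δ/2)` normalized, and a predictor's relative
importance is the sum of the weights of models containing it
(sum-of-weights; no coefficient averaging). Backward stepwise removal is
run as a cross-check and asserted never to beat the exhaustive minimum.
Ties within 1e−10 of AICc prefer fewer parameters, then lexicographic
predictor order — determinism over arbitrary library ordering. With nine
observations and up to five predictors the larger models are legal but
fragile; the fitter warns when fewer than three residual degrees of
freedom remain rather than refusing.

*Diagnostics.* The Breusch–Pagan test is the studentized form: n·R² from
regressing squared residuals on the model's predictors, against χ² with
p degrees of freedom. Degenerate (constant) residuals return statistic 0,
p = 1. No multiple-testing correction is applied across the four
responses; the reports note this.

## Synthetic studies

The generator emulates the monitoring design: 3 regions × 3 meadows ×
9 seasonal times × 5 replicate quadrats, a regional pool of 50 species,
15 residents per time. Two incidence processes act per time step:

- **replacement** — a Binomial(richness, r) subset of residents swaps
  for uniformly drawn non-resident pool species, keeping richness
  constant (so pure-replacement series have β_SNE = 0 exactly);
- **ordered loss** — a Binomial(richness, ℓ) number of residents is
  removed in a fixed random nesting order (so pure-loss series are
  perfectly nested chains with β_SIM = 0). Default ℓ = 0.02, a small
  nestedness background as observed in most real meadows.

Abundances follow a lognormal species-abundance distribution
(log-mean 1, log-sd 1, truncated to ≥ 1 individual) with AR(1)
persistence ρ = 0.5 of the log-abundance across times; replicates are
equal-effort multinomial splits of each time's totals. Habitat
predictor series are positive series with prescribed per-meadow CVs
(a standardized normal shape scaled to the target CV, floored at 5% of
the mean — realized CVs are recorded in the truth output); SST and PAR
are seasonal sinusoids with region-specific baselines.

The driver signal couples each meadow's replacement rate to its realized
leaf-biomass CV: `r = clip(0.65 − 0.01·CV + ε)`, ε ~ N(0, 0.03), CV
targets spread evenly over 10–60%. This maps to per-step replacement
rates of roughly 0.05–0.55 and yields generated β_SIM values spanning
about 0.4–0.8 across meadows — bracketing the 0.50–0.77 range observed
in the motivating study. The negative slope encodes the study's
finding that *stable* meadows show *higher* turnover. Everything is
reproducible from the scenario seed (per-meadow generators are spawned
from (seed, meadow index), so meadows are independent streams).

What the generator does **not** emulate: spatial structure within a
meadow (replicates are exchangeable multinomial thinnings, so
between-replicate variance is at its binomial floor), species traits or
interactions, abundance-driver coupling (only the incidence process is
coupled to a predictor), observation error in the predictors, and
seasonality of the assemblage itself. Passing tests therefore
demonstrate that the statistics and the inference chain recover known
structure under idealized sampling — not that nine meadows give the
driver analysis high power against weak real-world effects.

## Problem sizes and numerical choices

The test suite and the reproduction script run the oracle comparison on
1,000 random matrices (T ≤ 5, K ≤ 8), the driver-recovery and null
experiments on 20 simulated studies each at the full 3 × 3 × 9 × 5
design, monotonicity checks at 5 rate levels × 20 replicate meadows, and
the Breusch–Pagan size check on 500 homoskedastic replicates of n = 200
— sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo noise far from the asserted margins. Incidence
arithmetic is exact-integer up to the final division; oracle agreement
is asserted to 1e−12, and OLS coefficients are cross-checked against
normal equations to 1e−8.

## Known limitations

- The multiple-site statistics summarize one meadow's whole series; no
  sliding-window or pairwise-over-time trajectories are provided.
- With nine observations the driver models are descriptive: AICc
  rankings are reported, but five-predictor models carry one residual
  degree of freedom and their weights are correspondingly tiny.
- No mixed-effects or spatial autocorrelation structure; regions enter
  only through the generator, not the inference.
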