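# Methods

## Signature scoring model

Expression is standardized per gene across the whole cohort,
z = (x − μ)/σ, with σ the sample standard deviation (n−1 denominator).
Nothing in the score definition fixes the denominator convention; n−1 is
the conventional choice for cohort expression z-scores and is configurable
(`ddof`). A log2(x+1) transform precedes standardization by default because
the intended input is abundance-scale (RPKM/TPM-like); switch
`log_transform` off for data already on a log scale. The two conventions
give different scores and the package does not try to auto-detect the
scale.

A signed signature scores sample *i* as Σ z over its up-set minus Σ z over
its down-set. Consequences used as test oracles throughout:

- each z row sums to 0 over the cohort, so each signature's scores sum to 0
  (to machine precision scaled by genes × samples);
- swapping up- and down-sets negates every score;
- scores are invariant to gene/sample order;
- raising one up-set gene's expression in one sample strictly raises that
  sample's score (n > 2).

**Degenerate genes.** A gene constant across the cohort has σ = 0; its z
row is set to 0 and flagged rather than dropped, keeping matrix shapes
stable and making such genes exact no-ops in any signature. Constancy is
detected by zero range, not by the computed σ, because floating-point
summation can leave an O(1e-16) residual SD on an exactly constant row,
which would otherwise blow up the division.

**Missing signature genes** are intersected away with a recorded coverage
fraction (warned below 0.5); only a zero overlap is an error. Real-world
signature lists rarely match an arbitrary annotation exactly, and silently
renormalizing would change the score's scale.

**Cohort boundaries.** μ and σ are statistics of the scoring cohort.
Transforming samples outside the fitted cohort is refused unless
`allow_out_of_cohort=True`, because scoring a held-out subset against
another cohort's μ/σ changes what the score means.

**Segregation and dichotomization.** Sample ranking is by descending score;
the two-state segregation threshold defaults to 0 (a z-sum contrast is
centered at 0). Ties at the threshold go to "low" and are logged.
Single-gene dichotomization uses z ≥ 1 for "high" by default — high
expression means high z; both thresholds are configurable.

## Inferential layer

- **Pearson correlation** (scipy): two-sided p from
  t = r·√((n−2)/(1−r²)) on n−2 df; constant inputs are an error.
- **Fisher's exact test**, two-sided, is computed in-package with exact
  integer arithmetic: p is the sum of hypergeometric probabilities (over
  all tables with the observed margins) not exceeding the observed table's
  probability. Integer comparison of the binomial-product numerators makes
  probability ties exact rather than float-dependent; scipy's
  implementation is used as an independent cross-check in the tests. The
  odds ratio is the sample (a·d)/(b·c), reported as inf when b·c = 0 with
  a·d > 0 and as undefined (null) for 0/0.
- **Mutual exclusivity** builds the 2×2 high/low table of two markers,
  reports the high∧high cell, and attaches the Fisher result; "exclusive"
  is the descriptive statement that no sample is high for both. The Fisher
  p quantifies association, not exclusivity per se — a non-significant p is
  reported as-is and not interpreted.
- **Group comparison** is Welch's unequal-variance t-test (the safer
  default when group variances are unknown). Degenerate zero-variance
  inputs resolve by means (equal → t=0, p=1).
- No multiple-testing correction is applied anywhere; reports carry raw
  p-values and say so explicitly.

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test (standard
hypergeometric variance, 1-df chi-square, no weighting or stratification)
are delegated to lifelines behind the module surface; tests pin them to
hand-computed product-limit values, the ECDF complement in the absence of
censoring, and power/type-I simulations. Median survival is the smallest
event time with S(t) ≤ 0.5, "not reached" when the curve stays above.

Stratification rules:

- **Geometric-mean split**: gm = exp(mean(log(x + ε))); strictly above →
  "high", strictly below → "low", exact ties → "high" (deterministic,
  logged). The pseudocount ε defaults to 0 and zeros are an error, because
  the split is meant for positive intensity-scale data; set ε > 0 for
  RNA-seq zeros. With ε = 0 the split is invariant to positive rescaling.
- **Score quadrants**: samples are labelled ++, +−, −+, −− by the signs of
  two scores relative to thresholds (default 0,0; at-threshold counts as
  +), and the ++ vs −− contrast feeds the log-rank test. An empty contrast
  arm is an error rather than a silent skip.

## Synthetic cohort generator

The generator produces the structure the analysis assumes, with planted
ground truth, and is itself first-class tested code.

Per sample: a latent binary precursor state s ~ Bernoulli(prevalence,
default 27/57 progenitor-like in a 57-sample cohort); latent STAT3 and EMT
activities from a unit-variance bivariate normal with correlation
`pathway_coupling` (default 0.5), both shifted upward by
`activity_state_shift` (default 0.5 SD) in progenitor-like samples. Per
gene: log2-expression = baseline (N(5, 2)) + aligned effect + N(0,
noise_sd). State-aligned blocks (stem, progenitor, proneural, mesenchymal,
SLUG-up, SLUG-down) shift by `effect_size` × noise_sd between states with
the biologically motivated orientations (progenitor ↔ mesenchymal ↔
SLUG-induced); STAT3/EMT blocks scale with their latent activity.
Abundance is 2^log-expression, so the matrix is log-normal and strictly
positive, matching the scorer's default log2(x+1) handling. Default
cardinalities mirror the real signatures (68/68, 151/198, 57, 64, 90/90)
over 1000 pure-noise background genes.

Outcomes: survival is exponential with log-hazard
`hazard_log_multiplier` × latent progenitor activity (activity = state
contrast plus mean pathway activity), baseline scale 400 days; a sample is
censored with probability `censoring_rate` (default 0.3) at a uniform
fraction of its event time. Recurrence labels follow a logistic link on
standardized activity with slope `recurrent_score_shift` (default 1.5) and
base rate `recurrent_fraction` (default 0.25), so enrichment of recurrent
lines among high-scoring samples is probabilistic, not a hard threshold.

Calibration choices (no empirical effect sizes exist for the real cohort):
effect_size 1.0 within-gene SD is a clearly detectable but not separable
single-gene effect whose aggregate over ~136 genes cleanly separates the
states; hazard_log_multiplier 1.0 corresponds to a hazard ratio of ~e per
SD of latent activity, a strong but plausible effect for an
aggressiveness axis. The null generator zeroes every effect
(effect_size, coupling, state shift, hazard slope, recurrence slope) while
keeping the sampling machinery, giving exact negative controls.

**Coupling recovery and the state confound.** When
`activity_state_shift` > 0 the shared state component adds
(shift²·p(1−p))/(1 + shift²·p(1−p)) ≈ +0.06 to the STAT3–EMT score
correlation on top of the planted coupling. Recovery checks therefore run
with the shift disabled to isolate the coupling term; with the default
shift the measured correlation is expected to sit slightly above the
planted value.

What the generator does **not** emulate: real GBM expression distributions,
platform mixtures (microarray vs RNA-seq), batch effects, gene–gene
correlation beyond the planted blocks, or cross-cohort harmonization.
Passing tests demonstrate that the pipeline's operations are correct and
calibrated under the stated model, not that the biological signatures
themselves are valid in new data.

Randomness is a single seed feeding a hierarchical `SeedSequence` stream
(genes / samples / noise / outcomes), so cohorts are bit-reproducible.

## Pipeline

Stages run in fixed order (inputs → scoring → ranking → correlations →
exclusivity → group comparison → survival → report); a failure aborts with
an error naming the stage. The JSON report validates against
`report_schema.json` (shipped in the package, checked by a minimal
in-package validator) and carries a provenance block — package version,
seed, and a SHA-256 hash of the analysis-relevant config (the output
directory is excluded so identical analyses hash identically). Reports
contain no timestamps, making re-runs byte-identical.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 200 random matrices up to
500×100 for standardization; all 2×2 tables with margins ≤ 12 (5,550
tables) for the Fisher oracle; 100 datasets for the KM/ECDF oracle; 200
simulations each for log-rank power (n = 200/arm, hazard ratio 3), type-I
calibration (57-sample null cohorts), and mutual-exclusivity direction;
100 seeds at n = 60 for state recovery; and n = 500 for coupling recovery.
These sizes give simulation standard errors comfortably inside the asserted
bands (e.g. ±1.5% on a 5% rejection rate at 200 runs).
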