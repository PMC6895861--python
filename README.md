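# sigscore

Cohort z-score gene-signature scoring and downstream cohort statistics for
bulk expression data, built around the signature-contrast analyses used to
characterize glioblastoma (GBM) brain-tumor stem-cell (BTSC) cohorts: the
stem-like → progenitor-like precursor-state axis, the proneural →
mesenchymal subtype axis, STAT3 target-gene activity, a multi-cancer EMT
(epithelial–mesenchymal transition) signature, and a SLUG-overexpression
transcriptional program.

## Who this is for

Computational biologists who have a gene × sample abundance matrix
(RPKM/TPM-like TSV), gene signatures in GMT format, and sample annotations,
and who want reproducible signature scores plus the standard inferential
layer on top: score correlations, marker mutual-exclusivity testing, and
survival stratifications. A built-in synthetic-cohort generator plants
known structure so every stage can be validated without any external data.

## The score

For gene *g* and sample *i*, expression is standardized across the whole
cohort:

    z_gi = (x_gi − μ_g) / σ_g

with μ_g the cohort mean and σ_g the cohort standard deviation (n−1
denominator) of gene *g*, optionally after a log2(x+1) transform (the
default for abundance-scale input). A signed signature with an up-set U and
a down-set D then scores each sample as

    score_i = Σ_{g∈U} z_gi − Σ_{g∈D} z_gi .

One-sided signatures (e.g. the 57-gene STAT3 target score, the 64-gene EMT
score) use only the up-set sum. Because each z row sums to zero across the
cohort, every signature's scores also sum to zero: the score is a
within-cohort contrast, not an absolute activity. Downstream analyses are
Pearson correlations between scores (two-sided t reference), two-sided
Fisher's exact tests of marker mutual exclusivity on z-dichotomized genes,
Welch t comparisons between sample groups, and Kaplan–Meier / log-rank
survival contrasts using either a geometric-mean expression split or
STAT3/EMT score-sign quadrants. All p-values are reported raw; no
multiple-testing correction is applied.

## Worked example

Run the full pipeline on a synthetic 57-sample cohort with the default
planted structure and render the report:

```sh
python -c "
import sigscore as ss
cfg = ss.PipelineConfig(generator=ss.GeneratorConfig(), seed=11, output_dir='demo')
ss.run_pipeline(cfg)
"
sigscore report demo/report.json
```

which prints (abridged):

```
sigscore 0.1.0 report (seed 11, config 06004f533067)
ranking by stem_progenitor: 29 high / 28 low (threshold 0.0)
  corr stem_progenitor ~ proneural_mesenchymal: r=+0.983 (n=57, p=5.92e-42)
  corr STAT3 ~ EMT: r=+0.569 (n=57, p=3.82e-06)
  corr stem_progenitor ~ SLUG_OE: r=+0.975 (n=57, p=1.13e-37)
  exclusivity SLUGUP_0001 / SLUGDN_0001: co-occurrence=1, p=0.672
  SLUG_OE by primary_or_recurrent: means -15.29 vs 26.21, t=-1.93, p=0.0609
  quadrant STAT3/EMT: sizes {'++': 20, '+-': 8, '-+': 6, '--': 23}, log-rank p=1.15e-06
p-values are raw (no multiple-testing correction)
```

Reading this: the segregation at score 0 splits the cohort 29/28 into
progenitor-like ("high") and stem-like samples, recovering the planted
latent states; the precursor-state score correlates strongly with the
proneural→mesenchymal and SLUG-overexpression scores because all three are
driven by the same latent state; the STAT3–EMT correlation (r = 0.57)
reflects the planted pathway coupling of 0.5 plus the state co-activation;
and patients in the STAT3⁺/EMT⁺ quadrant die significantly earlier than
STAT3⁻/EMT⁻ patients because the generator ties the hazard to the latent
pathway activity. The same machinery runs on real data via
`sigscore score --expression expr.tsv --gene-sets sets.gmt --out scores.tsv`
or a file-based `sigscore analyze` config.

The CLI also exposes `sigscore simulate` (write a synthetic cohort's
expression/annotations/GMT files) and `sigscore analyze --config cfg.yaml`
(full pipeline: `scores.tsv`, `report.json`, `survival_curves.tsv`,
`run.log`).

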