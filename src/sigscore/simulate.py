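"""Synthetic expression cohorts with planted signature structure.

The generator emulates the statistical structure the scoring analysis
assumes: a cohort of tumor stem-cell lines drawn from two latent precursor
states (stem-like vs progenitor-like), log-normal gene abundances whose
signature genes shift with the state or with correlated latent pathway
activities (STAT3, EMT), exponential survival whose log-hazard is linear in
the latent progenitor activity, and recurrence labels enriched among
high-activity samples through a logistic link.

Default cardinalities mirror the real signatures the pipeline is built for:
136 stem/progenitor genes (split 68/68), 151 proneural + 198 mesenchymal
genes, 57 STAT3 target genes, 64 mesenchymal-transition (EMT) genes, and 180
SLUG-overexpression genes (split 90/90), in a default cohort of 57 samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSet, SignatureDefinition

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_gene_sets",
    "generate_null_cohort",
]

# signature name -> (config cardinality field(s), latent driver)
STEM_PROGENITOR = "stem_progenitor"
PRONEURAL_MESENCHYMAL = "proneural_mesenchymal"
STAT3 = "STAT3"
EMT = "EMT"
SLUG_OE = "SLUG_OE"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``effect_size`` is the mean log2-expression shift of a state-aligned gene
    between the two precursor states, in units of the within-gene residual SD
    (``noise_sd``). ``pathway_coupling`` is the latent correlation between
    STAT3 and EMT activities; ``activity_state_shift`` is the mean activity
    elevation (in activity SD units) in progenitor-like samples. Survival is
    exponential with ``survival_scale_days`` baseline scale and log-hazard
    ``hazard_log_multiplier`` per unit latent progenitor activity.
    """

    n_samples: int = 57
    n_background_genes: int = 1000
    n_total_genes: int | None = None  # optional cap on the whole gene universe
    n_stem_genes: int = 68
    n_progenitor_genes: int = 68
    n_proneural_genes: int = 151
    n_mesenchymal_genes: int = 198
    n_stat3_genes: int = 57
    n_emt_genes: int = 64
    n_slug_up_genes: int = 90
    n_slug_down_genes: int = 90
    state_prevalence: float = 27 / 57  # probability of the progenitor-like state
    effect_size: float = 1.0
    activity_state_shift: float = 0.5
    pathway_coupling: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    survival_scale_days: float = 400.0
    hazard_log_multiplier: float = 1.0
    censoring_rate: float = 0.3
    recurrent_fraction: float = 0.25
    recurrent_score_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        counts = {
            "n_samples": self.n_samples,
            "n_background_genes": self.n_background_genes,
            "n_stem_genes": self.n_stem_genes,
            "n_progenitor_genes": self.n_progenitor_genes,
            "n_proneural_genes": self.n_proneural_genes,
            "n_mesenchymal_genes": self.n_mesenchymal_genes,
            "n_stat3_genes": self.n_stat3_genes,
            "n_emt_genes": self.n_emt_genes,
            "n_slug_up_genes": self.n_slug_up_genes,
            "n_slug_down_genes": self.n_slug_down_genes,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v <= 0:
                errors.append(f"{name} must be a positive integer, got {v!r}")
        for name, v in (
            ("state_prevalence", self.state_prevalence),
            ("censoring_rate", self.censoring_rate),
            ("recurrent_fraction", self.recurrent_fraction),
        ):
            if not 0.0 < v < 1.0:
                errors.append(f"{name} must lie in (0, 1), got {v!r}")
        if not -1.0 < self.pathway_coupling < 1.0:
            errors.append(
                f"pathway_coupling must lie in (-1, 1), got {self.pathway_coupling!r}"
            )
        if self.noise_sd <= 0:
            errors.append(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if self.effect_size < 0:
            errors.append(f"effect_size must be >= 0, got {self.effect_size!r}")
        if self.survival_scale_days <= 0:
            errors.append(
                f"survival_scale_days must be > 0, got {self.survival_scale_days!r}"
            )
        if self.baseline_sd < 0:
            errors.append(f"baseline_sd must be >= 0, got {self.baseline_sd!r}")
        if self.n_total_genes is not None and self.n_total_genes <= 0:
            errors.append(f"n_total_genes must be positive, got {self.n_total_genes!r}")
        if errors:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(errors))

    @property
    def n_signature_genes(self) -> int:
        return (
            self.n_stem_genes
            + self.n_progenitor_genes
            + self.n_proneural_genes
            + self.n_mesenchymal_genes
            + self.n_stat3_genes
            + self.n_emt_genes
            + self.n_slug_up_genes
            + self.n_slug_down_genes
        )

    def effective_background(self) -> int:
        """Background (pure-noise) gene count, honoring ``n_total_genes``."""
        if self.n_total_genes is None:
            return self.n_background_genes
        background = self.n_total_genes - self.n_signature_genes
        if background < 0:
            raise ValueError(
                f"signature cardinalities ({self.n_signature_genes}) exceed the "
                f"gene universe (n_total_genes={self.n_total_genes})"
            )
        return background


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted ground truth."""

    expression: pd.DataFrame  # genes x samples, non-negative abundances
    annotations: pd.DataFrame  # indexed by sample_id
    signatures: list[SignatureDefinition]
    latent: pd.DataFrame  # per-sample: state, stat3/emt activity, progenitor activity
    config: GeneratorConfig = field(repr=False, default=None)


def _gene_blocks(config: GeneratorConfig) -> dict[str, list[str]]:
    def names(prefix: str, n: int) -> list[str]:
        return [f"{prefix}_{i + 1:04d}" for i in range(n)]

    return {
        "stem": names("STEM", config.n_stem_genes),
        "progenitor": names("PROG", config.n_progenitor_genes),
        "proneural": names("PN", config.n_proneural_genes),
        "mesenchymal": names("MES", config.n_mesenchymal_genes),
        "stat3": names("STAT3T", config.n_stat3_genes),
        "emt": names("EMTG", config.n_emt_genes),
        "slug_up": names("SLUGUP", config.n_slug_up_genes),
        "slug_down": names("SLUGDN", config.n_slug_down_genes),
        "background": names("BG", config.effective_background()),
    }


def generate_gene_sets(config: GeneratorConfig) -> list[SignatureDefinition]:
    """The five planted signatures at the configured cardinalities.

    Blocks are pairwise disjoint; membership is exactly the set of genes that
    carry the planted effects in :func:`generate_cohort`.
    """
    blocks = _gene_blocks(config)

    def gs(name: str, genes: list[str]) -> GeneSet:
        return GeneSet(name=name, genes=tuple(genes))

    return [
        SignatureDefinition(
            name=STEM_PROGENITOR,
            up_set=gs(f"{STEM_PROGENITOR}_up", blocks["progenitor"]),
            down_set=gs(f"{STEM_PROGENITOR}_down", blocks["stem"]),
        ),
        SignatureDefinition(
            name=PRONEURAL_MESENCHYMAL,
            up_set=gs(f"{PRONEURAL_MESENCHYMAL}_up", blocks["mesenchymal"]),
            down_set=gs(f"{PRONEURAL_MESENCHYMAL}_down", blocks["proneural"]),
        ),
        SignatureDefinition(name=STAT3, up_set=gs(f"{STAT3}_up", blocks["stat3"])),
        SignatureDefinition(name=EMT, up_set=gs(f"{EMT}_up", blocks["emt"])),
        SignatureDefinition(
            name=SLUG_OE,
            up_set=gs(f"{SLUG_OE}_up", blocks["slug_up"]),
            down_set=gs(f"{SLUG_OE}_down", blocks["slug_down"]),
        ),
    ]


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (expression, annotations, latent truth).

    Per sample: state ~ Bernoulli(state_prevalence); latent (STAT3, EMT)
    activities from a unit-variance bivariate normal with correlation
    ``pathway_coupling``, mean shifted by ``activity_state_shift`` in
    progenitor-like samples. Log2 expression of each gene is its baseline plus
    the aligned effect (state- or activity-driven, scaled by ``effect_size``
    x ``noise_sd``) plus Normal(0, noise_sd) residual noise; abundance is
    2**log-expression. Survival, censoring and recurrence are derived from
    the latent progenitor activity. Fully reproducible from ``config.seed``.
    """
    blocks = _gene_blocks(config)
    signatures = generate_gene_sets(config)
    gene_ids = [g for block in blocks.values() for g in block]
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    n_genes, n = len(gene_ids), config.n_samples

    ss_genes, ss_samples, ss_noise, ss_outcomes = np.random.SeedSequence(
        config.seed
    ).spawn(4)
    rng_genes = np.random.default_rng(ss_genes)
    rng_samples = np.random.default_rng(ss_samples)
    rng_noise = np.random.default_rng(ss_noise)
    rng_out = np.random.default_rng(ss_outcomes)

    # latent sample structure
    state = rng_samples.random(n) < config.state_prevalence  # True = progenitor-like
    rho = config.pathway_coupling
    cov = np.array([[1.0, rho], [rho, 1.0]])
    activities = rng_samples.multivariate_normal(
        mean=[0.0, 0.0], cov=cov, size=n, method="cholesky"
    )
    shift = config.activity_state_shift * state.astype(float)
    stat3_act = activities[:, 0] + shift
    emt_act = activities[:, 1] + shift
    progenitor_activity = (
        config.effect_size * (state.astype(float) - config.state_prevalence)
        + (stat3_act + emt_act) / 2.0
    )

    # per-gene effect coefficients on the log2 scale
    d = config.effect_size * config.noise_sd
    s = state.astype(float)
    drivers = {
        "stem": d * (1.0 - s),  # up in stem-like samples
        "progenitor": d * s,
        "proneural": d * (1.0 - s),
        "mesenchymal": d * s,
        "stat3": d * stat3_act,
        "emt": d * emt_act,
        "slug_up": d * s,  # SLUG-induced program tracks the progenitor state
        "slug_down": d * (1.0 - s),
        "background": np.zeros(n),
    }
    effect = np.empty((n_genes, n))
    row = 0
    for block_name, genes in blocks.items():
        effect[row : row + len(genes), :] = drivers[block_name][None, :]
        row += len(genes)

    baseline = rng_genes.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    log_expr = (
        baseline[:, None]
        + effect
        + rng_noise.normal(0.0, config.noise_sd, size=(n_genes, n))
    )
    expression = pd.DataFrame(
        np.exp2(log_expr), index=gene_ids, columns=sample_ids
    )

    # outcomes: exponential survival, Bernoulli censoring, logistic recurrence
    rate = np.exp(config.hazard_log_multiplier * progenitor_activity) / (
        config.survival_scale_days
    )
    event_time = rng_out.exponential(1.0 / rate)
    censored = rng_out.random(n) < config.censoring_rate
    observed_time = np.where(
        censored, event_time * rng_out.uniform(0.0, 1.0, size=n), event_time
    )
    observed_time = np.maximum(observed_time, 1e-6)  # times must stay > 0

    act_sd = progenitor_activity.std(ddof=1)
    act_z = (
        (progenitor_activity - progenitor_activity.mean()) / act_sd
        if act_sd > 0
        else np.zeros(n)
    )
    logit0 = np.log(config.recurrent_fraction / (1.0 - config.recurrent_fraction))
    p_recurrent = 1.0 / (1.0 + np.exp(-(logit0 + config.recurrent_score_shift * act_z)))
    recurrent = rng_out.random(n) < p_recurrent

    annotations = pd.DataFrame(
        {
            "precursor_state": np.where(state, "progenitor-like", "stem-like"),
            "subtype": np.where(state, "mesenchymal", "proneural"),
            "primary_or_recurrent": np.where(recurrent, "recurrent", "primary"),
            "survival_time": observed_time,
            "event": ~censored,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    latent = pd.DataFrame(
        {
            "state": state.astype(int),
            "stat3_activity": stat3_act,
            "emt_activity": emt_act,
            "progenitor_activity": progenitor_activity,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression=expression,
        annotations=annotations,
        signatures=signatures,
        latent=latent,
        config=config,
    )


def generate_null_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Same machinery with every planted effect zeroed.

    No state effect on expression, no pathway coupling or state shift, no
    hazard dependence, no recurrence enrichment — the negative control for
    the inferential operations.
    """
    null_config = dataclasses.replace(
        config,
        effect_size=0.0,
        pathway_coupling=0.0,
        activity_state_shift=0.0,
        hazard_log_multiplier=0.0,
        recurrent_score_shift=0.0,
    )
    return generate_cohort(null_config)
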