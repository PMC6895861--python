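import numpy as np
import pandas as pd
import pytest

from sigscore import GeneratorConfig, GeneSet, SignatureDefinition, generate_cohort


@pytest.fixture
def tiny_expr() -> pd.DataFrame:
    """3 genes x 4 samples, strictly positive abundances."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 10.0, 10.0], [5.0, 1.0, 2.0, 8.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def small_signature() -> SignatureDefinition:
    return SignatureDefinition(
        name="sig",
        up_set=GeneSet(name="sig_up", genes=("g1",)),
        down_set=GeneSet(name="sig_down", genes=("g3",)),
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down cohort: fast to draw, keeps all five signatures."""
    return GeneratorConfig(
        n_samples=30,
        n_background_genes=50,
        n_stem_genes=10,
        n_progenitor_genes=10,
        n_proneural_genes=12,
        n_mesenchymal_genes=15,
        n_stat3_genes=8,
        n_emt_genes=9,
        n_slug_up_genes=10,
        n_slug_down_genes=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-cardinality cohort at the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=7))


def rng_stream(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators derived from one seed (for repeat simulations)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
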