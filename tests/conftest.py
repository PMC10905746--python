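import numpy as np
import pytest

from osteotag import pipeline as pl
from osteotag import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


def small_generator_config(seed: int = 5, **overrides) -> sim.GeneratorConfig:
    """A miniature study layout for fast pipeline-level tests."""
    kw = dict(
        seed=seed,
        chrom_length=1_350_000,
        n_stem=4, n_early=4, n_late=4,
        n_flat_genes=20, n_silent_genes=2,
        n_promoter_elements=4, n_unbound_enhancers=12,
    )
    kw.update(overrides)
    return sim.GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def small_bundle():
    return sim.generate(small_generator_config())


@pytest.fixture(scope="session")
def demo_run():
    """One full default-scale demo (bundle, result, metrics), shared."""
    return pl.demo(seed=0)
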