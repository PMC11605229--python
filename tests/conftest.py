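import numpy as np
import pandas as pd
import pytest

from proxidiff.simulate import (
    BioIDSimConfig,
    ExpressionSimConfig,
    generate_bioid,
    generate_expression,
)


@pytest.fixture(scope="session")
def bioid_default():
    """Default five-condition simulation with ground truth."""
    return generate_bioid(BioIDSimConfig(n_proteins=400, seed=7))


@pytest.fixture(scope="session")
def bioid_clean():
    """Noiseless simulation without missingness (exact recovery regime).

    With zero replicate noise the contrasts are deterministic: null-protein
    p-values are exactly 1 and effect carriers hit the zero-variance
    degenerate convention, so interactor recovery is exact.  (At any
    positive noise level, however small, null-protein t-test p-values stay
    uniform, so BH admits a few false discoveries.)
    """
    config = BioIDSimConfig(
        n_proteins=300, noise_sd=0.0, seed=11, lod_threshold=None
    )
    return generate_bioid(config)


@pytest.fixture(scope="session")
def expression_planted():
    """Two-group expression study: one shifted set, two null sets, 3 modules."""
    config = ExpressionSimConfig.with_layout(
        400,
        module_sizes=[40, 40, 40],
        set_sizes=[("PLANTED", 30, 2.0), ("NULL_A", 30, 0.0), ("NULL_B", 30, 0.0)],
        n_controls=30,
        n_cases=30,
        noise_sd=0.5,
        seed=13,
    )
    expr, phenotype, truth = generate_expression(config)
    return config, expr, phenotype, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
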