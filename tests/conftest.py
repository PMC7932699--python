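import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hourglass_kit.expression import ExpressionMatrix, filter_expressed, scale
from hourglass_kit.synthetic import (
    ExpressionSimConfig,
    simulate_expression,
    toy_two_gene_example,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(species, genes, stages, means, n_reps=1):
    """ExpressionMatrix with exact means (replicates identical)."""
    arr = np.repeat(np.asarray(means, float)[:, :, None], n_reps, axis=2)
    return ExpressionMatrix(species, pd.Index(genes), list(stages), arr)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed 11)."""
    cfg = ExpressionSimConfig(seed=11)
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def scaled_sim(default_sim):
    """Max-1 scaled, expression-filtered matrices plus shared ortholog pairs."""
    ma, mb, truth = default_sim
    ea, eb = filter_expressed(ma), filter_expressed(mb)
    sa, sb = scale(ma.subset(ea), "max1"), scale(mb.subset(eb), "max1")
    keep_a, keep_b = set(ea), set(eb)
    pairs = [(a, b) for a, b in sorted(truth.ortholog_truth) if a in keep_a and b in keep_b]
    return sa, sb, pairs, truth


@pytest.fixture(scope="session")
def toy():
    return toy_two_gene_example()
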