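import numpy as np
import pytest

import dnbkit as dk


@pytest.fixture(scope="session")
def demo_model():
    """Default demo network: 500 genes, 10-gene planted module, seed 42."""
    return dk.default_demo_model(seed=42)


@pytest.fixture(scope="session")
def demo_series(demo_model):
    """Default HDLSS stage series (8 samples/stage, seed 42)."""
    return dk.generate_stage_series(demo_model, 8, 0.1, seed=42)


@pytest.fixture(scope="session")
def planted_gene_ids(demo_series):
    return set(demo_series.provenance["dnb_genes"])


@pytest.fixture
def small_model():
    """20-gene model with a 4-gene module, cheap enough for tight loops."""
    return dk.build_network(20, 4, intra_coupling=2.0, seed=3)


def make_matrix(values, stage_label="stage0", gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return dk.ExpressionMatrix(
        gene_ids=list(gene_ids),
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        stage_label=stage_label,
    )
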