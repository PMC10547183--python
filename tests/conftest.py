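import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_group(rng):
    """Small samples x genes group with a planted bimodal axis."""
    from bistab import ExpressionGroup

    n, g = 40, 12
    side = rng.choice([-1.0, 1.0], size=n)
    direction = np.ones(g) / np.sqrt(g)
    values = (
        5.0
        + 2.0 * side[:, None] * direction[None, :]
        + 0.3 * rng.normal(size=(n, g))
    )
    return ExpressionGroup(
        values=values,
        gene_ids=[f"gene{j}" for j in range(g)],
        sample_ids=[f"s{i}" for i in range(n)],
        group_label="planted",
    )
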