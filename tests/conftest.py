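import numpy as np
import pandas as pd
import pytest

from coexsurv.io import ExpressionMatrix
from coexsurv.synthetic import DevelopmentSimSpec, simulate_development


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_expression(rng):
    """Random 20-gene x 9-timepoint matrix (no planted structure)."""
    data = pd.DataFrame(
        rng.standard_normal((20, 9)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"T{t}" for t in range(9)],
    )
    return ExpressionMatrix(data, axis_kind="timepoints")


@pytest.fixture
def planted_development():
    """Three stage-peaked modules of 30 genes plus 10 background genes."""
    spec = DevelopmentSimSpec(
        n_genes=100,
        module_defs=[(30, "early", 0.9), (30, "middle", 0.9), (30, "late", 0.9)],
        noise_sd=1.0,
        mrna_agreement=0.6,
        seed=7,
    )
    return simulate_development(spec)
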