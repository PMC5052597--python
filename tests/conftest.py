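import numpy as np
import pandas as pd
import pytest

from netstrat import (AnalysisConfig, ExpressionMatrix, SimulationParams,
                      generate_cohort)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_samples=120, n_network_nodes=16,
                            n_background_features=40,
                            n_background_mut_genes=30, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A 120-sample cohort with a 16-node network and planted effects."""
    return generate_cohort(small_params)


@pytest.fixture
def tiny_expr():
    vals = pd.DataFrame([[0.0, 3.0, 7.0], [1.0, 0.0, 15.0]],
                        index=["G1", "M1"], columns=["S1", "S2", "S3"])
    kinds = pd.Series(["mRNA", "miRNA"], index=["G1", "M1"])
    return ExpressionMatrix(values=vals, feature_kinds=kinds, transform="raw")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
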