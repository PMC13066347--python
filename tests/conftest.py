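import numpy as np
import pytest

from csense import gsa_prcc, sensitivity_graph, synthetic_data


@pytest.fixture(scope="session")
def glucose_model():
    return synthetic_data.make_toy_model("sp1", ["glc"], [], rng_seed=1)


@pytest.fixture(scope="session")
def community_seed7():
    return synthetic_data.make_community_scenario(5, 8, 4, rng_seed=7)


@pytest.fixture(scope="session")
def gsa_results_seed7(community_seed7):
    """K=200 LHS + PRCC for every model of the seed-7 scenario."""
    results = []
    for i, model in enumerate(community_seed7.models):
        design = gsa_prcc.design_for_model(model, n_samples=200, rng_seed=7 + i)
        results.append(gsa_prcc.run_gsa(model, design))
    return results


@pytest.fixture(scope="session")
def graph_seed7(gsa_results_seed7):
    return sensitivity_graph.build_graph(gsa_results_seed7, alpha=0.1, adjust="none")


@pytest.fixture(scope="session")
def lcms_seed3():
    """12 samples, 6 QCs, 5% noise, no drift (isolates dilution)."""
    return synthetic_data.make_lcms_scenario(
        50, 12, 6, noise_cv=0.05, rng_seed=3, drift_slope=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
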