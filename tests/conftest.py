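import numpy as np
import pytest

from granulekit.simulate import (
    GranuleImageSpec,
    SrnaExperimentSpec,
    generate_granule_image,
    generate_srna_experiment,
)

NOISE_OFF = {"poisson_scale": 0.0, "gaussian_sd": 0.0}


@pytest.fixture(scope="session")
def small_spec():
    """A compact granule stack spec used across imaging tests."""
    return GranuleImageSpec(
        n_nuclei=2, granules_per_nucleus=4, n_planes=16, query_enrichment_ratio=3.0
    )


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return generate_granule_image(small_spec, seed=7)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free stack with planted enrichment ratio 3."""
    spec = GranuleImageSpec(
        n_nuclei=2,
        granules_per_nucleus=4,
        n_planes=16,
        query_enrichment_ratio=3.0,
        noise_model=dict(NOISE_OFF),
    )
    return generate_granule_image(spec, seed=7)


@pytest.fixture(scope="session")
def tiny_experiment():
    """200-gene, 3-replicate, 2-condition IP/input experiment."""
    spec = SrnaExperimentSpec(
        n_genes=200, n_default_targets=40, library_depth=200_000
    )
    return generate_srna_experiment(spec, seed=11, with_coverage=False)


def rng_for(seed):
    return np.random.default_rng(seed)
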