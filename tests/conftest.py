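import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methylcap.differential import DesignInfo
from methylcap.simulate import SimulationParams, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SAMPLES = ["L1_control", "L1_treated", "L2_control", "L2_treated"]


@pytest.fixture(scope="session")
def tiny_study():
    """Small but complete simulated study shared by read-only tests."""
    return simulate_study(
        genome_kwargs=dict(n_chrom=2, chrom_len=500_000, n_genes=40,
                           desert_chroms=()),
        methylome_kwargs=dict(n_regulated=8),
        seed=11,
    )


@pytest.fixture()
def paired_design():
    return DesignInfo(
        samples=SAMPLES,
        block=["L1", "L1", "L2", "L2"],
        treatment=["control", "treated", "control", "treated"],
        offsets=np.zeros(4),
    )


def nb_counts(rng, mu, phi, size):
    """Negative-binomial draws parameterised by mean and dispersion."""
    if phi <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


@pytest.fixture()
def nb_sampler():
    return nb_counts
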