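"""Shared fixtures: small synthetic worlds with known ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from insolubilome.synthetic_data import (
    QuantSimParams,
    gen_annotation_catalog,
    gen_quant_experiment,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spiked_experiment():
    """2000-protein experiment with 200 strong spikes and complete pairs."""
    params = QuantSimParams(
        n_proteins=2000,
        spike_fraction=0.1,
        spike_log2fc=3.0,
        noise_sd=0.2,
        missing_rate=0.0,
        seed=11,
    )
    return params, *gen_quant_experiment(params)


@pytest.fixture(scope="session")
def annotation_world():
    """Catalog world with 50 planted high-sharing proteins (boost 20)."""
    n = 400
    planted = frozenset(f"P{i:05d}" for i in range(50))
    collection, orthology, catalog, truth = gen_annotation_catalog(
        n_proteins=n, planted_set=planted, sharing_boost=20.0, seed=7
    )
    return collection, orthology, catalog, truth


def hypergeom_tail_oracle(N: int, a: int, b: int, k: int) -> float:
    """Independent enumeration: P(X >= k) by direct summation of C terms."""
    from math import comb

    denom = comb(N, b)
    num = sum(comb(a, i) * comb(N - a, b - i) for i in range(k, min(a, b) + 1))
    return num / denom


@pytest.fixture(scope="session")
def hypergeom_oracle():
    return hypergeom_tail_oracle
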