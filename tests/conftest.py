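"""Shared fixtures: small genome pairs, read pools, and a cached aligner.

Session scope amortizes genome/index construction across tests; anything
mutated inside a test gets its own copy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xenosort.align import DualAligner
from xenosort.synthetic import (
    DivergenceSpec,
    SimParams,
    generate_genome_pair,
    random_expression_profile,
    simulate_reads,
)


@pytest.fixture(scope="session")
def pair8():
    """Study-condition pair: 8% substitution divergence, small scale."""
    return generate_genome_pair(
        60, 1200, DivergenceSpec(0.08, 0.002, 3.0), seed=11
    )


@pytest.fixture(scope="session")
def aligner8(pair8):
    return DualAligner(pair8)


@pytest.fixture(scope="session")
def pools8(pair8):
    """Truth-labeled graft and host read pools at the study conditions."""
    gp = random_expression_profile(
        [g for g in pair8.graft_transcribed if pair8.graft_all[g].exons], seed=21
    )
    hp = random_expression_profile(pair8.host_transcribed, seed=22)
    graft = simulate_reads(
        pair8.graft_all, gp, SimParams(n_fragments=1500, seed=23), species="graft"
    )
    host = simulate_reads(
        pair8.host_all, hp, SimParams(n_fragments=1500, seed=24), species="host"
    )
    return graft, host


@pytest.fixture(scope="session")
def null_counts():
    """NB null count matrix: two groups simulated from one distribution."""
    rng = np.random.default_rng(77)
    G, n = 500, 12
    mu = rng.lognormal(5.0, 1.5, G)
    phi = 0.05 + 2.0 / mu
    r = 1.0 / phi
    y = rng.poisson(rng.gamma(r[:, None], (mu / r)[:, None], (G, n)))
    counts = pd.DataFrame(
        y, index=[f"g{i:04d}" for i in range(G)],
        columns=[f"s{j}" for j in range(n)],
    )
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=counts.columns)
    return counts, groups
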