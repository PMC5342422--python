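"""Shared fixtures: tiny hand-built matrices/graphs and a small synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

from slranker.io import ExpressionMatrix, MutationMatrix, RunConfig
from slranker.network import CancerNetwork, build_cancer_network
from slranker.io import GenePair
from slranker.synthdata import SimConfig, simulate_cohort, simulate_network


@pytest.fixture
def small_mut() -> MutationMatrix:
    """10 samples; A mutated in s1,s3,s6; B in s3,s8,s9 (the worked coverage layout)."""
    samples = [f"s{i}" for i in range(1, 11)]
    df = pd.DataFrame(0, index=["A", "B", "C"], columns=samples)
    df.loc["A", ["s1", "s3", "s6"]] = 1
    df.loc["B", ["s3", "s8", "s9"]] = 1
    df.loc["C", ["s1", "s2"]] = 1
    return MutationMatrix(df)


@pytest.fixture
def small_expr(small_mut) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.standard_normal((3, 10)), index=["A", "B", "C"], columns=small_mut.samples
    )
    return ExpressionMatrix(df)


@pytest.fixture
def path3() -> CancerNetwork:
    return build_cancer_network([GenePair.of("A", "B"), GenePair.of("B", "C")], {"A", "B", "C"})


@pytest.fixture
def cycle4() -> CancerNetwork:
    edges = [GenePair.of(a, b) for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]]
    return build_cancer_network(edges, {"A", "B", "C", "D"})


@pytest.fixture(scope="session")
def mini_sim():
    """Small but fully structured cohort: fast enough for per-module tests."""
    sim = SimConfig(n_samples=150, n_genes=120, n_planted_pairs=6, rng_seed=42)
    edges, biomarkers = simulate_network(sim)
    net = build_cancer_network(edges, biomarkers)
    mut, expr, positives = simulate_cohort(sim, net)
    return sim, net, mut, expr, positives


@pytest.fixture
def default_cfg() -> RunConfig:
    return RunConfig(rng_seed=42)
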