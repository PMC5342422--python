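"""Seeded synthetic cohorts with the statistical structure the pipeline screens for.

The generator emulates a tumor cohort: a long-tailed spectrum of per-gene
background mutation rates (most genes rarely mutated, a minority frequently),
a preferential-attachment interaction network over part of the gene universe,
and a set of planted synthetic-lethal pairs.  Each planted pair mutates through
a shared per-sample event: with probability epsilon exactly one member (chosen
uniformly) is mutated, otherwise both, so the pair's empirical exclusivity
concentrates at epsilon while its co-mutation count falls well below the
independence expectation.  Planted genes also act as expression drivers: in
their mutated samples the expression of their network neighbors is shifted by
a fixed number of standard deviations, which the outlier-based driver scorer
can attribute back to the mutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePair, MutationMatrix
from .network import CancerNetwork

__all__ = ["SimConfig", "simulate_network", "simulate_cohort"]


@dataclass
class SimConfig:
    """Synthetic-cohort parameters.

    Planted per-gene mutation rates default to 0.40 — the territory of highly
    recurrent driver genes (e.g. TP53 in serous cohorts) — because mutual
    exclusivity is only statistically detectable at cohort scale when both
    genes are frequently mutated.  Background rates are a two-tier mixture
    mimicking the long tail of real cohorts.
    """

    n_samples: int = 200
    n_genes: int = 300
    background_rate_range: tuple[float, float] = (0.005, 0.05)
    frequent_gene_fraction: float = 0.15
    frequent_rate_range: tuple[float, float] = (0.05, 0.30)
    n_planted_pairs: int = 10
    planted_exclusivity: float = 0.9  # epsilon
    planted_mutation_rate: float = 0.4  # per-gene marginal rate
    driver_effect_size: float = 4.0  # SD units added to affected neighbor samples
    driver_penetrance: float = 0.25  # chance a mutated sample dysregulates a neighbor
    network_attachment: int = 2  # preferential-attachment edges per new node
    network_fraction: float = 0.5  # fraction of genes placed in the network
    biomarker_fraction: float = 0.8  # fraction of network nodes that are biomarkers
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need n_genes >= 10")
        if not 0.0 <= self.planted_exclusivity <= 1.0:
            raise ValueError("planted_exclusivity must be in [0,1]")
        for lo, hi in (self.background_rate_range, self.frequent_rate_range):
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError("rate ranges must satisfy 0 < lo <= hi < 1")
        if not 0.0 < self.planted_mutation_rate < 1.0:
            raise ValueError("planted_mutation_rate must be in (0,1)")
        if not 0.0 < self.driver_penetrance <= 1.0:
            raise ValueError("driver_penetrance must be in (0,1]")
        # event rate lambda = r / (1 - eps/2) must stay a probability
        if self.event_rate > 1.0:
            raise ValueError(
                "planted_mutation_rate too high for the requested exclusivity"
            )

    @property
    def event_rate(self) -> float:
        """Per-sample probability of a planted-pair mutation event.

        An event mutates exactly one member with probability epsilon, both
        otherwise, so the per-gene marginal is lambda * (1 - epsilon/2).
        """
        return self.planted_mutation_rate / (1.0 - self.planted_exclusivity / 2.0)

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{str(i).zfill(width)}" for i in range(self.n_genes)]


def simulate_network(cfg: SimConfig) -> tuple[list[GenePair], list[str]]:
    """Connected preferential-attachment network over a gene subset, plus biomarkers.

    Biomarkers cover ``biomarker_fraction`` of the network's nodes, so the
    downstream biomarker filter prunes some edges (all of them when the
    fraction is 0, none when it is 1).
    """
    rng = np.random.default_rng([cfg.rng_seed, 1])
    genes = cfg.gene_names()
    n_net = max(3, round(cfg.network_fraction * cfg.n_genes))
    members = sorted(rng.choice(genes, size=n_net, replace=False).tolist())
    m = min(cfg.network_attachment, n_net - 1)
    g = nx.barabasi_albert_graph(n_net, m, seed=int(rng.integers(2**31)))
    edges = [GenePair.of(members[u], members[v]) for u, v in g.edges()]
    n_bio = round(cfg.biomarker_fraction * n_net)
    biomarkers = sorted(rng.choice(members, size=n_bio, replace=False).tolist())
    return sorted(edges), biomarkers


def simulate_cohort(
    cfg: SimConfig, network: CancerNetwork
) -> tuple[MutationMatrix, ExpressionMatrix, list[GenePair]]:
    """Mutation/expression matrices plus the planted positive pairs.

    Planted genes are drawn from the (biomarker-filtered) network's nodes so
    the pairs are enumerable and carry centrality signal; they receive no
    additional background mutations, keeping their exclusivity at epsilon.
    """
    rng = np.random.default_rng([cfg.rng_seed, 2])
    genes = cfg.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_g, n_s = cfg.n_genes, cfg.n_samples
    samples = [f"S{str(j).zfill(len(str(n_s - 1)))}" for j in range(n_s)]

    net_nodes = sorted(network.nodes & set(genes))
    if 2 * cfg.n_planted_pairs > len(net_nodes):
        raise ValueError(
            f"{cfg.n_planted_pairs} planted pairs need {2 * cfg.n_planted_pairs} "
            f"network genes, only {len(net_nodes)} available"
        )
    planted_genes = rng.choice(net_nodes, size=2 * cfg.n_planted_pairs, replace=False).tolist()
    positives = [
        GenePair.of(planted_genes[2 * i], planted_genes[2 * i + 1])
        for i in range(cfg.n_planted_pairs)
    ]
    planted_set = {g for p in positives for g in p}

    # background: two-tier per-gene rates, planted genes excluded
    lo, hi = cfg.background_rate_range
    rates = rng.uniform(lo, hi, size=n_g)
    frequent = rng.random(n_g) < cfg.frequent_gene_fraction
    flo, fhi = cfg.frequent_rate_range
    rates[frequent] = rng.uniform(flo, fhi, size=int(frequent.sum()))
    mut = (rng.random((n_g, n_s)) < rates[:, None]).astype(np.int8)
    for g in planted_set:
        mut[gene_idx[g], :] = 0

    # planted pairs: shared event, exclusive assignment with probability epsilon
    eps = cfg.planted_exclusivity
    for pair in positives:
        ia, ib = gene_idx[pair.a], gene_idx[pair.b]
        events = rng.random(n_s) < cfg.event_rate
        exclusive = rng.random(n_s) < eps
        pick_a = rng.random(n_s) < 0.5
        both = events & ~exclusive
        only_a = events & exclusive & pick_a
        only_b = events & exclusive & ~pick_a
        mut[ia, both | only_a] = 1
        mut[ib, both | only_b] = 1

    # expression: unit noise + driver shift on network neighbors in mutated samples.
    # The shift hits each (neighbor, mutated sample) with probability
    # driver_penetrance: frequent drivers would otherwise inflate the neighbor's
    # SD until shifted samples stop being outliers under a z-score rule.
    expr = rng.standard_normal((n_g, n_s))
    for g in sorted(planted_set):
        nbrs = sorted(network.neighbors(g))
        if not nbrs:
            continue
        cols = np.nonzero(mut[gene_idx[g]])[0]
        rows = [gene_idx[x] for x in nbrs if x in gene_idx]
        for r in rows:
            hit = cols[rng.random(cols.size) < cfg.driver_penetrance]
            expr[r, hit] += cfg.driver_effect_size

    mut_m = MutationMatrix(pd.DataFrame(mut, index=genes, columns=samples))
    expr_m = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    return mut_m, expr_m, positives
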