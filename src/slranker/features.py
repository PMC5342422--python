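"""Per-pair features: mutation coverage, driver mutation score, network centrality.

Coverage is the fraction of cohort samples mutated in at least one member of
the pair.  The driver score is -log10 of the smaller of the two genes' driver
p-values.  Driver p-values come either from an external per-gene TSV (e.g. the
output of a dedicated driver-discovery package) or from the built-in scorer: a
greedy bipartite cover linking mutated genes to expression-outlier events in
the same sample through the interaction network, with significance assessed by
permuting the mutation matrix's gene labels.

All three features are min-max normalized to [0,1] jointly over the union of
positive and candidate pairs, so the ranker compares both sets on one scale.
"""

from __future__ import annotations

import heapq
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import (
    ExpressionMatrix,
    GenePair,
    MutationMatrix,
    PairRecord,
    RunConfig,
)
from .network import CancerNetwork, pair_information_centrality

logger = logging.getLogger(__name__)

__all__ = [
    "pair_coverage",
    "expression_outliers",
    "driver_pvalues",
    "load_driver_pvalues",
    "pair_driver_score",
    "minmax_normalize",
    "build_feature_table",
]

P_FLOOR = 1e-16  # p-values are floored here before -log10


def pair_coverage(pair: GenePair | tuple[str, str], mut: MutationMatrix) -> float:
    """Fraction of samples mutated in at least one member of the pair."""
    a, b = tuple(pair)
    union = mut.row(a).astype(bool) | mut.row(b).astype(bool)
    return float(union.sum()) / len(mut.samples)


def expression_outliers(expr: ExpressionMatrix, z_cutoff: float) -> set[tuple[str, str]]:
    """(gene, sample) events where |per-gene z-score| >= z_cutoff.

    z-scores use each gene's mean/SD across samples (population SD); genes with
    zero SD yield no events.
    """
    vals = expr.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, np.nan)
    genes = expr.genes
    samples = expr.samples
    gi, sj = np.nonzero(np.abs(z) >= z_cutoff)
    return {(genes[i], samples[j]) for i, j in zip(gi, sj)}


def _greedy_cover(
    mut_samples: Mapping[str, Sequence[int]],
    outliers_by_sample: Sequence[set[str]],
    neighborhoods: Mapping[str, frozenset],
) -> list[tuple[str, int]]:
    """Greedy max-coverage of outlier events by mutated genes.

    An event (g, s) is coverable by mutated gene m in sample s iff g == m or g
    is a network neighbor of m.  Repeatedly selects the gene covering the most
    uncovered events (ties broken lexicographically) until nothing is coverable.
    Returns [(gene, events_covered_at_selection), ...] in selection order.

    Lazy-greedy: cached gains only shrink as events get covered, so a popped
    entry whose recomputed gain still beats the heap top is exactly the greedy
    choice.
    """
    cover: dict[str, set[tuple[str, int]]] = {}
    for gene, cols in mut_samples.items():
        nbr = neighborhoods.get(gene, frozenset((gene,)))
        evts = {
            (g, s)
            for s in cols
            for g in (nbr & outliers_by_sample[s])
        }
        if evts:
            cover[gene] = evts

    heap = [(-len(evts), gene) for gene, evts in cover.items()]
    heapq.heapify(heap)
    covered: set[tuple[str, int]] = set()
    picks: list[tuple[str, int]] = []
    while heap:
        neg_gain, gene = heapq.heappop(heap)
        evts = cover[gene]
        evts -= covered
        gain = len(evts)
        if gain == 0:
            continue
        if heap and (-gain, gene) > heap[0]:
            heapq.heappush(heap, (-gain, gene))
            continue
        covered |= evts
        picks.append((gene, gain))
    return picks


def driver_pvalues(
    mut: MutationMatrix,
    expr: ExpressionMatrix,
    net: CancerNetwork,
    cfg: RunConfig,
) -> dict[str, float]:
    """Per-gene driver p-values from greedy event cover + gene-label permutations.

    The observed run greedily explains expression-outlier events with mutated
    genes through the interaction network.  The null re-runs the cover on
    matrices whose gene labels (rows) are randomly permuted; a selected gene's
    p-value is (1 + #permutations whose same-rank selection covers at least as
    many events) / (1 + #permutations).  Unselected genes get p = 1.
    """
    if mut.samples != expr.samples:
        raise ValueError("matrices must be sample-aligned (see align_samples)")
    events = expression_outliers(expr, cfg.outlier_z)
    pvals = {g: 1.0 for g in mut.genes}
    if not events:
        logger.warning("no expression-outlier events; all driver p-values = 1")
        return pvals

    samples = mut.samples
    sample_idx = {s: j for j, s in enumerate(samples)}
    outliers_by_sample: list[set[str]] = [set() for _ in samples]
    for g, s in events:
        outliers_by_sample[sample_idx[s]].add(g)

    neighborhoods = {
        g: frozenset(net.neighbors(g) | {g}) for g in mut.genes
    }

    vals = mut.values
    genes = list(mut.genes)

    def mut_cols(row_order: np.ndarray) -> dict[str, np.ndarray]:
        # gene label i carries the mutation profile of row row_order[i]
        out = {}
        for i, g in enumerate(genes):
            cols = np.nonzero(vals[row_order[i]])[0]
            if cols.size:
                out[g] = cols
        return out

    identity = np.arange(len(genes))
    observed = _greedy_cover(mut_cols(identity), outliers_by_sample, neighborhoods)
    if not observed:
        logger.warning("no coverable events; all driver p-values = 1")
        return pvals

    rng = np.random.default_rng(cfg.rng_seed)
    n_perm = cfg.permutations
    # null coverage at each greedy rank, per permutation
    null_by_rank = np.zeros((n_perm, len(observed)), dtype=int)
    for p in range(n_perm):
        perm = rng.permutation(len(genes))
        picks = _greedy_cover(mut_cols(perm), outliers_by_sample, neighborhoods)
        for r in range(min(len(picks), len(observed))):
            null_by_rank[p, r] = picks[r][1]

    for rank, (gene, cov) in enumerate(observed):
        exceed = int((null_by_rank[:, rank] >= cov).sum())
        pvals[gene] = (1 + exceed) / (1 + n_perm)
    return pvals


def load_driver_pvalues(path: str | Path, genes: Iterable[str]) -> dict[str, float]:
    """Read an external per-gene driver p-value TSV (gene <tab> p); missing genes get p=1."""
    pvals = {g: 1.0 for g in genes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gene, p_str = fields
            if lineno == 1 and p_str.lower() in {"p", "pvalue", "p_value"}:
                continue
            p = float(p_str)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}:{lineno}: p-value {p} outside [0,1]")
            if gene in pvals:
                pvals[gene] = p
    return pvals


def pair_driver_score(pair: GenePair | tuple[str, str], pvals: Mapping[str, float]) -> float:
    """-log10 of the smaller member p-value, floored at 1e-16 (missing gene -> p=1)."""
    a, b = tuple(pair)
    p = min(pvals.get(a, 1.0), pvals.get(b, 1.0))
    return -math.log10(max(p, P_FLOOR))


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def build_feature_table(
    candidates: Sequence[PairRecord],
    positives: Sequence[GenePair],
    mut: MutationMatrix,
    expr: ExpressionMatrix,
    net: CancerNetwork,
    cfg: RunConfig,
) -> list[PairRecord]:
    """Compute and jointly normalize the three features for positives and candidates.

    Positive pairs lacking a gene in the mutation matrix are dropped (counted);
    a candidate identical to a positive pair is re-labeled positive so no pair
    is both labeled and unlabeled.  Returned records are positives first, then
    candidates, each block sorted by pair name.
    """
    in_matrix = set(mut.genes)
    pos_pairs = []
    n_dropped = 0
    for p in positives:
        if p.a in in_matrix and p.b in in_matrix:
            pos_pairs.append(p)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d positive pair(s) absent from the mutation matrix", n_dropped)
    pos_set = set(pos_pairs)

    records: list[PairRecord] = [
        PairRecord(pair=p, label="positive") for p in sorted(set(pos_pairs))
    ]
    for rec in sorted(candidates, key=lambda r: r.pair):
        if rec.pair in pos_set:
            rec.label = "positive"
            # merge screening stats into the existing positive record
            for prec in records:
                if prec.pair == rec.pair:
                    prec.contingency = rec.contingency
                    prec.chi2_p = rec.chi2_p
                    prec.exclusivity = rec.exclusivity
                    break
            continue
        records.append(rec)

    if cfg.driver_pvalue_file:
        pvals = load_driver_pvalues(cfg.driver_pvalue_file, mut.genes)
    else:
        pvals = driver_pvalues(mut, expr, net, cfg)

    for rec in records:
        rec.coverage = pair_coverage(rec.pair, mut)
        rec.driver_score = pair_driver_score(rec.pair, pvals)
        rec.centrality = pair_information_centrality(
            net, rec.pair, recompute_diameter=cfg.recompute_diameter
        )

    for attr in ("coverage", "driver_score", "centrality"):
        normed = minmax_normalize([getattr(r, attr) for r in records])
        for r, v in zip(records, normed):
            setattr(r, f"_norm_{attr}", float(v))
    for r in records:
        r.normalized = (r._norm_coverage, r._norm_driver_score, r._norm_centrality)
        del r._norm_coverage, r._norm_driver_score, r._norm_centrality

    return records
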