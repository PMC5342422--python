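"""Candidate pair screening: mutation rate cutoff, chi-square independence, exclusivity.

A candidate pair joins a frequently mutated gene with any gene of the cancer
network.  For each pair the 2x2 contingency table over samples is

    M = both mutated, N = A only, X = B only, Y = neither,

tested for independence with Pearson's chi-square (Yates-corrected by default).
Mutation exclusivity is (X+N)/(M+N+X), the fraction of mutated samples that
carry exactly one of the two mutations.  Pairs pass the screen when
chi2 p <= p_max AND exclusivity >= excl_min (both boundaries inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenePair, MutationMatrix, PairRecord, RunConfig
from .network import CancerNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "mutation_rates",
    "select_candidate_genes",
    "enumerate_raw_pairs",
    "contingency",
    "chi_square_p",
    "exclusivity",
    "screen_candidates",
    "write_candidate_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 mutation co-occurrence counts for one gene pair."""

    m: int  # both mutated
    n: int  # gene A only
    x: int  # gene B only
    y: int  # neither

    def __post_init__(self) -> None:
        if min(self.m, self.n, self.x, self.y) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.m + self.n + self.x + self.y

    def as_array(self) -> np.ndarray:
        return np.array([[self.m, self.n], [self.x, self.y]], dtype=float)

    def has_zero_marginal(self) -> bool:
        return (
            self.m + self.n == 0
            or self.x + self.y == 0
            or self.m + self.x == 0
            or self.n + self.y == 0
        )


def mutation_rates(mut: MutationMatrix) -> pd.Series:
    """Per-gene fraction of mutated samples."""
    vals = mut.values
    return pd.Series(vals.sum(axis=1) / vals.shape[1], index=mut.genes, name="mutation_rate")


def select_candidate_genes(rates: pd.Series, cutoff: float) -> set[str]:
    """Genes with mutation rate >= cutoff (boundary inclusive)."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0,1]")
    selected = set(rates.index[rates >= cutoff])
    if not selected:
        logger.warning("no gene reaches mutation rate %.4g", cutoff)
    return selected


def enumerate_raw_pairs(
    cand_genes: Iterable[str], net: CancerNetwork, mut: MutationMatrix
) -> list[GenePair]:
    """All unordered (candidate gene, network gene) pairs with both genes in the matrix."""
    in_matrix = set(mut.genes)
    cands = sorted(set(cand_genes) & in_matrix)
    net_genes = net.nodes & in_matrix
    pairs = {
        GenePair.of(c, g)
        for c in cands
        for g in net_genes
        if g != c
    }
    return sorted(pairs)


def contingency(pair: GenePair | tuple[str, str], mut: MutationMatrix) -> ContingencyTable:
    """Count the 2x2 table (M, N, X, Y) for a pair over all samples."""
    a, b = tuple(pair)
    ra = mut.row(a).astype(bool)
    rb = mut.row(b).astype(bool)
    m = int((ra & rb).sum())
    n = int((ra & ~rb).sum())
    x = int((~ra & rb).sum())
    y = int((~ra & ~rb).sum())
    return ContingencyTable(m, n, x, y)


def chi_square_p(table: ContingencyTable, continuity: bool = True) -> float:
    """Pearson chi-square p-value for independence on the 2x2 table.

    Returns NaN when a row or column marginal is zero (test undefined); such
    pairs are excluded downstream.
    """
    if table.has_zero_marginal():
        return math.nan
    _, p, _, _ = stats.chi2_contingency(table.as_array(), correction=continuity)
    return float(p)


def exclusivity(table: ContingencyTable) -> float:
    """(X+N)/(M+N+X): fraction of mutated samples mutated in exactly one gene.

    NaN when no sample carries either mutation.
    """
    denom = table.m + table.n + table.x
    if denom == 0:
        return math.nan
    return (table.x + table.n) / denom


def screen_candidates(
    raw_pairs: Sequence[GenePair],
    mut: MutationMatrix,
    cfg: RunConfig,
) -> list[PairRecord]:
    """Retain pairs with chi2 p <= cfg.chi2_p_max and exclusivity >= cfg.exclusivity_min.

    Pairs with undefined statistics (zero marginal, or no mutated sample) are
    dropped and counted; both thresholds are boundary-inclusive.
    """
    kept: list[PairRecord] = []
    n_undefined = 0
    for pair in raw_pairs:
        tab = contingency(pair, mut)
        p = chi_square_p(tab, continuity=cfg.chi2_continuity)
        excl = exclusivity(tab)
        if math.isnan(p) or math.isnan(excl):
            n_undefined += 1
            continue
        if p <= cfg.chi2_p_max and excl >= cfg.exclusivity_min:
            kept.append(
                PairRecord(pair=pair, contingency=tab, chi2_p=p, exclusivity=excl)
            )
    if n_undefined:
        logger.info("excluded %d pair(s) with undefined statistics", n_undefined)
    if not kept:
        logger.warning("no pair passed screening (of %d raw pairs)", len(raw_pairs))
    logger.info("screened %d -> %d candidate pairs", len(raw_pairs), len(kept))
    return kept


def write_candidate_table(records: Sequence[PairRecord], path) -> None:
    """Write the screened-candidate TSV: gene_a, gene_b, M, N, X, Y, chi2_p, exclusivity."""
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tM\tN\tX\tY\tchi2_p\texclusivity\n")
        for rec in records:
            t: ContingencyTable = rec.contingency
            fh.write(
                f"{rec.pair.a}\t{rec.pair.b}\t{t.m}\t{t.n}\t{t.x}\t{t.y}\t"
                f"{rec.chi2_p:.6g}\t{rec.exclusivity:.6g}\n"
            )
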