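"""Ranking evaluation: NDCG@p, hypergeometric enrichment, 10x5-fold CV, alpha tuning.

NDCG@p for binary relevance:

    DCG@p  = sum_{i=1..p} (2^{rel_i} - 1) / log2(i + 1)
    NDCG@p = DCG@p / idealDCG@p

where the ideal ranking places the min(total_relevant, p) relevant items first.
Enrichment of k positives in a top-n list drawn from N pairs containing M
positives uses the hypergeometric tail  p = 1 - sum_{x=0..k} pmf(x)  (strictly
greater than k, as the screening literature prints it); the conventional >= k
tail is available behind a flag.

Cross-validation splits the positives into folds; held-out positives join the
unlabeled set (y = 0) and are scored like candidates, so a fold's NDCG measures
how early the ranker rediscovers them.  The affinity graph is built once per
record set; only the label vector changes across folds, and each alpha's linear
system is factorized once and reused for every shuffle x fold.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import lu_factor, lu_solve

from .io import PairRecord, RunConfig
from .ranking import ITER_MAX, ITER_TOL, affinity_matrix, normalized_affinity

logger = logging.getLogger(__name__)

__all__ = [
    "ndcg_at_p",
    "enrichment_p",
    "CvFold",
    "CvResult",
    "cross_validate",
    "optimize_alpha",
    "label_permuted_records",
    "compare_drug_sensitivity",
    "relative_growth",
]


def ndcg_at_p(ranked_relevances: Sequence[int], p: int, total_relevant: int) -> float:
    """NDCG at cutoff p for a binary relevance list in rank order.

    Returns 0.0 when no relevant item can appear (ideal DCG of 0).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if total_relevant < 0:
        raise ValueError("total_relevant must be >= 0")
    dcg = 0.0
    for i, rel in enumerate(ranked_relevances[:p], start=1):
        if rel not in (0, 1):
            raise ValueError("relevance values must be binary")
        if rel:
            dcg += 1.0 / math.log2(i + 1)
    ideal = sum(1.0 / math.log2(i + 1) for i in range(1, min(total_relevant, p) + 1))
    if ideal == 0.0:
        return 0.0
    return dcg / ideal


def enrichment_p(
    n_total: int, m_pos: int, top_n: int, k: int, tail: str = "printed"
) -> float:
    """Hypergeometric enrichment of k positives in a top-n list.

    ``printed`` tail: p = 1 - sum_{x<=k} pmf(x) = P(K > k); ``ge``: P(K >= k).
    """
    if not (0 <= m_pos <= n_total and 0 <= top_n <= n_total):
        raise ValueError("need 0 <= M <= N and 0 <= n <= N")
    if not 0 <= k <= min(m_pos, top_n):
        raise ValueError("need 0 <= k <= min(M, n)")
    dist = stats.hypergeom(n_total, m_pos, top_n)
    if tail == "printed":
        p = dist.sf(k)
    elif tail == "ge":
        p = dist.sf(k - 1)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class CvFold:
    """Metrics of one shuffle x fold evaluation."""

    shuffle: int
    fold: int
    p: int  # NDCG/enrichment cutoff used
    ndcg: float
    enrichment_p: float
    heldout_ranks: tuple[int, ...]
    n_ranked: int


@dataclass
class CvResult:
    """All fold evaluations at one alpha, with their means."""

    alpha: float
    folds: list[CvFold]

    @property
    def mean_ndcg(self) -> float:
        return float(np.mean([f.ndcg for f in self.folds]))

    @property
    def mean_enrichment_p(self) -> float:
        return float(np.mean([f.enrichment_p for f in self.folds]))

    def heldout_top_fraction(self, fraction: float = 0.10) -> float:
        """Fraction of held-out positives ranked within the top `fraction` of their list."""
        hits = total = 0
        for f in self.folds:
            cut = math.ceil(fraction * f.n_ranked)
            for r in f.heldout_ranks:
                total += 1
                if r <= cut:
                    hits += 1
        return hits / total if total else 0.0


class _CvEngine:
    """Shared affinity/partition state so an alpha grid reuses one factorization per alpha."""

    def __init__(self, records: Sequence[PairRecord], cfg: RunConfig):
        self.cfg = cfg
        self.names = [r.pair.name for r in records]
        for r in records:
            if r.normalized is None:
                raise ValueError(f"record {r.pair.name} lacks normalized features")
        pts = np.array([r.normalized for r in records], dtype=float)
        self.lap = normalized_affinity(affinity_matrix(pts, cfg.affinity))
        self.n = len(records)
        self.pos_idx = np.array(
            [i for i, r in enumerate(records) if r.label == "positive"], dtype=int
        )
        if len(self.pos_idx) < cfg.cv_folds:
            raise ValueError(
                f"{len(self.pos_idx)} positives < {cfg.cv_folds} folds"
            )
        # fold partitions are fixed across alphas: seeded per shuffle
        self.partitions: list[list[np.ndarray]] = []
        for s in range(cfg.cv_shuffles):
            rng = np.random.default_rng([cfg.rng_seed, s])
            perm = rng.permutation(self.pos_idx)
            self.partitions.append(np.array_split(perm, cfg.cv_folds))

    def _solve_factory(self, alpha: float):
        if self.cfg.solver == "iterative":
            lap = self.lap

            def solve(y: np.ndarray) -> np.ndarray:
                f = y.copy()
                for _ in range(ITER_MAX):
                    f_next = alpha * (lap @ f) + (1.0 - alpha) * y
                    if np.max(np.abs(f_next - f)) < ITER_TOL:
                        return f_next
                    f = f_next
                return f

            return solve
        lu = lu_factor(np.eye(self.n) - alpha * self.lap)
        return lambda y: (1.0 - alpha) * lu_solve(lu, y)

    def evaluate(self, alpha: float) -> CvResult:
        solve = self._solve_factory(alpha)
        pos_set = set(self.pos_idx.tolist())
        folds: list[CvFold] = []
        for s, partition in enumerate(self.partitions):
            for f_i, held in enumerate(partition):
                held_set = set(held.tolist())
                y = np.zeros(self.n)
                for i in pos_set - held_set:
                    y[i] = 1.0
                f = solve(y)
                unlabeled = [i for i in range(self.n) if i not in pos_set or i in held_set]
                # round-off-robust ordering: ties resolve by pair name
                unlabeled.sort(key=lambda i: (-round(f[i], 12), self.names[i]))
                p = self.cfg.top_k or len(held_set)
                rel = [1 if i in held_set else 0 for i in unlabeled]
                ndcg = ndcg_at_p(rel, p, total_relevant=len(held_set))
                k = sum(rel[:p])
                enr = enrichment_p(
                    len(unlabeled), len(held_set), min(p, len(unlabeled)),
                    min(k, len(held_set)), tail=self.cfg.enrichment_tail
                )
                ranks = tuple(
                    sorted(r + 1 for r, i in enumerate(unlabeled) if i in held_set)
                )
                folds.append(
                    CvFold(s, f_i, p, ndcg, enr, ranks, len(unlabeled))
                )
        return CvResult(alpha=alpha, folds=folds)


def cross_validate(
    records: Sequence[PairRecord], cfg: RunConfig, alpha: float
) -> CvResult:
    """Seeded cv_shuffles x cv_folds cross-validation at a fixed alpha.

    Each fold trains on the remaining positives and ranks candidates plus the
    held-out positives; NDCG@p and enrichment use p = held-out count unless
    cfg.top_k overrides it.
    """
    return _CvEngine(records, cfg).evaluate(alpha)


def optimize_alpha(
    records: Sequence[PairRecord], cfg: RunConfig
) -> tuple[float, list[CvResult]]:
    """Run CV at every grid alpha; return the alpha maximizing mean NDCG (ties: smallest)."""
    if not cfg.alpha_grid:
        raise ValueError("alpha grid is empty")
    engine = _CvEngine(records, cfg)
    results = [engine.evaluate(alpha) for alpha in cfg.alpha_grid]
    best = max(results, key=lambda r: (r.mean_ndcg, -r.alpha))
    logger.info("optimized alpha = %.2f (mean NDCG %.4f)", best.alpha, best.mean_ndcg)
    return best.alpha, results


def label_permuted_records(
    records: Sequence[PairRecord], seed: int
) -> list[PairRecord]:
    """Copy of the records with the positive labels reassigned uniformly at random.

    Feature values stay attached to their pairs; only which pairs count as
    positives moves.  Serves as the no-signal baseline for CV comparisons.
    """
    rng = np.random.default_rng(seed)
    n_pos = sum(1 for r in records if r.label == "positive")
    out = [copy.deepcopy(r) for r in records]
    pos_positions = set(rng.choice(len(out), size=n_pos, replace=False).tolist())
    for i, r in enumerate(out):
        r.label = "positive" if i in pos_positions else "candidate"
    return out


def compare_drug_sensitivity(
    values_mut: Sequence[float],
    values_wt: Sequence[float],
    higher_is_sensitive: bool = True,
) -> float:
    """One-sided Welch t-test that the mutant-background group is MORE drug sensitive.

    ``higher_is_sensitive`` selects the direction of "sensitive" for the
    readout (PIC50: higher; z-scored GI50: lower).  Two constant groups with
    equal means return 0.5 by convention.
    """
    a = np.asarray(values_mut, dtype=float)
    b = np.asarray(values_wt, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    alternative = "greater" if higher_is_sensitive else "less"
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.5
        favored = a.mean() > b.mean() if higher_is_sensitive else a.mean() < b.mean()
        return 0.0 if favored else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def relative_growth(treated: float, placebo: float) -> float:
    """Relative cell growth: treated readout / placebo readout."""
    if placebo <= 0:
        raise ValueError("placebo growth must be positive")
    return treated / placebo
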