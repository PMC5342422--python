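"""Semi-supervised manifold ranking of candidate pairs against known positives.

Points are the normalized feature triples of all pairs; the first q points are
positives (y_i = 1), the rest candidates (y_i = 0).  Labels diffuse over a
cosine-similarity affinity graph:

    W_ij = cos(x_i, x_j)   (i != j),  W_ii = 0
    L = D^{-1/2} W D^{-1/2},  D_ii = sum_j W_ij
    f* = (1 - alpha) (I - alpha L)^{-1} y,  alpha in [0, 1)

equivalently the fixed point of f^{t+1} = alpha L f^t + (1-alpha) y from
f^0 = y.  Candidates are ranked by f* descending.  The affinity can instead be
read as a cosine *distance* (1 - cos) behind a config flag; similarity is the
default since the quantity weights the relevance between neighboring points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "RankingProblem",
    "affinity_matrix",
    "normalized_affinity",
    "manifold_rank",
    "rank_candidates",
]

AffinityKind = Literal["similarity", "distance"]
SolverMode = Literal["closed_form", "iterative"]

ITER_TOL = 1e-9
ITER_MAX = 10_000


def affinity_matrix(points: np.ndarray | Sequence, kind: AffinityKind = "similarity") -> np.ndarray:
    """Pairwise cosine affinity with zero diagonal.

    ``similarity``: W_ij = cos(x_i, x_j); ``distance``: W_ij = 1 - cos(x_i, x_j).
    Zero-norm points have affinity 0 to everything in both readings.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be a 2-D array (n_points x n_features)")
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = x / safe[:, None]
    w = unit @ unit.T
    zero = norms == 0
    w[zero, :] = 0.0
    w[:, zero] = 0.0
    if kind == "distance":
        w = 1.0 - w
        w[zero, :] = 0.0
        w[:, zero] = 0.0
    np.fill_diagonal(w, 0.0)
    # cosine of non-negative vectors lies in [0,1]; clip fp noise
    return np.clip(w, 0.0, None)


def normalized_affinity(w: np.ndarray) -> np.ndarray:
    """Symmetric normalization L = D^{-1/2} W D^{-1/2}; zero-degree rows stay zero."""
    w = np.asarray(w, dtype=float)
    deg = w.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return inv_sqrt[:, None] * w * inv_sqrt[None, :]


@dataclass
class RankingProblem:
    """Feature points with a leading block of q positives and diffusion parameter alpha."""

    points: np.ndarray
    q: int
    alpha: float
    names: Optional[list[str]] = None  # pair names for deterministic tie-breaks
    affinity: AffinityKind = "similarity"
    y: np.ndarray = field(init=False)
    w: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)
    f_star: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.points)
        if not 0 <= self.q <= n:
            raise ValueError("q must be in [0, n]")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0,1)")
        if self.names is not None and len(self.names) != n:
            raise ValueError("names length must match points")
        self.y = np.zeros(n)
        self.y[: self.q] = 1.0
        self.w = affinity_matrix(self.points, self.affinity)
        self.laplacian = normalized_affinity(self.w)

    @property
    def n(self) -> int:
        return len(self.points)


def manifold_rank(problem: RankingProblem, mode: SolverMode = "closed_form") -> np.ndarray:
    """Converged ranking scores f*.

    ``closed_form`` solves (I - alpha L) f = (1-alpha) y directly; ``iterative``
    runs the diffusion update until max-abs change < 1e-9 (cap 10,000 steps).
    The system is always solvable: L's spectral radius is <= 1 and alpha < 1.
    """
    alpha, lap, y = problem.alpha, problem.laplacian, problem.y
    if mode == "closed_form":
        a = np.eye(problem.n) - alpha * lap
        f = (1.0 - alpha) * linalg.solve(a, y, assume_a="sym")
    elif mode == "iterative":
        f = y.copy()
        for _ in range(ITER_MAX):
            f_next = alpha * (lap @ f) + (1.0 - alpha) * y
            if np.max(np.abs(f_next - f)) < ITER_TOL:
                f = f_next
                break
            f = f_next
    else:
        raise ValueError(f"unknown solver mode {mode!r}")
    problem.f_star = f
    return f


def rank_candidates(
    problem: RankingProblem, f_star: Optional[np.ndarray] = None
) -> list[tuple[int, int, float]]:
    """Rank the unlabeled points (indices >= q) by f* descending.

    Ties are broken by pair name (lexicographic) when names are given, else by
    point index.  Returns [(rank, point_index, score), ...] with ranks 1..n-q.
    """
    f = problem.f_star if f_star is None else np.asarray(f_star, dtype=float)
    if f is None:
        raise ValueError("f_star has not been computed")
    idx = range(problem.q, problem.n)
    # round the sort key so exact ties fall through to the name rule instead of
    # being split by solver round-off
    if problem.names is not None:
        key = lambda i: (-round(f[i], 12), problem.names[i])
    else:
        key = lambda i: (-round(f[i], 12), i)
    ordered = sorted(idx, key=key)
    return [(r + 1, i, float(f[i])) for r, i in enumerate(ordered)]
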