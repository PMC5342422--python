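"""Domain types and file I/O for mutation/expression matrices, pair lists and ranked output.

All tabular formats are plain TSV.  Matrices are gene-by-sample: the header row
holds sample IDs, the first column holds gene symbols.  Gene symbols are matched
case-sensitively after whitespace stripping; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "MutationMatrix",
    "ExpressionMatrix",
    "PairRecord",
    "RunConfig",
    "load_matrix",
    "write_matrix",
    "align_samples",
    "load_pair_list",
    "load_gene_list",
    "write_ranked_pairs",
    "RANKED_COLUMNS",
]


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered gene pair stored in canonical (lexicographic) order."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-pair not allowed: {self.a!r}")
        if self.a > self.b:  # canonicalize so {A,B} == {B,A}
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @classmethod
    def of(cls, x: str, y: str) -> "GenePair":
        x, y = x.strip(), y.strip()
        return cls(*sorted((x, y)))

    @property
    def name(self) -> str:
        return f"{self.a}|{self.b}"

    def __iter__(self):
        return iter((self.a, self.b))


def _validate_labels(labels: Iterable[str], what: str) -> list[str]:
    out = [str(x).strip() for x in labels]
    seen: set[str] = set()
    for lab in out:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return out


class _GeneSampleMatrix:
    """Gene-by-sample matrix backed by a pandas DataFrame (genes in rows)."""

    _min_samples = 1

    def __init__(self, df: pd.DataFrame):
        genes = _validate_labels(df.index, "gene")
        samples = _validate_labels(df.columns, "sample")
        if len(genes) < 1 or len(samples) < self._min_samples:
            raise ValueError(
                f"matrix needs >=1 gene and >={self._min_samples} samples, "
                f"got {len(genes)}x{len(samples)}"
            )
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {genes[bad[0]]!r}, sample {samples[bad[1]]!r}"
            )
        self._df = pd.DataFrame(self._coerce(values, genes, samples), index=genes, columns=samples)

    @staticmethod
    def _coerce(values: np.ndarray, genes, samples) -> np.ndarray:
        return values

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def restrict_samples(self, samples: Sequence[str]):
        return type(self)(self._df.loc[:, list(samples)])

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def row(self, gene: str) -> np.ndarray:
        if gene not in self._df.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self._df.loc[gene].to_numpy()


class MutationMatrix(_GeneSampleMatrix):
    """Binary somatic-mutation incidence matrix (1 = mutated)."""

    _min_samples = 2

    @staticmethod
    def _coerce(values: np.ndarray, genes, samples) -> np.ndarray:
        bad = ~np.isin(values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"mutation value not in {{0,1}} at gene {genes[i]!r}, "
                f"sample {samples[j]!r}: {values[i, j]}"
            )
        return values.astype(np.int8)

    def mutated_samples(self, gene: str) -> set[str]:
        row = self.row(gene)
        return {s for s, v in zip(self.samples, row) if v}


class ExpressionMatrix(_GeneSampleMatrix):
    """Continuous gene-expression matrix; values are taken as given (no rescaling)."""


Kind = Literal["mutation", "expression"]


def load_matrix(path: str | Path, kind: Kind) -> MutationMatrix | ExpressionMatrix:
    """Load a gene-by-sample TSV matrix.

    The header row carries sample IDs; the first column carries gene symbols.
    Mutation matrices must be strictly 0/1.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse numeric matrix: {exc}") from exc
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        col = next(c for c, d in df.dtypes.items() if not np.issubdtype(d, np.number))
        raise ValueError(f"{path}: non-numeric cell(s) in column {col!r}")
    cls = MutationMatrix if kind == "mutation" else ExpressionMatrix
    try:
        return cls(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_matrix(matrix: _GeneSampleMatrix, path: str | Path) -> None:
    """Write a matrix back to TSV (inverse of :func:`load_matrix`)."""
    df = matrix.df
    if isinstance(matrix, MutationMatrix):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene")


def align_samples(
    mut: MutationMatrix, expr: ExpressionMatrix
) -> tuple[MutationMatrix, ExpressionMatrix]:
    """Restrict both matrices to their sample intersection, in mutation-matrix order."""
    common = [s for s in mut.samples if s in set(expr.samples)]
    if not common:
        raise ValueError("mutation and expression matrices share no samples")
    logger.info("sample intersection: %d of %d/%d", len(common), len(mut.samples), len(expr.samples))
    if common == mut.samples and common == expr.samples:
        return mut, expr
    return mut.restrict_samples(common), expr.restrict_samples(common)


def load_pair_list(path: str | Path) -> list[GenePair]:
    """Read a two-column TSV of gene pairs; canonicalized, deduplicated, self-pairs dropped.

    A first line whose fields repeat elsewhere is data; a header line is detected
    only as the literal field names starting with '#' or named gene_a/gene_b.
    """
    path = Path(path)
    pairs: list[GenePair] = []
    seen: set[GenePair] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            a, b = (f.strip() for f in fields)
            if lineno == 1 and (a.startswith("#") or (a.lower(), b.lower()) == ("gene_a", "gene_b")):
                continue
            if a == b:
                n_self += 1
                continue
            pair = GenePair.of(a, b)
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if n_self:
        logger.warning("dropped %d self-pair(s) from %s", n_self, path)
    return pairs


def load_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines and '#' comments skipped)."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


# --------------------------------------------------------------------------
# pair records and run configuration


@dataclass
class PairRecord:
    """One gene pair with its screening statistics, features and ranking score."""

    pair: GenePair
    contingency: Optional["object"] = None  # candidates.ContingencyTable
    chi2_p: Optional[float] = None
    exclusivity: Optional[float] = None
    coverage: Optional[float] = None
    driver_score: Optional[float] = None
    centrality: Optional[float] = None
    normalized: Optional[tuple[float, float, float]] = None
    label: Literal["positive", "candidate"] = "candidate"
    score: Optional[float] = None
    rank: Optional[int] = None

    def features(self) -> tuple[float, float, float]:
        if self.coverage is None or self.driver_score is None or self.centrality is None:
            raise ValueError(f"features not computed for {self.pair.name}")
        return (self.coverage, self.driver_score, self.centrality)


@dataclass
class RunConfig:
    """Tunable parameters of the screening/ranking pipeline.

    Defaults follow the published analysis: 1% mutation-rate cutoff, chi-square
    p <= 0.05, exclusivity >= 0.8, alpha grid 0.00-0.99 (step 0.01), 10x5-fold CV.
    """

    mutation_rate_cutoff: float = 0.01
    chi2_p_max: float = 0.05
    exclusivity_min: float = 0.8
    chi2_continuity: bool = True
    alpha_grid: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(100))
    cv_folds: int = 5
    cv_shuffles: int = 10
    top_k: Optional[int] = None  # None -> held-out positive count
    rng_seed: int = 0
    driver_pvalue_file: Optional[str] = None  # external per-gene p-value TSV
    outlier_z: float = 2.0
    permutations: int = 100
    affinity: Literal["similarity", "distance"] = "similarity"
    enrichment_tail: Literal["printed", "ge"] = "printed"
    solver: Literal["closed_form", "iterative"] = "closed_form"
    recompute_diameter: bool = False  # recompute D on the node-deleted graph

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation_rate_cutoff <= 1.0:
            raise ValueError("mutation_rate_cutoff must be in (0,1]")
        if not 0.0 <= self.chi2_p_max <= 1.0:
            raise ValueError("chi2_p_max must be in [0,1]")
        if not 0.0 <= self.exclusivity_min <= 1.0:
            raise ValueError("exclusivity_min must be in [0,1]")
        if any(not 0.0 <= a < 1.0 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0,1)")
        if self.cv_folds < 2 or self.cv_shuffles < 1:
            raise ValueError("cv_folds >= 2 and cv_shuffles >= 1 required")


RANKED_COLUMNS = (
    "gene_a",
    "gene_b",
    "label",
    "coverage",
    "driver_score",
    "centrality",
    "coverage_norm",
    "driver_score_norm",
    "centrality_norm",
    "chi2_p",
    "exclusivity",
    "score",
    "rank",
)


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    return format(float(x), ".6g")


def write_ranked_pairs(records: Sequence[PairRecord], path: str | Path) -> None:
    """Write scored records as a rank-sorted TSV with deterministic byte output."""
    for rec in records:
        if rec.rank is None or rec.score is None:
            raise ValueError(f"record {rec.pair.name} is not ranked")
    ordered = sorted(records, key=lambda r: r.rank)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(RANKED_COLUMNS) + "\n")
        for rec in ordered:
            norm = rec.normalized if rec.normalized is not None else (None, None, None)
            row = (
                rec.pair.a,
                rec.pair.b,
                rec.label,
                _fmt(rec.coverage),
                _fmt(rec.driver_score),
                _fmt(rec.centrality),
                _fmt(norm[0]),
                _fmt(norm[1]),
                _fmt(norm[2]),
                _fmt(rec.chi2_p),
                _fmt(rec.exclusivity),
                _fmt(rec.score),
                str(rec.rank),
            )
            fh.write("\t".join(row) + "\n")
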