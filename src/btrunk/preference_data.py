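"""Rankings, paired comparisons, and the log-linear Bradley-Terry design matrix.

A complete ranking of ``n_o`` objects by each of ``H`` judges is converted to
the ``n_o*(n_o-1)/2`` binary paired-comparison outcomes per judge.  Those
outcomes feed a log-linear (Poisson, two cells per comparison) representation
of the Bradley-Terry model in which each judge-pair contributes two rows whose
expected counts sum to one; a nuisance parameter per judge-pair fixes that
total, and signed object-contrast columns carry the structural worth
parameters.  Subject covariates and trunk-region indicators enter as
object-contrast interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankingTable",
    "PairedComparisonSet",
    "CovariateTable",
    "Region",
    "LLBTDesign",
    "pairs_from_rankings",
    "rankings_from_pairs",
    "build_design",
    "check_transitivity",
    "project_to_nearest_permutation",
    "pair_index",
    "permutation_patterns",
]


def pair_index(n_o: int) -> list[tuple[int, int]]:
    """All object pairs ``(i, j)`` with ``i < j`` in label order."""
    return list(itertools.combinations(range(n_o), 2))


@dataclass
class RankingTable:
    """Complete rankings (1 = most preferred) of ``n_o`` objects by ``H`` judges."""

    judge_ids: list
    ranks: np.ndarray  # (H, n_o) integers, each row a permutation of 1..n_o
    object_labels: list[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        n_o = len(self.object_labels)
        if n_o < 3:
            raise ValueError("at least 3 objects are required")
        if self.ranks.shape != (len(self.judge_ids), n_o):
            raise ValueError("ranks must be (H, n_o)")
        expected = np.arange(1, n_o + 1)
        for jid, row in zip(self.judge_ids, self.ranks):
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(
                    f"judge {jid!r}: ranks {row.tolist()} are not a permutation "
                    f"of 1..{n_o} (ties or out-of-range values)"
                )

    @property
    def n_objects(self) -> int:
        return len(self.object_labels)

    @property
    def n_judges(self) -> int:
        return len(self.judge_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, judge_col: str = "judge") -> "RankingTable":
        labels = [c for c in frame.columns if c != judge_col]
        return cls(frame[judge_col].tolist(), frame[labels].to_numpy(dtype=int), labels)

    @classmethod
    def read_csv(cls, path, judge_col: str = "judge") -> "RankingTable":
        return cls.from_frame(pd.read_csv(path), judge_col=judge_col)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.ranks, columns=self.object_labels)
        out.insert(0, "judge", self.judge_ids)
        return out


@dataclass
class PairedComparisonSet:
    """Binary outcomes of all pairwise comparisons, one block per judge.

    ``y01[h, k] = 1`` means the first (lower-indexed) object of pair ``k``
    was preferred by judge ``h``.
    """

    judge_ids: list
    y01: np.ndarray  # (H, n_pairs) in {0, 1}
    object_labels: list[str]
    derived_from_rankings: bool = False

    def __post_init__(self) -> None:
        self.y01 = np.asarray(self.y01, dtype=int)
        n_pairs = len(self.pairs)
        if self.y01.shape != (len(self.judge_ids), n_pairs):
            raise ValueError("y01 must be (H, n_o*(n_o-1)/2)")
        if not np.isin(self.y01, (0, 1)).all():
            raise ValueError("comparison outcomes must be 0/1")

    @property
    def n_objects(self) -> int:
        return len(self.object_labels)

    @property
    def n_judges(self) -> int:
        return len(self.judge_ids)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(len(self.object_labels))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.object_labels
        for jid, yrow in zip(self.judge_ids, self.y01):
            for (i, j), y in zip(self.pairs, yrow):
                rows.append((jid, labels[i], labels[j], int(y)))
        return pd.DataFrame(rows, columns=["judge", "object_i", "object_j", "y"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, object_labels: Sequence[str] | None = None) -> "PairedComparisonSet":
        if object_labels is None:
            object_labels = sorted(set(frame["object_i"]) | set(frame["object_j"]))
        labels = list(object_labels)
        idx = {o: k for k, o in enumerate(labels)}
        pairs = pair_index(len(labels))
        pair_pos = {p: k for k, p in enumerate(pairs)}
        judges = list(dict.fromkeys(frame["judge"]))
        jpos = {j: h for h, j in enumerate(judges)}
        y = np.full((len(judges), len(pairs)), -1, dtype=int)
        for jid, oi, oj, val in frame[["judge", "object_i", "object_j", "y"]].itertuples(index=False):
            i, j = idx[oi], idx[oj]
            if i > j:
                i, j, val = j, i, 1 - val
            y[jpos[jid], pair_pos[(i, j)]] = val
        if (y < 0).any():
            raise ValueError("incomplete paired-comparison table")
        return cls(judges, y, labels)


@dataclass
class CovariateTable:
    """One row of numeric subject covariates per judge (no missing values)."""

    judge_ids: list
    values: np.ndarray  # (H, P)
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.judge_ids), len(self.names)):
            raise ValueError("values must be (H, P)")
        if np.isnan(self.values).any():
            raise ValueError("covariates contain missing values")

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, judge_col: str = "judge") -> "CovariateTable":
        names = [c for c in frame.columns if c != judge_col]
        return cls(frame[judge_col].tolist(), frame[names].to_numpy(dtype=float), names)

    @classmethod
    def read_csv(cls, path, judge_col: str = "judge") -> "CovariateTable":
        return cls.from_frame(pd.read_csv(path), judge_col=judge_col)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.names)
        out.insert(0, "judge", self.judge_ids)
        return out


@dataclass(frozen=True)
class Region:
    """Axis-aligned region of covariate space: a conjunction of threshold rules.

    Each condition is ``(covariate_index, op, threshold)`` with ``op`` one of
    ``"<="`` or ``">"``.  An empty condition list matches every judge.
    """

    conditions: tuple[tuple[int, str, float], ...]
    label: str = ""

    def contains(self, covariates: CovariateTable) -> np.ndarray:
        mask = np.ones(covariates.values.shape[0], dtype=bool)
        for p, op, v in self.conditions:
            col = covariates.values[:, p]
            mask &= (col <= v) if op == "<=" else (col > v)
        return mask

    def describe(self, names: Sequence[str]) -> str:
        if not self.conditions:
            return "all"
        return " & ".join(
            f"{names[p]} {op} {v:g}" for p, op, v in self.conditions
        )


# ---------------------------------------------------------------------------
# rankings <-> comparisons

def pairs_from_rankings(rankings: RankingTable) -> PairedComparisonSet:
    """Expand each complete ranking into its pairwise-preference outcomes."""
    pairs = pair_index(rankings.n_objects)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    y = (rankings.ranks[:, i_idx] < rankings.ranks[:, j_idx]).astype(int)
    return PairedComparisonSet(
        list(rankings.judge_ids), y, list(rankings.object_labels), derived_from_rankings=True
    )


def rankings_from_pairs(pairs: PairedComparisonSet) -> RankingTable:
    """Recover complete rankings from transitive comparison patterns.

    Each judge's pattern must correspond to a permutation; the rank of an
    object is then determined by its number of wins.
    """
    n_o = pairs.n_objects
    ranks = np.empty((pairs.n_judges, n_o), dtype=int)
    for h, row in enumerate(pairs.y01):
        ok, _ = check_transitivity(row, n_o)
        if not ok:
            raise ValueError(f"judge {pairs.judge_ids[h]!r}: non-transitive pattern")
        wins = np.zeros(n_o, dtype=int)
        for (i, j), y in zip(pairs.pairs, row):
            wins[i if y == 1 else j] += 1
        ranks[h] = n_o - wins
    return RankingTable(list(pairs.judge_ids), ranks, list(pairs.object_labels))


# ---------------------------------------------------------------------------
# transitivity

@lru_cache(maxsize=None)
def permutation_patterns(n_o: int) -> tuple[np.ndarray, np.ndarray]:
    """Comparison patterns of all ``n_o!`` complete rankings.

    Returns ``(patterns, rank_vectors)`` where ``patterns`` is an
    ``(n_o!, n_pairs)`` 0/1 array in the canonical ``i < j`` pair order.
    """
    pairs = pair_index(n_o)
    perms = list(itertools.permutations(range(1, n_o + 1)))
    ranks = np.array(perms, dtype=int)
    pats = np.array(
        [[1 if r[i] < r[j] else 0 for (i, j) in pairs] for r in perms], dtype=np.uint8
    )
    return pats, ranks


def check_transitivity(binary_vector: Sequence[int], n_o: int) -> tuple[bool, int]:
    """Whether a binary comparison pattern corresponds to some complete ranking.

    Of the ``2**(n_o*(n_o-1)/2)`` conceivable 0/1 patterns only ``n_o!`` are
    transitive; the second return value is that count.
    """
    vec = np.asarray(binary_vector, dtype=int)
    n_pairs = n_o * (n_o - 1) // 2
    if vec.shape != (n_pairs,):
        raise ValueError(f"expected a vector of length {n_pairs}, got shape {vec.shape}")
    pats, _ = permutation_patterns(n_o)
    allowed = bool((pats == vec.astype(np.uint8)).all(axis=1).any())
    return allowed, pats.shape[0]


def project_to_nearest_permutation(
    binary_vector: Sequence[int], n_o: int, rng: np.random.Generator
) -> np.ndarray:
    """Replace a (possibly cyclic) pattern by the closest transitive one.

    Distance is Hamming distance on the comparison vector, which for the
    implied orders coincides with the Kendall distance.  Ties among equally
    close permutations are broken uniformly at random with ``rng``;
    transitive inputs are returned unchanged.
    """
    vec = np.asarray(binary_vector, dtype=np.uint8)
    n_pairs = n_o * (n_o - 1) // 2
    if vec.shape != (n_pairs,):
        raise ValueError(f"expected a vector of length {n_pairs}, got shape {vec.shape}")
    pats, _ = permutation_patterns(n_o)
    dist = (pats != vec).sum(axis=1)
    best = np.flatnonzero(dist == dist.min())
    if len(best) == 1:
        choice = best[0]
    else:
        choice = rng.choice(best)
    return pats[choice].astype(int)


# ---------------------------------------------------------------------------
# design matrix

@dataclass
class LLBTDesign:
    """Log-linear Bradley-Terry design, two Poisson cells per (judge, pair).

    The compact arrays hold one record per (judge, pair) for estimation on the
    profiled (binomial) form: ``X`` already carries the factor-2 contrast
    coding so the linear predictor of the preference logit is ``X @ coef``.
    The canonical long form (``n = n_o*(n_o-1)*H`` rows with signed contrast
    columns and a nuisance cell id) is available from :meth:`to_long_frame`.
    """

    y01: np.ndarray  # (m,) observed outcome per judge-pair
    X: np.ndarray  # (m, p) structural columns, factor-2 coding
    column_names: list[str]
    judge_index: np.ndarray  # (m,) row index into judge_ids
    pair_of_row: np.ndarray  # (m,) index into pair_index(n_o)
    judge_ids: list
    object_labels: list[str]
    covariate_names: list[str]
    regions: list[Region] = field(default_factory=list)  # non-reference regions

    @property
    def n_objects(self) -> int:
        return len(self.object_labels)

    @property
    def n_judges(self) -> int:
        return len(self.judge_ids)

    @property
    def n_rows(self) -> int:
        """Row count of the long (two cells per comparison) form."""
        return 2 * self.y01.shape[0]

    @property
    def n_structural(self) -> int:
        return self.X.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        """Expand to the two-rows-per-comparison Poisson layout for audit."""
        pairs = pair_index(self.n_objects)
        labels = self.object_labels
        m = self.y01.shape[0]
        rec: dict[str, list] = {"y": [], "cell_id": [], "sign": []}
        cols = [f"{name}" for name in self.column_names]
        half = self.X / 2.0  # undo the factor-2 logit coding
        data = np.empty((2 * m, len(cols)))
        for r in range(m):
            h = self.judge_index[r]
            i, j = pairs[self.pair_of_row[r]]
            cid = f"{self.judge_ids[h]}:{labels[i]}-{labels[j]}"
            rec["y"] += [int(self.y01[r]), int(1 - self.y01[r])]
            rec["cell_id"] += [cid, cid]
            rec["sign"] += [1, -1]
            data[2 * r] = half[r]
            data[2 * r + 1] = -half[r]
        out = pd.DataFrame(rec)
        for k, c in enumerate(cols):
            out[c] = data[:, k]
        return out


def _contrast_rows(n_o: int) -> np.ndarray:
    """Per-pair object contrasts (delta_i - delta_j) on the first n_o-1 objects."""
    pairs = pair_index(n_o)
    A = np.zeros((len(pairs), n_o - 1))
    for k, (i, j) in enumerate(pairs):
        if i < n_o - 1:
            A[k, i] = 1.0
        if j < n_o - 1:
            A[k, j] = -1.0
    return A


def build_design(
    pairs: PairedComparisonSet,
    covariates: CovariateTable | None = None,
    regions: Sequence[Region] = (),
) -> LLBTDesign:
    """Assemble the structural design matrix for the (extended) model.

    Columns: ``n_o - 1`` object worths (last object is the zero reference),
    then one object-contrast block per covariate, then one per non-reference
    region.  ``regions`` must be disjoint; every judge in ``pairs`` must have
    a covariate row.
    """
    n_o = pairs.n_objects
    H = pairs.n_judges
    labels = pairs.object_labels
    if covariates is None:
        covariates = CovariateTable(list(pairs.judge_ids), np.empty((H, 0)), [])
    if list(covariates.judge_ids) != list(pairs.judge_ids):
        missing = set(pairs.judge_ids) - set(covariates.judge_ids)
        if missing:
            raise ValueError(f"judges missing covariates: {sorted(map(str, missing))}")
        order = {j: k for k, j in enumerate(covariates.judge_ids)}
        perm = [order[j] for j in pairs.judge_ids]
        covariates = CovariateTable(
            list(pairs.judge_ids), covariates.values[perm], list(covariates.names)
        )

    regions = list(regions)
    memberships = np.array([r.contains(covariates) for r in regions], dtype=float)
    if len(regions) and (memberships.sum(axis=0) > 1).any():
        raise ValueError("regions overlap: a judge belongs to more than one region")

    n_pairs = n_o * (n_o - 1) // 2
    A = 2.0 * _contrast_rows(n_o)  # factor-2 coding of the preference logit
    m = H * n_pairs
    P = covariates.n_covariates
    T1 = len(regions)
    p_cols = (n_o - 1) * (1 + P + T1)
    X = np.empty((m, p_cols))
    judge_index = np.repeat(np.arange(H), n_pairs)
    pair_of_row = np.tile(np.arange(n_pairs), H)
    Atall = np.tile(A, (H, 1))
    X[:, : n_o - 1] = Atall
    col = n_o - 1
    for p in range(P):
        X[:, col : col + n_o - 1] = Atall * covariates.values[judge_index, p][:, None]
        col += n_o - 1
    for t in range(T1):
        X[:, col : col + n_o - 1] = Atall * memberships[t, judge_index][:, None]
        col += n_o - 1

    names = [f"lambda[{labels[i]}]" for i in range(n_o - 1)]
    for p in range(P):
        names += [f"beta[{labels[i]}:{covariates.names[p]}]" for i in range(n_o - 1)]
    for t, reg in enumerate(regions):
        tag = reg.label or f"R{t + 2}"
        names += [f"beta[{labels[i]}:{tag}]" for i in range(n_o - 1)]

    return LLBTDesign(
        y01=pairs.y01.reshape(-1).copy(),
        X=X,
        column_names=names,
        judge_index=judge_index,
        pair_of_row=pair_of_row,
        judge_ids=list(pairs.judge_ids),
        object_labels=list(labels),
        covariate_names=list(covariates.names),
        regions=regions,
    )
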