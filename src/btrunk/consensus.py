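"""Per-node consensus summaries: tau_x rank correlation and median rankings.

The tau_x correlation (score matrices with ties counting as agreement)
compares two rankings, possibly weak (tied) ones.  The median ranking of a
group is the weak order maximizing the average tau_x with the group's
members, found here by exhaustive enumeration of all weak orders (13, 75 and
541 for 3, 4 and 5 objects), which is exact and cheap for the small object
sets this model targets.  Ties are allowed in the consensus but members are
complete rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .preference_data import RankingTable
from .trunk import Trunk

__all__ = [
    "tau_x",
    "score_matrix",
    "enumerate_weak_orders",
    "median_ranking",
    "summarize_nodes",
    "ConsensusSummary",
    "encode_weak_order",
]


def _normalize_ranks(r) -> np.ndarray:
    """Map tied rank values onto the contiguous set 1..k (dense ranking)."""
    r = np.asarray(r)
    _, dense = np.unique(r, return_inverse=True)
    return dense + 1


def score_matrix(ranks) -> np.ndarray:
    """Pairwise score matrix: +1 if ranked ahead of or tied with, -1 if behind."""
    r = np.asarray(ranks, dtype=float)
    a = np.where(r[:, None] <= r[None, :], 1.0, -1.0)
    np.fill_diagonal(a, 0.0)
    return a


def tau_x(r1, r2) -> float:
    """Rank correlation in [-1, 1] treating ties as agreement; symmetric."""
    r1, r2 = np.asarray(r1), np.asarray(r2)
    if r1.shape != r2.shape:
        raise ValueError("rankings must cover the same objects")
    n = len(r1)
    return float(np.sum(score_matrix(r1) * score_matrix(r2)) / (n * (n - 1)))


@lru_cache(maxsize=None)
def enumerate_weak_orders(n: int) -> np.ndarray:
    """All weak orders of ``n`` objects as dense rank vectors.

    A weak order is an ordered set partition; the count is the Fubini
    number (13, 75, 541 for n = 3, 4, 5).  Enumeration is exponential, so
    ``n`` is capped at 6.
    """
    if n > 6:
        raise ValueError("weak-order enumeration is supported for n <= 6")

    out: list[list[int]] = []

    def rec(remaining: tuple[int, ...], rank: int, assigned: dict[int, int]) -> None:
        if not remaining:
            out.append([assigned[i] for i in range(n)])
            return
        # the next rank's block is any nonempty subset of the remaining objects
        for k in range(1, len(remaining) + 1):
            for block in combinations(remaining, k):
                new_assigned = dict(assigned)
                for obj in block:
                    new_assigned[obj] = rank
                rec(tuple(o for o in remaining if o not in block), rank + 1, new_assigned)

    rec(tuple(range(n)), 1, {})
    return np.array(out, dtype=int)


def encode_weak_order(ranks) -> str:
    """Compact string of rank positions per object, e.g. ``\"21234\"``."""
    return "".join(str(int(v)) for v in _normalize_ranks(ranks))


def median_ranking(rankings, n_objects: int | None = None) -> tuple[np.ndarray, float, np.ndarray]:
    """Weak order maximizing the mean tau_x with the member rankings.

    Returns ``(consensus, tau_bar, all_maximizers)``; the first maximizer in
    enumeration order is the display choice.
    """
    R = np.asarray(rankings)
    if R.ndim == 1:
        R = R[None, :]
    n = n_objects or R.shape[1]
    candidates = enumerate_weak_orders(n)
    B = np.zeros((n, n))
    for row in R:
        B += score_matrix(row)
    B /= R.shape[0]
    scores = np.array([np.sum(score_matrix(c) * B) for c in candidates]) / (n * (n - 1))
    best = scores.max()
    maximizers = candidates[np.isclose(scores, best, rtol=0, atol=1e-12)]
    return maximizers[0].copy(), float(best), maximizers


@dataclass
class ConsensusSummary:
    node_id: int
    n_judges: int
    consensus: np.ndarray
    c_string: str
    tau_bar: float


def summarize_nodes(
    trunk: Trunk, rankings: RankingTable, n_splits: int | None = None
) -> list[ConsensusSummary]:
    """Median ranking and mean tau_x for each terminal node of a trunk."""
    if list(rankings.judge_ids) != list(trunk.covariates.judge_ids):
        raise ValueError("rankings and trunk cover different judges")
    out = []
    for nid in trunk.terminal_ids(n_splits):
        mask = trunk.nodes[nid].mask
        member = rankings.ranks[mask]
        if member.shape[0] == 0:
            continue
        consensus, tau_bar, _ = median_ranking(member)
        out.append(
            ConsensusSummary(nid, int(mask.sum()), consensus, encode_weak_order(consensus), tau_bar)
        )
    return out


def consensus_frame(summaries: list[ConsensusSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [s.node_id for s in summaries],
            "H": [s.n_judges for s in summaries],
            "C": [s.c_string for s in summaries],
            "tau_bar": [s.tau_bar for s in summaries],
        }
    )
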