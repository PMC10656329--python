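"""Growing the regression trunk: deviance-driven threshold-interaction search.

A trunk is a small binary tree over the judge covariates.  Each terminal
region contributes an indicator that is crossed with the object contrasts and
added to the main-effects Bradley-Terry model; one region (the terminal
reached from the root by always taking the ">" branch) is the reference and
carries no indicator.  At every step the split maximizing the decrease in
model deviance over all terminal nodes, covariates and observed thresholds is
applied and all coefficients are re-estimated.

Two search modes are supported: one-split-only (OSO), in which a covariate
used in any previous split is no longer a candidate, and multiple-splitting
(MS), in which covariates may be reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import llbt
from .preference_data import (
    CovariateTable,
    LLBTDesign,
    PairedComparisonSet,
    Region,
    build_design,
)

__all__ = [
    "SplitCandidate",
    "TrunkNode",
    "Trunk",
    "enumerate_candidates",
    "best_split",
    "grow",
    "count_parameters",
]

logger = logging.getLogger(__name__)


def count_parameters(n_o: int, P: int, T: int) -> int:
    """Structural parameter count: worths + main effects + region effects.

    ``(n_o - 1) + P*(n_o - 1) + (T - 1)*(n_o - 1)`` for ``T`` terminal nodes.
    """
    if n_o < 2 or P < 0 or T < 1:
        raise ValueError("require n_o >= 2, P >= 0, T >= 1")
    return (n_o - 1) * (1 + P + (T - 1))


@dataclass
class SplitCandidate:
    node_id: int
    covariate: int
    threshold: float
    n_left: int
    n_right: int
    deviance_decrease: float | None = None


@dataclass
class TrunkNode:
    id: int
    depth: int
    parent: int | None
    mask: np.ndarray  # judge membership (bool, length H)
    conditions: tuple[tuple[int, str, float], ...]  # path from root
    created_at_step: int
    split: tuple[int, float] | None = None  # (covariate, threshold)
    split_at_step: int | None = None
    left: int | None = None
    right: int | None = None

    @property
    def n_judges(self) -> int:
        return int(self.mask.sum())

    def predicate(self) -> Region:
        return Region(self.conditions)


class Trunk:
    """Binary threshold tree over judges plus the fitted model sequence.

    Nodes use heap numbering (root = 1, children of ``k`` are ``2k`` and
    ``2k + 1``); the left child holds ``x_p <= v``.  ``fits[t]`` is the model
    with ``t`` splits applied.
    """

    def __init__(
        self,
        covariates: CovariateTable,
        mode: str = "oso",
        min_bucket: int = 5,
    ) -> None:
        if mode not in ("oso", "ms"):
            raise ValueError("mode must be 'oso' or 'ms'")
        self.covariates = covariates
        self.mode = mode
        self.min_bucket = min_bucket
        H = len(covariates.judge_ids)
        self.nodes: dict[int, TrunkNode] = {
            1: TrunkNode(1, 0, None, np.ones(H, dtype=bool), (), 0)
        }
        self.split_history: list[SplitCandidate] = []
        self.fits: list[llbt.BTRTFit] = []

    # -- structure ---------------------------------------------------------

    @property
    def n_splits(self) -> int:
        return len(self.split_history)

    @property
    def n_terminals(self) -> int:
        return self.n_splits + 1

    def apply_split(self, node_id: int, covariate: int, threshold: float) -> tuple[int, int]:
        """Split a terminal node at ``x_covariate <= threshold``."""
        node = self.nodes[node_id]
        if node.split is not None:
            raise ValueError(f"node {node_id} is already split")
        step = self.n_splits + 1
        vals = self.covariates.values[:, covariate]
        left_mask = node.mask & (vals <= threshold)
        right_mask = node.mask & ~(vals <= threshold)
        lid, rid = 2 * node_id, 2 * node_id + 1
        self.nodes[lid] = TrunkNode(
            lid, node.depth + 1, node_id, left_mask,
            node.conditions + ((covariate, "<=", threshold),), step,
        )
        self.nodes[rid] = TrunkNode(
            rid, node.depth + 1, node_id, right_mask,
            node.conditions + ((covariate, ">", threshold),), step,
        )
        node.split = (covariate, threshold)
        node.split_at_step = step
        node.left, node.right = lid, rid
        self.split_history.append(
            SplitCandidate(node_id, covariate, threshold, int(left_mask.sum()), int(right_mask.sum()))
        )
        return lid, rid

    def terminal_ids(self, n_splits: int | None = None) -> list[int]:
        """Terminal node ids of the trunk truncated to its first ``n_splits`` splits."""
        t = self.n_splits if n_splits is None else n_splits
        out = [
            nid
            for nid, node in self.nodes.items()
            if node.created_at_step <= t and (node.split_at_step is None or node.split_at_step > t)
        ]
        return sorted(out)

    @staticmethod
    def reference_id(terminal_ids: list[int], nodes: dict[int, TrunkNode]) -> int:
        """The terminal reached from the root by always branching right."""
        for nid in terminal_ids:
            if all(op == ">" for _, op, _ in nodes[nid].conditions):
                return nid
        raise RuntimeError("no all-right terminal found")  # pragma: no cover

    def regions_at(self, n_splits: int | None = None) -> list[Region]:
        """Non-reference terminal regions, ordered by node id."""
        terms = self.terminal_ids(n_splits)
        ref = self.reference_id(terms, self.nodes)
        regions = []
        for k, nid in enumerate(t for t in terms if t != ref):
            regions.append(Region(self.nodes[nid].conditions, label=f"R{k + 2}(node{nid})"))
        return regions

    def region_node_ids(self, n_splits: int | None = None) -> list[int]:
        terms = self.terminal_ids(n_splits)
        ref = self.reference_id(terms, self.nodes)
        return [t for t in terms if t != ref]

    def used_covariates(self) -> set[int]:
        return {s.covariate for s in self.split_history}

    # -- reporting ---------------------------------------------------------

    def split_table(self) -> pd.DataFrame:
        """Per-size model table: split node, covariate, point, deviance."""
        names = self.covariates.names
        rows = [
            {"model": "mod0", "node": None, "covariate": "main effects (no splits)",
             "split_point": None,
             "deviance": self.fits[0].deviance if self.fits else None}
        ]
        for k, s in enumerate(self.split_history, start=1):
            rows.append(
                {
                    "model": f"mod{k}",
                    "node": s.node_id,
                    "covariate": names[s.covariate],
                    "split_point": s.threshold,
                    "deviance": self.fits[k].deviance if len(self.fits) > k else None,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        names = self.covariates.names
        return {
            "mode": self.mode,
            "min_bucket": self.min_bucket,
            "n_terminals": self.n_terminals,
            "nodes": [
                {
                    "id": n.id,
                    "depth": n.depth,
                    "n_judges": n.n_judges,
                    "predicate": n.predicate().describe(names),
                    "split": None
                    if n.split is None
                    else {"covariate": names[n.split[0]], "threshold": n.split[1]},
                    "children": None if n.split is None else [n.left, n.right],
                }
                for n in sorted(self.nodes.values(), key=lambda x: x.id)
            ],
            "splits": [
                {
                    "step": k + 1,
                    "node": s.node_id,
                    "covariate": names[s.covariate],
                    "threshold": s.threshold,
                    "deviance_decrease": s.deviance_decrease,
                }
                for k, s in enumerate(self.split_history)
            ],
            "deviance_sequence": [f.deviance for f in self.fits],
        }

    def render(self) -> str:
        names = self.covariates.names
        lines: list[str] = []

        def rec(nid: int) -> None:
            n = self.nodes[nid]
            tag = f"node {nid} (H={n.n_judges})"
            if n.split is not None:
                p, v = n.split
                tag += f" split: {names[p]} <= {v:g}"
            lines.append("  " * n.depth + tag)
            if n.split is not None:
                rec(n.left)
                rec(n.right)

        rec(1)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# split search

class _SearchState:
    """Precomputed design blocks shared across candidate refits."""

    def __init__(self, pairs: PairedComparisonSet, covariates: CovariateTable):
        self.design0 = build_design(pairs, covariates)
        n_o = pairs.n_objects
        self.q = n_o - 1
        self.X_main = self.design0.X  # worths + covariate blocks, factor-2 coding
        self.A = self.design0.X[:, : self.q]  # object-contrast block
        self.judge_index = self.design0.judge_index
        self.y01 = self.design0.y01

    def region_block(self, mask: np.ndarray) -> np.ndarray:
        return self.A * mask[self.judge_index][:, None]

    def model_matrix(self, masks: list[np.ndarray]) -> np.ndarray:
        if not masks:
            return self.X_main
        return np.hstack([self.X_main] + [self.region_block(m) for m in masks])


def enumerate_candidates(
    trunk: Trunk,
    node_id: int,
    mode: str | None = None,
    min_bucket: int | None = None,
) -> list[SplitCandidate]:
    """All admissible splits of one terminal node.

    Candidate thresholds are the distinct covariate values observed inside
    the node, excluding the maximum; in OSO mode covariates already used by
    previous splits are excluded; candidates leaving fewer than
    ``min_bucket`` judges on either side are dropped.
    """
    mode = mode or trunk.mode
    min_bucket = trunk.min_bucket if min_bucket is None else min_bucket
    node = trunk.nodes[node_id]
    if node.split is not None:
        raise ValueError(f"node {node_id} is not terminal")
    out: list[SplitCandidate] = []
    if node.n_judges < 2 * min_bucket:
        return out
    used = trunk.used_covariates() if mode == "oso" else set()
    vals_all = trunk.covariates.values[node.mask]
    for p in range(trunk.covariates.n_covariates):
        if p in used:
            continue
        uniq = np.unique(vals_all[:, p])
        for v in uniq[:-1]:
            n_left = int((vals_all[:, p] <= v).sum())
            n_right = node.n_judges - n_left
            if n_left >= min_bucket and n_right >= min_bucket:
                out.append(SplitCandidate(node_id, p, float(v), n_left, n_right))
    return out


def _candidate_masks_and_warm(
    trunk: Trunk,
    state: _SearchState,
    cand: SplitCandidate,
    current_fit: llbt.BTRTFit,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Region masks after a hypothetical split, plus a warm-start coefficient."""
    node = trunk.nodes[cand.node_id]
    vals = trunk.covariates.values[:, cand.covariate]
    left_mask = node.mask & (vals <= cand.threshold)
    right_mask = node.mask & ~(vals <= cand.threshold)
    left_cond = node.conditions + ((cand.covariate, "<=", cand.threshold),)
    right_cond = node.conditions + ((cand.covariate, ">", cand.threshold),)

    # hypothetical terminal list: existing terminals minus the split node,
    # plus its two children (ids 2k, 2k+1), kept in node-id order
    entries = []
    for nid in trunk.terminal_ids():
        if nid == cand.node_id:
            entries.append((2 * nid, trunk.nodes[nid], left_cond, left_mask))
            entries.append((2 * nid + 1, trunk.nodes[nid], right_cond, right_mask))
        else:
            n = trunk.nodes[nid]
            entries.append((nid, n, n.conditions, n.mask))
    entries.sort(key=lambda e: e[0])
    ref = next(eid for eid, _, cond, _ in entries if all(op == ">" for _, op, _ in cond))

    # warm start: main effects from the current fit; persisting regions keep
    # their coefficient, new children inherit the parent's (0 if reference)
    q = state.q
    current_region_ids = trunk.region_node_ids()
    coef_by_node = {
        nid: current_fit.coef[q * (1 + trunk.covariates.n_covariates) + t * q :][:q]
        for t, nid in enumerate(current_region_ids)
    }
    masks, warm_blocks = [], []
    for eid, parent, cond, mask in entries:
        if eid == ref:
            continue
        masks.append(mask)
        if eid in coef_by_node:
            warm_blocks.append(coef_by_node[eid])
        elif eid >= 2 * cand.node_id and cand.node_id in coef_by_node:
            warm_blocks.append(coef_by_node[cand.node_id])
        else:
            warm_blocks.append(np.zeros(q))
    n_main = q * (1 + trunk.covariates.n_covariates)
    warm = np.concatenate([current_fit.coef[:n_main]] + warm_blocks) if warm_blocks else current_fit.coef[:n_main].copy()
    return masks, warm


def best_split(
    trunk: Trunk,
    state: _SearchState,
    current_fit: llbt.BTRTFit,
) -> SplitCandidate | None:
    """Best admissible split over all terminal nodes.

    Every candidate's full model (all existing terms plus the candidate's
    region indicators) is refitted and its deviance decrease recorded; ties
    go to the lowest node id, then covariate index, then threshold, by the
    deterministic scan order and strict improvement.
    """
    best: SplitCandidate | None = None
    best_dd = -np.inf
    for nid in trunk.terminal_ids():
        node = trunk.nodes[nid]
        if node.split is not None or node.n_judges < 2 * trunk.min_bucket:
            continue
        for cand in enumerate_candidates(trunk, nid):
            masks, warm = _candidate_masks_and_warm(trunk, state, cand, current_fit)
            X = state.model_matrix(masks)
            _, dev, _, converged, _, _ = llbt.irls_logit(X, state.y01, start=warm)
            if not converged:
                logger.warning(
                    "candidate fit (node %d, covariate %d, threshold %g) did not converge; skipped",
                    cand.node_id, cand.covariate, cand.threshold,
                )
                continue
            dd = current_fit.deviance - dev
            if dd > best_dd:
                cand.deviance_decrease = dd
                best, best_dd = cand, dd
    return best


def grow(
    pairs: PairedComparisonSet,
    covariates: CovariateTable,
    mode: str = "oso",
    max_T: int = 5,
    min_bucket: int = 5,
) -> Trunk:
    """Grow a trunk to at most ``max_T`` terminal nodes.

    After each accepted split the complete model (main effects plus all
    region indicators) is refitted; the fit sequence for trunk sizes
    ``1..T`` is stored on the returned trunk.
    """
    if max_T < 1:
        raise ValueError("max_T must be >= 1")
    state = _SearchState(pairs, covariates)
    trunk = Trunk(covariates, mode=mode, min_bucket=min_bucket)
    design0 = state.design0
    fit = llbt.fit(design0)
    trunk.fits.append(fit)
    while trunk.n_terminals < max_T:
        cand = best_split(trunk, state, trunk.fits[-1])
        if cand is None:
            break
        prev_fit = trunk.fits[-1]
        prev_region_ids = trunk.region_node_ids()
        trunk.apply_split(cand.node_id, cand.covariate, cand.threshold)
        trunk.split_history[-1].deviance_decrease = cand.deviance_decrease
        design = build_design(pairs, covariates, trunk.regions_at())
        q = pairs.n_objects - 1
        n_main = q * (1 + covariates.n_covariates)
        coef_by_node = {
            nid: prev_fit.coef[n_main + t * q : n_main + (t + 1) * q]
            for t, nid in enumerate(prev_region_ids)
        }
        warm = np.zeros(design.X.shape[1])
        warm[:n_main] = prev_fit.coef[:n_main]
        for t, nid in enumerate(trunk.region_node_ids()):
            block = coef_by_node.get(nid)
            if block is None:
                block = coef_by_node.get(nid // 2)  # child inherits parent's effect
            if block is not None:
                warm[n_main + t * q : n_main + (t + 1) * q] = block
        new_fit = llbt.fit(design, start=warm)
        if new_fit.deviance > prev_fit.deviance + 1e-6:
            # the model nests the previous one, so its deviance cannot be
            # larger at the optimum; retry from a cold start
            cold = llbt.fit(design)
            if cold.deviance < new_fit.deviance:
                new_fit = cold
        trunk.fits.append(new_fit)
    return trunk


def design_at(
    trunk: Trunk,
    pairs: PairedComparisonSet,
    n_splits: int | None = None,
) -> LLBTDesign:
    """Design matrix of the trunk model truncated to ``n_splits`` splits."""
    return build_design(pairs, trunk.covariates, trunk.regions_at(n_splits))
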