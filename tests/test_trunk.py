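"""Trunk growth: node bookkeeping, candidate enumeration, split search."""

import numpy as np
import pytest
from scipy.special import expit

from btrunk import (
    CovariateTable,
    PairedComparisonSet,
    Trunk,
    build_design,
    count_parameters,
    fit,
    grow,
)
from btrunk.preference_data import pair_index
from btrunk.trunk import _SearchState, best_split, design_at, enumerate_candidates


def threshold_dataset(H=60, seed=0, strength=1.2):
    """Judges with x1 <= 0 hold reversed worths; x2 is pure noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((H, 2))
    lam_hi = np.array([strength, strength / 3, 0.0, -strength / 3])
    pairs = pair_index(4)
    y = np.empty((H, len(pairs)), dtype=int)
    for h in range(H):
        lam = lam_hi if x[h, 0] > 0 else -lam_hi
        for k, (i, j) in enumerate(pairs):
            y[h, k] = rng.random() < expit(2 * (lam[i] - lam[j]))
    pc = PairedComparisonSet(list(range(H)), y, ["A", "B", "C", "D"])
    cov = CovariateTable(list(range(H)), x, ["x1", "x2"])
    return pc, cov


class TestCountParameters:
    @pytest.mark.parametrize(
        "n_o, P, T, expected",
        [
            (4, 0, 1, 3),
            (4, 1, 5, 18),
            (5, 4, 8, 48),
            (5, 4, 1, 20),
            (4, 4, 2, 18),
        ],
    )
    def test_values(self, n_o, P, T, expected):
        assert count_parameters(n_o, P, T) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_parameters(4, 1, 0)

    def test_matches_design_columns(self):
        pc, cov = threshold_dataset(H=20, seed=1)
        trunk = grow(pc, cov, max_T=2)
        design = design_at(trunk, pc)
        assert design.n_structural == count_parameters(4, 2, trunk.n_terminals)


class TestStructure:
    @pytest.fixture
    def cov8(self):
        vals = np.arange(16.0).reshape(8, 2)
        return CovariateTable(list(range(8)), vals, ["x1", "x2"])

    def test_heap_numbering_and_left_rule(self, cov8):
        trunk = Trunk(cov8, min_bucket=1)
        lid, rid = trunk.apply_split(1, 0, 6.0)
        assert (lid, rid) == (2, 3)
        assert trunk.nodes[2].conditions == ((0, "<=", 6.0),)
        assert trunk.nodes[3].conditions == ((0, ">", 6.0),)
        assert trunk.nodes[2].n_judges == 4  # x1 in {0,2,4,6}
        lid, rid = trunk.apply_split(2, 1, 3.0)
        assert (lid, rid) == (4, 5)
        assert trunk.nodes[4].depth == 2

    def test_cannot_resplit(self, cov8):
        trunk = Trunk(cov8, min_bucket=1)
        trunk.apply_split(1, 0, 6.0)
        with pytest.raises(ValueError, match="already split"):
            trunk.apply_split(1, 0, 4.0)

    def test_terminal_replay(self, cov8):
        trunk = Trunk(cov8, min_bucket=1)
        trunk.apply_split(1, 0, 6.0)
        trunk.apply_split(2, 1, 3.0)
        trunk.apply_split(3, 1, 11.0)
        assert trunk.terminal_ids(0) == [1]
        assert trunk.terminal_ids(1) == [2, 3]
        assert trunk.terminal_ids(2) == [3, 4, 5]
        assert trunk.terminal_ids(3) == [4, 5, 6, 7]
        assert trunk.terminal_ids() == [4, 5, 6, 7]

    def test_reference_is_all_right_path(self, cov8):
        trunk = Trunk(cov8, min_bucket=1)
        trunk.apply_split(1, 0, 6.0)
        assert Trunk.reference_id(trunk.terminal_ids(), trunk.nodes) == 3
        trunk.apply_split(3, 1, 11.0)
        # the old reference was split; its right child takes over
        assert Trunk.reference_id(trunk.terminal_ids(), trunk.nodes) == 7
        regions = trunk.regions_at()
        assert [r.label for r in regions] == ["R2(node2)", "R3(node6)"]

    def test_left_chain_structure(self, cov8):
        """Repeatedly splitting leftmost nodes yields terminals 16,17,9,5,3."""
        trunk = Trunk(cov8, min_bucket=0)
        trunk.apply_split(1, 0, 8.0)
        trunk.apply_split(2, 0, 4.0)
        trunk.apply_split(4, 0, 2.0)
        trunk.apply_split(8, 0, 0.0)
        assert trunk.terminal_ids() == [3, 5, 9, 16, 17]
        assert Trunk.reference_id(trunk.terminal_ids(), trunk.nodes) == 3
        assert trunk.region_node_ids() == [5, 9, 16, 17]

    def test_region_masks_partition_judges(self, cov8):
        trunk = Trunk(cov8, min_bucket=1)
        trunk.apply_split(1, 0, 6.0)
        trunk.apply_split(3, 1, 11.0)
        masks = np.array([trunk.nodes[t].mask for t in trunk.terminal_ids()])
        assert (masks.sum(axis=0) == 1).all()


class TestEnumerate:
    def test_thresholds_exclude_maximum(self):
        vals = np.array([[1.0], [2.0], [2.0], [3.0], [4.0], [1.0], [3.0], [2.0], [4.0], [1.0]])
        cov = CovariateTable(list(range(10)), vals, ["x1"])
        trunk = Trunk(cov, min_bucket=1)
        cands = enumerate_candidates(trunk, 1)
        assert sorted({c.threshold for c in cands}) == [1.0, 2.0, 3.0]

    def test_min_bucket_enforced(self):
        vals = np.arange(10.0)[:, None]
        cov = CovariateTable(list(range(10)), vals, ["x1"])
        trunk = Trunk(cov, min_bucket=4)
        cands = enumerate_candidates(trunk, 1)
        # only splits leaving >= 4 judges each side: thresholds 3..5
        assert sorted(c.threshold for c in cands) == [3.0, 4.0, 5.0]
        assert all(c.n_left >= 4 and c.n_right >= 4 for c in cands)

    def test_small_node_has_no_candidates(self):
        vals = np.arange(7.0)[:, None]
        cov = CovariateTable(list(range(7)), vals, ["x1"])
        trunk = Trunk(cov, min_bucket=4)
        assert enumerate_candidates(trunk, 1) == []

    def test_oso_excludes_used_covariate(self):
        vals = np.column_stack([np.arange(20.0), np.arange(20.0) % 7])
        cov = CovariateTable(list(range(20)), vals, ["x1", "x2"])
        trunk = Trunk(cov, mode="oso", min_bucket=2)
        trunk.apply_split(1, 0, 9.0)
        assert {c.covariate for c in enumerate_candidates(trunk, 2)} == {1}
        ms = Trunk(cov, mode="ms", min_bucket=2)
        ms.apply_split(1, 0, 9.0)
        assert {c.covariate for c in enumerate_candidates(ms, 2)} == {0, 1}


def _brute_force_best(pc, cov, trunk):
    """Independent exhaustive scan: rebuild the trunk and refit from scratch
    for every candidate via the full design-matrix path."""
    base = fit(design_at(trunk, pc)).deviance
    best, best_dd = None, -np.inf
    for nid in trunk.terminal_ids():
        for cand in enumerate_candidates(trunk, nid):
            probe = Trunk(cov, mode=trunk.mode, min_bucket=trunk.min_bucket)
            for s in trunk.split_history:
                probe.apply_split(s.node_id, s.covariate, s.threshold)
            probe.apply_split(cand.node_id, cand.covariate, cand.threshold)
            dd = base - fit(build_design(pc, cov, probe.regions_at())).deviance
            if dd > best_dd:
                best, best_dd = cand, dd
    return best, best_dd


class TestBestSplit:
    def test_agrees_with_exhaustive_rescan(self):
        pc, cov = threshold_dataset(H=30, seed=4)
        trunk = Trunk(cov, min_bucket=5)
        state = _SearchState(pc, cov)
        trunk.fits.append(fit(state.design0))
        chosen = best_split(trunk, state, trunk.fits[0])
        oracle, oracle_dd = _brute_force_best(pc, cov, trunk)
        assert (chosen.node_id, chosen.covariate, chosen.threshold) == (
            oracle.node_id,
            oracle.covariate,
            oracle.threshold,
        )
        assert chosen.deviance_decrease == pytest.approx(oracle_dd, abs=1e-5)

    def test_second_step_agrees_with_rescan(self):
        pc, cov = threshold_dataset(H=40, seed=6)
        trunk = grow(pc, cov, max_T=2, min_bucket=5)
        state = _SearchState(pc, cov)
        chosen = best_split(trunk, state, trunk.fits[-1])
        oracle, oracle_dd = _brute_force_best(pc, cov, trunk)
        assert (chosen.node_id, chosen.covariate, chosen.threshold) == (
            oracle.node_id,
            oracle.covariate,
            oracle.threshold,
        )
        assert chosen.deviance_decrease == pytest.approx(oracle_dd, abs=1e-5)

    def test_recovers_constructed_threshold(self):
        """A strong preference reversal at x1 = 0 is found at the first split."""
        pc, cov = threshold_dataset(H=80, seed=2, strength=1.5)
        trunk = grow(pc, cov, max_T=2, min_bucket=5)
        s = trunk.split_history[0]
        assert s.covariate == 0
        assert abs(s.threshold) < 0.4
        assert s.deviance_decrease > 50


class TestGrow:
    def test_deviance_sequence_non_increasing(self):
        pc, cov = threshold_dataset(H=50, seed=8)
        trunk = grow(pc, cov, max_T=4, min_bucket=5)
        devs = [f.deviance for f in trunk.fits]
        assert len(devs) == trunk.n_splits + 1
        assert all(a >= b - 1e-8 for a, b in zip(devs, devs[1:]))

    def test_deterministic(self):
        pc, cov = threshold_dataset(H=50, seed=8)
        t1 = grow(pc, cov, max_T=4, min_bucket=5)
        t2 = grow(pc, cov, max_T=4, min_bucket=5)
        h1 = [(s.node_id, s.covariate, s.threshold) for s in t1.split_history]
        h2 = [(s.node_id, s.covariate, s.threshold) for s in t2.split_history]
        assert h1 == h2

    def test_oso_uses_each_covariate_once(self):
        pc, cov = threshold_dataset(H=60, seed=3)
        trunk = grow(pc, cov, mode="oso", max_T=3, min_bucket=5)
        covs = [s.covariate for s in trunk.split_history]
        assert len(covs) == len(set(covs))

    def test_ms_first_split_decrease_at_least_oso(self):
        pc, cov = threshold_dataset(H=60, seed=3)
        oso = grow(pc, cov, mode="oso", max_T=3, min_bucket=5)
        ms = grow(pc, cov, mode="ms", max_T=3, min_bucket=5)
        total_oso = oso.fits[0].deviance - oso.fits[-1].deviance
        total_ms = ms.fits[0].deviance - ms.fits[-1].deviance
        assert total_ms >= total_oso - 1e-6

    def test_split_table_and_dict(self):
        pc, cov = threshold_dataset(H=40, seed=9)
        trunk = grow(pc, cov, max_T=3, min_bucket=5)
        table = trunk.split_table()
        assert list(table["model"]) == [f"mod{k}" for k in range(trunk.n_splits + 1)]
        blob = trunk.to_dict()
        assert blob["n_terminals"] == trunk.n_terminals
        assert len(blob["splits"]) == trunk.n_splits
        assert "node 1" in trunk.render()

    def test_stops_when_no_admissible_split(self):
        pc, cov = threshold_dataset(H=12, seed=5)
        trunk = grow(pc, cov, max_T=5, min_bucket=6)
        # 12 judges, bucket 6: only one split can ever fit
        assert trunk.n_terminals <= 2
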