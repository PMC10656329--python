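import numpy as np
import pytest

from btrunk import CovariateTable, RankingTable, pairs_from_rankings


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)


@pytest.fixture
def small_rankings():
    """Ten judges ranking four objects, with a covariate-linked preference flip."""
    ranks = np.array(
        [np.random.default_rng(7 + h).permutation(4) + 1 for h in range(10)]
    )
    return RankingTable(list(range(1, 11)), ranks, ["A", "B", "C", "D"])


@pytest.fixture
def small_covariates(small_rankings):
    rng = np.random.default_rng(13)
    vals = rng.standard_normal((small_rankings.n_judges, 2))
    return CovariateTable(list(small_rankings.judge_ids), vals, ["x1", "x2"])


@pytest.fixture
def small_pairs(small_rankings):
    return pairs_from_rankings(small_rankings)


def random_ranking_table(n_o, H, seed):
    rng = np.random.default_rng(seed)
    ranks = np.array([rng.permutation(n_o) + 1 for _ in range(H)])
    labels = [f"o{i+1}" for i in range(n_o)]
    return RankingTable(list(range(H)), ranks, labels)
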