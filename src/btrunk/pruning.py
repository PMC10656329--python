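"""Trunk pruning by judge-level cross-validated deviance and the c*SE rule.

The trunk structure is fixed from the full-data grow; along the size
sequence (0 splits up to the grown size) only the coefficients are refit on
each training split.  Folds are assigned at the judge level so that all rows
of a judge are held out together.  The case-wise cross-validation deviance
averages the per-row Poisson deviance contributions of the out-of-fold
predictions; its standard error is the root mean square of the per-row
contributions about that average.  The pruning rule selects the smallest
trunk whose cross-validated deviance is within ``c`` standard errors of the
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import llbt
from .preference_data import PairedComparisonSet
from .trunk import Trunk, _SearchState

__all__ = ["CVProfile", "assign_folds", "cv_deviance", "prune"]

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-10


@dataclass
class CVProfile:
    """Cross-validated deviance profile along the trunk-size sequence.

    Index ``t`` is the number of splits (``t = 0`` is the main-effects
    model).
    """

    D_train: np.ndarray
    D_cv: np.ndarray
    SE_cv: np.ndarray
    V: int
    seed: int | None = None
    fold_assignment: np.ndarray | None = None
    repeats: int = 1
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D_cv = np.asarray(self.D_cv, dtype=float)
        self.SE_cv = np.asarray(self.SE_cv, dtype=float)
        self.D_train = np.asarray(self.D_train, dtype=float)
        if (self.D_cv < 0).any() or (self.SE_cv < 0).any():
            raise ValueError("cross-validated deviances and SEs must be nonnegative")

    @property
    def n_sizes(self) -> int:
        return len(self.D_cv)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.labels or [f"mod{t}" for t in range(self.n_sizes)],
                "D": self.D_train,
                "Dcv": self.D_cv,
                "SEcv": self.SE_cv,
            }
        )


def assign_folds(n_judges: int, V: int, seed) -> np.ndarray:
    """Randomly partition judges into ``V`` folds of near-equal size.

    All design rows of a judge share its fold.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if not 2 <= V <= n_judges:
        raise ValueError(f"V must be in [2, H]; got V={V}, H={n_judges}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_judges)
    folds = np.empty(n_judges, dtype=int)
    folds[perm] = np.arange(n_judges) % V
    return folds


def _case_contributions(y01: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Per-row ``y*log(y/yhat)`` over the two Poisson cells of each comparison.

    Returns a vector of length ``2*m``: for each comparison, the observed
    cell contributes ``-log`` of its predicted mean and the empty cell
    contributes zero (0*log(0) = 0 convention).
    """
    p = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    obs = np.where(y01 == 1, -np.log(p), -np.log1p(-p))
    out = np.zeros(2 * len(y01))
    # observed cell is the "i preferred" row when y=1, the other row when y=0
    out[0::2] = np.where(y01 == 1, obs, 0.0)
    out[1::2] = np.where(y01 == 0, obs, 0.0)
    return out


def cv_deviance(
    trunk: Trunk,
    pairs: PairedComparisonSet,
    V: int = 10,
    seed=None,
    folds: np.ndarray | None = None,
    repeats: int = 1,
) -> CVProfile:
    """Case-wise cross-validated deviance for every trunk size.

    For each size ``t`` and fold, coefficients of the size-``t`` model are
    refit on the other ``V - 1`` folds and the held-out comparisons are
    predicted.  A region with no training judges in some fold keeps a zero
    coefficient for prediction.  With ``repeats > 1`` the whole procedure is
    repeated with fresh fold assignments and the profiles averaged.
    """
    covariates = trunk.covariates
    H = len(covariates.judge_ids)
    state = _SearchState(pairs, covariates)
    n_sizes = trunk.n_splits + 1
    base_rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    D_all = np.zeros((repeats, n_sizes))
    SE_all = np.zeros((repeats, n_sizes))
    first_folds = None
    for rep in range(repeats):
        fold_of_judge = folds if (folds is not None and rep == 0) else assign_folds(H, V, base_rng)
        if first_folds is None:
            first_folds = fold_of_judge
        fold_of_row = fold_of_judge[state.judge_index]
        for t in range(n_sizes):
            node_ids = trunk.region_node_ids(t)
            masks = [trunk.nodes[nid].mask for nid in node_ids]
            X = state.model_matrix(masks)
            warm = trunk.fits[t].coef if len(trunk.fits) > t else None
            prob_hat = np.empty(len(state.y01))
            for v in np.unique(fold_of_judge):
                train = fold_of_row != v
                test = ~train
                if warm is not None and (X[train] != 0).any(axis=0).sum() < X.shape[1]:
                    logger.debug("size %d fold %d: empty region in training; coefficient held at 0", t, v)
                coef, _, _, converged, _, _ = llbt.irls_logit(X[train], state.y01[train], start=warm)
                if not converged:
                    logger.warning("CV fit (size %d, fold %d) did not converge", t, v)
                eta = np.clip(X[test] @ coef, -30.0, 30.0)
                prob_hat[test] = 1.0 / (1.0 + np.exp(-eta))
            contrib = _case_contributions(state.y01, prob_hat)
            n = len(contrib)  # long-form row count n_o*(n_o-1)*H
            D_cv = 2.0 * contrib.sum() / n
            SE_cv = np.sqrt(np.mean((contrib - D_cv) ** 2))
            D_all[rep, t] = D_cv
            SE_all[rep, t] = SE_cv

    D_train = np.array(
        [trunk.fits[t].deviance if len(trunk.fits) > t else np.nan for t in range(n_sizes)]
    )
    return CVProfile(
        D_train=D_train,
        D_cv=D_all.mean(axis=0),
        SE_cv=SE_all.mean(axis=0),
        V=V,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        fold_assignment=first_folds,
        repeats=repeats,
    )


def prune(profile: CVProfile, c: float) -> int:
    """Trunk size (number of splits) selected by the ``c*SE`` rule.

    Let ``t*`` minimize the cross-validated deviance (smallest index on
    ties); the selected size ``t**`` is the smallest ``t`` with
    ``Dcv[t] <= Dcv[t*] + c * SEcv[t*]``.
    """
    if c < 0:
        raise ValueError("c must be nonnegative")
    t_star = int(np.argmin(profile.D_cv))
    threshold = profile.D_cv[t_star] + c * profile.SE_cv[t_star]
    return int(np.flatnonzero(profile.D_cv <= threshold)[0])
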