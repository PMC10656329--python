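"""Maximum-likelihood fitting of the (extended) log-linear Bradley-Terry model.

The log-linear form places each comparison in two Poisson cells whose means
sum to one (a nuisance parameter per judge-pair fixes the total).  Profiling
those nuisance parameters out analytically leaves a binomial-logit model for
the observed 0/1 outcome with preference logit 2*(lambda_i - lambda_j), which
is what the IRLS routine below maximizes; the reported deviance is the Poisson
deviance of the two-cell representation, which coincides with the binomial
deviance of the profiled form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import expit

from .preference_data import LLBTDesign, Region

__all__ = [
    "ModelSpec",
    "BTRTFit",
    "fit",
    "irls_logit",
    "preference_probability",
    "poisson_deviance",
    "estimate_dispersion",
]

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-10
_ETA_CAP = 30.0  # |logit| cap guarding against complete separation


@dataclass(frozen=True)
class ModelSpec:
    """Which structural terms of a design enter the fitted model.

    ``None`` means "all available".  The reference object is always the last
    object in label order (its worth is fixed at zero by the design coding).
    """

    covariates: tuple[int, ...] | None = None
    regions: tuple[int, ...] | None = None

    def column_mask(self, design: LLBTDesign) -> np.ndarray:
        n_o = design.n_objects
        P = len(design.covariate_names)
        T1 = len(design.regions)
        blocks = [True]  # object worths always included
        cov_keep = set(range(P)) if self.covariates is None else set(self.covariates)
        reg_keep = set(range(T1)) if self.regions is None else set(self.regions)
        blocks += [p in cov_keep for p in range(P)]
        blocks += [t in reg_keep for t in range(T1)]
        return np.repeat(np.asarray(blocks, dtype=bool), n_o - 1)


@dataclass
class BTRTFit:
    """Fitted worths, covariate and region effects, and fit diagnostics."""

    lambda_: np.ndarray  # (n_o,) worths, last = 0
    beta_main: np.ndarray  # (P, n_o - 1)
    beta_region: np.ndarray  # (T - 1, n_o - 1)
    coef: np.ndarray  # flat structural coefficients (design column order)
    column_names: list[str]
    deviance: float
    fitted_prob: np.ndarray  # (m,) fitted P(first object of pair preferred)
    dispersion: float
    se_raw: np.ndarray
    se_corrected: np.ndarray
    converged: bool
    n_iter: int
    n_rows: int  # long-form row count, n_o*(n_o-1)*H
    df_resid: int
    object_labels: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.column_names,
                "estimate": self.coef,
                "se_raw": self.se_raw,
                "se_corrected": self.se_corrected,
            }
        )

    def to_dict(self) -> dict:
        return {
            "object_labels": list(self.object_labels),
            "lambda": self.lambda_.tolist(),
            "beta_main": self.beta_main.tolist(),
            "beta_region": self.beta_region.tolist(),
            "coefficients": dict(zip(self.column_names, map(float, self.coef))),
            "deviance": float(self.deviance),
            "dispersion": float(self.dispersion),
            "se_raw": self.se_raw.tolist(),
            "se_corrected": self.se_corrected.tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_rows": int(self.n_rows),
            "df_resid": int(self.df_resid),
        }


def preference_probability(lambda_i, lambda_j):
    """P(object i preferred over j) given judge-specific worths.

    Uses the half-log-worth convention, logit = 2*(lambda_i - lambda_j),
    evaluated with a numerically stable sigmoid.
    """
    return expit(2.0 * (np.asarray(lambda_i, dtype=float) - np.asarray(lambda_j, dtype=float)))


def poisson_deviance(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Deviance ``2 * sum y*log(y/m)`` over Poisson cells, with 0*log(0) = 0.

    ``fitted`` means are clipped away from {0, 1} before the log so that an
    impossible prediction yields a large finite deviance rather than inf.
    """
    y = np.asarray(observed, dtype=float)
    m = np.asarray(fitted, dtype=float)
    if ((m <= 0) & (y > 0)).any():
        logger.warning("fitted mean of 0 with observed count > 0; clipping")
    m = np.clip(m, _PROB_EPS, 1.0 - _PROB_EPS)
    pos = y > 0
    return float(2.0 * np.sum(y[pos] * np.log(y[pos] / m[pos])))


def _binomial_deviance(y01: np.ndarray, prob: np.ndarray) -> float:
    p = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-2.0 * np.sum(np.where(y01 == 1, np.log(p), np.log1p(-p))))


def irls_logit(
    X: np.ndarray,
    y01: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    compute_cov: bool = False,
):
    """Unpenalized logistic IRLS on the profiled two-cell model.

    Returns ``(coef, deviance, prob, converged, n_iter, cov)``; ``cov`` is the
    inverse Fisher information (``None`` unless requested).  Columns that are
    identically zero (e.g. a region empty in a cross-validation training
    fold) get coefficient zero.  Coefficients are capped so the preference
    logit stays within +-30, which bounds estimates under complete
    separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    m, p = X.shape
    active = np.flatnonzero((X != 0).any(axis=0))
    Xa = X[:, active]
    beta = np.zeros(len(active))
    if start is not None:
        beta = np.asarray(start, dtype=float)[active].copy()
    def _dev_at(b: np.ndarray) -> float:
        return _binomial_deviance(y, expit(np.clip(Xa @ b, -_ETA_CAP, _ETA_CAP)))

    dev = _dev_at(beta)
    converged = False
    it = 0
    prob = np.full(m, 0.5)
    for it in range(1, max_iter + 1):
        eta = np.clip(Xa @ beta, -_ETA_CAP, _ETA_CAP)
        prob = expit(eta)
        w = np.maximum(prob * (1.0 - prob), 1e-12)
        z = eta + (y - prob) / w
        Xw = Xa * w[:, None]
        H = Xa.T @ Xw
        H.flat[:: H.shape[0] + 1] += 1e-12 * (1.0 + np.trace(H) / max(H.shape[0], 1))
        g = Xa.T @ (w * z)
        try:
            beta_new = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(H, g, rcond=None)
        # backtrack along the IRLS step until the deviance does not increase
        frac = 1.0
        step = beta_new - beta
        new_dev = _dev_at(beta_new)
        while (not np.isfinite(new_dev) or new_dev > dev + 1e-10) and frac > 1e-8:
            frac *= 0.5
            new_dev = _dev_at(beta + frac * step)
        if frac <= 1e-8 and (not np.isfinite(new_dev) or new_dev >= dev):
            converged = True  # no descent direction left: numerical optimum
            break
        beta = beta + frac * step
        delta = abs(dev - new_dev) / (abs(new_dev) + 0.1)
        dev = new_dev
        if delta < tol:
            converged = True
            break
    eta = np.clip(Xa @ beta, -_ETA_CAP, _ETA_CAP)
    prob = expit(eta)
    cov = None
    if compute_cov:
        w = np.maximum(prob * (1.0 - prob), 1e-12)
        H = Xa.T @ (Xa * w[:, None])
        try:
            cov_a = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_a = np.linalg.pinv(H)
        cov = np.full((p, p), np.nan)
        cov[np.ix_(active, active)] = cov_a
    coef = np.zeros(p)
    coef[active] = beta
    return coef, dev, prob, converged, it, cov


def fit(design: LLBTDesign, spec: ModelSpec | None = None, start: np.ndarray | None = None) -> BTRTFit:
    """Fit the model by Poisson maximum likelihood with nuisance profiling.

    Equivalent to the explicit Poisson fit carrying one dummy per judge-pair
    cell total; the structural estimates and deviance differences agree.
    Non-convergence is flagged on the returned fit rather than raised.
    """
    spec = spec or ModelSpec()
    mask = spec.column_mask(design)
    X = design.X[:, mask]
    names = [n for n, keep in zip(design.column_names, mask) if keep]
    coef, dev, prob, converged, n_iter, cov = irls_logit(
        X, design.y01, start=start, compute_cov=True
    )
    if not converged:
        warnings.warn("IRLS did not converge within the iteration limit", stacklevel=2)

    n_o = design.n_objects
    q = n_o - 1
    P = len(design.covariate_names)
    cov_keep = list(range(P)) if spec.covariates is None else list(spec.covariates)
    T1 = len(design.regions)
    reg_keep = list(range(T1)) if spec.regions is None else list(spec.regions)

    lambda_ = np.zeros(n_o)
    lambda_[: n_o - 1] = coef[:q]
    beta_main = coef[q : q * (1 + len(cov_keep))].reshape(len(cov_keep), q) if cov_keep else np.zeros((0, q))
    beta_region = (
        coef[q * (1 + len(cov_keep)) :].reshape(len(reg_keep), q) if reg_keep else np.zeros((0, q))
    )

    se_raw = np.sqrt(np.diag(cov)) if cov is not None else np.full(len(coef), np.nan)
    m = design.y01.shape[0]
    df_resid = m - X.shape[1]  # long rows minus nuisance cells minus structural
    p_clip = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    pearson = float(np.sum((design.y01 - p_clip) ** 2 / (p_clip * (1.0 - p_clip))))
    if df_resid > 0:
        dispersion = pearson / df_resid
    else:
        logger.warning("non-positive residual df; dispersion undefined, set to nan")
        dispersion = float("nan")

    return BTRTFit(
        lambda_=lambda_,
        beta_main=beta_main,
        beta_region=beta_region,
        coef=coef,
        column_names=names,
        deviance=dev,
        fitted_prob=prob,
        dispersion=dispersion,
        se_raw=se_raw,
        se_corrected=se_raw * np.sqrt(dispersion) if np.isfinite(dispersion) else se_raw * np.nan,
        converged=converged,
        n_iter=n_iter,
        n_rows=design.n_rows,
        df_resid=df_resid,
        object_labels=list(design.object_labels),
        covariate_names=[design.covariate_names[p] for p in cov_keep],
        regions=[design.regions[t] for t in reg_keep],
    )


def estimate_dispersion(fitted: BTRTFit) -> float:
    """Pearson overdispersion ratio X^2 / df of a converged fit."""
    return fitted.dispersion
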