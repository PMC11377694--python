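"""Single-random-effect linear mixed models by 1-D profile likelihood.

The models here all have the form

    y = X beta + Z u + e,   u ~ N(0, sigma2_w * K),   e ~ N(0, sigma2_e * I)

where the random-effect covariance ``sigma2_w * Z K Z'`` is either the
animal-grouping structure (K = I over animals, Z the indicator matrix) or a
genomic relationship matrix. Writing lambda = sigma2_w / sigma2_e, the
marginal covariance is sigma2_e * (I + lambda * M) with M = Z K Z'. After
rotating into the eigenbasis of M the covariance is diagonal, beta has an
exact GLS solution given lambda, and both ML and REML log-likelihoods reduce
to cheap 1-D functions of lambda which are maximised by bounded scalar
optimisation. The eigendecomposition depends only on the design, so it is
computed once and reused across thousands of features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["RandomStructure", "LmmFit", "fit_lmm", "lrt_variance_p"]

_LOG2PI = np.log(2.0 * np.pi)
_LAMBDA_MAX = 1e6


class RandomStructure:
    """Precomputed eigenstructure of the random-effect covariance M = Z K Z'.

    For animal grouping pass ``groups`` (one label per observation); for a
    genomic model pass the PSD matrix ``M`` directly (one row per observation).
    """

    def __init__(self, groups=None, M: np.ndarray | None = None):
        if (groups is None) == (M is None):
            raise ValueError("pass exactly one of groups or M")
        if groups is not None:
            groups = np.asarray(groups)
            labels, idx = np.unique(groups, return_inverse=True)
            n = len(groups)
            Z = np.zeros((n, len(labels)))
            Z[np.arange(n), idx] = 1.0
            M = Z @ Z.T
            self.group_labels = labels
            self.Z = Z
        else:
            M = np.asarray(M, dtype=float)
            self.group_labels = None
            self.Z = None
        # symmetrise before eigendecomposition for numerical hygiene
        M = 0.5 * (M + M.T)
        d, Q = np.linalg.eigh(M)
        d = np.clip(d, 0.0, None)
        self.M = M
        self.eigenvalues = d
        self.Q = Q
        self.n = M.shape[0]

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.Q.T @ a


@dataclass
class LmmFit:
    """Result of a profiled mixed-model fit."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_w: float
    sigma2_e: float
    lam: float
    loglik: float
    criterion: str  # "ML" or "REML"
    n_params: int  # fixed effects + 2 variance components
    n_obs: int
    converged: bool
    boundary: bool  # lambda pinned at 0 or the upper bound

    @property
    def repeatability(self) -> float:
        tot = self.sigma2_w + self.sigma2_e
        return float(self.sigma2_w / tot) if tot > 0 else 0.0

    @property
    def bic(self) -> float:
        # only meaningful for ML fits
        return float(-2.0 * self.loglik + self.n_params * np.log(self.n_obs))


def _profile_loglik(lam, d, Xt, yt, reml):
    """Profile log-likelihood of lambda after rotation; returns (ll, beta, cov, s2e)."""
    n, p = Xt.shape
    w = 1.0 / (1.0 + lam * d)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    logdetV = float(np.sum(np.log1p(lam * d)))
    if reml:
        dof = n - p
        s2 = rss / dof
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * (dof * (_LOG2PI + 1.0 + np.log(s2)) + logdetV + logdetA)
    else:
        s2 = rss / n
        ll = -0.5 * (n * (_LOG2PI + 1.0 + np.log(s2)) + logdetV)
    cov = np.linalg.inv(A) * s2
    return ll, beta, cov, s2


def fit_lmm(
    y,
    X,
    structure: RandomStructure | None = None,
    groups=None,
    criterion: str = "REML",
    lam_fixed: float | None = None,
) -> LmmFit:
    """Fit y = X beta + (random effect) + e, maximising ML or REML over lambda.

    Parameters
    ----------
    y, X : response vector and fixed-effect design (with intercept column).
    structure : precomputed :class:`RandomStructure`; supply this when fitting
        many responses on the same design.
    groups : observation-level grouping labels, used to build the structure
        if one is not given.
    criterion : "REML" for variance components (repeatability), "ML" for
        likelihood-ratio comparison of fixed-effect structures.
    lam_fixed : evaluate at a fixed variance ratio instead of optimising
        (used for the lambda = 0 null of the repeatability test).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if structure is None:
        structure = RandomStructure(groups=groups)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")
    reml = criterion.upper() == "REML"
    d = structure.eigenvalues
    yt = structure.rotate(y)
    Xt = structure.rotate(X)

    if lam_fixed is not None:
        ll, beta, cov, s2e = _profile_loglik(lam_fixed, d, Xt, yt, reml)
        lam_hat, converged = float(lam_fixed), True
    else:
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(lam, d, Xt, yt, reml)[0],
            bounds=(0.0, _LAMBDA_MAX),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        converged = bool(res.success)
        # the bounded optimiser never quite reaches the ends; snap if flat
        ll0 = _profile_loglik(0.0, d, Xt, yt, reml)[0]
        if ll0 >= -res.fun:
            lam_hat = 0.0
        ll, beta, cov, s2e = _profile_loglik(lam_hat, d, Xt, yt, reml)

    boundary = lam_hat <= 0.0 or lam_hat >= _LAMBDA_MAX * 0.99
    return LmmFit(
        beta=beta,
        beta_cov=cov,
        sigma2_w=lam_hat * s2e,
        sigma2_e=s2e,
        lam=lam_hat,
        loglik=float(ll),
        criterion="REML" if reml else "ML",
        n_params=X.shape[1] + 2,
        n_obs=len(y),
        converged=converged,
        boundary=boundary,
    )


def lrt_variance_p(ll_full: float, ll_null: float) -> tuple[float, float]:
    """Boundary LRT of sigma2_w = 0.

    The null pins the variance at the edge of its parameter space, so the LRT
    statistic follows the half-and-half mixture 0.5*chi2_0 + 0.5*chi2_1 rather
    than chi2_1. Returns (statistic, p).
    """
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    if stat == 0.0:
        return 0.0, 1.0
    return stat, float(0.5 * stats.chi2.sf(stat, df=1))
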