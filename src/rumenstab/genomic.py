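"""Genomic relationship matrix, GBLUP and EBV-microbiome association.

The genomic relationship matrix G (VanRaden method 2) standardises each
marker's dosage by its own allele-frequency variance and averages the
cross-products over markers, so unrelated individuals have expected
relationship 0 and the diagonal averages 1 under Hardy-Weinberg.

GBLUP fits y = X beta + g + e with g ~ N(0, G sigma2_g): heritability
h2 = sigma2_g/(sigma2_g + sigma2_e) and the BLUP of g are the estimated
breeding values (EBVs). Variance components are estimated by a deterministic
1-D REML profile over sigma2_g/sigma2_e in the eigenbasis of G; a seeded
scalar-update Gibbs sampler with flat priors is available as a stochastic
cross-check of the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import RandomStructure, fit_lmm

__all__ = [
    "GenomicRelationship",
    "GblupFit",
    "vanraden_g",
    "fit_gblup",
    "gblup_gibbs",
    "ebv_association",
]


@dataclass
class GenomicRelationship:
    G: pd.DataFrame
    n_markers: int
    allele_freq: np.ndarray


@dataclass
class GblupFit:
    beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    ebv: pd.Series

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0


def vanraden_g(genotypes: pd.DataFrame) -> GenomicRelationship:
    """VanRaden method-2 G: per-marker standardised dosages, averaged over markers.

    z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)), G = Z Z' / m. Monomorphic
    markers (p in {0, 1}) must be removed upstream.
    """
    X = genotypes.to_numpy(dtype=float)
    p = X.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        bad = genotypes.columns[(p <= 0) | (p >= 1)][0]
        raise ValueError(f"monomorphic marker {bad!r}: filter before building G")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = X.shape[1]
    G = Z @ Z.T / m
    return GenomicRelationship(
        G=pd.DataFrame(G, index=genotypes.index, columns=genotypes.index),
        n_markers=m,
        allele_freq=p,
    )


def fit_gblup(trait, fixed_design, G, animal_ids=None) -> GblupFit:
    """REML GBLUP: variance components and EBVs.

    The mixed model is solved by profiling the ratio sigma2_g/sigma2_e in
    the eigenbasis of G (jittered to PSD); EBVs are the BLUP
    g_hat = lambda G (I + lambda G)^-1 (y - X beta_hat).
    """
    Gdf = G.G if isinstance(G, GenomicRelationship) else G
    ids = list(Gdf.index) if isinstance(Gdf, pd.DataFrame) else (
        list(animal_ids) if animal_ids is not None else list(range(len(trait)))
    )
    Gm = np.asarray(Gdf.values if isinstance(Gdf, pd.DataFrame) else Gdf, dtype=float)
    Gm = 0.5 * (Gm + Gm.T) + 1e-8 * np.eye(Gm.shape[0])
    y = np.asarray(trait, dtype=float).ravel()
    X = np.asarray(fixed_design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    structure = RandomStructure(M=Gm)
    fit = fit_lmm(y, X, structure=structure, criterion="REML")
    lam = fit.lam
    resid = y - X @ fit.beta
    # BLUP in the eigenbasis: ghat = Q diag(lam d/(1+lam d)) Q' resid
    d = structure.eigenvalues
    r_rot = structure.rotate(resid)
    ghat = structure.Q @ (lam * d / (1.0 + lam * d) * r_rot)
    return GblupFit(
        beta=fit.beta,
        sigma2_g=fit.sigma2_w,
        sigma2_e=fit.sigma2_e,
        ebv=pd.Series(ghat, index=ids),
    )


def gblup_gibbs(
    trait, fixed_design, G, n_iter: int = 2000, burn_in: int = 500, seed: int = 0
) -> GblupFit:
    """Seeded Gibbs sampler for the same GBLUP model with flat priors.

    Works in the eigenbasis of G, where the breeding-value coordinates are
    conditionally independent scalars; variances are drawn from their scaled
    inverse-chi-square full conditionals (flat priors). Posterior means are
    returned in the same structure as :func:`fit_gblup` for direct comparison.
    """
    Gdf = G.G if isinstance(G, GenomicRelationship) else G
    ids = list(Gdf.index) if isinstance(Gdf, pd.DataFrame) else list(range(len(trait)))
    Gm = np.asarray(Gdf.values if isinstance(Gdf, pd.DataFrame) else Gdf, dtype=float)
    Gm = 0.5 * (Gm + Gm.T) + 1e-8 * np.eye(Gm.shape[0])
    y = np.asarray(trait, dtype=float).ravel()
    X = np.asarray(fixed_design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape

    d, Q = np.linalg.eigh(Gm)
    d = np.clip(d, 1e-10, None)
    rng = np.random.default_rng(seed)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    gamma = np.zeros(n)  # breeding values in the eigenbasis
    s2e = float(np.var(y - X @ beta)) or 1.0
    s2g = s2e
    XtX = X.T @ X
    sums = {"beta": np.zeros(p), "g": np.zeros(n), "s2g": 0.0, "s2e": 0.0}
    kept = 0
    for it in range(n_iter):
        g = Q @ gamma
        # beta | rest
        cov = np.linalg.inv(XtX / s2e)
        mean = cov @ (X.T @ (y - g)) / s2e
        beta = rng.multivariate_normal(mean, cov)
        # gamma | rest (conditionally independent scalars in the eigenbasis)
        r_rot = Q.T @ (y - X @ beta)
        prec = 1.0 / s2e + 1.0 / (s2g * d)
        mu = (r_rot / s2e) / prec
        gamma = mu + rng.standard_normal(n) / np.sqrt(prec)
        g = Q @ gamma
        # variances | rest, flat priors -> scaled inverse chi-square
        ss_g = float(np.sum(gamma * gamma / d))
        s2g = ss_g / rng.chisquare(max(n - 2, 1))
        resid = y - X @ beta - g
        s2e = float(resid @ resid) / rng.chisquare(max(n - 2, 1))
        if it >= burn_in:
            kept += 1
            sums["beta"] += beta
            sums["g"] += g
            sums["s2g"] += s2g
            sums["s2e"] += s2e
    return GblupFit(
        beta=sums["beta"] / kept,
        sigma2_g=sums["s2g"] / kept,
        sigma2_e=sums["s2e"] / kept,
        ebv=pd.Series(sums["g"] / kept, index=ids),
    )


def ebv_association(
    tensor: pd.DataFrame,
    heritable_feature_ids,
    ebv_table: pd.DataFrame,
    vip_threshold: float = 0.8,
    min_timepoints: int = 4,
    n_components: int = 2,
):
    """PLS of heritable features on EBVs per timepoint, with stability selection.

    ``ebv_table`` is animal x trait (EBVs). Delegates to the PLS machinery
    with the EBVs as responses; returns (explained-variance table,
    {trait: StableFeatureSet}).
    """
    from .pls import explained_variance_by_timepoint, stability_selection

    if ebv_table.nunique().min() <= 1:
        raise ValueError("degenerate EBVs: no variance to explain")
    table, models = explained_variance_by_timepoint(
        tensor, ebv_table, feature_subset=list(map(str, heritable_feature_ids)),
        n_components=n_components,
    )
    stable = {}
    for trait in ebv_table.columns:
        per_tp = {tp: m for (tr, tp), m in models.items() if tr == trait}
        stable[trait] = stability_selection(
            per_tp, vip_threshold=vip_threshold, min_timepoints=min_timepoints, trait=trait
        )
    return table, stable
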