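"""Alpha and beta diversity on absolute counts.

Diversity is computed on the unfiltered count tables: rare features
contribute to richness and evenness and to Bray-Curtis dissimilarity even
when they are too noisy for per-feature modelling.

Alpha diversity is the Shannon index adjusted for richness (divided by
ln S, the maximum possible Shannon index for a sample with S nonzero
features), so samples with different richness are comparable on a 0-1
evenness scale. Its timepoint stability is tested with a mixed model
(timepoint fixed, animal random) and a Wald chi-square test.

Beta diversity uses Bray-Curtis dissimilarity with PERMANOVA for the
timepoint effect, pairwise post hoc PERMANOVAs, a dispersion
(homoscedasticity) test, and NMDS ordination for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .lmm import RandomStructure, fit_lmm

__all__ = [
    "AlphaTestResult",
    "PermanovaResult",
    "OrdinationResult",
    "shannon_index",
    "adjusted_shannon",
    "alpha_diversity_table",
    "alpha_timepoint_test",
    "bray_curtis_matrix",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "nmds",
]


@dataclass
class AlphaTestResult:
    wald_chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame | None  # filled only when the omnibus test is significant


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False


@dataclass
class OrdinationResult:
    configuration: pd.DataFrame  # sample x k
    stress: float
    n_restarts: int
    seed: int
    restart_stresses: list[float] = field(default_factory=list)


def shannon_index(count_row) -> float:
    """Shannon entropy (nats) of a sample's relative abundances."""
    x = np.asarray(count_row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def adjusted_shannon(count_row) -> float:
    """Shannon index divided by its maximum ln(S) for the sample's richness S.

    A pure evenness measure in [0, 1]; defined as 0 for a single-feature
    sample, whose evenness is degenerate.
    """
    x = np.asarray(count_row, dtype=float)
    s = int((x > 0).sum())
    if s <= 1:
        if x.sum() <= 0:
            raise ValueError("all-zero sample")
        return 0.0
    return shannon_index(x) / np.log(s)


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, row in counts.iterrows():
        x = row.to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sid,
                "richness": int((x > 0).sum()),
                "shannon": shannon_index(x),
                "adjusted_shannon": adjusted_shannon(x),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def alpha_timepoint_test(
    alpha_values, metadata: pd.DataFrame, alpha: float = 0.05
) -> AlphaTestResult:
    """Mixed-model Wald chi-square test of timepoint on adjusted Shannon.

    Model: value ~ timepoint (fixed) + animal (random intercept), REML.
    If the omnibus test is significant, all pairwise timepoint contrasts of
    the model means are compared with a Tukey-style studentized-range
    adjustment.
    """
    y = np.asarray(alpha_values, dtype=float)
    tps = sorted(metadata["timepoint"].astype(str).unique())
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    # intercept + treatment coding relative to the first timepoint
    X = np.column_stack(
        [np.ones(len(y))]
        + [(metadata["timepoint"].astype(str) == t).to_numpy(float) for t in tps[1:]]
    )
    structure = RandomStructure(groups=metadata["animal_id"].to_numpy())
    fit = fit_lmm(y, X, structure=structure, criterion="REML")

    idx = np.arange(1, len(tps))
    b = fit.beta[idx]
    V = fit.beta_cov[np.ix_(idx, idx)]
    wald = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    p = float(stats.chi2.sf(wald, df))

    pairwise = None
    if p < alpha:
        # model means: intercept (+ contrast for non-reference levels)
        L = np.zeros((len(tps), len(fit.beta)))
        L[:, 0] = 1.0
        for i in range(1, len(tps)):
            L[i, i] = 1.0
        means = L @ fit.beta
        cov_means = L @ fit.beta_cov @ L.T
        k = len(tps)
        ddof = fit.n_obs - len(fit.beta)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                se = np.sqrt(cov_means[i, i] + cov_means[j, j] - 2 * cov_means[i, j])
                q = abs(diff) / (se / np.sqrt(2.0))
                p_adj = float(stats.studentized_range.sf(q, k, ddof))
                rows.append(
                    {
                        "pair": f"{tps[i]}-{tps[j]}",
                        "difference": diff,
                        "se": se,
                        "p_adj": min(1.0, p_adj),
                    }
                )
        pairwise = pd.DataFrame(rows)
    return AlphaTestResult(wald_chi2=wald, df=df, p=p, pairwise=pairwise)


def bray_curtis_matrix(counts) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities, sum|a-b| / sum(a+b), on raw counts."""
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts, float))
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        bad = df.index[x.sum(axis=1) <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _gower_ss(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(d2[np.triu_indices(n, 1)].sum() / n)


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    # sum over groups of (within-group sum of squared d) / group size
    m = d2 @ onehot
    per_group = 0.5 * np.einsum("ig,ig->g", onehot, m)
    return per_group / sizes


def permanova(D, groups, n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) from the Gower-centred
    sum-of-squares decomposition; the p-value counts label permutations whose
    F reaches the observed one, with the +1 correction.
    """
    D = np.asarray(D.values if isinstance(D, pd.DataFrame) else D, dtype=float)
    groups = np.asarray(groups)
    labels, idx = np.unique(groups, return_inverse=True)
    a = len(labels)
    n = D.shape[0]
    if a < 2:
        raise ValueError("need at least 2 groups")
    d2 = D * D
    onehot = np.zeros((n, a))
    onehot[np.arange(n), idx] = 1.0
    sizes = onehot.sum(axis=0)

    ss_total = _gower_ss(d2)
    ss_within = float(_ss_within(d2, onehot, sizes).sum())
    ss_between = ss_total - ss_within
    if ss_within <= 1e-12:
        if ss_total <= 1e-12:
            return PermanovaResult(np.nan, 0.0, 1.0, n_permutations, degenerate=True)
        f_obs = np.inf
    else:
        f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = 0.0 if ss_total <= 0 else ss_between / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        sw = float(_ss_within(d2, onehot[perm], sizes).sum())
        sb = ss_total - sw
        f = np.inf if sw <= 1e-12 else (sb / (a - 1)) / (sw / (n - a))
        if f >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(r2), p=float(p), n_permutations=n_permutations
    )


def pairwise_permanova(
    D, groups, n_permutations: int = 999, seed: int = 0, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Post hoc PERMANOVA restricted to each pair of groups, Bonferroni-adjusted."""
    D = np.asarray(D.values if isinstance(D, pd.DataFrame) else D, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    rows = []
    for k, (g1, g2) in enumerate(pairs):
        mask = (groups == g1) | (groups == g2)
        sub = D[np.ix_(mask, mask)]
        res = permanova(sub, groups[mask], n_permutations=n_permutations, seed=seed + k)
        rows.append(
            {"pair": f"{g1}-{g2}", "pseudo_f": res.pseudo_f, "r2": res.r2, "p_raw": res.p}
        )
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(pairs))
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def _pcoa_embedding(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D * D) @ J
    w, v = np.linalg.eigh(0.5 * (G + G.T))
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    return v[:, order] * np.sqrt(w[order])


def permdisp(D, groups, n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Homogeneity-of-dispersions test (beta-dispersion).

    Samples are embedded by principal coordinates (negative eigenvalues
    truncated at zero); the distance of each sample to its own-group centroid
    is submitted to a one-way ANOVA F, with a permutation p obtained by
    shuffling those distances across groups.
    """
    D = np.asarray(D.values if isinstance(D, pd.DataFrame) else D, dtype=float)
    groups = np.asarray(groups)
    labels, idx = np.unique(groups, return_inverse=True)
    emb = _pcoa_embedding(D)
    z = np.empty(len(groups))
    for g in range(len(labels)):
        mask = idx == g
        centroid = emb[mask].mean(axis=0)
        z[mask] = np.linalg.norm(emb[mask] - centroid, axis=1)

    def f_stat(zv):
        gm = zv.mean()
        ssb = sum(((zv[idx == g].mean() - gm) ** 2) * (idx == g).sum() for g in range(len(labels)))
        ssw = sum(((zv[idx == g] - zv[idx == g].mean()) ** 2).sum() for g in range(len(labels)))
        dfb = len(labels) - 1
        dfw = len(zv) - len(labels)
        if ssw <= 1e-15:
            return 0.0 if ssb <= 1e-15 else np.inf
        return (ssb / dfb) / (ssw / dfw)

    f_obs = f_stat(z)
    rng = np.random.default_rng(seed)
    count = sum(f_stat(rng.permutation(z)) >= f_obs for _ in range(n_permutations))
    p = (1 + count) / (1 + n_permutations)
    return float(f_obs), float(p)


def kruskal_stress(D, configuration) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ) over the upper triangle,
    where d are the configuration's Euclidean distances and dhat the isotonic
    (monotone, primary tie approach) regression of d on the ranks of D.
    """
    from sklearn.isotonic import IsotonicRegression

    D = np.asarray(D.values if isinstance(D, pd.DataFrame) else D, dtype=float)
    conf = np.asarray(configuration, dtype=float)
    iu = np.triu_indices(D.shape[0], 1)
    delta = D[iu]
    d = squareform(pdist(conf))[iu]
    dhat = IsotonicRegression().fit_transform(delta, d)
    denom = float((d * d).sum())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(D, k: int = 2, n_restarts: int = 4, seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    One run starts from the classical-scaling (PCoA) configuration and
    ``n_restarts`` further runs start from seeded random configurations; the
    lowest-stress configuration wins. Reported stress is recomputed from the
    final configuration with :func:`kruskal_stress`.
    """
    Ddf = D if isinstance(D, pd.DataFrame) else None
    D = np.asarray(D.values if Ddf is not None else D, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise ValueError("embedding dimension must be below the sample count")

    def run(init):
        mds = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",  # overridden by the explicit init below
            max_iter=max_iter,
            random_state=0,
            normalized_stress=True,
        )
        conf = mds.fit_transform(D, init=init)
        return conf, kruskal_stress(D, conf)

    inits = [_pcoa_embedding(D)[:, :k]]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        inits.append(rng.standard_normal((n, k)))
    results = [run(init) for init in inits]
    stresses = [s for _, s in results]
    best_conf, best_stress = results[int(np.argmin(stresses))]
    index = Ddf.index if Ddf is not None else pd.RangeIndex(n)
    return OrdinationResult(
        configuration=pd.DataFrame(
            best_conf, index=index, columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        stress=best_stress,
        n_restarts=n_restarts,
        seed=seed,
        restart_stresses=stresses,
    )
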