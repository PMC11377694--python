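"""PLS1 regression, VIP scores and longitudinal biomarker-stability selection.

Microbiome matrices have far more correlated features than samples, so
ordinary regression of a host trait on them is ill-posed. Partial least
squares (PLS) extracts a small number of latent components that maximise
covariance with the trait; the Variable Importance in Projection (VIP)
score then summarises each feature's contribution across components, with
the normalisation mean(VIP^2) = 1, so VIP > 0.8-1.0 is the conventional
"important predictor" band.

Temporal stability of an association is judged across repeated per-timepoint
models: a feature is *important* when its VIP exceeds the threshold in at
least ``min_timepoints`` timepoints, and *stable* when additionally its
regression coefficient keeps one sign in at least ``min_timepoints``
timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlsModel",
    "StableFeatureSet",
    "residualize_traits",
    "fit_pls",
    "vip_scores",
    "explained_variance_by_timepoint",
    "stability_selection",
    "evaluate_biomarker_subset",
]


@dataclass
class PlsModel:
    """A fitted single-response PLS model (NIPALS)."""

    feature_ids: list[str]
    n_components: int
    x_weights: np.ndarray  # p x A
    x_scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coef: np.ndarray  # p, on the centred/scaled predictor space
    r2y: float
    r2y_per_component: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    scaled: bool


@dataclass
class StableFeatureSet:
    trait: str
    important: set[str]
    stable: set[str]
    direction: dict[str, int]  # +1 / -1 for stable features
    vip_threshold: float
    min_timepoints: int
    table: pd.DataFrame


def residualize_traits(phenotypes: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Residuals of each trait after OLS on allocation weight and basal diet.

    Removes the parts of the phenotype trivially explained by starting body
    weight and the basal-diet contrast, so that PLS associations reflect
    microbiome signal rather than these covariates. Requires columns
    ``allocation_weight`` and ``diet``.
    """
    if traits is None:
        traits = [
            c
            for c in phenotypes.columns
            if c not in ("animal_id", "allocation_weight", "diet", "breed")
        ]
    w = phenotypes["allocation_weight"].to_numpy(dtype=float)
    cols = [np.ones(len(phenotypes)), w]
    diets = phenotypes["diet"].astype(str)
    if diets.nunique() > 1:
        cols.append((diets == sorted(diets.unique())[-1]).to_numpy(float))
    else:
        warnings.warn("single basal diet: diet term dropped from residualisation")
    X = np.column_stack(cols)
    out = {}
    for t in traits:
        y = phenotypes[t].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[t] = y - X @ beta
    return pd.DataFrame(out, index=phenotypes.index)


def fit_pls(X, y, n_components: int = 2, scale: bool = True, feature_ids=None) -> PlsModel:
    """Single-response PLS by the NIPALS algorithm.

    X columns are centred (and unit-variance scaled when ``scale``), y is
    centred. Per component: w proportional to X'y (unit norm), t = Xw,
    loadings by least squares, then X is deflated by t p'. Coefficients are
    reported on the centred/scaled predictor space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [str(j) for j in range(p)]
    feature_ids = [str(f) for f in feature_ids]

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        zero = x_scale <= 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance predictors left unscaled")
            x_scale = np.where(zero, 1.0, x_scale)
        Xc = Xc / x_scale
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())
    yc = y - y_mean
    ssy_total = float(yc @ yc)

    A = min(n_components, p, max(1, np.linalg.matrix_rank(Xc)))
    if A < n_components:
        warnings.warn(f"n_components truncated from {n_components} to {A}")

    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    r2_comp = np.zeros(A)
    Xd = Xc.copy()
    yd = yc.copy()
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            A = a
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            A = a
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        r2_comp[a] = 0.0 if ssy_total <= 0 else qa * qa * tt / ssy_total
    W, T, P, q, r2_comp = W[:, :A], T[:, :A], P[:, :A], q[:A], r2_comp[:A]

    # coefficients on the centred/scaled X space: B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q) if A > 0 else np.zeros(p)
    return PlsModel(
        feature_ids=feature_ids,
        n_components=A,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        r2y=float(r2_comp.sum()),
        r2y_per_component=r2_comp,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        scaled=scale,
    )


def vip_scores(model: PlsModel) -> pd.Series:
    """Variable Importance in Projection, SSY-weighted across components.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), so that
    sum_j VIP_j^2 = p. If the model explains no variance, every VIP is
    defined as 1 (uniform importance).
    """
    p = len(model.feature_ids)
    ssy = model.y_loadings**2 * np.einsum("na,na->a", model.x_scores, model.x_scores)
    total = ssy.sum()
    if total <= 0 or model.n_components == 0:
        warnings.warn("zero explained variance: VIP set uniformly to 1")
        return pd.Series(np.ones(p), index=model.feature_ids)
    wn = model.x_weights / np.linalg.norm(model.x_weights, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / total)
    return pd.Series(vip, index=model.feature_ids)


def _tensor_matrix(tensor: pd.DataFrame, timepoint: str, subset=None) -> pd.DataFrame:
    """Extract the animal x feature matrix of one timepoint from a long table.

    ``tensor`` is a samples x features frame with a two-level index or
    columns ('animal_id', 'timepoint') available via metadata join; here we
    require a MultiIndex (animal_id, timepoint).
    """
    sub = tensor.xs(timepoint, level="timepoint")
    if subset is not None:
        subset = [s for s in subset if s in sub.columns]
        sub = sub.loc[:, subset]
    return sub.sort_index()


def explained_variance_by_timepoint(
    tensor: pd.DataFrame,
    traits: pd.DataFrame,
    feature_subset=None,
    n_components: int = 2,
    scale: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PlsModel]]:
    """Per-(trait, timepoint) PLS fits and their explained variances.

    ``tensor`` must carry a (animal_id, timepoint) MultiIndex; ``traits`` is
    animal x trait. Returns a long table with R2Y percentages plus the
    mean +/- sd across timepoints per trait, and the fitted models keyed by
    (trait, timepoint).
    """
    timepoints = sorted(tensor.index.get_level_values("timepoint").unique())
    rows = []
    models: dict[tuple[str, str], PlsModel] = {}
    for tp in timepoints:
        Xdf = _tensor_matrix(tensor, tp, feature_subset)
        if feature_subset is not None and Xdf.shape[1] == 0:
            raise ValueError("no features of the requested subset are available")
        animals = Xdf.index
        for trait in traits.columns:
            y = traits.loc[animals, trait].to_numpy(dtype=float)
            m = fit_pls(
                Xdf.to_numpy(), y, n_components=n_components, scale=scale,
                feature_ids=list(Xdf.columns),
            )
            models[(trait, tp)] = m
            rows.append({"trait": trait, "timepoint": tp, "r2y_percent": 100.0 * m.r2y})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("trait")["r2y_percent"].agg(["mean", "std"]).reset_index()
    )
    table = table.merge(summary, on="trait", suffixes=("", "_trait"))
    return table, models


def stability_selection(
    per_timepoint_models: dict[str, PlsModel],
    vip_threshold: float = 0.8,
    min_timepoints: int = 4,
    trait: str = "",
) -> StableFeatureSet:
    """Apply the longitudinal VIP + sign-consistency rule across timepoints.

    important: VIP > threshold in >= min_timepoints timepoints.
    stable: important AND max(#positive, #negative coefficients) >=
    min_timepoints (a zero coefficient counts as neither sign).
    """
    if len(per_timepoint_models) < min_timepoints:
        raise ValueError("fewer fitted timepoints than min_timepoints")
    tps = sorted(per_timepoint_models)
    feats = per_timepoint_models[tps[0]].feature_ids
    vips = pd.DataFrame({tp: vip_scores(per_timepoint_models[tp]) for tp in tps})
    coefs = pd.DataFrame(
        {tp: pd.Series(per_timepoint_models[tp].coef, index=per_timepoint_models[tp].feature_ids) for tp in tps}
    )
    vips = vips.loc[feats]
    coefs = coefs.loc[feats]

    n_vip = (vips > vip_threshold).sum(axis=1)
    n_pos = (coefs > 0).sum(axis=1)
    n_neg = (coefs < 0).sum(axis=1)
    important_mask = n_vip >= min_timepoints
    sign_mask = np.maximum(n_pos, n_neg) >= min_timepoints
    stable_mask = important_mask & sign_mask
    direction = {
        f: (1 if n_pos[f] >= n_neg[f] else -1) for f in coefs.index[stable_mask]
    }
    table = pd.DataFrame(
        {
            "trait": trait,
            "feature_id": feats,
            "n_timepoints_vip": n_vip.values,
            "n_pos": n_pos.values,
            "n_neg": n_neg.values,
            "important": important_mask.values,
            "stable": stable_mask.values,
            "direction": [direction.get(f, 0) for f in feats],
            "mean_vip": vips.mean(axis=1).values,
        }
    )
    return StableFeatureSet(
        trait=trait,
        important=set(coefs.index[important_mask]),
        stable=set(coefs.index[stable_mask]),
        direction=direction,
        vip_threshold=vip_threshold,
        min_timepoints=min_timepoints,
        table=table,
    )


def evaluate_biomarker_subset(
    tensor: pd.DataFrame,
    traits: pd.DataFrame,
    subset_ids,
    n_components: int = 2,
    scale: bool = True,
) -> pd.DataFrame:
    """Explained variance of traits using only an externally supplied feature set.

    Subset members missing from the table are reported and dropped (they
    failed the inclusion criteria of this dataset); an empty surviving subset
    is an error.
    """
    available = set(map(str, tensor.columns))
    subset_ids = [str(s) for s in subset_ids]
    missing = [s for s in subset_ids if s not in available]
    surviving = [s for s in subset_ids if s in available]
    if not surviving:
        raise ValueError("no subset features present in the data")
    if missing:
        warnings.warn(f"{len(missing)} subset features absent and dropped: {missing[:5]}...")
    table, _ = explained_variance_by_timepoint(
        tensor, traits, feature_subset=surviving, n_components=n_components, scale=scale
    )
    return table
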