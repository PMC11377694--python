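"""Per-feature repeatability and fixed-effect model comparisons.

Repeatability (Rpt, the intraclass correlation) of a microbial feature is
the fraction of its variance attributable to consistent between-animal
differences, sigma2_w / (sigma2_w + sigma2_e), estimated from a mixed model
with animal as random effect and diet + timepoint as fixed effects. A high
Rpt means an animal's relative ranking for that feature persists across
samplings — the defining property of a temporally stable "core" feature.

Two conventions matter and are easy to get wrong:

* model-comparison tests of fixed effects (timepoint, feed additive) use ML
  fits, because REML likelihoods are not comparable across fixed-effect
  structures;
* the significance of Rpt itself uses a REML likelihood-ratio test whose null
  pins sigma2_w at the boundary, hence the 0.5*chi2_0 + 0.5*chi2_1 mixture
  p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LmmFit, RandomStructure, fit_lmm, lrt_variance_p

__all__ = [
    "RepeatabilityEstimate",
    "EffectTestResult",
    "design_matrix",
    "test_timepoint_effect",
    "test_additive_effect",
    "estimate_repeatability",
    "repeatability_table",
    "core_microbiome",
    "compare_rpt_between_diets",
]


@dataclass
class RepeatabilityEstimate:
    feature_id: str
    rpt: float
    sigma2_w: float
    sigma2_e: float
    lrt: float
    p: float
    diet_context: str  # "both", "CON" or "FOR"
    boundary: bool = False


@dataclass
class EffectTestResult:
    feature_id: str
    p_raw: float
    p_bonferroni: float
    delta_bic: float  # with-effect minus without-effect
    supported: bool


def design_matrix(metadata: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Treatment-coded design with intercept for the requested factor columns."""
    cols = [np.ones(len(metadata))]
    for f in factors:
        d = pd.get_dummies(metadata[f].astype(str), drop_first=True, dtype=float)
        cols.extend(d[c].to_numpy() for c in d.columns)
    return np.column_stack(cols)


def _model_comparison(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    full_factors: list[str],
    reduced_factors: list[str],
    tested: str,
    alpha: float,
) -> list[EffectTestResult]:
    X_full = design_matrix(metadata, full_factors)
    X_red = design_matrix(metadata, reduced_factors)
    df_test = X_full.shape[1] - X_red.shape[1]
    if df_test < 1:
        raise ValueError(f"factor {tested!r} adds no columns to the design")
    structure = RandomStructure(groups=metadata["animal_id"].to_numpy())
    m = features.shape[1]
    out = []
    for fid in features.columns:
        y = features[fid].to_numpy(dtype=float)
        try:
            full = fit_lmm(y, X_full, structure=structure, criterion="ML")
            red = fit_lmm(y, X_red, structure=structure, criterion="ML")
        except np.linalg.LinAlgError:
            out.append(EffectTestResult(str(fid), np.nan, np.nan, np.nan, False))
            continue
        lrt = max(0.0, 2.0 * (full.loglik - red.loglik))
        p_raw = float(stats.chi2.sf(lrt, df=df_test))
        p_bonf = min(1.0, p_raw * m)
        delta_bic = full.bic - red.bic
        out.append(
            EffectTestResult(
                feature_id=str(fid),
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                delta_bic=delta_bic,
                supported=bool(p_bonf < alpha and delta_bic < 0),
            )
        )
    return out


def test_timepoint_effect(
    features: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> list[EffectTestResult]:
    """ML model comparison {diet+breed+timepoint} vs {diet+breed}, per feature.

    A feature is "timepoint-affected" only if the Bonferroni-adjusted LRT p
    is below ``alpha`` AND the richer model also has the lower BIC.
    """
    return _model_comparison(
        features,
        metadata,
        ["diet", "breed", "timepoint"],
        ["diet", "breed"],
        "timepoint",
        alpha,
    )


def test_additive_effect(
    features: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> list[EffectTestResult]:
    """ML model comparison {diet+additive+breed+timepoint} vs the same without additive."""
    return _model_comparison(
        features,
        metadata,
        ["diet", "additive", "breed", "timepoint"],
        ["diet", "breed", "timepoint"],
        "additive",
        alpha,
    )


def _rpt_factors(diet_context: str) -> list[str]:
    # within a single diet the diet column is constant and must be dropped
    return ["diet", "timepoint"] if diet_context == "both" else ["timepoint"]


def estimate_repeatability(
    y,
    metadata: pd.DataFrame,
    diet_context: str = "both",
    feature_id: str = "",
    structure: RandomStructure | None = None,
) -> RepeatabilityEstimate:
    """REML variance components and the boundary-LRT significance of Rpt."""
    if diet_context not in ("both", "CON", "FOR"):
        raise ValueError(f"unknown diet context {diet_context!r}")
    y = np.asarray(y, dtype=float).ravel()
    if diet_context != "both":
        mask = (metadata["diet"].astype(str) == diet_context).to_numpy()
        y = y[mask]
        metadata = metadata.loc[mask]
        if metadata["animal_id"].nunique() < 2:
            raise ValueError(f"fewer than 2 animals in diet context {diet_context!r}")
        structure = None
    X = design_matrix(metadata, _rpt_factors(diet_context))
    if structure is None:
        structure = RandomStructure(groups=metadata["animal_id"].to_numpy())
    full = fit_lmm(y, X, structure=structure, criterion="REML")
    null = fit_lmm(y, X, structure=structure, criterion="REML", lam_fixed=0.0)
    lrt, p = lrt_variance_p(full.loglik, null.loglik)
    return RepeatabilityEstimate(
        feature_id=str(feature_id),
        rpt=full.repeatability,
        sigma2_w=full.sigma2_w,
        sigma2_e=full.sigma2_e,
        lrt=lrt,
        p=p,
        diet_context=diet_context,
        boundary=full.boundary,
    )


def repeatability_table(
    features: pd.DataFrame, metadata: pd.DataFrame, diet_context: str = "both"
) -> pd.DataFrame:
    """Rpt estimates for every feature column, sharing one eigendecomposition."""
    if diet_context == "both":
        sub_meta = metadata
        sub_feat = features
    else:
        mask = (metadata["diet"].astype(str) == diet_context).to_numpy()
        sub_meta = metadata.loc[mask]
        sub_feat = features.loc[mask]
    structure = RandomStructure(groups=sub_meta["animal_id"].to_numpy())
    X = design_matrix(sub_meta, _rpt_factors(diet_context))
    rows = []
    for fid in features.columns:
        y = sub_feat[fid].to_numpy(dtype=float)
        full = fit_lmm(y, X, structure=structure, criterion="REML")
        null = fit_lmm(y, X, structure=structure, criterion="REML", lam_fixed=0.0)
        lrt, p = lrt_variance_p(full.loglik, null.loglik)
        rows.append(
            RepeatabilityEstimate(
                feature_id=str(fid),
                rpt=full.repeatability,
                sigma2_w=full.sigma2_w,
                sigma2_e=full.sigma2_e,
                lrt=lrt,
                p=p,
                diet_context=diet_context,
                boundary=full.boundary,
            )
        )
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "context": [r.diet_context for r in rows],
            "sigma2_w": [r.sigma2_w for r in rows],
            "sigma2_e": [r.sigma2_e for r in rows],
            "rpt": [r.rpt for r in rows],
            "lrt": [r.lrt for r in rows],
            "p": [r.p for r in rows],
            "significant": [r.p < 0.05 for r in rows],
        }
    )


def core_microbiome(
    rpt_both: pd.DataFrame,
    rpt_con: pd.DataFrame | None = None,
    rpt_for: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Feature sets with significant (raw p < alpha) repeatability.

    Returns the across-diet core plus, when the within-diet tables are given,
    the per-diet cores and their intersection. p-values are deliberately
    unadjusted: the core set is defined by raw p < 0.05.
    """
    out = {"both": set(rpt_both.loc[rpt_both["p"] < alpha, "feature_id"])}
    if rpt_con is not None:
        out["CON"] = set(rpt_con.loc[rpt_con["p"] < alpha, "feature_id"])
    if rpt_for is not None:
        out["FOR"] = set(rpt_for.loc[rpt_for["p"] < alpha, "feature_id"])
    if rpt_con is not None and rpt_for is not None:
        out["intersection"] = out["CON"] & out["FOR"]
    return out


def compare_rpt_between_diets(
    estimates_con: pd.DataFrame, estimates_for: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Paired two-sided Wilcoxon signed-rank test of Rpt differences across diets."""
    merged = estimates_con.merge(
        estimates_for, on="feature_id", suffixes=("_con", "_for")
    )
    if len(merged) < 5:
        raise ValueError("fewer than 5 shared features between diet contexts")
    diff = merged["rpt_con"] - merged["rpt_for"]
    table = merged[["feature_id", "rpt_con", "rpt_for"]].assign(difference=diff)
    if np.allclose(diff, 0.0):
        return 1.0, table
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue), table
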