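"""Feature filtering and compositional log-ratio transforms.

Microbiome count tables are compositional: only relative information is
meaningful, so abundances are mapped to unconstrained real space with the
centred log-ratio (CLR) or additive log-ratio (ALR) transform before any
Euclidean modelling. The ALR reference feature is chosen data-driven: a good
denominator yields an ALR geometry close to the CLR geometry (high Procrustes
correlation) while itself varying little on the log scale, so that log-ratios
are interpretable as the numerator's own variation.

All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "TransformedAbundances",
    "DenominatorDiagnostics",
    "relative_abundance",
    "filter_features",
    "clr_transform",
    "alr_transform",
    "procrustes_correlation",
    "select_alr_denominator",
    "center_features",
]


@dataclass
class FilterReport:
    """Bookkeeping for a prevalence + mean-relative-abundance filter.

    Features failing both rules are counted once, under prevalence.
    """

    n_input_features: int
    n_removed_prevalence: int
    n_removed_abundance: int
    retained: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


@dataclass
class TransformedAbundances:
    """A sample x feature real-valued matrix plus transform provenance."""

    matrix: pd.DataFrame
    transform: str  # "CLR" or "ALR"
    denominator_id: str | None = None
    pseudocount: float = 0.0


@dataclass
class DenominatorDiagnostics:
    """Per-candidate diagnostics of the ALR reference selection rule."""

    table: pd.DataFrame  # columns: feature_id, procrustes_r, log_variance
    selected: str
    top_fraction: float


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    return pd.DataFrame(np.asarray(counts, dtype=float))


def relative_abundance(counts) -> pd.DataFrame:
    """Convert a sample x feature count table to per-sample proportions."""
    df = _as_frame(counts)
    sums = df.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = df.index[zero][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return df.div(sums, axis=0)


def filter_features(
    counts,
    min_prevalence_fraction: float = 1.0,
    min_mean_relabund: float = 1e-5,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rare features before modelling.

    A feature is retained only if it is nonzero in at least
    ``min_prevalence_fraction`` of the samples AND its mean relative
    abundance over all samples is at least ``min_mean_relabund``
    (0.001% corresponds to the fraction 1e-5). Low-abundance features carry
    mostly sampling noise and inflate the multiple-testing burden downstream.
    """
    df = _as_frame(counts)
    rel = relative_abundance(df)
    n = df.shape[0]
    prevalence = (df > 0).sum(axis=0) / n
    mean_rel = rel.mean(axis=0)

    fails_prev = prevalence < min_prevalence_fraction
    fails_abund = mean_rel < min_mean_relabund
    keep = ~(fails_prev | fails_abund)
    if not keep.any():
        raise ValueError("all features removed by the filter")
    report = FilterReport(
        n_input_features=df.shape[1],
        n_removed_prevalence=int(fails_prev.sum()),
        n_removed_abundance=int((fails_abund & ~fails_prev).sum()),
        retained=[str(c) for c in df.columns[keep]],
    )
    return df.loc[:, keep], report


def _log_with_pseudocount(df: pd.DataFrame, pseudocount: float) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("zero entries present; a positive pseudocount is required")
    return np.log(x + pseudocount)


def clr_transform(counts, pseudocount: float = 0.5) -> TransformedAbundances:
    """Centred log-ratio: log x minus the per-sample mean of log x.

    Rows of the result sum to zero; the transform removes the arbitrary
    total-count scale of each sample.
    """
    df = _as_frame(counts)
    logx = _log_with_pseudocount(df, pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return TransformedAbundances(
        matrix=pd.DataFrame(out, index=df.index, columns=df.columns),
        transform="CLR",
        pseudocount=pseudocount,
    )


def alr_transform(counts, denominator_id, pseudocount: float = 0.5) -> TransformedAbundances:
    """Additive log-ratio against a fixed reference feature.

    Every feature j != d becomes log((x_j + pc) / (x_d + pc)); the reference
    column is dropped, so the output has one fewer column than the input.
    """
    df = _as_frame(counts)
    if denominator_id not in df.columns:
        raise KeyError(f"denominator {denominator_id!r} not in table")
    logx = _log_with_pseudocount(df, pseudocount)
    d_pos = df.columns.get_loc(denominator_id)
    out = logx - logx[:, [d_pos]]
    keep = [c for c in df.columns if c != denominator_id]
    out = np.delete(out, d_pos, axis=1)
    return TransformedAbundances(
        matrix=pd.DataFrame(out, index=df.index, columns=keep),
        transform="ALR",
        denominator_id=str(denominator_id),
        pseudocount=pseudocount,
    )


def procrustes_correlation(X, Y) -> float:
    """Procrustes correlation between two sample configurations.

    Both matrices are column-centred; the correlation is
    sum of singular values of Y'X divided by sqrt(tr(X'X) tr(Y'Y)),
    i.e. the cosine similarity of the two configurations after optimal
    rotation, invariant to orthogonal rotation and global scaling of either
    argument.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows (samples)")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssx = np.sum(Xc * Xc)
    ssy = np.sum(Yc * Yc)
    if ssx <= 0 or ssy <= 0:
        raise ValueError("zero-variance configuration: Procrustes correlation undefined")
    s = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
    return float(s.sum() / np.sqrt(ssx * ssy))


def select_alr_denominator(
    counts, pseudocount: float = 0.5, top_fraction: float = 0.1
) -> DenominatorDiagnostics:
    """Pick the ALR reference feature.

    For every candidate d, compute the Procrustes correlation between
    ALR_d and the CLR matrix, and the variance of log(x_d + pc) across
    samples. Among the candidates in the top ``top_fraction`` by Procrustes
    correlation, pick the one with minimum log-variance; ties broken by
    column order.
    """
    df = _as_frame(counts)
    if df.shape[1] < 3:
        raise ValueError("need at least 3 features to select an ALR denominator")
    logx = _log_with_pseudocount(df, pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    log_var = logx.var(axis=0, ddof=1)

    rs = np.empty(df.shape[1])
    for j in range(df.shape[1]):
        alr = np.delete(logx - logx[:, [j]], j, axis=1)
        rs[j] = procrustes_correlation(alr, clr)

    n_top = max(1, int(np.ceil(top_fraction * df.shape[1])))
    # stable sort; among equal r the earlier column wins a top-set place
    order = np.argsort(-rs, kind="stable")
    top = order[:n_top]
    best = min(top, key=lambda j: (log_var[j], j))
    table = pd.DataFrame(
        {
            "feature_id": [str(c) for c in df.columns],
            "procrustes_r": rs,
            "log_variance": log_var,
        }
    )
    return DenominatorDiagnostics(
        table=table, selected=str(df.columns[best]), top_fraction=top_fraction
    )


def center_features(matrix) -> pd.DataFrame:
    """Centre each feature column on its grand mean over all samples."""
    df = _as_frame(matrix)
    return df - df.mean(axis=0)
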