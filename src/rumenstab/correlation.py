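"""Pearson correlation of whole microbiome profiles between timepoints.

Each timepoint's animal x feature matrix (log-ratio transformed abundances,
centred per feature on the grand mean over all samples) is flattened in a
fixed animal-major order; the Pearson correlation of two timepoints'
vectors measures how well the whole multivariate profile is preserved
between samplings. Restricting to the repeatable "core" features raises
these correlations — the temporal signal lives in the repeatable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import center_features

__all__ = ["TimepointCorrelationMatrix", "timepoint_correlations"]


@dataclass
class TimepointCorrelationMatrix:
    matrix: pd.DataFrame  # T x T Pearson r
    feature_subset: str
    n_animals: int
    n_features: int


def timepoint_correlations(
    tensor: pd.DataFrame,
    feature_subset=None,
    subset_label: str = "all",
    center: bool = True,
) -> TimepointCorrelationMatrix:
    """Pairwise Pearson r between vectorized per-timepoint matrices.

    ``tensor`` is a samples x features frame with a (animal_id, timepoint)
    MultiIndex. Features are centred on their grand mean over all samples
    (after subsetting); every animal must be present at every timepoint.
    """
    if feature_subset is not None:
        cols = [c for c in tensor.columns if str(c) in set(map(str, feature_subset))]
        if not cols:
            raise ValueError("feature subset empty after intersection with data")
        tensor = tensor.loc[:, cols]
    if center:
        tensor = center_features(tensor)

    timepoints = sorted(tensor.index.get_level_values("timepoint").unique())
    animals = sorted(tensor.index.get_level_values("animal_id").unique())
    vecs = {}
    for tp in timepoints:
        sub = tensor.xs(tp, level="timepoint")
        missing = [a for a in animals if a not in sub.index]
        if missing:
            raise ValueError(f"animal {missing[0]!r} missing at timepoint {tp!r}")
        # animal-major flattening in a fixed animal order
        vecs[tp] = sub.loc[animals].to_numpy(dtype=float).ravel()

    T = len(timepoints)
    r = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            r[i, j] = r[j, i] = np.corrcoef(vecs[timepoints[i]], vecs[timepoints[j]])[0, 1]
    return TimepointCorrelationMatrix(
        matrix=pd.DataFrame(r, index=timepoints, columns=timepoints),
        feature_subset=subset_label,
        n_animals=len(animals),
        n_features=tensor.shape[1],
    )
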