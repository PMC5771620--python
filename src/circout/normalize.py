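"""Cross-time-point normalizations for peak x time signal matrices.

Two schemes correct for global differences in assay efficiency between
circadian time points (e.g. ChIP efficiency drifting between samples):

* **mean normalization** — divide each time point by the mean signal over a
  large reference site set (e.g. the top 40,000 open-chromatin sites),
  assuming genome-wide levels of the mark are constant over the day;
* **rank (quantile-style) normalization** — replace each value by the
  across-time average of the order statistics at its within-column rank,
  forcing identical signal distributions at every time point.

Matrices are wide pandas DataFrames: rows = sites/peaks, columns = time
points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReferenceProfile", "reference_profile", "mean_normalize", "rank_normalize"]


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-time-point mean signal over a reference site set."""

    reference_mean: pd.Series  # index = time points

    def __post_init__(self) -> None:
        bad = self.reference_mean[self.reference_mean <= 0]
        if len(bad):
            raise ValueError(
                f"reference mean must be positive; offending time points: "
                f"{list(bad.index)}"
            )


def reference_profile(matrix: pd.DataFrame, reference_ids=None) -> ReferenceProfile:
    """Column means over the reference rows (all rows when ``reference_ids``
    is None)."""
    sub = matrix if reference_ids is None else matrix.loc[list(reference_ids)]
    return ReferenceProfile(sub.mean(axis=0))


def mean_normalize(matrix: pd.DataFrame, reference: ReferenceProfile) -> pd.DataFrame:
    """value(site, t) / reference_mean(t), column-aligned."""
    missing = [c for c in matrix.columns if c not in reference.reference_mean.index]
    if missing:
        raise ValueError(f"reference profile lacks time points {missing}")
    return matrix / reference.reference_mean.reindex(matrix.columns)


def rank_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-style ranking normalization across time-point columns.

    Each column is sorted, the across-column mean of the sorted values is
    taken at every rank, and each raw value is replaced by the rank-mean at
    its within-column rank.  Ties receive the mean of their tied ranks'
    reference values, so the result is well-defined and idempotent.  All
    output columns share the same sorted values (and hence the same mean).
    """
    if matrix.isna().any().any():
        raise ValueError("matrix must be complete (no missing values)")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    rank_means = np.sort(x, axis=0).mean(axis=1)  # reference distribution

    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n)
        # average the reference over tied ranks
        vals = rank_means[ranks.astype(int)]
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=vals)
        cnts = np.bincount(inv)
        out[:, j] = (sums / cnts)[inv]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
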