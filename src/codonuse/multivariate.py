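"""Principal component analysis of 59-dimensional RSCU vectors.

Each gene is a point in the 59-codon RSCU space; centered, unscaled PCA
summarizes the main trends of synonymous codon usage variation. Undefined
RSCU entries (families unobserved in a gene) are imputed with the column
mean, which makes them inert after centering. Axis signs are fixed by a
deterministic convention (the loading with the largest magnitude on each
axis is made positive) so score tables reproduce bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codons import CODON_UNIVERSE, to_rna
from .rscu import RSCUVector


@dataclass(frozen=True)
class PCAResult:
    """Inertia fractions, per-gene scores and per-codon loadings."""

    inertia: np.ndarray  # explained-inertia fraction of every positive axis
    scores: pd.DataFrame  # rows = sequences, columns axis1..axisN
    loadings: pd.DataFrame  # rows = RNA codons, columns axis1..axisN
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pca_rscu(
    vectors: Sequence[RSCUVector],
    ids: Sequence[str] | None = None,
    n_axes: int = 4,
) -> PCAResult:
    """Centered PCA of a set of RSCU vectors.

    Returns inertia fractions for all positive-variance axes and scores and
    loadings for the first ``n_axes`` (truncated with a warning if the rank
    is lower).
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 sequences for PCA")
    if ids is None:
        ids = [f"seq{i+1}" for i in range(len(vectors))]
    if len(ids) != len(vectors):
        raise ValueError("ids/vectors length mismatch")

    X = np.vstack([v.as_array() for v in vectors])
    # impute undefined entries with the column mean (inert once centered)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    centered = X - X.mean(axis=0)
    total_var = float((centered**2).sum())
    if total_var == 0.0:
        axes = [f"axis{i+1}" for i in range(n_axes)]
        scores = pd.DataFrame(0.0, index=list(ids), columns=axes)
        loadings = pd.DataFrame(
            0.0, index=[to_rna(c) for c in CODON_UNIVERSE], columns=axes
        )
        return PCAResult(
            inertia=np.array([]), scores=scores, loadings=loadings,
            degenerate=True,
        )

    pca = PCA(n_components=None, svd_solver="full")
    raw_scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    positive = ratios > 1e-12
    rank = int(positive.sum())
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_axes = rank

    comps = pca.components_[:n_axes]
    scores_kept = raw_scores[:, :n_axes].copy()
    for j in range(n_axes):
        lead = int(np.argmax(np.abs(comps[j])))
        if comps[j, lead] < 0:
            comps[j] = -comps[j]
            scores_kept[:, j] = -scores_kept[:, j]

    axes = [f"axis{i+1}" for i in range(n_axes)]
    scores = pd.DataFrame(scores_kept, index=list(ids), columns=axes)
    loadings = pd.DataFrame(
        comps.T, index=[to_rna(c) for c in CODON_UNIVERSE], columns=axes
    )
    return PCAResult(
        inertia=ratios[:rank].copy(), scores=scores, loadings=loadings
    )


def inertia_table(result: PCAResult) -> pd.DataFrame:
    """Per-axis explained and cumulative inertia (percent)."""
    pct = 100.0 * result.inertia
    return pd.DataFrame(
        {
            "axis": [f"axis{i+1}" for i in range(len(pct))],
            "inertia_pct": pct,
            "cumulative_pct": np.cumsum(pct),
        }
    )
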