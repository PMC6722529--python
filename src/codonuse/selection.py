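"""Mutation-versus-selection diagnostics.

Three complementary views of what drives codon usage:

* PR2 plot -- within fourfold-degenerate families, pure strand-symmetric
  mutation predicts A=U and G=C at third positions, i.e. both A3/(A3+U3)
  and G3/(G3+C3) equal 0.5.
* Neutrality plot -- OLS regression of GC12 on GC3 across genes; the slope
  is read as the mutational share of the pressure on codon usage (slope 1 =
  pure mutation), selection share = 100 - 100*slope.
* Spearman rank correlations between protein covariates (GRAVY, aromaticity)
  and usage summaries (ENC, GC3s, GC, PCA axes), with the usual star
  convention (** p<0.01, * p<0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AA_TO_CODONS, FOURFOLD_AAS, SIXFOLD_FOURFOLD_BOXES
from .seq_io import CodonCounts

PR2Mode = Literal["strict4", "include6fold"]


@dataclass(frozen=True)
class PR2Point:
    at_bias: float  # A3 / (A3 + U3)
    gc_bias: float  # G3 / (G3 + C3)
    n_codons: int
    at_defined: bool = True
    gc_defined: bool = True


def pr2_point(counts: CodonCounts, mode: PR2Mode = "strict4") -> PR2Point:
    """PR2 coordinates from fourfold-family third positions.

    ``strict4`` uses Ala/Gly/Pro/Thr/Val only; ``include6fold`` adds the
    fourfold codon boxes of Leu, Ser and Arg.
    """
    codons: list[str] = []
    for aa in FOURFOLD_AAS:
        codons.extend(AA_TO_CODONS[aa])
    if mode == "include6fold":
        for box in SIXFOLD_FOURFOLD_BOXES.values():
            codons.extend(box)
    third = {"A": 0, "C": 0, "G": 0, "T": 0}
    total = 0
    for c in codons:
        g = counts.g[c]
        third[c[2]] += g
        total += g
    if total == 0:
        raise ValueError("no fourfold-family codons observed")
    au = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    return PR2Point(
        at_bias=third["A"] / au if au else math.nan,
        gc_bias=third["G"] / gc if gc else math.nan,
        n_codons=total,
        at_defined=au > 0,
        gc_defined=gc > 0,
    )


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def neutrality_fit(
    gc12: Sequence[float], gc3: Sequence[float]
) -> NeutralityFit:
    """OLS regression of GC12 on GC3 with a two-sided slope t-test."""
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    if gc12.shape != gc3.shape:
        raise ValueError("GC12 and GC3 lengths differ")
    n = gc12.size
    if n < 3:
        raise ValueError("need at least 3 points for a neutrality fit")
    if np.ptp(gc3) == 0:
        raise ValueError("degenerate regression: GC3 is constant")
    fit = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        pvalue=float(fit.pvalue),
        n=int(n),
    )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    n: int
    method: str

    @property
    def stars(self) -> str:
        if math.isnan(self.pvalue):
            return "na"
        if self.pvalue < 0.01:
            return "**"
        if self.pvalue < 0.05:
            return "*"
        return "ns"


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (mid-ranks, n <= 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "t", "exact"] = "auto",
) -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties.

    p-values use the t approximation; ``exact`` enumerates all rank
    permutations (feasible for n <= 10), the default for small samples
    under ``auto``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, "constant")
    if method == "auto":
        method = "exact" if n <= 10 else "t"
    rho, p_t = stats.spearmanr(x, y)
    if method == "t":
        return CorrelationResult(float(rho), float(p_t), n, "t")
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    p = _exact_spearman_p(x, y, float(rho))
    return CorrelationResult(float(rho), p, n, "exact")


def correlation_matrix(
    table: pd.DataFrame,
    rows: Sequence[str] = ("gravy", "aroma"),
    cols: Sequence[str] = ("enc", "gc3s", "gc", "axis1", "axis2"),
    method: Literal["auto", "t", "exact"] = "t",
) -> pd.DataFrame:
    """Tidy Spearman-correlation table between covariates and usage summaries."""
    missing = [c for c in (*rows, *cols) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table) < 5:
        raise ValueError("need at least 5 sequences")
    if table[list(rows) + list(cols)].isna().any().any():
        raise ValueError("missing values in correlation inputs")
    out = []
    for r in rows:
        for c in cols:
            res = spearman(table[r], table[c], method=method)
            out.append(
                {
                    "variable": r,
                    "against": c,
                    "rho": res.rho,
                    "pvalue": res.pvalue,
                    "stars": res.stars,
                    "n": res.n,
                }
            )
    return pd.DataFrame(out)
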