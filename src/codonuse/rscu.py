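"""Relative synonymous codon usage.

RSCU of codon i in a family of n_i synonyms is the observed count divided by
the family mean count, equivalently g_ij * n_i / sum_family(g). A value of 1
means no bias; values above 1.6 are called overrepresented and below 0.6
underrepresented. Families with zero observations are undefined (NaN), never
imputed as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    CODON_UNIVERSE,
    DEGENERATE_AAS,
    to_rna,
)
from .seq_io import CodonCounts, pool_counts

OVER_THRESHOLD = 1.6
UNDER_THRESHOLD = 0.6


def classify(value: float, over: float = OVER_THRESHOLD,
             under: float = UNDER_THRESHOLD) -> str:
    if math.isnan(value):
        return "undefined"
    if value > over:
        return "overrepresented"
    if value < under:
        return "underrepresented"
    return "normal"


@dataclass(frozen=True)
class RSCUVector:
    """RSCU value per codon of the 59-codon universe (NaN = family unseen)."""

    values: Mapping[str, float]
    n_per_family: Mapping[str, int]

    def __post_init__(self):
        missing = set(CODON_UNIVERSE) - set(self.values)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")

    def classification(self) -> dict[str, str]:
        return {c: classify(v) for c, v in self.values.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.values[c] for c in CODON_UNIVERSE])

    def defined_families(self) -> tuple[str, ...]:
        return tuple(
            aa for aa in DEGENERATE_AAS if self.n_per_family.get(aa, 0) > 0
        )


def rscu(counts: CodonCounts) -> RSCUVector:
    """RSCU vector of one sequence's codon counts."""
    if not counts.exclude_nonbias:
        raise ValueError("RSCU is defined on the 59-codon universe")
    values: dict[str, float] = {}
    n_fam: dict[str, int] = {}
    for aa in DEGENERATE_AAS:
        fam = AA_TO_CODONS[aa]
        n = sum(counts.g[c] for c in fam)
        n_fam[aa] = n
        if n == 0:
            for c in fam:
                values[c] = math.nan
            continue
        k = len(fam)
        for c in fam:
            values[c] = counts.g[c] * k / n
    return RSCUVector(values=values, n_per_family=n_fam)


def mean_rscu(group: Sequence[RSCUVector]) -> RSCUVector:
    """Per-codon arithmetic mean over sequences whose family is defined.

    This is the "mean of per-sequence RSCU" convention; codons whose family
    is unobserved in a given sequence are excluded from that codon's mean
    rather than counted as zero.
    """
    if not group:
        raise ValueError("empty group")
    values: dict[str, float] = {}
    n_fam: dict[str, int] = {}
    for aa in DEGENERATE_AAS:
        defined = [v for v in group if v.n_per_family.get(aa, 0) > 0]
        n_fam[aa] = len(defined)
        for c in AA_TO_CODONS[aa]:
            if defined:
                values[c] = float(np.mean([v.values[c] for v in defined]))
            else:
                values[c] = math.nan
    return RSCUVector(values=values, n_per_family=n_fam)


def pooled_rscu(counts: Iterable[CodonCounts]) -> RSCUVector:
    """RSCU of the pooled codon tally (alternative to :func:`mean_rscu`)."""
    return rscu(pool_counts(counts))


def preferred_codons(vec: RSCUVector) -> dict[str, tuple[str, bool]]:
    """Most-used codon per family: (codon, tie_flag), ties lexicographic."""
    out: dict[str, tuple[str, bool]] = {}
    for aa in DEGENERATE_AAS:
        fam = AA_TO_CODONS[aa]
        vals = [(vec.values[c], c) for c in fam]
        if all(math.isnan(v) for v, _ in vals):
            continue
        best = max(v for v, _ in vals if not math.isnan(v))
        winners = sorted(c for v, c in vals if v == best)
        out[aa] = (winners[0], len(winners) > 1)
    return out


def rscu_table(groups: Mapping[str, RSCUVector]) -> pd.DataFrame:
    """Publication-style RSCU table: codon, amino acid, one column per group.

    A ``<group>_preferred`` marker column flags each family's most-used codon
    (the bolding of printed tables); ``<group>_tie`` flags lexicographic
    tie-breaks.
    """
    rows = []
    marks = {name: preferred_codons(vec) for name, vec in groups.items()}
    for codon in CODON_UNIVERSE:
        aa = CODON_TO_AA[codon]
        row: dict[str, object] = {"codon": to_rna(codon), "aa": aa}
        for name, vec in groups.items():
            row[name] = vec.values[codon]
            pref = marks[name].get(aa)
            row[f"{name}_preferred"] = bool(pref and pref[0] == codon)
            row[f"{name}_tie"] = bool(pref and pref[0] == codon and pref[1])
        rows.append(row)
    return pd.DataFrame(rows)
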