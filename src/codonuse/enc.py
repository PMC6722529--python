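"""Wright's effective number of codons (ENC) and the ENC-GC3s expected curve.

For a k-fold degenerate family with total count n and codon counts n_i, the
codon homozygosity is S = sum((n_i/n)^2) and F = (nS - 1)/(n - 1). Class means
Fbar_k over k in {2, 3, 4, 6} assemble

    ENC = 2 + 9/Fbar_2 + 1/Fbar_3 + 5/Fbar_4 + 3/Fbar_6

ranging from 20 (one codon per family) to 61 (uniform synonymous usage).
Genes with ENC <= 35 are conventionally called significantly biased. The
null expectation under pure GC-driven mutation pressure is

    ENC_expected(s) = 2 + s + 29 / (s^2 + (1-s)^2),   s = GC3s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .codons import AA_TO_CODONS, DEGENERACY, DEGENERATE_AAS
from .composition import gc3s_fraction
from .seq_io import CodingSequence, CodonCounts, count_codons

#: number of amino-acid families per degeneracy class
FAMILIES_PER_CLASS = {2: 9, 3: 1, 4: 5, 6: 3}

SIGNIFICANT_BIAS_THRESHOLD = 35.0


class ENCError(ValueError):
    """ENC cannot be estimated from these counts."""


@dataclass(frozen=True)
class FamilyF:
    aa: str
    k: int
    n: int
    S: float
    F: float


@dataclass(frozen=True)
class ENCResult:
    enc: float
    fbar: dict[int, float]
    families: tuple[FamilyF, ...]
    gc3s: float
    imputed: tuple[int, ...] = ()
    excluded: tuple[str, ...] = ()  # families skipped (n<2 or F<=0)
    clamped: bool = False

    @property
    def usable(self) -> bool:
        return not self.imputed

    @property
    def significant_bias(self) -> bool:
        return self.enc <= SIGNIFICANT_BIAS_THRESHOLD


def family_F(family_counts: Sequence[int]) -> float:
    """Codon homozygosity estimator F = (nS - 1)/(n - 1) for one family."""
    n = sum(family_counts)
    if n < 2:
        raise ENCError(f"family total n={n} < 2")
    S = sum((ni / n) ** 2 for ni in family_counts)
    return (n * S - 1.0) / (n - 1.0)


def enc(counts: CodonCounts) -> ENCResult:
    """Wright's ENC from a codon tally (59-codon universe)."""
    if not counts.exclude_nonbias:
        raise ValueError("ENC is defined on the 59-codon universe")
    families: list[FamilyF] = []
    excluded: list[str] = []
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa in DEGENERATE_AAS:
        fam = counts.family_counts(aa)
        n = sum(fam)
        if n < 2:
            excluded.append(aa)
            continue
        S = sum((ni / n) ** 2 for ni in fam)
        F = (n * S - 1.0) / (n - 1.0)
        if F <= 0.0:
            # n*S = 1 can occur for tiny equi-used families; CodonW drops them
            excluded.append(aa)
            continue
        families.append(FamilyF(aa=aa, k=DEGENERACY[aa], n=n, S=S, F=F))
        per_class[DEGENERACY[aa]].append(F)

    fbar = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if 2 not in fbar or 4 not in fbar:
        raise ENCError("sequence too short for ENC (no 2- or 4-fold family)")
    if 6 not in fbar:
        raise ENCError("sequence too short for ENC (no 6-fold family)")
    imputed: tuple[int, ...] = ()
    if 3 not in fbar:
        # Wright's correction when Ile is absent
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
        imputed = (3,)

    value = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    clamped = value > 61.0
    if clamped:
        value = 61.0
    return ENCResult(
        enc=value,
        fbar=fbar,
        families=tuple(families),
        gc3s=gc3s_fraction(counts),
        imputed=imputed,
        excluded=tuple(excluded),
        clamped=clamped,
    )


def enc_expected(s: float) -> float:
    """Expected ENC under pure mutational GC pressure at GC3s = s (0-1)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_plot_table(seqs: Sequence[CodingSequence]) -> pd.DataFrame:
    """Per-sequence (GC3s, ENC, expected ENC, below-curve flag) table."""
    if not seqs:
        raise ValueError("no sequences")
    rows = []
    for s in seqs:
        res = enc(count_codons(s, exclude_nonbias=True))
        exp = enc_expected(res.gc3s)
        rows.append(
            {
                "id": s.id,
                "host": s.host,
                "group": s.group,
                "gc3s": res.gc3s,
                "enc": res.enc,
                "expected_enc": exp,
                "below_curve": res.enc < exp,
                "significant_bias": res.significant_bias,
            }
        )
    return pd.DataFrame(rows)
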