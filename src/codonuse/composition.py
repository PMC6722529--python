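"""Nucleotide composition and protein-level covariates.

Overall A/C/G/U percentages are computed over the full coding sequence;
positional statistics (A3s..U3s, GC1s/GC2s/GC3s) are computed over
synonymous codons only, i.e. after removing the five non-bias codons
(AUG, UGG and the three stops), which is the CodonW convention. GC12s is
the arithmetic mean of GC1s and GC2s.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .codons import CODON_UNIVERSE
from .seq_io import CodingSequence, CodonCounts, count_codons, translate

_GC = frozenset("GC")
_STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CompositionProfile:
    """Percent composition of one CDS (0-100 scale throughout)."""

    a: float
    c: float
    g: float
    u: float
    a3s: float
    c3s: float
    g3s: float
    u3s: float
    gc1s: float
    gc2s: float
    gc3s: float
    gc12s: float
    gc: float
    au: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class ProteinIndices:
    """Kyte-Doolittle GRAVY and aromatic-residue fraction of a protein."""

    gravy: float
    aroma: float


def gc3s_fraction(counts: CodonCounts) -> float:
    """G+C fraction (0-1) at third positions of synonymous codons."""
    syn = {c: counts.g[c] for c in CODON_UNIVERSE}
    n = sum(syn.values())
    if n == 0:
        raise ValueError("no synonymous codons")
    return sum(g for c, g in syn.items() if c[2] in _GC) / n


def composition_profile(
    seq: CodingSequence, counts: CodonCounts | None = None
) -> CompositionProfile:
    """Full nucleotide-composition profile of one coding sequence."""
    if counts is None:
        counts = count_codons(seq, exclude_nonbias=True)
    if not counts.exclude_nonbias:
        raise ValueError("positional statistics need exclude_nonbias counts")

    nt = seq.sequence
    total = len(nt)
    overall = {b: 100.0 * nt.count(b) / total for b in "ACGT"}

    syn = {c: counts.g[c] for c in CODON_UNIVERSE}
    n_syn = sum(syn.values())
    if n_syn == 0:
        raise ValueError(f"{seq.id}: no synonymous codons")

    def pos_pct(base: str, pos: int) -> float:
        return 100.0 * sum(g for c, g in syn.items() if c[pos] == base) / n_syn

    def gc_pct(pos: int) -> float:
        return 100.0 * sum(g for c, g in syn.items() if c[pos] in _GC) / n_syn

    gc1s, gc2s, gc3s = gc_pct(0), gc_pct(1), gc_pct(2)
    gc_total = overall["G"] + overall["C"]
    return CompositionProfile(
        a=overall["A"],
        c=overall["C"],
        g=overall["G"],
        u=overall["T"],
        a3s=pos_pct("A", 2),
        c3s=pos_pct("C", 2),
        g3s=pos_pct("G", 2),
        u3s=pos_pct("T", 2),
        gc1s=gc1s,
        gc2s=gc2s,
        gc3s=gc3s,
        gc12s=(gc1s + gc2s) / 2.0,
        gc=gc_total,
        au=100.0 - gc_total,
    )


def protein_indices(protein: str) -> ProteinIndices:
    """GRAVY (mean Kyte-Doolittle hydropathy) and aromaticity of a protein.

    Aromaticity is the fraction of Phe + Tyr + Trp residues. GRAVY lies in
    [-4.5, 4.5], the extremes of the Kyte-Doolittle per-residue scale.
    """
    if not protein:
        raise ValueError("empty protein")
    unknown = set(protein) - _STANDARD_AAS
    if unknown:
        raise ValueError(f"unknown residues: {sorted(unknown)}")
    pa = ProteinAnalysis(protein)
    return ProteinIndices(gravy=pa.gravy(), aroma=pa.aromaticity())


def composition_table(seqs: Sequence[CodingSequence]) -> pd.DataFrame:
    """One row per sequence: labels, composition profile, GRAVY/ARO."""
    rows = []
    for s in seqs:
        counts = count_codons(s, exclude_nonbias=True)
        prof = composition_profile(s, counts)
        prot = protein_indices(translate(s))
        rows.append(
            {
                "id": s.id,
                "host": s.host,
                "group": s.group,
                **prof.as_dict(),
                "gravy": prot.gravy,
                "aroma": prot.aroma,
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    table: pd.DataFrame, by: str = "host", ddof: int = 0
) -> pd.DataFrame:
    """Mean and SD of every numeric column per group.

    SD is population SD (ddof=0) by default; pass ddof=1 for sample SD.
    """
    numeric = table.select_dtypes("number")
    grouped = numeric.groupby(table[by])
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=ddof).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).sort_index(axis=1)
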