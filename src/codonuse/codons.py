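"""Standard genetic code tables shared by every analysis module.

All sequences are stored internally on the DNA alphabet (T); reports that
mirror published codon-usage tables print RNA codons (U). The analysis
universe is the 59 sense codons obtained by dropping the two non-degenerate
codons (AUG/Met, UGG/Trp); stop codons are never counted.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid, 61 sense codons, DNA alphabet
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, [])
for _codon in SENSE_CODONS:
    AA_TO_CODONS[CODON_TO_AA[_codon]].append(_codon)
AA_TO_CODONS = {aa: tuple(cods) for aa, cods in AA_TO_CODONS.items()}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

#: degeneracy class k per amino acid (1, 2, 3, 4 or 6 synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in AA_TO_CODONS.items()}

#: amino acids with a single codon (Met, Trp) -- carry no usage-bias signal
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, k in DEGENERACY.items() if k == 1
)

#: the two "non-bias" sense codons excluded from bias statistics
NONBIAS_CODONS: tuple[str, ...] = ("ATG", "TGG")

#: amino acids with k >= 2, the 18 families entering RSCU / ENC
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if DEGENERACY[aa] >= 2
)

#: the shared 59-codon universe (61 sense codons minus AUG and UGG)
CODON_UNIVERSE: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in NONBIAS_CODONS
)

#: strictly fourfold-degenerate families (third position fully free)
FOURFOLD_AAS: tuple[str, ...] = ("A", "G", "P", "T", "V")

#: the fourfold codon boxes inside the three sixfold families
SIXFOLD_FOURFOLD_BOXES: dict[str, tuple[str, ...]] = {
    "L": ("CTA", "CTC", "CTG", "CTT"),
    "R": ("CGA", "CGC", "CGG", "CGT"),
    "S": ("TCA", "TCC", "TCG", "TCT"),
}

VALID_NUCLEOTIDES = frozenset("ACGT")


def to_dna(seq: str) -> str:
    """Normalize a nucleotide string to the canonical DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    """Render a stored DNA codon in the RNA alphabet used in reports."""
    return codon.replace("T", "U")
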