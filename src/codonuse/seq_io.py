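"""Reading, validating and tallying coding sequences.

A coding sequence is stored as an ordered tuple of DNA triplets. Input may be
DNA or RNA (T and U are equivalent); a terminal stop codon is stripped and
remembered; an internal stop is always fatal for that record. Codons carrying
ambiguity codes (N, R, Y, ...) are dropped by default, mirroring how partially
determined GenBank records are usually handled.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERATE_AAS,
    NONBIAS_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    VALID_NUCLEOTIDES,
    to_dna,
    to_rna,
)

logger = logging.getLogger(__name__)

AmbiguityPolicy = Literal["drop-codon", "reject-sequence"]


class SequenceError(ValueError):
    """A coding-sequence record violates a structural invariant."""


@dataclass(frozen=True)
class CodingSequence:
    """One validated CDS: identifier, codons, and optional metadata labels."""

    id: str
    codons: tuple[str, ...]
    host: str | None = None
    group: str | None = None
    terminal_stop: str | None = None
    dropped_codons: int = 0

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:
        return len(self.codons)


def coding_sequence(
    seq_id: str,
    raw: str,
    alphabet_policy: AmbiguityPolicy = "drop-codon",
    **labels,
) -> CodingSequence:
    """Validate a raw nucleotide string into a :class:`CodingSequence`.

    Raises :class:`SequenceError` when the length is not a multiple of 3,
    an internal stop codon is present, or (under ``reject-sequence``) an
    ambiguity code occurs.
    """
    seq = to_dna("".join(raw.split()))
    if len(seq) % 3 != 0:
        raise SequenceError(
            f"{seq_id}: length {len(seq)} is not a multiple of 3"
        )
    triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not triplets:
        raise SequenceError(f"{seq_id}: empty record")

    terminal_stop = None
    if triplets[-1] in STOP_CODONS:
        terminal_stop = triplets.pop()

    kept: list[str] = []
    dropped = 0
    for pos, codon in enumerate(triplets):
        if codon in STOP_CODONS:
            raise SequenceError(
                f"{seq_id}: internal stop codon {codon} at codon {pos + 1}"
            )
        if not set(codon) <= VALID_NUCLEOTIDES:
            if alphabet_policy == "reject-sequence":
                raise SequenceError(
                    f"{seq_id}: ambiguous codon {codon} at codon {pos + 1}"
                )
            dropped += 1
            continue
        kept.append(codon)
    if not kept:
        raise SequenceError(f"{seq_id}: no unambiguous codons remain")
    return CodingSequence(
        id=seq_id,
        codons=tuple(kept),
        terminal_stop=terminal_stop,
        dropped_codons=dropped,
        **labels,
    )


def read_fasta(
    path: str | Path,
    alphabet_policy: AmbiguityPolicy = "drop-codon",
    on_invalid: Literal["skip", "raise"] = "skip",
) -> list[CodingSequence]:
    """Read a multi-record FASTA of coding sequences.

    Invalid records (length, internal stops) are skipped with a warning by
    default; ``on_invalid="raise"`` aborts on the first offender.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[CodingSequence] = []
    for rec in records:
        try:
            out.append(coding_sequence(rec.id, str(rec.seq), alphabet_policy))
        except SequenceError as exc:
            if on_invalid == "raise":
                raise
            warnings.warn(f"skipping record: {exc}", stacklevel=2)
            logger.warning("skipping record: %s", exc)
    if not out:
        raise SequenceError(f"{path}: no valid coding sequences")
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read an id/host/group metadata TSV."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in meta.columns:
        raise ValueError(f"{path}: metadata must have an 'id' column")
    return meta


def attach_metadata(
    seqs: Sequence[CodingSequence], meta: pd.DataFrame
) -> list[CodingSequence]:
    """Stamp host/group labels from a metadata table onto sequences."""
    indexed = meta.set_index("id")
    out = []
    for s in seqs:
        if s.id in indexed.index:
            row = indexed.loc[s.id]
            out.append(
                replace(
                    s,
                    host=row.get("host", s.host),
                    group=row.get("group", s.group),
                )
            )
        else:
            out.append(s)
    return out


@dataclass(frozen=True)
class CodonCounts:
    """Per-sequence tally of sense codons.

    ``g`` maps every sense codon to its count; when ``exclude_nonbias`` is
    set, AUG and UGG carry zero and do not enter ``n_total``. Stop codons are
    never counted.
    """

    g: Mapping[str, int]
    exclude_nonbias: bool = True

    def __post_init__(self):
        bad = set(self.g) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in counts: {sorted(bad)}")
        if any(v < 0 for v in self.g.values()):
            raise ValueError("negative codon counts")
        full = {c: int(self.g.get(c, 0)) for c in SENSE_CODONS}
        if self.exclude_nonbias:
            for c in NONBIAS_CODONS:
                full[c] = 0
        object.__setattr__(self, "g", full)

    @property
    def n_total(self) -> int:
        return sum(self.g.values())

    @property
    def n_per_aa(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for codon, n in self.g.items():
            aa = CODON_TO_AA[codon]
            totals[aa] = totals.get(aa, 0) + n
        return totals

    def family_counts(self, aa: str) -> tuple[int, ...]:
        """Counts of the synonymous codons of one amino acid, codon order."""
        return tuple(self.g[c] for c in AA_TO_CODONS[aa])


def count_codons(
    seq: CodingSequence, exclude_nonbias: bool = True
) -> CodonCounts:
    """Tally the sense codons of one sequence."""
    if len(seq) == 0:
        raise SequenceError(f"{seq.id}: empty sequence")
    tally: dict[str, int] = {}
    for codon in seq.codons:
        tally[codon] = tally.get(codon, 0) + 1
    return CodonCounts(g=tally, exclude_nonbias=exclude_nonbias)


def pool_counts(counts: Iterable[CodonCounts]) -> CodonCounts:
    """Sum codon tallies across sequences (pooled-gene counts)."""
    counts = list(counts)
    if not counts:
        raise ValueError("no counts to pool")
    flags = {c.exclude_nonbias for c in counts}
    if len(flags) != 1:
        raise ValueError("cannot pool counts with mixed exclude_nonbias")
    pooled: dict[str, int] = {}
    for c in counts:
        for codon, n in c.g.items():
            pooled[codon] = pooled.get(codon, 0) + n
    return CodonCounts(g=pooled, exclude_nonbias=flags.pop())


def translate(seq: CodingSequence) -> str:
    """Standard-code translation; stops were stripped at parse time."""
    return "".join(CODON_TO_AA[c] for c in seq.codons)


def counts_to_dict(counts: CodonCounts, rna: bool = True) -> dict[str, int]:
    """Counts keyed by RNA (default) or DNA codon, for JSON/TSV dumps."""
    key = to_rna if rna else (lambda c: c)
    return {key(c): counts.g[c] for c in SENSE_CODONS}


def write_counts_json(counts: CodonCounts, path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts_to_dict(counts), indent=1))


# families entering bias statistics, exported for convenience
DEGENERATE_FAMILIES: tuple[str, ...] = DEGENERATE_AAS
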