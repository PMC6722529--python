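"""Synthetic coding-sequence generator.

Generates CDS sets with the statistical structure the analyses assume, so
every stage of the pipeline is testable at desk scale without downloads:

* mutational pressure -- a nucleotide distribution ``pi`` (typically
  parametrized by its GC content) that drives codon choice in the absence
  of selection;
* translational selection -- with probability ``w_sel`` a codon position is
  emitted as the host table's preferred codon instead of the mutational
  draw (a mixture model at the codon-choice level);
* amino-acid composition -- either a fixed profile (positions 1-2 then
  carry no mutational signal beyond the sixfold families), or, when
  ``aa_profile`` is None, the *neutral* regime in which whole codons are
  drawn from ``pi`` applied at all three positions (stops excluded), so
  GC12 and GC3 co-vary as the neutrality plot assumes.

Two ready-made regimes mirror the study system: a GC-rich gene with mild
host selection (coat-protein-like) and an AU-rich gene
(nucleic-acid-binding-protein-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .adaptation import HostUsageTable, load_builtin_host
from .codons import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    to_dna,
)
from .seq_io import CodingSequence

#: average globular-protein amino-acid frequencies (UniProt-style), used as
#: the default fixed composition profile
DEFAULT_AA_PROFILE: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


def mutation_profile_from_gc(gc: float) -> dict[str, float]:
    """Symmetric nucleotide distribution with the given GC content."""
    if not 0.0 < gc < 1.0:
        raise ValueError("GC content must be in (0, 1)")
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic CDS set (all randomness via ``seed``)."""

    n_sequences: int = 30
    length_codons: int = 300
    mutation_profile: Mapping[str, float] = field(
        default_factory=lambda: mutation_profile_from_gc(0.5)
    )
    aa_profile: Mapping[str, float] | None = None
    w_sel: float = 0.0
    host: HostUsageTable | None = None
    noise_rate: float = 0.0
    seed: int = 0
    host_label: str | None = None
    group_label: str | None = None
    id_prefix: str = "syn"

    def __post_init__(self):
        pi = {to_dna(k): float(v) for k, v in self.mutation_profile.items()}
        if set(pi) != set("ACGT") or any(v < 0 for v in pi.values()):
            raise ValueError("mutation_profile must cover A, C, G, T/U")
        if not np.isclose(sum(pi.values()), 1.0, atol=1e-8):
            raise ValueError("mutation_profile must sum to 1")
        object.__setattr__(self, "mutation_profile", pi)
        if self.aa_profile is not None:
            aa = {k: float(v) for k, v in self.aa_profile.items()}
            unknown = set(aa) - set(AMINO_ACIDS)
            if unknown:
                raise ValueError(f"unknown amino acids: {sorted(unknown)}")
            total = sum(aa.values())
            if not 0.95 <= total <= 1.05:
                raise ValueError("aa_profile must sum to ~1")
            aa = {k: v / total for k, v in aa.items()}
            if not any(len(AA_TO_CODONS[a]) >= 2 and p > 0
                       for a, p in aa.items()):
                raise ValueError("aa_profile has no degenerate families")
            object.__setattr__(self, "aa_profile", aa)
        if not 0.0 <= self.w_sel <= 1.0:
            raise ValueError("w_sel must be in [0, 1]")
        if self.w_sel > 0 and self.host is None:
            raise ValueError("w_sel > 0 requires a host table")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.length_codons < 30:
            raise ValueError("length_codons must be >= 30 for ENC stability")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def _mutational_codon_probs(pi: Mapping[str, float]) -> np.ndarray:
    """P(codon) proportional to pi applied at all three positions, stops out."""
    p = np.array(
        [pi[c[0]] * pi[c[1]] * pi[c[2]] for c in SENSE_CODONS], dtype=float
    )
    total = p.sum()
    if total <= 0:
        raise ValueError("mutation profile incompatible with sense codons")
    return p / total


def _synonym_probs(aa: str, pi: Mapping[str, float]) -> np.ndarray:
    """Synonym choice under mutation: third position from pi (restricted to
    the thirds the family offers), then uniform among codons sharing it."""
    fam = AA_TO_CODONS[aa]
    thirds = [c[2] for c in fam]
    z = sum(pi[t] for t in set(thirds))
    if z <= 0:
        # family's thirds all have zero mutational mass: fall back to uniform
        return np.full(len(fam), 1.0 / len(fam))
    counts = {t: thirds.count(t) for t in set(thirds)}
    return np.array([pi[c[2]] / z / counts[c[2]] for c in fam])


def generate(
    spec: GeneratorSpec,
) -> tuple[list[CodingSequence], dict[str, object]]:
    """Generate the CDS set described by ``spec`` plus its truth record."""
    rng = np.random.default_rng(spec.seed)
    pi = spec.mutation_profile
    sense = np.array(SENSE_CODONS)
    mut_codon_p = _mutational_codon_probs(pi)

    if spec.aa_profile is None:
        # neutral regime: amino acids follow the mutational distribution
        sel_aa = sorted(AMINO_ACIDS)
        aa_marginal = {a: 0.0 for a in sel_aa}
        for c, p in zip(SENSE_CODONS, mut_codon_p):
            aa_marginal[CODON_TO_AA[c]] += p
        sel_aa_p = np.array([aa_marginal[a] for a in sel_aa])
    else:
        sel_aa = sorted(spec.aa_profile)
        sel_aa_p = np.array([spec.aa_profile[a] for a in sel_aa])
        sel_aa_p = sel_aa_p / sel_aa_p.sum()
        syn_probs = {a: _synonym_probs(a, pi) for a in sel_aa}

    preferred: dict[str, str] = {}
    if spec.host is not None:
        preferred = {a: spec.host.preferred_codon(a) for a in AMINO_ACIDS}

    seqs: list[CodingSequence] = []
    L = spec.length_codons
    for i in range(spec.n_sequences):
        selected = rng.random(L) < spec.w_sel
        codons = np.empty(L, dtype=object)

        n_mut = int((~selected).sum())
        if n_mut:
            if spec.aa_profile is None:
                codons[~selected] = rng.choice(sense, size=n_mut, p=mut_codon_p)
            else:
                aas = rng.choice(sel_aa, size=n_mut, p=sel_aa_p)
                drawn = np.empty(n_mut, dtype=object)
                for a in np.unique(aas):
                    mask = aas == a
                    fam = np.array(AA_TO_CODONS[a])
                    drawn[mask] = rng.choice(
                        fam, size=int(mask.sum()), p=syn_probs[a]
                    )
                codons[~selected] = drawn

        n_sel = int(selected.sum())
        if n_sel:
            aas = rng.choice(sel_aa, size=n_sel, p=sel_aa_p)
            codons[selected] = np.array([preferred[a] for a in aas])

        if spec.noise_rate > 0:
            noisy = np.nonzero(rng.random(L) < spec.noise_rate)[0]
            for j in noisy:
                fam = AA_TO_CODONS[CODON_TO_AA[codons[j]]]
                codons[j] = fam[rng.integers(len(fam))]

        seqs.append(
            CodingSequence(
                id=f"{spec.id_prefix}{i + 1:03d}",
                codons=tuple(codons.tolist()),
                host=spec.host_label,
                group=spec.group_label,
            )
        )

    truth = {
        "w_sel": spec.w_sel,
        "mutation_profile": dict(pi),
        "aa_profile": dict(spec.aa_profile) if spec.aa_profile else None,
        "host": spec.host.name if spec.host else None,
        "noise_rate": spec.noise_rate,
        "seed": spec.seed,
        "n_sequences": spec.n_sequences,
        "length_codons": spec.length_codons,
    }
    return seqs, truth


def write_fasta(seqs: Sequence[CodingSequence], path: str | Path) -> None:
    """Write sequences as plain multi-record FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            seq = s.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_metadata(seqs: Sequence[CodingSequence], path: str | Path) -> None:
    """Write the id/host/group metadata TSV matching a FASTA."""
    with open(path, "w") as fh:
        fh.write("id\thost\tgroup\n")
        for s in seqs:
            fh.write(f"{s.id}\t{s.host or ''}\t{s.group or ''}\n")


def _fixture(
    seed: int,
    out_dir: str | Path,
    stem: str,
    gc: float,
    host_name: str,
    w_sel: float,
) -> tuple[Path, Path, dict[str, object]]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    host = load_builtin_host(host_name)
    hosts = ("mock_gc_rich", "mock_at_rich", "mock_balanced")
    groups = ("GP1", "GP2")
    all_seqs: list[CodingSequence] = []
    for j, label in enumerate(hosts):
        spec = GeneratorSpec(
            n_sequences=10,
            length_codons=300,
            mutation_profile=mutation_profile_from_gc(gc),
            aa_profile=DEFAULT_AA_PROFILE,
            w_sel=w_sel,
            host=host,
            seed=seed + j,
            host_label=label,
            group_label=groups[j % 2],
            id_prefix=f"{stem}_{label}_",
        )
        seqs, _ = generate(spec)
        all_seqs.extend(seqs)
    fasta = out_dir / f"{stem}.fasta"
    meta = out_dir / f"{stem}.meta.tsv"
    write_fasta(all_seqs, fasta)
    write_metadata(all_seqs, meta)
    truth = {
        "gc": gc, "w_sel": w_sel, "host": host_name, "seed": seed,
        "n_sequences": len(all_seqs), "length_codons": 300,
    }
    return fasta, meta, truth


def cp_like_fixture(
    seed: int, out_dir: str | Path
) -> tuple[Path, Path, dict[str, object]]:
    """GC-rich gene set (coat-protein-like regime, mean GC around 53%)."""
    return _fixture(
        seed, out_dir, "cp_like",
        gc=0.56, host_name="mock_gc_rich", w_sel=0.25,
    )


def nabp_like_fixture(
    seed: int, out_dir: str | Path
) -> tuple[Path, Path, dict[str, object]]:
    """AU-rich gene set (NABP-like regime, mean AU around 54%)."""
    return _fixture(
        seed, out_dir, "nabp_like",
        gc=0.42, host_name="mock_at_rich", w_sel=0.25,
    )
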