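"""Host-adaptation statistics: CAI, RCDI and the similarity index SiD.

All three compare a query gene's codon usage with a host reference
codon-usage table (Kazusa-style per-thousand frequencies or raw counts):

* CAI  -- geometric mean of relative adaptedness w_c = f_c / max(f) within
  each synonymous family; 1 means every codon is the host-preferred one.
* RCDI -- usage-weighted mean ratio of query to host within-family codon
  frequencies; 1 iff the query matches the host pattern exactly, larger
  values mean deoptimization.
* SiD  -- D(A,B) = (1 - R(A,B))/2 where R is the cosine similarity between
  the 59-dimensional RSCU vectors of virus and host; the alternative
  reading 1 - R/2 of the ambiguous printed equation is available behind a
  flag.

Met, Trp and stop codons are excluded throughout (the 59-codon universe).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    CODON_UNIVERSE,
    DEGENERATE_AAS,
    SENSE_CODONS,
    STOP_CODONS,
    to_dna,
)
from .rscu import RSCUVector
from .seq_io import CodonCounts

SiDConvention = Literal["half-diff", "one-minus-half"]

#: pseudocount added (on the per-thousand scale) when a table has zeros
ZERO_SMOOTHING = 0.5


@dataclass(frozen=True)
class HostUsageTable:
    """Reference codon usage of one host, with derived adaptedness weights.

    ``per_thousand`` is the normalized frequency of each sense codon;
    ``rel_freq`` the within-family relative frequency; ``w`` the relative
    adaptedness f/max(f) within each family; ``rscu`` the host RSCU vector
    over the 59-codon universe.
    """

    name: str
    per_thousand: Mapping[str, float]
    rel_freq: Mapping[str, float]
    w: Mapping[str, float]
    rscu: RSCUVector
    smoothed: bool = False

    @classmethod
    def from_counts(
        cls, name: str, counts: Mapping[str, float]
    ) -> "HostUsageTable":
        """Build a table from per-codon counts or frequencies.

        Keys may be DNA or RNA codons; stop codons are ignored; all 61 sense
        codons must be present (zeros allowed). The table is normalized to
        per-thousand first, so every derived quantity is invariant to the
        overall scale of the input; zero-frequency codons are then smoothed
        with a +0.5 per-thousand pseudocount (applied to every codon so that
        within-family comparisons stay consistent).
        """
        clean: dict[str, float] = {}
        for key, value in counts.items():
            codon = to_dna(key.strip())
            if codon in STOP_CODONS:
                continue
            if codon not in CODON_TO_AA:
                raise ValueError(f"{name}: unknown codon {key!r}")
            if value < 0:
                raise ValueError(f"{name}: negative value for {key}")
            clean[codon] = float(value)
        missing = set(SENSE_CODONS) - set(clean)
        if missing:
            raise ValueError(
                f"{name}: table missing {len(missing)} sense codons "
                f"(e.g. {sorted(missing)[:3]})"
            )
        total = sum(clean.values())
        if total <= 0:
            raise ValueError(f"{name}: all-zero table")
        per_thousand = {c: 1000.0 * v / total for c, v in clean.items()}
        smoothed = any(v == 0.0 for v in per_thousand.values())
        if smoothed:
            per_thousand = {
                c: v + ZERO_SMOOTHING for c, v in per_thousand.items()
            }

        rel_freq: dict[str, float] = {}
        w: dict[str, float] = {}
        rscu_values: dict[str, float] = {}
        n_fam: dict[str, int] = {}
        for aa, fam in AA_TO_CODONS.items():
            fam_total = sum(per_thousand[c] for c in fam)
            fam_max = max(per_thousand[c] for c in fam)
            for c in fam:
                rel_freq[c] = per_thousand[c] / fam_total
                w[c] = per_thousand[c] / fam_max
        for aa in DEGENERATE_AAS:
            fam = AA_TO_CODONS[aa]
            n_fam[aa] = 1
            k = len(fam)
            for c in fam:
                rscu_values[c] = k * rel_freq[c]
        return cls(
            name=name,
            per_thousand=per_thousand,
            rel_freq=rel_freq,
            w=w,
            rscu=RSCUVector(values=rscu_values, n_per_family=n_fam),
            smoothed=smoothed,
        )

    def preferred_codon(self, aa: str) -> str:
        """Most frequent codon of one family (ties broken lexicographically)."""
        fam = AA_TO_CODONS[aa]
        best = max(self.per_thousand[c] for c in fam)
        return min(c for c in fam if self.per_thousand[c] == best)


_KAZUSA_ENTRY = re.compile(
    r"([ACGUTacgut]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)"
)


def load_host_table(
    path: str | Path,
    fmt: Literal["kazusa", "counts_tsv"] = "kazusa",
    name: str | None = None,
) -> HostUsageTable:
    """Read a host codon-usage table.

    ``kazusa`` parses the classic ``GCU 17.6 ( 12345)`` entries (any layout,
    counts preferred over the printed frequencies); ``counts_tsv`` expects
    two columns, codon and count.
    """
    path = Path(path)
    name = name or path.stem
    text = path.read_text()
    counts: dict[str, float] = {}
    if fmt == "kazusa":
        for codon, _freq, count in _KAZUSA_ENTRY.findall(text):
            counts[to_dna(codon)] = float(count)
        if not counts:
            raise ValueError(f"{path}: no Kazusa-style entries found")
    elif fmt == "counts_tsv":
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            counts[to_dna(fields[0])] = float(fields[1])
    else:
        raise ValueError(f"unknown host-table format {fmt!r}")
    return HostUsageTable.from_counts(name, counts)


def builtin_hosts() -> tuple[str, ...]:
    """Names of the bundled mock host tables."""
    pkg = resources.files("codonuse").joinpath("data")
    return tuple(
        sorted(
            p.name.removesuffix(".kazusa.txt")
            for p in pkg.iterdir()
            if p.name.endswith(".kazusa.txt")
        )
    )


def load_builtin_host(name: str) -> HostUsageTable:
    """Load one of the bundled mock host tables by name."""
    ref = resources.files("codonuse").joinpath(f"data/{name}.kazusa.txt")
    with resources.as_file(ref) as path:
        return load_host_table(path, fmt="kazusa", name=name)


def cai(counts: CodonCounts, host: HostUsageTable) -> float:
    """Codon adaptation index: exp(sum g_c ln w_c / sum g_c) over 59 codons."""
    if not counts.exclude_nonbias:
        raise ValueError("CAI is defined on the 59-codon universe")
    log_sum = 0.0
    n = 0
    for c in CODON_UNIVERSE:
        g = counts.g[c]
        if g == 0:
            continue
        log_sum += g * math.log(host.w[c])
        n += g
    if n == 0:
        raise ValueError("no informative codons for CAI")
    return math.exp(log_sum / n)


def rcdi(counts: CodonCounts, host: HostUsageTable) -> float:
    """Relative codon deoptimization index (>= 1; 1 iff host-matched).

    RCDI = sum_c (CiFa/ChFh) * N_c / N with CiFa the query's within-family
    relative frequency of codon c, ChFh the host's, N_c the query count and
    N the total counted codons.
    """
    if not counts.exclude_nonbias:
        raise ValueError("RCDI is defined on the 59-codon universe")
    n_total = counts.n_total
    if n_total == 0:
        raise ValueError("no informative codons for RCDI")
    per_aa = counts.n_per_aa
    total = 0.0
    for c in CODON_UNIVERSE:
        g = counts.g[c]
        if g == 0:
            continue
        q = g / per_aa[CODON_TO_AA[c]]
        h = host.rel_freq[c]
        total += (q / h) * g / n_total
    return total


def sid(
    virus_rscu: RSCUVector,
    host: HostUsageTable,
    convention: SiDConvention = "half-diff",
) -> tuple[float, float]:
    """Similarity index against a host: returns (R cosine, SiD).

    R(A,B) = sum(a_i b_i) / sqrt(sum(a_i^2) sum(b_i^2)) over the 59-codon
    RSCU vectors, undefined entries dropped pairwise. SiD = (1 - R)/2 under
    the default convention, 1 - R/2 under ``one-minus-half``.
    """
    a = virus_rscu.as_array()
    b = host.rscu.as_array()
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size == 0 or not a.any() or not b.any():
        raise ValueError("cannot compute SiD from an all-zero RSCU vector")
    r = float(a @ b / math.sqrt((a @ a) * (b @ b)))
    if convention == "half-diff":
        d = (1.0 - r) / 2.0
    elif convention == "one-minus-half":
        d = 1.0 - r / 2.0
    else:
        raise ValueError(f"unknown SiD convention {convention!r}")
    return r, d


@dataclass(frozen=True)
class AdaptationScores:
    host: str
    cai: float
    rcdi: float
    r_cos: float
    sid: float


def adaptation_scores(
    counts: CodonCounts,
    virus_rscu: RSCUVector,
    host: HostUsageTable,
    convention: SiDConvention = "half-diff",
) -> AdaptationScores:
    """CAI, RCDI and SiD of one gene against one host table."""
    r, d = sid(virus_rscu, host, convention)
    return AdaptationScores(
        host=host.name,
        cai=cai(counts, host),
        rcdi=rcdi(counts, host),
        r_cos=r,
        sid=d,
    )
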