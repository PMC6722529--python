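"""Shared fixtures: mock hosts, synthetic gene sets, and count builders."""

from __future__ import annotations

import pytest
from hypothesis import settings

from codonuse.adaptation import HostUsageTable, load_builtin_host
from codonuse.codons import AA_TO_CODONS, SENSE_CODONS
from codonuse.seq_io import CodingSequence, CodonCounts

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_counts(g: dict[str, int], exclude_nonbias: bool = True) -> CodonCounts:
    return CodonCounts(g=g, exclude_nonbias=exclude_nonbias)


def make_seq(seq_id: str, codons: list[str], **labels) -> CodingSequence:
    return CodingSequence(id=seq_id, codons=tuple(codons), **labels)


@pytest.fixture(scope="session")
def gc_rich_host() -> HostUsageTable:
    return load_builtin_host("mock_gc_rich")


@pytest.fixture(scope="session")
def at_rich_host() -> HostUsageTable:
    return load_builtin_host("mock_at_rich")


@pytest.fixture(scope="session")
def balanced_host() -> HostUsageTable:
    return load_builtin_host("mock_balanced")


@pytest.fixture(scope="session")
def peaked_host(gc_rich_host) -> HostUsageTable:
    """Host that uses only its preferred codon per family (smoothed zeros).

    This is the reference against which the generator's selected component
    is an exact match at w_sel = 1, making CAI/RCDI monotone in w_sel.
    """
    counts = {c: 0.0 for c in SENSE_CODONS}
    for aa in AA_TO_CODONS:
        counts[gc_rich_host.preferred_codon(aa)] = 1000.0
    return HostUsageTable.from_counts("mock_gc_rich_preferred", counts)


@pytest.fixture(scope="session")
def uniform_host() -> HostUsageTable:
    return HostUsageTable.from_counts(
        "uniform", {c: 100.0 for c in SENSE_CODONS}
    )


@pytest.fixture(scope="session")
def cp_fixture(tmp_path_factory):
    from codonuse.synthetic import cp_like_fixture

    out = tmp_path_factory.mktemp("cp_like")
    fasta, meta, truth = cp_like_fixture(seed=7, out_dir=out)
    return fasta, meta, truth


@pytest.fixture(scope="session")
def nabp_fixture(tmp_path_factory):
    from codonuse.synthetic import nabp_like_fixture

    out = tmp_path_factory.mktemp("nabp_like")
    fasta, meta, truth = nabp_like_fixture(seed=7, out_dir=out)
    return fasta, meta, truth
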