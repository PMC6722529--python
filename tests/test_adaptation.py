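"""Host tables and the CAI / RCDI / SiD adaptation indices."""

import math

import numpy as np
import pytest

from codonuse.adaptation import (
    HostUsageTable,
    adaptation_scores,
    cai,
    load_host_table,
    rcdi,
    sid,
)
from codonuse.codons import (
    AA_TO_CODONS,
    CODON_UNIVERSE,
    DEGENERATE_AAS,
    SENSE_CODONS,
)
from codonuse.rscu import rscu

from conftest import make_counts


def host_from(counts: dict[str, float], name: str = "test") -> HostUsageTable:
    full = {c: 1.0 for c in SENSE_CODONS}
    full.update(counts)
    return HostUsageTable.from_counts(name, full)


class TestHostTable:
    def test_uniform_table_gives_unit_weights(self, uniform_host):
        assert all(w == pytest.approx(1.0) for w in uniform_host.w.values())
        defined = [
            v for v in uniform_host.rscu.values.values() if not math.isnan(v)
        ]
        assert all(v == pytest.approx(1.0) for v in defined)

    def test_builtin_kazusa_fixture_parses(self, gc_rich_host):
        assert sum(gc_rich_host.per_thousand.values()) == pytest.approx(
            1000.0
        )
        assert len(gc_rich_host.per_thousand) == 61
        for aa, fam in AA_TO_CODONS.items():
            assert max(gc_rich_host.w[c] for c in fam) == pytest.approx(1.0)

    def test_host_rscu_family_mean_is_one(self, gc_rich_host):
        for aa in DEGENERATE_AAS:
            fam = AA_TO_CODONS[aa]
            vals = [gc_rich_host.rscu.values[c] for c in fam]
            assert np.mean(vals) == pytest.approx(1.0)

    def test_zero_codon_smoothed_positive(self):
        table = host_from({"TTT": 0.0})
        assert table.smoothed
        assert table.w["TTT"] > 0.0

    def test_missing_codons_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            HostUsageTable.from_counts("bad", {"TTT": 1.0, "TTC": 1.0})

    def test_negative_values_rejected(self):
        counts = {c: 1.0 for c in SENSE_CODONS}
        counts["TTT"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            HostUsageTable.from_counts("bad", counts)

    def test_counts_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "host.tsv"
        path.write_text(
            "\n".join(f"{c}\t{i + 1}" for i, c in enumerate(SENSE_CODONS))
        )
        table = load_host_table(path, fmt="counts_tsv")
        assert len(table.per_thousand) == 61

    def test_preferred_codon_tie_is_lexicographic(self, uniform_host):
        assert uniform_host.preferred_codon("F") == "TTC"


class TestCAI:
    def test_host_preferred_sequence_scores_one(self, gc_rich_host):
        g = {
            gc_rich_host.preferred_codon(aa): 10 for aa in DEGENERATE_AAS
        }
        assert cai(make_counts(g), gc_rich_host) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # Phe family 4:1 -> w(TTC) = 0.25; query uses TTT and TTC once each
        host = host_from({"TTT": 4.0, "TTC": 1.0})
        value = cai(make_counts({"TTT": 1, "TTC": 1}), host)
        assert value == pytest.approx(math.sqrt(0.25))

    def test_duplication_invariance(self, gc_rich_host):
        g = {"TTT": 3, "TTC": 1, "GCT": 2, "GCA": 5}
        once = cai(make_counts(g), gc_rich_host)
        twice = cai(make_counts({c: 7 * n for c, n in g.items()}), gc_rich_host)
        assert once == pytest.approx(twice)

    def test_no_informative_codons_errors(self, gc_rich_host):
        with pytest.raises(ValueError, match="informative"):
            cai(make_counts({}), gc_rich_host)


class TestRCDI:
    def test_host_matched_query_scores_one(self, gc_rich_host):
        g = {
            c: int(round(30 * gc_rich_host.per_thousand[c]))
            for c in CODON_UNIVERSE
        }
        host = host_from({c: float(n) for c, n in g.items()})
        assert rcdi(make_counts(g), host) == pytest.approx(1.0)

    def test_single_codon_against_even_host_is_two(self):
        host = host_from({"TTT": 5.0, "TTC": 5.0})
        assert rcdi(make_counts({"TTT": 8}), host) == pytest.approx(2.0)

    def test_at_least_one_with_equality_iff_matched(self):
        rng = np.random.default_rng(17)
        fam = AA_TO_CODONS["I"]  # 3-codon toy family
        for _ in range(50):
            h = rng.integers(1, 20, size=3).astype(float)
            q = rng.integers(0, 20, size=3)
            if q.sum() == 0:
                continue
            host = host_from(dict(zip(fam, h)))
            counts = make_counts({c: int(n) for c, n in zip(fam, q)})
            value = rcdi(counts, host)
            # brute-force evaluation of the weighted frequency-ratio sum
            n = q.sum()
            expected = sum(
                (qi / n) / (hi / h.sum()) * qi / n
                for qi, hi in zip(q, h)
                if qi > 0
            )
            assert value == pytest.approx(expected, abs=1e-12)
            assert value >= 1.0 - 1e-12
            matched = np.allclose(q / n, h / h.sum())
            if not matched:
                assert value > 1.0 + 1e-12

    def test_scale_invariance_in_host_counts(self):
        g = {"TTT": 3, "TTC": 1, "GGT": 4, "GGC": 2}
        base = {c: 1.0 for c in SENSE_CODONS}
        base.update({"TTT": 7.0, "GGT": 3.0})
        h1 = HostUsageTable.from_counts("a", base)
        h2 = HostUsageTable.from_counts(
            "b", {c: 1000.0 * v for c, v in base.items()}
        )
        counts = make_counts(g)
        assert rcdi(counts, h1) == pytest.approx(rcdi(counts, h2), abs=1e-12)
        assert cai(counts, h1) == pytest.approx(cai(counts, h2), abs=1e-12)


class TestSiD:
    def test_identical_vectors_give_zero_distance(self, gc_rich_host):
        g = {
            c: int(round(50 * gc_rich_host.per_thousand[c]))
            for c in CODON_UNIVERSE
        }
        host = host_from({c: float(n) for c, n in g.items()}, "self")
        vec = rscu(make_counts(g))
        r, d = sid(vec, host)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_uniform_virus_vs_biased_host_is_positive(self, gc_rich_host):
        vec = rscu(make_counts({c: 5 for c in CODON_UNIVERSE}))
        r, d = sid(vec, gc_rich_host)
        assert r < 1.0 and d > 0.0

    def test_cosine_matches_brute_force(self, gc_rich_host):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = {c: int(rng.integers(1, 40)) for c in CODON_UNIVERSE}
            vec = rscu(make_counts(g))
            r, _ = sid(vec, gc_rich_host)
            a = [vec.values[c] for c in CODON_UNIVERSE]
            b = [gc_rich_host.rscu.values[c] for c in CODON_UNIVERSE]
            num = sum(x * y for x, y in zip(a, b))
            den = math.sqrt(sum(x * x for x in a) * sum(y * y for y in b))
            assert r == pytest.approx(num / den, abs=1e-12)

    def test_conventions(self, gc_rich_host):
        vec = rscu(make_counts({c: 5 for c in CODON_UNIVERSE}))
        r, d_half = sid(vec, gc_rich_host, convention="half-diff")
        _, d_alt = sid(vec, gc_rich_host, convention="one-minus-half")
        assert d_half == pytest.approx((1 - r) / 2)
        assert d_alt == pytest.approx(1 - r / 2)

    def test_genes_score_higher_against_their_selecting_host(
        self, gc_rich_host, at_rich_host
    ):
        """Genes evolved toward host A beat host B on CAI, per gene."""
        from codonuse.seq_io import count_codons
        from codonuse.synthetic import (
            DEFAULT_AA_PROFILE, GeneratorSpec, generate,
        )

        spec = GeneratorSpec(
            n_sequences=20, length_codons=300,
            aa_profile=DEFAULT_AA_PROFILE, w_sel=0.4, host=gc_rich_host,
            seed=29,
        )
        seqs, _ = generate(spec)
        wins = 0
        for s in seqs:
            counts = count_codons(s)
            wins += cai(counts, gc_rich_host) > cai(counts, at_rich_host)
        assert wins == 20

    def test_scores_bundle(self, gc_rich_host):
        g = {c: 5 for c in CODON_UNIVERSE}
        counts = make_counts(g)
        sc = adaptation_scores(counts, rscu(counts), gc_rich_host)
        assert sc.host == "mock_gc_rich"
        assert 0 < sc.cai <= 1 and sc.rcdi >= 1 and 0 <= sc.sid <= 1
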