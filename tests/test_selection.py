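"""PR2, neutrality regression and Spearman correlations."""

import math

import numpy as np
import pytest
from scipy import stats

from codonuse.selection import (
    correlation_matrix,
    neutrality_fit,
    pr2_point,
    spearman,
)

from conftest import make_counts


class TestPR2:
    def test_equal_fourfold_usage_is_centered(self):
        g = {c: 5 for c in ("GCT", "GCC", "GCA", "GCG")}
        p = pr2_point(make_counts(g))
        assert p.at_bias == pytest.approx(0.5)
        assert p.gc_bias == pytest.approx(0.5)

    def test_hand_ratio(self):
        # A3=3, U3=1, G3=1, C3=1 within the Ala family
        g = {"GCA": 3, "GCT": 1, "GCG": 1, "GCC": 1}
        p = pr2_point(make_counts(g))
        assert p.at_bias == pytest.approx(0.75)
        assert p.gc_bias == pytest.approx(0.5)

    def test_at_bias_complement_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = {
                c: int(rng.integers(0, 20))
                for c in ("GCT", "GCC", "GCA", "GCG", "GGT", "GGA")
            }
            counts = make_counts(g)
            try:
                p = pr2_point(counts)
            except ValueError:
                continue
            if p.at_defined:
                a3 = sum(
                    v for c, v in counts.g.items()
                    if c[2] == "A" and c[:2] in ("GC", "GG", "CC", "AC", "GT")
                )
                u3 = sum(
                    v for c, v in counts.g.items()
                    if c[2] == "T" and c[:2] in ("GC", "GG", "CC", "AC", "GT")
                )
                assert p.at_bias + u3 / (a3 + u3) == pytest.approx(1.0)

    def test_sixfold_boxes_change_the_point(self):
        g = {"GCT": 2, "GCA": 2, "GCG": 2, "GCC": 2, "CTA": 6, "CGA": 6}
        strict = pr2_point(make_counts(g), mode="strict4")
        wide = pr2_point(make_counts(g), mode="include6fold")
        assert strict.at_bias == pytest.approx(0.5)
        assert wide.at_bias > strict.at_bias  # Leu/Arg A-ending boxes added

    def test_empty_fourfold_tally_errors(self):
        with pytest.raises(ValueError, match="fourfold"):
            pr2_point(make_counts({"TTT": 5}))

    def test_zero_denominator_flagged(self):
        g = {"GCG": 3, "GCC": 1}  # no A3/U3 at all
        p = pr2_point(make_counts(g))
        assert not p.at_defined and math.isnan(p.at_bias)
        assert p.gc_defined and p.gc_bias == pytest.approx(0.75)


class TestNeutrality:
    def test_diagonal_points_have_unit_slope(self):
        gc3 = [30.0, 40.0, 50.0, 60.0]
        fit = neutrality_fit(gc3, gc3)
        assert fit.slope == pytest.approx(1.0)
        assert fit.mutation_pct == pytest.approx(100.0)

    def test_constant_gc12_means_full_selection(self):
        fit = neutrality_fit([50.0] * 5, [30.0, 40.0, 50.0, 60.0, 70.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.selection_pct == pytest.approx(100.0)

    def test_percentages_always_sum_to_one_hundred(self):
        rng = np.random.default_rng(3)
        fit = neutrality_fit(rng.random(20), rng.random(20))
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_constant_gc3_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            neutrality_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            neutrality_fit([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(4)
        gc3 = rng.uniform(30, 70, 50)
        gc12 = 0.3 * gc3 + rng.normal(0, 2, 50) + 35
        fit = neutrality_fit(gc12, gc3)
        ref = stats.linregress(gc3, gc12)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.pvalue == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        up = spearman(x, [v**2 for v in x])
        down = spearman(x, [-v for v in x])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        res = spearman(x, y, method="t")
        rho_oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)

    def test_exact_p_agrees_with_enumeration_direction(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, 4.0, 6.0, 5.0]
        exact = spearman(x, y, method="exact")
        assert 0.0 < exact.pvalue < 0.2
        assert exact.method == "exact"

    def test_constant_column_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.rho) and res.method == "constant"

    def test_star_convention(self):
        from codonuse.selection import CorrelationResult

        assert CorrelationResult(0.5, 0.005, 10, "t").stars == "**"
        assert CorrelationResult(0.5, 0.03, 10, "t").stars == "*"
        assert CorrelationResult(0.5, 0.5, 10, "t").stars == "ns"


class TestCorrelationMatrix:
    @pytest.fixture
    def table(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 30
        gc3s = rng.uniform(30, 70, n)
        return pd.DataFrame(
            {
                "gravy": rng.normal(size=n),
                "aroma": rng.uniform(0, 0.2, n),
                "enc": 61 - 0.2 * gc3s + rng.normal(0, 2, n),
                "gc3s": gc3s,
                "gc": gc3s * 0.5 + 25,
                "axis1": rng.normal(size=n),
                "axis2": rng.normal(size=n),
            }
        )

    def test_full_matrix_shape_and_values(self, table):
        result = correlation_matrix(table)
        assert len(result) == 10  # 2 covariates x 5 summaries
        row = result[
            (result["variable"] == "gravy") & (result["against"] == "enc")
        ].iloc[0]
        rho, p = stats.spearmanr(table["gravy"], table["enc"])
        assert row["rho"] == pytest.approx(rho)
        assert row["pvalue"] == pytest.approx(p)

    def test_missing_column_errors(self, table):
        with pytest.raises(ValueError, match="missing columns"):
            correlation_matrix(table.drop(columns=["axis2"]))

    def test_too_few_rows_errors(self, table):
        with pytest.raises(ValueError, match="at least 5"):
            correlation_matrix(table.head(4))
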