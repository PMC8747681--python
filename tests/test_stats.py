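"""Year encodings, centering, ANOVA, Pearson and the envelope rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from grainaging.config import StudyConfig
from grainaging.stats import (
    center_by_group,
    encode_year,
    exclude_germination_outliers,
    one_way_anova,
    pearson_r,
    randomization_test,
    year_encoding,
    year_trend_analysis,
)
from grainaging.synthetic import generate_study

YEARS = (2003, 2004, 2009, 2014)


class TestYearEncoding:
    def test_yearrank(self):
        s = year_encoding("YearRank", YEARS)
        assert list(encode_year(YEARS, s)) == [1, 2, 3, 4]

    def test_year01_splits_early_late(self):
        s = year_encoding("Year01", YEARS)
        assert list(encode_year(YEARS, s)) == [0, 0, 1, 1]

    def test_year_identity(self):
        s = year_encoding("Year", YEARS)
        assert list(encode_year(YEARS, s)) == [2003, 2004, 2009, 2014]

    def test_unknown_year_rejected(self):
        s = year_encoding("YearRank", YEARS)
        with pytest.raises(ValueError, match="1999"):
            encode_year([1999], s)


class TestCentering:
    def test_single_group(self):
        assert np.allclose(center_by_group([1, 2, 3], ["a"] * 3), [-1, 0, 1])

    def test_singleton_groups_zero(self):
        assert np.allclose(center_by_group([5, 9], ["a", "b"]), [0, 0])

    @given(st.integers(0, 10**6))
    def test_group_residual_means_vanish(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        values = rng.normal(size=n)
        groups = rng.integers(0, 4, size=n)
        resid = center_by_group(values, groups)
        for g in np.unique(groups):
            assert abs(resid[groups == g].mean()) < 1e-10


class TestAnova:
    def test_hand_worked_example(self):
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        scipy_res = sps.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-10)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=60)
        factor = rng.integers(0, 4, size=60)
        res = one_way_anova(values, factor)
        groups = [values[factor == g] for g in range(4)]
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_means_give_zero_f(self):
        res = one_way_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.F == pytest.approx(0.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "a"])

    def test_degenerate_flagged(self):
        res = one_way_anova([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert res.undefined


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    @given(st.floats(0.1, 50), st.floats(-100, 100), st.integers(0, 10**6))
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = pearson_r(x, y)
        r2 = pearson_r(scale * x + shift, y)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRandomizationTest:
    def test_perfect_correlation_is_significant(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], 44)
        res = randomization_test(x, x, rng=np.random.default_rng(0))
        assert res.r_real == pytest.approx(1.0)
        assert res.significant

    def test_envelopes_deterministic_under_seed(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        x = np.arange(30.0)
        y = np.sin(x)
        a = randomization_test(x, y, rng=rng1)
        b = randomization_test(x, y, rng=rng2)
        assert (a.perm_min, a.perm_max, a.boot_min, a.boot_max) == (
            b.perm_min, b.perm_max, b.boot_min, b.boot_max)

    def test_envelope_ordering_and_range(self):
        rng = np.random.default_rng(1)
        res = randomization_test(rng.normal(size=50), rng.normal(size=50),
                                 rng=rng)
        assert -1 <= res.perm_min <= res.perm_max <= 1
        assert -1 <= res.boot_min <= res.boot_max <= 1

    def test_invalid_n_rep(self):
        with pytest.raises(ValueError):
            randomization_test(np.arange(20.0), np.arange(20.0), n_rep=0)


@pytest.fixture(scope="module")
def gt_table():
    """Ground-truth redness table (imaging bypassed): isolates the
    statistics from imaging error."""
    cfg = StudyConfig(seed=0)
    bundle = generate_study(cfg, outdir=None, render=False)
    return cfg, bundle.ground_truth[["genotype", "year", "redness"]].copy()


class TestYearTrendAnalysis:
    def test_recovers_configured_correlation(self, gt_table):
        cfg, t = gt_table
        out = year_trend_analysis(t, traits=("redness",),
                                  rng=np.random.default_rng(0))
        yr = out[out.scheme == "YearRank"].iloc[0]
        assert yr.r == pytest.approx(cfg.target_year_r, abs=0.1)
        assert yr.significant

    def test_encodings_agree_on_monotone_effects(self, gt_table):
        _, t = gt_table
        out = year_trend_analysis(t, traits=("redness",),
                                  rng=np.random.default_rng(0))
        r = out.set_index("scheme")["r"]
        assert abs(r["Year"] - r["YearRank"]) < 0.1
        assert abs(r["Year01"] - r["YearRank"]) < 0.15

    def test_output_rows_traits_times_schemes(self, gt_table):
        _, t = gt_table
        t = t.assign(other=np.arange(len(t), dtype=float))
        out = year_trend_analysis(t, traits=("redness", "other"),
                                  rng=np.random.default_rng(0))
        assert len(out) == 2 * 3

    def test_null_trait_rarely_significant(self):
        """Independent trait: the envelope rule fires well below 1% of
        the time over repeated synthetic studies."""
        rng = np.random.default_rng(7)
        x = np.tile([1.0, 2.0, 3.0, 4.0], 44)
        geno = np.repeat(np.arange(44), 4)
        hits = 0
        n_studies = 200
        for _ in range(n_studies):
            y = center_by_group(rng.normal(size=len(x)), geno)
            hits += randomization_test(x, y, rng=rng).significant
        assert hits / n_studies < 0.01

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            year_trend_analysis(pd.DataFrame({"year": [2003, 2004]}),
                                traits=())


class TestGerminationOutliers:
    def _germ(self, values_by_cell):
        rows = []
        for (geno, year), v in values_by_cell.items():
            for rep in range(1, 5):
                rows.append({"genotype": geno, "year": year,
                             "replicate": rep, "percent": v})
        return pd.DataFrame(rows)

    def test_exclusion_arithmetic(self):
        """Year mean 64.9: a cell at 80 centers to 15.1 (excluded), a
        cell at 70 centers to 5.1 (retained); 15.1 > 15 > 5.1."""
        cells = {("A", 2009): 80.0, ("B", 2009): 70.0,
                 ("C", 2009): 60.0, ("D", 2009): 49.6}
        germ = self._germ(cells)
        assert germ.percent.mean() == pytest.approx(64.9)
        retained, flags = exclude_germination_outliers(germ, limit=15.0)
        flagged = flags.set_index("genotype")
        assert flagged.loc["A", "excluded"]
        assert not flagged.loc["B", "excluded"]
        assert flagged.loc["A", "centered"] == pytest.approx(15.1)
        assert flagged.loc["B", "centered"] == pytest.approx(5.1)
        # D centers to -15.3 and is dropped on the low side
        assert set(retained.genotype) == {"B", "C"}

    def test_boundary_value_retained(self):
        cells = {("A", 2009): 80.0, ("B", 2009): 50.0}
        # year mean 65 -> centered exactly ±15: closed interval retained
        retained, _ = exclude_germination_outliers(self._germ(cells), 15.0)
        assert set(retained.genotype) == {"A", "B"}
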