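import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnkin import (
    build_tables,
    generate_cohort,
    pct_change_symmetric,
    pct_diff_reference,
    ttest_unpaired,
)
from turnkin.io_ingest import features_to_frame
from turnkin.pipeline import PipelineConfig, analyze_trial
from turnkin import reference_values as ref


def pooled_ttest_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_identical_samples(self):
        t, p, sig = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_matches_textbook_formula(self):
        t, p, sig = ttest_unpaired([1, 2, 3], [4, 5, 6])
        t0, p0 = pooled_ttest_oracle([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)
        assert sig

    def test_welch_variant_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0, 1.05]
        b = [2.0, 5.0, -1.0, 4.0, 0.5]
        _, p_pooled, _ = ttest_unpaired(a, b, variant="pooled")
        _, p_welch, _ = ttest_unpaired(a, b, variant="welch")
        assert p_pooled != pytest.approx(p_welch, abs=1e-6)

    def test_degenerate_zero_variance_convention(self):
        t, p, sig = ttest_unpaired([2.0, 2.0], [2.0, 2.0])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_nonfinite_fatal(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0, np.nan], [1.0, 2.0])

    @given(shift=st.floats(-100, 100),
           seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_location_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=5)
        t1, p1, _ = ttest_unpaired(a, b)
        t2, p2, _ = ttest_unpaired(a + shift, b + shift)
        assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-9)


class TestPercentConventions:
    def test_reference_form_worked_examples(self):
        assert round(pct_diff_reference(5.86, 3.5)) == 67
        assert round(pct_diff_reference(1.43, 0.89)) == 61
        assert pct_diff_reference(4.2, 4.2) == 0.0

    def test_symmetric_form_worked_examples(self):
        assert round(pct_change_symmetric(0.77, 0.67)) == -14
        assert round(pct_change_symmetric(2.26, 1.13)) == -67
        assert pct_change_symmetric(3.3, 3.3) == 0.0

    def test_reference_zero_denominator_flagged(self):
        assert np.isnan(pct_diff_reference(1.0, 0.0))
        assert np.isnan(pct_change_symmetric(1.0, -1.0))

    @given(x1=st.floats(0.01, 1e4), x2=st.floats(0.01, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_antisymmetry_and_bound(self, x1, x2):
        f = pct_change_symmetric(x1, x2)
        r = pct_change_symmetric(x2, x1)
        assert f == pytest.approx(-r, rel=1e-9, abs=1e-9)
        assert abs(f) <= 200.0 + 1e-9


class TestPublishedPartitionComparisons:
    """The symmetric convention reproduces every printed partition-comparison
    cell of the spatial tables from that table's printed means (±1 from
    rounding of the printed means)."""

    @pytest.mark.parametrize("row", ref.ALL_SPATIAL_ROWS,
                             ids=lambda r: f"{r['placement']}-{r['direction']}"
                                           f"-{r['parameter']}-{r['group']}")
    def test_row(self, row):
        got = pct_change_symmetric(*row["k2"])
        assert abs(got - row["k2_cmp"][0]) <= 1.0
        for j in range(3):
            got = pct_change_symmetric(row["k4"][j], row["k4"][j + 1])
            assert abs(got - row["k4_cmp"][j]) <= 1.0


@pytest.fixture(scope="module")
def cohort_features():
    trials = generate_cohort(4, 4, seed=9)
    cfg = PipelineConfig(ks=(2, 4))
    records = []
    for tr in trials:
        records.extend(analyze_trial(tr, cfg)[2])
    return features_to_frame(records)


class TestBuildTables:
    def test_all_tables_complete(self, cohort_features):
        tables = build_tables(cohort_features)
        assert len(tables["temporal_summary"]) == 11
        assert len(tables["spatial_angular_velocity"]) == 20  # 10 params x 2
        assert len(tables["spatial_rom"]) == 12
        assert len(tables["spatial_relative"]) == 18
        ts = tables["temporal_summary"]
        assert ts["sd_ss"].ge(0).all() and ts["sd_hi"].ge(0).all()
        ok = ts["p_value"].between(0, 1)
        assert ok.all()
        assert (ts["significant"] == (ts["p_value"] < 0.05)).all()

    def test_comparison_columns_recomputable(self, cohort_features):
        """Stored partition-comparison columns derive from the stored means."""
        tab = build_tables(cohort_features)["spatial_angular_velocity"]
        for _, row in tab.iterrows():
            expect = pct_change_symmetric(row["k2_part1_mean"],
                                          row["k2_part2_mean"])
            assert row["k2_cmp_2_1"] == pytest.approx(expect, rel=1e-12)

    def test_missing_group_fatal(self, cohort_features):
        only_ss = cohort_features[cohort_features["group"] == "SS"]
        with pytest.raises(ValueError, match="HI"):
            build_tables(only_ss)
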