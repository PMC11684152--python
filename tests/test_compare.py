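import math

import numpy as np
import pytest

from ftmseda import (
    ComparisonConfig,
    GroupDefinition,
    SimulationConfig,
    ValidationError,
    gtest_uniqueness,
    simulate_dataset,
    threshold_uniqueness,
)
from ftmseda.compare import gtest_statistics
from conftest import build_dataset


# ---------------------------------------------------------------- oracle
def oracle_g_q_p(a, n1, b, n2):
    """Independently coded log-likelihood-ratio statistic for a 2x2
    presence table, Williams factor, and chi-square(1) tail via erfc."""
    table = [[a, n1 - a], [b, n2 - b]]
    n = n1 + n2
    col = [a + b, n - a - b]
    row = [n1, n2]
    if col[0] == 0 or col[1] == 0:
        return 0.0, 1.0, 1.0
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = table[i][j]
            if o > 0:
                e = row[i] * col[j] / n
                g += o * math.log(o / e)
    g *= 2.0
    q = 1.0 + ((n / row[0] + n / row[1] - 1.0)
               * (n / col[0] + n / col[1] - 1.0)) / (6.0 * n)
    p = math.erfc(math.sqrt(max(g / q, 0.0) / 2.0))
    return g, q, p


def presence_dataset(counts1, n1, counts2, n2):
    """Dataset whose per-peak observation counts are exactly as given."""
    counts1, counts2 = np.atleast_1d(counts1), np.atleast_1d(counts2)
    rows = []
    for a, b in zip(counts1, counts2):
        rows.append([1.0] * a + [np.nan] * (n1 - a)
                    + [1.0] * b + [np.nan] * (n2 - b))
    samples = [f"G1_s{i}" for i in range(n1)] + [f"G2_s{i}" for i in range(n2)]
    ds = build_dataset(rows, samples, formulas=["CH4"] * len(rows),
                       mass_ids=[f"p{i}" for i in range(len(rows))])
    groups = GroupDefinition({s: ("G1" if s.startswith("G1") else "G2")
                              for s in samples})
    return ds, groups


class TestGtestStatistic:
    def test_exhaustive_oracle_equivalence(self):
        """All 2x2 presence tables with group sizes up to 12 match an
        independently coded likelihood-ratio + erfc tail oracle to 1e-9."""
        for n1 in range(3, 13):
            for n2 in range(3, 13):
                a = np.repeat(np.arange(n1 + 1), n2 + 1)
                b = np.tile(np.arange(n2 + 1), n1 + 1)
                g, q, gc, p = gtest_statistics(a, n1, b, n2)
                for i in range(len(a)):
                    go, qo, po = oracle_g_q_p(int(a[i]), n1, int(b[i]), n2)
                    assert g[i] == pytest.approx(go, abs=1e-9)
                    assert q[i] == pytest.approx(qo, abs=1e-9)
                    assert p[i] == pytest.approx(po, abs=1e-9)

    def test_worked_case_five_vs_zero(self):
        g, q, gc, p = gtest_statistics(np.array([5]), 5, np.array([0]), 5)
        assert g[0] == pytest.approx(20 * math.log(2), abs=1e-12)
        assert q[0] == pytest.approx(1.15, abs=1e-12)
        assert gc[0] == pytest.approx(20 * math.log(2) / 1.15, abs=1e-9)
        assert p[0] == pytest.approx(5.2e-4, rel=0.05)

    def test_identical_proportions_give_zero(self):
        g, q, gc, p = gtest_statistics(np.array([3]), 5, np.array([3]), 5)
        assert g[0] == 0.0 and p[0] == 1.0

    def test_degenerate_margins(self):
        for a, b in [(0, 0), (5, 5)]:
            g, _, _, p = gtest_statistics(np.array([a]), 5, np.array([b]), 5)
            assert g[0] == 0.0 and p[0] == 1.0

    def test_invariants_g_nonneg_q_ge_one_p_in_unit(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 11, 500)
        b = rng.integers(0, 11, 500)
        g, q, gc, p = gtest_statistics(a, 10, b, 10)
        assert (g >= 0).all() and (q >= 1).all()
        assert ((p > 0) & (p <= 1)).all()


class TestGtestUniqueness:
    def test_five_vs_zero_unique_to_group1(self):
        ds, groups = presence_dataset([5], 5, [0], 5)
        res = gtest_uniqueness(ds, groups, "G1", "G2")
        assert res.table["uniqueness"].iloc[0] == "unique_to_G1"

    def test_balanced_peak_observed_in_both(self):
        ds, groups = presence_dataset([3], 5, [3], 5)
        res = gtest_uniqueness(ds, groups, "G1", "G2")
        assert res.table["uniqueness"].iloc[0] == "observed_in_both"

    def test_groups_of_two_rejected(self):
        ds, groups = presence_dataset([2], 2, [1], 2)
        with pytest.raises(ValidationError, match="three samples"):
            gtest_uniqueness(ds, groups, "G1", "G2")

    def test_significant_but_sparse_is_insufficient(self):
        # 4/10 vs 0/10: not enough presence in G1 at the default 0.5 threshold
        ds, groups = presence_dataset([4], 10, [0], 10)
        res = gtest_uniqueness(ds, groups, "G1", "G2")
        row = res.table.iloc[0]
        if row["p_value"] <= 0.05:
            assert row["uniqueness"] == "insufficient"

    def test_bh_adjustment_column(self):
        ds, groups = presence_dataset([10, 5, 0], 10, [0, 5, 10], 10)
        res = gtest_uniqueness(ds, groups, "G1", "G2", bh_adjust=True)
        assert "p_adjusted" in res.table.columns
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-12).all()


class TestThresholdUniqueness:
    @pytest.mark.parametrize("a,b,expected", [
        (4, 0, "unique_to_G1"),   # p = (1.0, 0.0)
        (3, 3, "observed_in_both"),
        (1, 0, "insufficient"),   # p = (0.25, 0) below presence threshold
    ])
    def test_default_threshold_labels(self, a, b, expected):
        ds, groups = presence_dataset([a], 4, [b], 4)
        res = threshold_uniqueness(ds, groups, "G1", "G2")
        assert res.table["uniqueness"].iloc[0] == expected

    def test_p06_both_observed(self):
        ds, groups = presence_dataset([3], 5, [3], 5)
        res = threshold_uniqueness(ds, groups, "G1", "G2")
        assert res.table["uniqueness"].iloc[0] == "observed_in_both"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonConfig(pres_threshold=0.2, absn_threshold=0.5)
        with pytest.raises(ValidationError):
            ComparisonConfig(alpha=0)

    def test_agreement_with_gtest_on_extreme_peaks(self):
        ds, groups = presence_dataset([10, 0], 10, [0, 10], 10)
        th = threshold_uniqueness(ds, groups, "G1", "G2")
        gt = gtest_uniqueness(ds, groups, "G1", "G2")
        assert (th.table["uniqueness"] == gt.table["uniqueness"]).all()


class TestCalibration:
    def test_null_rejection_rate_matches_exact_size(self):
        """Under the null the simulated rejection rate agrees with the
        test's exact size, computed by enumerating the 11x11 count table
        with binomial weights."""
        from scipy import stats as _st

        exact = 0.0
        for a in range(11):
            for b in range(11):
                w = _st.binom.pmf(a, 10, 0.5) * _st.binom.pmf(b, 10, 0.5)
                _, _, p = oracle_g_q_p(a, 10, b, 10)
                if p <= 0.05:
                    exact += w
        cfg = SimulationConfig(n_peaks=5000, samples_per_group=(10, 10),
                               frac_differential=0.0,
                               null_presence_range=(0.5, 0.5), seed=0)
        ds, groups, _ = simulate_dataset(cfg)
        res = gtest_uniqueness(ds, groups, "G1", "G2")
        rate = (res.table["p_value"] <= 0.05).mean()
        mc_sd = math.sqrt(exact * (1 - exact) / 5000)
        assert abs(rate - exact) < 4 * mc_sd
        # conservative but close to nominal at these group sizes
        assert 0.03 < exact <= 0.05

    def test_power_on_well_separated_groups(self):
        """Presence 0.9 vs 0.1 with 10 samples per group: at least 80% of
        truly different peaks are labelled unique."""
        cfg = SimulationConfig(n_peaks=2000, samples_per_group=(10, 10),
                               frac_differential=1.0,
                               diff_presence=(0.9, 0.1), seed=0)
        ds, groups, truth = simulate_dataset(cfg)
        res = gtest_uniqueness(ds, groups, "G1", "G2")
        labelled = res.table["uniqueness"].str.startswith("unique_to")
        assert labelled[truth["true_difference"]].mean() >= 0.80
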