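from itertools import combinations
from math import comb

import numpy as np
import pytest

from drest.stats import (CohortTable, mann_whitney_exact, percentile_bounds,
                         separation_sigmas, summary_table, welch_t)


def brute_force_mwu(a, b, sides=2):
    """Oracle: enumerate every assignment of the pooled values to the two
    groups and count U statistics at least as extreme as observed."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def ustat(x, y):
        return float(np.sum(x[:, None] > y[None, :])
                     + 0.5 * np.sum(x[:, None] == y[None, :]))

    pooled = np.concatenate([a, b])
    n = len(pooled)
    u_obs = ustat(a, b)
    ge = le = tot = 0
    for idx in combinations(range(n), len(a)):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        u = ustat(pooled[sel], pooled[~sel])
        tot += 1
        ge += u >= u_obs - 1e-9
        le += u <= u_obs + 1e-9
    if sides == 1:
        return ge / tot
    return min(1.0, 2.0 * min(ge / tot, le / tot))


class TestPercentileBounds:
    def test_full_range(self):
        assert percentile_bounds([1, 2, 3, 4, 5], 0, 100) == [1.0, 5.0]

    def test_linear_interpolation(self):
        # type-7: rank positions 0.2*(n-1)=0.8 and 0.8*(n-1)=3.2
        assert percentile_bounds([10, 20, 30, 40, 50]) == [18.0, 42.0]

    def test_all_equal(self):
        assert percentile_bounds([7.0, 7.0, 7.0]) == [7.0, 7.0]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            percentile_bounds([1.0])


class TestMannWhitneyExact:
    def test_one_sided_small_example(self):
        p, u = mann_whitney_exact([1, 2, 3], [4, 5], sides=1)
        assert u == 0.0
        assert p == pytest.approx(1.0, abs=1e-12)  # a smaller than b
        p_rev, _ = mann_whitney_exact([4, 5], [1, 2, 3], sides=1)
        assert p_rev == pytest.approx(0.1, abs=1e-12)  # 1/C(5,2)

    def test_identical_multisets(self):
        p, _ = mann_whitney_exact([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_25_vs_3(self):
        a = list(np.linspace(0.02, 0.06, 25))
        b = [0.18, 0.21, 0.22]
        p, _ = mann_whitney_exact(a, b)
        assert p == pytest.approx(2.0 / comb(28, 3), rel=1e-9)  # 6.105e-4

    @pytest.mark.parametrize("seed,na,nb,with_ties", [
        (0, 3, 3, False), (1, 4, 5, False), (2, 6, 4, False),
        (3, 5, 5, True), (4, 3, 7, True), (5, 8, 3, True),
    ])
    def test_matches_brute_force_enumeration(self, seed, na, nb, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            a = rng.integers(0, 4, na).astype(float)
            b = rng.integers(0, 4, nb).astype(float)
        else:
            a = rng.normal(size=na)
            b = rng.normal(0.5, size=nb)
        for sides in (1, 2):
            p, _ = mann_whitney_exact(a, b, sides=sides)
            assert p == pytest.approx(brute_force_mwu(a, b, sides), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=6), rng.normal(1.0, size=5)
        p0, _ = mann_whitney_exact(a, b)
        p1, _ = mann_whitney_exact(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        """n=20 per group: exact and tie-corrected normal approximation
        agree within 10 % relative p."""
        from scipy import stats as sstats

        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        b = rng.normal(0.6, size=20)
        p_exact, _ = mann_whitney_exact(a, b)
        p_norm = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue
        assert p_norm == pytest.approx(p_exact, rel=0.10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestWelchT:
    def test_equal_groups(self):
        p, t = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        p, t = welch_t([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0 and t == 0.0

    def test_against_permutation_oracle(self):
        """Strong separation on 8 values: parametric p agrees with the
        brute-force label-permutation test about rejecting at 5 %."""
        a, b = [0.0, 0.0, 1.0, 1.0], [10.0, 10.0, 11.0, 11.0]
        p, t = welch_t(a, b)
        assert t < 0
        assert p < 0.05
        # permutation oracle: |mean difference| at least as extreme
        pooled = np.array(a + b)
        obs = abs(np.mean(a) - np.mean(b))
        cnt = tot = 0
        for idx in combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(idx)] = True
            cnt += abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12
            tot += 1
        assert cnt / tot < 0.05

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestSeparationSigmas:
    def test_at_mean_is_zero(self):
        assert separation_sigmas([1.0, 2.0, 3.0], 2.0) == 0.0

    def test_direct_arithmetic(self):
        assert separation_sigmas([0.03, 0.04, 0.05], 0.2) == pytest.approx(16.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            separation_sigmas([1.0, 1.0], 2.0)


class TestCohortTable:
    def test_duplicate_subjects_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": ["a", "a"], "group": ["g", "g"],
                           "drest": [0.03, 0.04]})
        with pytest.raises(ValueError):
            CohortTable(df)

    def test_summary_table_shape(self):
        import pandas as pd

        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["h"] * 4 + ["t"] * 2,
            "mean_rr_ms": [800.0, 820, 840, 860, 900, 950],
            "drest": [0.03, 0.04, 0.05, 0.045, 0.2, 0.21],
            "qtc_ms": [390.0, 400, 410, 395, 480, 520],
            "t90_tpe_s": [100.0, 120, 150, 130, 260, 280],
            "t90_qt_s": [110.0, 130, 140, 120, 270, 280],
            "tpec_ms": [85.0, 90, 95, 88, 110, 100],
        })
        tab = summary_table(CohortTable(df))
        assert list(tab["group"]) == ["h", "t"]
        h = tab[tab.group == "h"].iloc[0]
        assert h["drest_p20"] <= h["drest_p80"]
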