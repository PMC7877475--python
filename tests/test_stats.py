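import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from spineclust.stats import (
    bca_bootstrap_diff,
    fisher_exact,
    mann_whitney,
    pearson_test,
    two_way_anova,
)


def mwu_exact_enumeration(x, y):
    """Oracle: exact two-sided Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    u_obs = u_of(range(n))
    us = [u_of(c) for c in combinations(range(n + m), n)]
    mean_u = n * m / 2
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us)
    return min(u_obs, n * m - u_obs), extreme / len(us)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert min(r.statistic, 9 - r.statistic) == 0
        assert r.p_value == pytest.approx(0.1)  # 2/C(6,3)
        assert r.exact

    def test_identical_samples_symmetric(self):
        r = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.p_value == pytest.approx(1.0)

    def test_constant_pooled_values_warn(self):
        with pytest.warns(UserWarning):
            r = mann_whitney([3.0, 3.0], [3.0, 3.0])
        assert r.p_value == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n, m = rng.integers(3, 6), rng.integers(3, 6)
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            _, p_oracle = mwu_exact_enumeration(x, y)
            assert mann_whitney(x, y).p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=20), rng.normal(size=15)
        a = mann_whitney(x, y)
        b = mann_whitney(rng.permutation(x), rng.permutation(y))
        assert a.p_value == b.p_value and a.statistic == b.statistic


def fisher_oracle_p(a, b, c, d):
    """Oracle: two-sided Fisher p by direct hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
            if 0 <= c1 - x <= r2
            else 0.0
        )

    p_obs = table_p(a)
    return sum(p for x in range(0, min(r1, c1) + 1) if (p := table_p(x)) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_balanced_table_p1(self):
        assert fisher_exact(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        r = fisher_exact(10, 0, 0, 10)
        assert r.p_value == pytest.approx(2 / math.comb(20, 10))

    def test_sample_odds_ratio(self):
        assert fisher_exact(2, 1, 1, 2).statistic == pytest.approx(4.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(0, 0, 3, 4)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            a, b, c, d = rng.integers(1, 15, size=4)
            assert fisher_exact(a, b, c, d).p_value == pytest.approx(
                fisher_oracle_p(a, b, c, d), abs=1e-9
            )


def anova_type3_oracle(y, A, B):
    """Oracle: Type-III F statistics by explicit least-squares projections
    with sum-to-zero contrasts (model comparison on residual SS)."""
    y = np.asarray(y, float)
    a_levels = sorted(set(A))
    b_levels = sorted(set(B))

    def contrast(levels, values):
        # sum-to-zero coding with one column per non-reference level
        cols = []
        for lev in levels[:-1]:
            col = np.where(np.asarray(values) == lev, 1.0, 0.0)
            col[np.asarray(values) == levels[-1]] = -1.0
            cols.append(col)
        return np.column_stack(cols)

    Xa, Xb = contrast(a_levels, A), contrast(b_levels, B)
    inter = np.column_stack([Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])])
    one = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    full = np.column_stack([one, Xa, Xb, inter])
    rss_full = rss(full)
    df_resid = len(y) - full.shape[1]
    out = {}
    for name, drop in (
        ("genotype", Xa),
        ("training", Xb),
        ("interaction", inter),
    ):
        keep = [m for m in (one, Xa, Xb, inter) if m is not drop]
        rss_red = rss(np.column_stack(keep))
        df_eff = drop.shape[1]
        F = ((rss_red - rss_full) / df_eff) / (rss_full / df_resid)
        out[name] = (F, df_eff, df_resid)
    return out


class TestTwoWayAnova:
    def test_no_effect_factor(self):
        # cell means identical across training levels: its F is exactly 0
        y = [1.0, 2.0, 1.0, 2.0, 5.0, 6.0, 5.0, 6.0]
        g = ["WT"] * 4 + ["DUP"] * 4
        t = ["tr", "tr", "un", "un"] * 2
        res, _ = two_way_anova(y, g, t)
        assert res["training"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["training"].p_value == pytest.approx(1.0)
        assert res["genotype"].p_value < 0.01

    @pytest.mark.parametrize("balanced", [True, False])
    def test_matches_projection_oracle(self, balanced):
        rng = np.random.default_rng(13)
        if balanced:
            g = ["WT"] * 8 + ["DUP"] * 8
            t = (["tr"] * 4 + ["un"] * 4) * 2
        else:
            g = ["WT"] * 9 + ["DUP"] * 6
            t = ["tr"] * 5 + ["un"] * 4 + ["tr"] * 2 + ["un"] * 4
        y = rng.normal(size=len(g)) + (np.asarray(g) == "DUP") * 0.8
        res, _ = two_way_anova(y, g, t)
        oracle = anova_type3_oracle(y, g, t)
        for effect in ("genotype", "training", "interaction"):
            F, df1, df2 = oracle[effect]
            assert res[effect].statistic == pytest.approx(F, abs=1e-8), effect
            p = 1 - sps.f.cdf(F, df1, df2)
            assert res[effect].p_value == pytest.approx(p, abs=1e-8)

    def test_empty_cell_drops_interaction(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        g = ["WT", "WT", "WT", "DUP", "DUP", "DUP"]
        t = ["tr", "tr", "un", "tr", "tr", "tr"]  # DUP/un cell empty
        with pytest.warns(UserWarning, match="empty cell"):
            res, _ = two_way_anova(y, g, t)
        assert res["interaction"] is None

    def test_tukey_table_covers_cell_pairs(self):
        rng = np.random.default_rng(14)
        g = ["WT"] * 8 + ["DUP"] * 8
        t = (["tr"] * 4 + ["un"] * 4) * 2
        _, tukey = two_way_anova(rng.normal(size=16), g, t)
        assert len(tukey) == 6  # C(4,2) cell pairs


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r = pearson_test(x, 2 * x + 1)
        assert r.statistic == pytest.approx(1.0)
        assert r.extra["r2"] == pytest.approx(1.0)

    def test_orthogonal_samples(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_test(x, y).statistic == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x, y = rng.normal(size=12), rng.normal(size=12)
            res = pearson_test(x, y)
            r = res.statistic
            tval = r * np.sqrt(10 / (1 - r * r))
            p = 2 * sps.t.sf(abs(tval), 10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBcaBootstrap:
    def test_degenerate_shift(self):
        with pytest.warns(UserWarning):
            r = bca_bootstrap_diff([3.0, 3.0], [1.0, 1.0], seed=0)
        assert (r.difference, r.ci_low, r.ci_high) == (2.0, 2.0, 2.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(2, 1, 12), rng.normal(0, 1, 10)
        a = bca_bootstrap_diff(x, y, n_boot=2000, seed=21)
        b = bca_bootstrap_diff(x, y, n_boot=2000, seed=21)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        r = bca_bootstrap_diff(x, y, n_boot=2000, seed=3)
        assert r.ci_low <= r.difference <= r.ci_high

    def test_coverage_near_nominal(self):
        # true mean difference of 1.0 should be covered ~95% of the time
        rng = np.random.default_rng(18)
        covered = 0
        trials = 150
        for _ in range(trials):
            x = rng.normal(1.0, 1.0, size=14)
            y = rng.normal(0.0, 1.0, size=14)
            r = bca_bootstrap_diff(x, y, n_boot=600, seed=int(rng.integers(2**31 - 1)))
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered / trials == pytest.approx(0.95, abs=0.05)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            bca_bootstrap_diff([1.0], [2.0, 3.0])
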