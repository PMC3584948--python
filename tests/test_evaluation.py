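import itertools

import numpy as np
import pytest
from scipy import stats

from proqa.evaluation import (
    bootstrap_support,
    evaluate_local,
    fisher_z,
    fisher_z_test,
    gdt1,
    grouped_correlations,
    pearson,
    roc_correct_incorrect,
    selection_zscore,
    top_fraction_deviation,
)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestFisherZ:
    def test_zero_correlation_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_equal_correlations_give_p_one(self):
        z, p = fisher_z_test(0.5, 100, 0.5, 200)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_p_decreases_with_n_and_matches_normal_cdf(self):
        ps = []
        for n in (50, 500, 5000):
            z, p = fisher_z_test(0.70, n, 0.62, n)
            # independent recomputation
            dz = np.arctanh(0.70) - np.arctanh(0.62)
            se = np.sqrt(2.0 / (n - 3))
            assert p == pytest.approx(2 * stats.norm.sf(abs(dz / se)), abs=1e-12)
            ps.append(p)
        assert ps[0] > ps[1] > ps[2]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(0.5, 3, 0.5, 100)


class TestSelection:
    def test_gdt1_sums_first_ranked(self):
        assert gdt1({"t1": 80.0, "t2": 60.0}) == pytest.approx(140.0)

    def test_perfect_selector_equals_best_possible(self):
        rng = np.random.default_rng(1)
        per_target = {f"t{i}": rng.uniform(20, 90, 5) for i in range(4)}
        best = {t: float(q.max()) for t, q in per_target.items()}
        assert gdt1(best) == pytest.approx(sum(q.max() for q in per_target.values()))

    def test_zscore_of_mean_selection_is_zero(self):
        q = np.array([10.0, 20.0, 30.0])
        assert selection_zscore(20.0, q) == pytest.approx(0.0)

    def test_zscore_degenerate_distribution(self):
        with pytest.warns(UserWarning):
            assert selection_zscore(5.0, np.full(4, 5.0)) == 0.0

    def test_random_selection_has_mean_zero_zscore(self):
        rng = np.random.default_rng(2)
        zs = []
        for _ in range(3000):
            q = rng.uniform(0, 100, 8)
            pick = rng.integers(8)
            zs.append(selection_zscore(q[pick], q))
        assert abs(np.mean(zs)) < 0.05


class TestRoc:
    def test_perfect_separation(self):
        d = np.array([0.5, 1.0, 2.0, 6.0, 8.0, 10.0])
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        *_, auc = roc_correct_incorrect(s, d)
        assert auc == pytest.approx(1.0)

    def test_constant_predictor(self):
        d = np.array([0.5, 1.0, 6.0, 8.0])
        s = np.full(4, 0.5)
        *_, auc = roc_correct_incorrect(s, d)
        assert auc == pytest.approx(0.5)

    def test_gray_zone_excluded_and_matches_mann_whitney(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 10, 300)
        s = np.clip(1 / (1 + d / 3) + rng.normal(0, 0.2, 300), 0, 1)
        *_, auc = roc_correct_incorrect(s, d)
        keep = (d < 3) | (d > 5)
        s_k, d_k = s[keep], d[keep]
        pos, neg = s_k[d_k < 3], s_k[d_k > 5]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-9)


class TestTopFraction:
    def test_full_fraction_is_overall_mean(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 12, 50)
        s = rng.uniform(0, 1, 50)
        out = top_fraction_deviation(s, d, fractions=(1.0,))
        assert out[0] == pytest.approx(d.mean())

    def test_perfect_predictor_gives_sorted_running_mean(self):
        d = np.array([5.0, 1.0, 3.0, 9.0, 7.0])
        s = 1 / (1 + d)  # perfect ordering
        fr = (0.2, 0.4, 0.6, 0.8, 1.0)
        out = top_fraction_deviation(s, d, fractions=fr)
        d_sorted = np.sort(d)
        expect = [d_sorted[:k].mean() for k in range(1, 6)]
        assert np.allclose(out, expect)

    def test_anti_predictor_dominates_perfect(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 10, 40)
        s_good = -d
        s_bad = d
        fr = (0.1, 0.3, 0.5, 0.8, 1.0)
        good = top_fraction_deviation(s_good, d, fractions=fr)
        bad = top_fraction_deviation(s_bad, d, fractions=fr)
        assert np.all(bad >= good)


class TestBootstrapSupport:
    def test_strict_winner(self):
        a = {f"t{i}": 50.0 + i for i in range(5)}
        b = {f"t{i}": 40.0 for i in range(5)}
        assert bootstrap_support(a, b, n_boot=200, seed=0) == 1.0

    def test_identical_methods_tie_at_half(self):
        a = {f"t{i}": 50.0 for i in range(5)}
        assert bootstrap_support(a, dict(a), n_boot=200, seed=0) == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration_on_three_targets(self):
        a = {"t0": 60.0, "t1": 45.0, "t2": 50.0}
        b = {"t0": 50.0, "t1": 55.0, "t2": 48.0}
        targets = sorted(a)
        av = np.array([a[t] for t in targets])
        bv = np.array([b[t] for t in targets])
        wins = 0.0
        for combo in itertools.product(range(3), repeat=3):
            sa, sb = av[list(combo)].sum(), bv[list(combo)].sum()
            wins += 1.0 if sa > sb else (0.5 if sa == sb else 0.0)
        exact = wins / 27
        approx = bootstrap_support(a, b, n_boot=20000, seed=1)
        assert approx == pytest.approx(exact, abs=0.02)


class TestGroupedCorrelations:
    def test_consistent_on_exchangeable_groups(self):
        rng = np.random.default_rng(6)
        n, g = 4000, 8
        true = rng.uniform(0, 1, n)
        pred = np.clip(true + rng.normal(0, 0.2, n), 0, 1)
        groups = np.repeat(np.arange(g), n // g)
        mean_r, pooled_r, skipped = grouped_correlations(pred, true, groups)
        assert skipped == 0
        assert mean_r == pytest.approx(pooled_r, abs=0.03)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        n = 300
        true = rng.uniform(0, 1, n)
        pred = np.clip(true + rng.normal(0, 0.3, n), 0, 1)
        groups = rng.integers(0, 4, n)
        perm = rng.permutation(n)
        r1 = grouped_correlations(pred, true, groups)
        r2 = grouped_correlations(pred[perm], true[perm], groups[perm])
        assert r1[0] == pytest.approx(r2[0])
        assert r1[1] == pytest.approx(r2[1])


def test_evaluate_local_report_fields():
    rng = np.random.default_rng(8)
    n = 600
    d = rng.uniform(0, 10, n)
    true_s = 1 / (1 + (d / 3) ** 2)
    pred = np.clip(true_s + rng.normal(0, 0.15, n), 0, 1)
    targets = np.repeat([f"t{i}" for i in range(3)], n // 3)
    models = np.tile(np.repeat([f"m{j}" for j in range(4)], n // 12), 3)
    rep = evaluate_local(pred, true_s, d, targets, models)
    assert -1 <= rep.R <= 1 and rep.R > 0.5
    assert rep.n == n
    assert rep.auc and rep.auc > 0.7
    assert "R" in rep.to_dict()
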