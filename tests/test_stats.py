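import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from watermaze.stats import (
    POOLED_SETS,
    chi_square_pooled,
    cohens_kappa,
    friedman_bonferroni,
    ks_normality,
    mann_whitney_u,
    pool_strategies,
    summarize,
)


class TestPooling:
    def test_all_direct_input(self):
        freq = pool_strategies(list("AAAA"))
        assert freq.pooled["direct"] == 4
        assert freq.pooled["indirect"] == freq.pooled["non_effective"] == 0

    def test_empty_group_gives_zero_row(self):
        freq = pool_strategies([])
        assert freq.n_trials == 0 and freq.pooled.sum() == 0

    def test_random_labels_match_bruteforce_tally(self, rng):
        cats = list("ABCDEFGHIJ")
        labels = [str(c) for c in rng.choice(cats, 200)]
        freq = pool_strategies(labels)
        for name, members in POOLED_SETS.items():
            assert freq.pooled[name] == sum(labels.count(c) for c in members)
        assert freq.n_trials == 200


class TestChiSquare:
    def test_identical_distributions_give_zero(self):
        f = pool_strategies(list("AAAABBEEEHHJ"))
        stat, dof, p = chi_square_pooled(f, f)
        assert stat == 0.0 and p == 1.0 and dof == 2

    def test_hand_computed_disjoint_table(self):
        """[[10,0,0],[0,10,0]] -> Pearson statistic 20 with 2 df... after the
        all-empty third column is dropped the exact value is 20, df 1."""
        f1 = pool_strategies(list("A" * 10))
        f2 = pool_strategies(list("E" * 10))
        with pytest.warns(UserWarning, match="dropping"):
            stat, dof, p = chi_square_pooled(f1, f2)
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_full_2x3_hand_formula(self):
        f1 = pool_strategies(list("AAAAAEEEHH"))
        f2 = pool_strategies(list("AAEEEEEHHH"))
        stat, dof, p = chi_square_pooled(f1, f2)
        table = np.array([[5, 3, 2], [2, 5, 3]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())
        assert dof == 2

    def test_group_swap_invariance(self, rng):
        f1 = pool_strategies([str(c) for c in rng.choice(list("ABEFHJ"), 40)])
        f2 = pool_strategies([str(c) for c in rng.choice(list("ABEFHJ"), 40)])
        assert chi_square_pooled(f1, f2)[0] == pytest.approx(chi_square_pooled(f2, f1)[0])

    def test_type_one_error_calibrated(self, rng):
        """Same-mixture simulations reject at roughly the nominal 5% level."""
        probs = np.array([0.4, 0.4, 0.2])
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.multinomial(32, probs)
            b = rng.multinomial(32, probs)
            fa = pool_strategies(["A"] * a[0] + ["E"] * a[1] + ["H"] * a[2])
            fb = pool_strategies(["A"] * b[0] + ["E"] * b[1] + ["H"] * b[2])
            rejections += chi_square_pooled(fa, fb)[2] < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


class TestKappa:
    def test_identical_vectors_give_one(self):
        res = cohens_kappa(list("ABCJEF"), list("ABCJEF"))
        assert res.kappa == 1.0
        assert res.n_items == 6
        assert np.trace(res.table.to_numpy()) == 6

    def test_independent_raters_near_zero(self, rng):
        cats = list("ABCDEFGHIJ")
        r1 = [str(c) for c in rng.choice(cats, 10000)]
        r2 = [str(c) for c in rng.choice(cats, 10000)]
        assert abs(cohens_kappa(r1, r2).kappa) < 0.05

    def test_contrived_table_matches_hand_formula(self):
        # 2 raters, 3 categories, constructed so p_o = 0.70 and p_e is
        # computable from the marginals by hand
        r1 = list("A" * 40 + "B" * 30 + "J" * 30)
        r2 = list("A" * 30 + "B" * 10 + "A" * 5 + "B" * 20 + "J" * 5 + "B" * 5 + "J" * 25)
        res = cohens_kappa(r1, r2)
        p_o = sum(a == b for a, b in zip(r1, r2)) / 100
        m1 = pd.Series(r1).value_counts() / 100
        m2 = pd.Series(r2).value_counts() / 100
        p_e = sum(m1.get(c, 0) * m2.get(c, 0) for c in "ABJ")
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_invariant_under_consistent_relabeling(self, rng):
        r1 = [str(c) for c in rng.choice(list("ABC"), 300)]
        r2 = [str(c) for c in rng.choice(list("ABC"), 300)]
        mapping = {"A": "H", "B": "I", "C": "J"}
        k1 = cohens_kappa(r1, r2).kappa
        k2 = cohens_kappa([mapping[c] for c in r1], [mapping[c] for c in r2]).kappa
        assert k1 == pytest.approx(k2)


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n*m/2 with midranks
        assert p > 0.9

    def test_agrees_with_exact_permutation_enumeration(self, rng):
        """Oracle: full enumeration of the n=6/6 group assignments."""
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        _, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        obs = ranks[:6].sum()
        count = total = 0
        for comb in itertools.combinations(range(12), 6):
            s = ranks[list(comb)].sum()
            total += 1
            count += abs(s - 39.0) >= abs(obs - 39.0) - 1e-12  # 39 = mean rank sum
        assert p == pytest.approx(count / total, abs=0.02)


class TestFriedman:
    def test_constant_matrix(self):
        stat, p, posthoc = friedman_bonferroni(np.ones((6, 4)))
        assert stat == 0.0 and p == 1.0
        assert (posthoc["p_adjusted"] == 1.0).all()

    def test_adjusted_p_at_least_raw_and_capped(self, rng):
        m = rng.normal(0, 1, (10, 4)) + np.array([0, 0.5, 1.0, 1.5])
        _, _, posthoc = friedman_bonferroni(m)
        assert (posthoc["p_adjusted"] >= posthoc["p_raw"] - 1e-12).all()
        assert (posthoc["p_adjusted"] <= 1.0).all()
        assert len(posthoc) == 6  # all day pairs

    def test_column_permutation_invariance(self, rng):
        m = rng.normal(0, 1, (12, 4))
        stat1, p1, _ = friedman_bonferroni(m)
        stat2, p2, _ = friedman_bonferroni(m[:, [2, 0, 3, 1]])
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)

    def test_agrees_with_permutation_oracle(self, rng):
        """Within-block permutations of condition assignments reproduce the
        asymptotic p within Monte-Carlo + approximation error."""
        m = rng.normal(0, 1, (12, 3)) + np.array([0, 0.4, 0.8])
        stat, p, _ = friedman_bonferroni(m)

        def friedman_stat(mm):
            r = np.apply_along_axis(sps.rankdata, 1, mm)
            rj = r.sum(axis=0)
            n, k = mm.shape
            return 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)

        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = np.array([row[rng.permutation(3)] for row in m])
            count += friedman_stat(perm) >= stat - 1e-12
        assert p == pytest.approx(count / n_perm, abs=0.08)

    def test_incomplete_blocks_rejected(self):
        m = np.ones((5, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_bonferroni(m)


class TestKSNormality:
    def test_gaussian_sample_not_rejected(self, rng):
        d, p = ks_normality(rng.normal(10, 2, 200))
        assert p > 0.05

    def test_strongly_skewed_sample_rejected(self, rng):
        d, p = ks_normality(rng.exponential(1.0, 200))
        assert p < 0.01


class TestSummarize:
    def test_single_trial_group_median_is_value(self):
        metrics = pd.DataFrame(
            {"group": ["young"], "day": [1], "platform_latency": [12.5]}
        )
        out = summarize(metrics=metrics)["metrics"]
        assert out["platform_latency_median"].iloc[0] == 12.5

    def test_known_medians(self, rng):
        vals = np.arange(1, 10, dtype=float)
        metrics = pd.DataFrame({"group": "g", "day": 1, "platform_latency": vals})
        out = summarize(metrics=metrics)["metrics"]
        assert out["platform_latency_median"].iloc[0] == 5.0
        assert out["platform_latency_q1"].iloc[0] == 3.0
        assert out["platform_latency_q3"].iloc[0] == 7.0

    def test_strategy_frequency_table(self):
        labels = pd.DataFrame({"group": ["young"] * 3 + ["aged"] * 3, "category": list("ABEEHJ")})
        out = summarize(labels=labels)["strategy_frequencies"]
        young = out[out["group"] == "young"].iloc[0]
        assert young["direct"] == 2 and young["indirect"] == 1

    def test_empty_inputs_yield_empty_tables(self):
        out = summarize(metrics=pd.DataFrame(), labels=pd.DataFrame())
        assert out["metrics"].empty and out["strategy_frequencies"].empty
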