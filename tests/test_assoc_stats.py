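"""Gate logic, omnibus tests, post hocs, letters, Pearson screens."""

import numpy as np
import pandas as pd
import pytest

from radsym import (GroupedData, anova_tukey, correlation_screen,
                    dunn_bonferroni, gate_test, kruskal_wallis, pearson)
from radsym.assoc_stats import compact_letters


def grouped(*samples, names=None):
    names = names or [f"g{i}" for i in range(len(samples))]
    values = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    groups = np.concatenate(
        [[n] * len(s) for n, s in zip(names, samples)])
    return GroupedData(values, groups)


from conftest import anova_f_oracle, kw_h_oracle, pearson_oracle


class TestGate:
    def test_normal_groups_go_parametric(self, rng):
        # the gate compounds 3 normality tests + Levene at alpha 0.05, so
        # even for exactly Gaussian groups the expected parametric rate is
        # about (1 - alpha_eff)^4 ~ 0.76-0.81; assert well above chance and
        # 3 binomial sds below that expectation
        chosen = []
        for _ in range(100):
            gd = grouped(*(rng.standard_normal(30) for _ in range(3)))
            chosen.append(gate_test(gd).branch == "parametric")
        assert np.mean(chosen) >= 0.62

    def test_lognormal_group_goes_nonparametric(self, rng):
        hits = 0
        for _ in range(20):
            gd = grouped(rng.standard_normal(30), rng.standard_normal(30),
                         np.exp(2.5 * rng.standard_normal(30)))
            hits += gate_test(gd).branch == "nonparametric"
        assert hits >= 18

    def test_identical_data_shares_one_letter(self):
        gd = grouped([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4])
        res = gate_test(gd)
        assert res.p_value == pytest.approx(1.0)
        assert len(set(res.letters.values())) == 1

    def test_small_group_named_in_error(self):
        gd = grouped([1.0, 2.0], [3.0])
        with pytest.raises(ValueError, match="g1"):
            gate_test(gd)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        gd = grouped([1, 2, 3], [4, 5, 6], [7, 8, 9])
        H, p = kruskal_wallis(gd)
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(0.0273, abs=1e-3)

    def test_all_tied_returns_zero(self):
        gd = grouped([5, 5, 5], [5, 5, 5])
        assert kruskal_wallis(gd) == (0.0, 1.0)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(50):
            samples = [rng.integers(0, 6, size=rng.integers(5, 15))
                       .astype(float) for _ in range(3)]
            if all(np.ptp(np.concatenate(samples)) == 0 for _ in [1]):
                continue
            gd = grouped(*samples)
            if np.ptp(gd.values) == 0:
                continue
            H, _ = kruskal_wallis(gd)
            assert H == pytest.approx(kw_h_oracle(samples), abs=1e-8)


class TestDunn:
    def test_identical_groups_same_letter(self):
        gd = grouped([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        res = dunn_bonferroni(gd)
        row = res.pairwise.iloc[0]
        assert row.statistic == pytest.approx(0.0)
        assert row.p_adj == pytest.approx(1.0)
        assert res.letters["g0"] == res.letters["g1"]

    def test_two_groups_single_comparison_unadjusted(self, rng):
        gd = grouped(rng.standard_normal(10), rng.standard_normal(10) + 5)
        res = dunn_bonferroni(gd)
        assert len(res.pairwise) == 1
        assert res.pairwise.iloc[0].p_adj == pytest.approx(
            min(1.0, res.pairwise.iloc[0].p_raw))

    def test_adjusted_p_clamped_and_ordered(self, rng):
        gd = grouped(*(rng.standard_normal(8) for _ in range(5)))
        res = dunn_bonferroni(gd)
        assert (res.pairwise.p_adj <= 1).all()
        assert (res.pairwise.p_adj >= res.pairwise.p_raw - 1e-12).all()

    def test_gradient_letter_pattern(self, rng):
        # A far from C, B in between: expect a / ab / b style letters
        gd = grouped(np.arange(10), np.arange(10) + 6, np.arange(10) + 12,
                     names=["A", "B", "C"])
        res = dunn_bonferroni(gd)
        sig = {frozenset((r.group_a, r.group_b))
               for r in res.pairwise.itertuples() if r.p_adj < 0.05}
        if sig == {frozenset(("A", "C"))}:
            assert res.letters == {"A": "a", "B": "ab", "C": "b"}
        # letters must always be consistent with the significance pattern
        for r in res.pairwise.itertuples():
            shared = set(res.letters[r.group_a]) & set(res.letters[r.group_b])
            assert bool(shared) == (r.p_adj >= 0.05)


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        gd = grouped([1, 2, 3], [1, 2, 3])
        res = anova_tukey(gd)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self, rng):
        from scipy.stats import ttest_ind

        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
        res = anova_tukey(grouped(a, b))
        t, p = ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(50):
            samples = [rng.standard_normal(rng.integers(5, 20))
                       for _ in range(4)]
            res = anova_tukey(grouped(*samples))
            assert res.statistic == pytest.approx(
                anova_f_oracle(samples), abs=1e-8)

    def test_zero_variance_separation_reported(self):
        res = anova_tukey(grouped([1, 1, 1], [2, 2, 2]))
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0
        assert res.letters["g0"] != res.letters["g1"]

    def test_letters_match_tukey_significance(self, rng):
        gd = grouped(rng.standard_normal(10), rng.standard_normal(10) + 3,
                     rng.standard_normal(10) + 6)
        res = anova_tukey(gd)
        for r in res.pairwise.itertuples():
            shared = set(res.letters[r.group_a]) & set(res.letters[r.group_b])
            assert bool(shared) == (r.p_adj >= 0.05)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_oracle(self, rng):
        for _ in range(50):
            x, y = rng.standard_normal(18), rng.standard_normal(18)
            r, p = pearson(x, y)
            ro, po = pearson_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-8)
            assert p == pytest.approx(po, abs=1e-8)


class TestCorrelationScreen:
    def test_emits_one_row_per_partner_and_skips_focal(self, rng):
        df = pd.DataFrame(rng.standard_normal((18, 5)),
                          columns=list("abcde"))
        out = correlation_screen(df, focal="a")
        assert len(out) == 4
        assert "a" not in set(out.partner)

    def test_recovers_planted_negative_correlation(self, rng):
        rs = []
        for _ in range(20):
            w = rng.standard_normal(18)
            taxon = -0.8 * w + np.sqrt(1 - 0.64) * rng.standard_normal(18)
            df = pd.DataFrame({"W": w, "taxon1": taxon})
            rs.append(correlation_screen(df, "W").iloc[0].r)
        assert abs(np.mean(rs) - (-0.8)) < 0.15

    def test_orphan_partner_listed(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        with pytest.raises(KeyError, match="zzz"):
            correlation_screen(df, "a", partners=["b", "zzz"])

    def test_stars_thresholds(self, rng):
        x = np.arange(18.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + rng.standard_normal(18) * .1,
                           "z": rng.standard_normal(18)})
        out = correlation_screen(df, "x").set_index("partner")
        assert out.loc["y", "stars"] == "***"


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        assert compact_letters(["a", "b", "c"], set()) == {
            "a": "a", "b": "a", "c": "a"}

    def test_chain_pattern(self):
        letters = compact_letters(
            ["A", "B", "C"], {frozenset(("A", "C"))})
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_all_different(self):
        import itertools

        groups = ["A", "B", "C"]
        sig = {frozenset(p) for p in itertools.combinations(groups, 2)}
        letters = compact_letters(groups, sig)
        assert len({letters[g] for g in groups}) == 3
        for a, b in itertools.combinations(groups, 2):
            assert not set(letters[a]) & set(letters[b])
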