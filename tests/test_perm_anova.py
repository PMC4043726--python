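"""Sequential-SS F statistics and permutation p-values."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gametolog_div.errors import DataError
from gametolog_div.perm_anova import (
    anova_f,
    brute_force_anova_f,
    design_table,
    exhaustive_permutation_p,
    permutation_p,
)
from gametolog_div.divergence import PdRecord

from .conftest import rng_for


def one_way(values_a, values_b):
    return pd.DataFrame(
        {
            "pd": list(values_a) + list(values_b),
            "sex": ["F"] * len(values_a) + ["M"] * len(values_b),
            "region": ["x"] * (len(values_a) + len(values_b)),
        }
    )


def random_two_way(rng, n):
    while True:
        df = pd.DataFrame(
            {
                "pd": rng.normal(size=n).round(2),
                "sex": rng.choice(["F", "M"], n),
                "region": rng.choice(["NW", "rest"], n),
            }
        )
        if df.groupby(["sex", "region"]).size().shape[0] == 4:
            return df


class TestAnovaF:
    def test_identical_groups_give_zero_f(self):
        res = anova_f(one_way([3, 3, 3], [3, 3, 3]))
        assert res[0].F == 0.0

    def test_hand_expanded_example(self):
        # groups {1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, F = 13.5/(4/4)
        (term,) = anova_f(one_way([1, 2, 3], [4, 5, 6]))
        assert (term.df_num, term.df_den) == (1, 4)
        assert term.F == pytest.approx(13.5)

    def test_one_way_df_is_n_minus_2(self):
        res = anova_f(one_way(range(10), range(7)))
        assert (res[0].df_num, res[0].df_den) == (1, 15)

    def test_single_level_factor_rejected(self):
        df = one_way([1, 2], [])
        with pytest.raises(DataError):
            anova_f(df)

    def test_empty_cell_named_in_error(self):
        df = pd.DataFrame(
            {
                "pd": [1, 2, 3, 4],
                "sex": ["F", "F", "M", "M"],
                "region": ["NW", "NW", "NW", "rest"],
            }
        )
        with pytest.raises(DataError, match="empty cell"):
            anova_f(df, model="two_way_full")

    def test_matches_bruteforce_oracle_one_way(self):
        rng = rng_for("anova-oracle-1w")
        for _ in range(300):
            n1, n2 = rng.integers(2, 9, 2)
            df = one_way(rng.normal(size=n1).round(2), rng.normal(size=n2).round(2))
            (term,) = anova_f(df)
            dfn, dfd, f = brute_force_anova_f(df)["sex"]
            assert (term.df_num, term.df_den) == (dfn, dfd)
            assert term.F == pytest.approx(f, rel=1e-9, abs=1e-12)

    def test_matches_bruteforce_oracle_two_way(self):
        rng = rng_for("anova-oracle-2w")
        for _ in range(200):
            df = random_two_way(rng, int(rng.integers(8, 30)))
            terms = {t.term: t for t in anova_f(df, model="two_way_full")}
            oracle = brute_force_anova_f(df, model="two_way_full")
            for name, (dfn, dfd, f) in oracle.items():
                assert (terms[name].df_num, terms[name].df_den) == (dfn, dfd)
                assert terms[name].F == pytest.approx(f, rel=1e-9, abs=1e-12)

    def test_matches_statsmodels_sequential_anova(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = rng_for("anova-statsmodels")
        for _ in range(40):
            df = random_two_way(rng, int(rng.integers(10, 40)))
            terms = {t.term: t for t in anova_f(df, model="two_way_full")}
            fit = ols("pd ~ C(sex) + C(region) + C(sex):C(region)", df).fit()
            table = sm.stats.anova_lm(fit, typ=1)
            for label, name in [
                ("C(sex)", "sex"),
                ("C(region)", "region"),
                ("C(sex):C(region)", "sex:region"),
            ]:
                assert terms[name].F == pytest.approx(
                    float(table.loc[label, "F"]), rel=1e-8
                )

    def test_type2_equals_type1_on_balanced_design(self):
        rng = rng_for("anova-type2")
        vals = rng.normal(size=16).round(2)
        df = pd.DataFrame(
            {
                "pd": vals,
                "sex": ["F", "M"] * 8,
                "region": ["NW"] * 8 + ["rest"] * 8,
            }
        )
        t1 = {t.term: t.F for t in anova_f(df, model="two_way_full", ss_type=1)}
        t2 = {t.term: t.F for t in anova_f(df, model="two_way_full", ss_type=2)}
        for k in t1:
            assert t1[k] == pytest.approx(t2[k])


class TestPermutationP:
    def test_constant_response_gives_p_one(self):
        df = one_way([5, 5, 5], [5, 5, 5])
        for r in permutation_p(df, n_perm=200, seed=1):
            assert r.p_perm == 1.0

    def test_p_bounds_and_determinism(self):
        rng = rng_for("perm-determinism")
        df = one_way(rng.normal(size=6), rng.normal(size=5) + 1)
        a = permutation_p(df, n_perm=500, seed=42)
        b = permutation_p(df, n_perm=500, seed=42)
        assert a == b
        assert 1 / 501 <= a[0].p_perm <= 1.0

    def test_perfect_separation_exhaustive(self):
        # {0,0,0} vs {10,10,10}: 2 of C(6,3)=20 assignments reach observed F
        df = one_way([0, 0, 0], [10, 10, 10])
        p = exhaustive_permutation_p(df)["sex"]
        assert p == pytest.approx(0.1)

    def test_exhaustive_matches_monte_carlo(self):
        rng = rng_for("perm-exhaustive-mc")
        for _ in range(5):
            df = one_way(rng.normal(size=4).round(2), rng.normal(size=4).round(2))
            p_ex = exhaustive_permutation_p(df)["sex"]
            p_mc = permutation_p(df, n_perm=4000, seed=9)[0].p_perm
            se = np.sqrt(p_ex * (1 - p_ex) / 4000)
            assert abs(p_mc - p_ex) < 4 * se + 2e-3

    def test_invariant_to_factor_relabelling(self):
        rng = rng_for("perm-relabel")
        df = one_way(rng.normal(size=7), rng.normal(size=6) + 0.5)
        swapped = df.copy()
        swapped["sex"] = swapped["sex"].map({"F": "M", "M": "F"})
        a = permutation_p(df, n_perm=800, seed=3)[0].p_perm
        b = permutation_p(swapped, n_perm=800, seed=3)[0].p_perm
        assert a == b

    def test_freedman_lane_agrees_with_manly_for_strong_effect(self):
        rng = rng_for("perm-fl")
        df = random_two_way(rng, 40)
        df.loc[df.sex == "M", "pd"] += 3.0
        manly = {r.term: r.p_perm for r in permutation_p(
            df, model="two_way_full", n_perm=2000, seed=7, scheme="manly")}
        fl = {r.term: r.p_perm for r in permutation_p(
            df, model="two_way_full", n_perm=2000, seed=7, scheme="freedman_lane")}
        assert manly["sex"] < 0.01 and fl["sex"] < 0.01

    def test_nperm_validated(self):
        df = one_way([1, 2], [3, 4])
        with pytest.raises(ValueError):
            permutation_p(df, n_perm=0)


class TestDesignTable:
    def test_region_dichotomy_applied(self):
        records = [
            PdRecord((1, "M", 1), "M", "SE_refugia", "m", 3),
            PdRecord((20, "F", 1), "F", "NW_Europe", "m", 1),
            PdRecord((15, "F", 1), "F", "Pannonian", "m", 2),
        ]
        df = design_table(records)
        assert sorted(df["region"].unique()) == ["NW", "SE_Pann"]
        assert list(df["pd"]) == [3, 1, 2]

    def test_empty_records_rejected(self):
        with pytest.raises(DataError):
            design_table([])
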