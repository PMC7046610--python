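"""Survival estimation and association statistics, checked against
hand-computed product limits, a permutation log-rank and an exact
hypergeometric enumeration."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from emtsig import (
    GeneSetCollection,
    SubgroupAssignment,
    compare_scores_between_groups,
    contingency_association,
    cox_fit,
    enrichment_test,
    fisher_exact,
    km_estimate,
    logrank_test,
)
from emtsig.io import ClinicalTable


def clinical_from(times, events, covariates=None, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=pd.Index(ids, name="id"))
    if covariates:
        for k, v in covariates.items():
            df[k] = v
    return ClinicalTable(df)


def groups_of(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SubgroupAssignment(pd.Series(labels, index=ids), method="truth")


class TestKaplanMeier:
    def test_hand_product_limit(self):
        clin = clinical_from([1, 2, 3], [1, 1, 1])
        curve = km_estimate(clin, groups_of(["Mes"] * 3))["Mes"]
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        clin = clinical_from([2, 5, 9], [0, 0, 0])
        curve = km_estimate(clin, groups_of(["Epi"] * 3))["Epi"]
        assert (curve.survival == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        clin = clinical_from(times, [1] * 40)
        curve = km_estimate(clin, groups_of(["Mes"] * 40))["Mes"]
        for t in [np.quantile(times, q) for q in (0.2, 0.5, 0.8)]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-10)

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(1)
        clin = clinical_from(rng.exponential(5, 60), rng.binomial(1, 0.7, 60))
        curve = km_estimate(clin, groups_of(["Epi"] * 60))["Epi"]
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 3.0, 4.0, 7.0]
        events = [1, 0, 1, 1]
        clin = clinical_from(times + times, events + events,
                             ids=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        g = groups_of(["Epi"] * 4 + ["Mes"] * 4,
                      ids=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        res = logrank_test(clin, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_permutation_reference(self):
        """Chi-square log-rank p agrees with a label-permutation p within
        Monte-Carlo error on a small cohort."""
        rng = np.random.default_rng(3)
        n = 40
        labels = np.array(["Epi"] * 20 + ["Mes"] * 20)
        times = np.where(labels == "Epi", rng.exponential(14, n), rng.exponential(7, n))
        clin = clinical_from(times, [1] * n)
        res = logrank_test(clin, groups_of(list(labels)))

        stats_perm = []
        for _ in range(3000):
            perm = rng.permutation(labels)
            stats_perm.append(logrank_test(clin, groups_of(list(perm))).statistic)
        p_perm = np.mean(np.asarray(stats_perm) >= res.statistic)
        mc_err = 3 * math.sqrt(max(p_perm, 1e-3) * (1 - min(p_perm, 0.999)) / 3000)
        assert abs(res.p - p_perm) < max(0.02, mc_err)

    def test_requires_two_groups(self):
        clin = clinical_from([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(clin, groups_of(["Mes"] * 3))


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(5)
        n = 600
        times = rng.exponential(10, n)
        group = rng.choice(["Epi", "Mes"], n)
        clin = clinical_from(times, [1] * n)
        res = cox_fit(clin, ["subgroup"], groups=groups_of(list(group)))
        row = res.table.iloc[0]
        assert row.ci_low < 1.0 < row.ci_high
        assert 0.8 < row.hr < 1.25

    def test_constant_covariate_rejected(self):
        clin = clinical_from([1, 2, 3, 4], [1, 1, 1, 1], covariates={"x": ["a"] * 4})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(clin, ["x"])

    def test_multivariate_uses_complete_cases(self):
        rng = np.random.default_rng(6)
        n = 120
        clin = clinical_from(
            rng.exponential(10, n), [1] * n,
            covariates={"age": np.where(rng.random(n) < 0.1, np.nan, rng.normal(60, 10, n)),
                        "hpv": rng.choice(["pos", "neg"], n)})
        with pytest.warns(UserWarning, match="dropped"):
            res = cox_fit(clin, ["age", "hpv"])
        assert res.model == "multivariate"
        assert res.n_used + res.n_dropped == n
        assert res.n_dropped > 0

    def test_reference_level_controls_direction(self):
        rng = np.random.default_rng(7)
        n = 400
        group = np.array(["Epi"] * 200 + ["Mes"] * 200)
        lam = np.where(group == "Epi", 0.05, 0.1)
        clin = clinical_from(rng.exponential(1 / lam), [1] * n,
                             covariates={"grp": group})
        hr_vs_mes = cox_fit(clin, ["grp"], reference_levels={"grp": "Mes"}).table.iloc[0].hr
        hr_vs_epi = cox_fit(clin, ["grp"], reference_levels={"grp": "Epi"}).table.iloc[0].hr
        assert hr_vs_mes < 1 < hr_vs_epi
        assert hr_vs_mes == pytest.approx(1 / hr_vs_epi, rel=1e-6)


class TestScoreComparisons:
    def test_identical_multisets_give_p_one_direction_none(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         index=[f"s{i}" for i in range(6)], name="sc")
        g = groups_of(["Epi"] * 3 + ["Mes"] * 3)
        res = compare_scores_between_groups(vals, g)
        assert res.loc["sc", "p"] == pytest.approx(1.0)
        assert res.loc["sc", "direction"] == "none"

    def test_swapping_labels_flips_direction_preserves_p(self):
        rng = np.random.default_rng(8)
        vals = pd.Series(rng.normal(size=30) + np.r_[np.zeros(15), np.ones(15)],
                         index=[f"s{i}" for i in range(30)], name="sc")
        g1 = groups_of(["Epi"] * 15 + ["Mes"] * 15)
        g2 = groups_of(["Mes"] * 15 + ["Epi"] * 15)
        r1 = compare_scores_between_groups(vals, g1)
        r2 = compare_scores_between_groups(vals, g2)
        assert r1.loc["sc", "p"] == pytest.approx(r2.loc["sc", "p"])
        assert r1.loc["sc", "direction"] == "Mes>Epi"
        assert r2.loc["sc", "direction"] == "Epi>Mes"

    def test_small_group_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"], name="sc")
        with pytest.raises(ValueError, match=">= 2"):
            compare_scores_between_groups(vals, groups_of(["Epi", "Mes", "Mes"],
                                                          ids=["a", "b", "c"]))


def exact_two_sided_fisher(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if pk <= obs:
            p += pk
    return float(p)


class TestFisherExact:
    def test_worked_diagonal_case(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / 252, rel=1e-12)

    def test_proportional_rows_give_p_one(self):
        res = fisher_exact([[4, 6], [4, 6]])
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            t = rng.integers(0, 10, (2, 2))
            assert fisher_exact(t).p == pytest.approx(fisher_exact(t.T).p, rel=1e-9)

    def test_matches_exact_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            assert fisher_exact([[a, b], [c, d]]).p == pytest.approx(
                exact_two_sided_fisher(a, b, c, d), abs=1e-10)

    @pytest.mark.parametrize("table", [[[1.5, 2], [3, 4]], [[-1, 2], [3, 4]]])
    def test_invalid_counts_rejected(self, table):
        with pytest.raises(ValueError, match="non-negative integers"):
            fisher_exact(table)


class TestContingency:
    def test_group_identical_variable_is_minimal_p(self):
        labels = ["Epi"] * 6 + ["Mes"] * 6
        clin = clinical_from([1] * 12, [1] * 12, covariates={"v": labels})
        res = contingency_association(clin, groups_of(labels), "v")
        assert res.method == "fisher"
        assert res.p == pytest.approx(exact_two_sided_fisher(6, 0, 0, 6), abs=1e-12)

    def test_two_by_two_path_delegates_to_fisher(self):
        rng = np.random.default_rng(11)
        labels = list(rng.choice(["Epi", "Mes"], 40))
        var = list(rng.choice(["x", "y"], 40))
        clin = clinical_from([1] * 40, [1] * 40, covariates={"v": var})
        res = contingency_association(clin, groups_of(labels), "v")
        counts = res.counts.to_numpy()
        assert res.p == pytest.approx(fisher_exact(counts).p, rel=1e-12)

    def test_multilevel_variable_uses_chi2(self):
        rng = np.random.default_rng(12)
        labels = list(rng.choice(["Epi", "Mes"], 90))
        var = list(rng.choice(["I", "II", "III"], 90))
        clin = clinical_from([1] * 90, [1] * 90, covariates={"v": var})
        res = contingency_association(clin, groups_of(labels), "v")
        assert res.method == "chi2"
        assert 0 <= res.p <= 1

    def test_single_level_variable_rejected(self):
        clin = clinical_from([1] * 4, [1] * 4, covariates={"v": ["x"] * 4})
        with pytest.raises(ValueError, match="levels"):
            contingency_association(clin, groups_of(["Epi", "Epi", "Mes", "Mes"]), "v")


class TestEnrichment:
    def test_full_set_query_matches_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection(sets={"S": universe[:6], "T": universe[10:14]},
                                 descriptions={})
        res = enrichment_test(universe[:6], sets, universe)
        # query == set S: 2x2 is [[6,0],[0,24]]
        assert res.loc["S", "p"] == pytest.approx(exact_two_sided_fisher(6, 0, 0, 24),
                                                  abs=1e-12)
        assert res.loc["S", "overlap"] == 6
        assert (res["q"] >= res["p"] - 1e-15).all()

    def test_disjoint_annotation_set_skipped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection(sets={"in": universe[:3], "out": ["zz1", "zz2"]},
                                 descriptions={})
        with pytest.warns(UserWarning, match="disjoint"):
            res = enrichment_test(universe[:3], sets, universe)
        assert "out" not in res.index

    def test_query_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection(sets={"in": universe[:3]}, descriptions={})
        with pytest.warns(UserWarning, match="outside"):
            res = enrichment_test(universe[:2] + ["alien"], sets, universe)
        assert res.loc["in", "query_size"] == 2

    def test_random_noise_query_rarely_significant(self):
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(1000)]
        sets = GeneSetCollection(
            sets={f"S{j}": list(rng.choice(universe, 30, replace=False))
                  for j in range(20)},
            descriptions={})
        hits = 0
        n_sims = 30
        for _ in range(n_sims):
            query = list(rng.choice(universe, 40, replace=False))
            res = enrichment_test(query, sets, universe)
            hits += res["q"].min() <= 0.05
        assert hits <= 0.1 * n_sims + 1
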