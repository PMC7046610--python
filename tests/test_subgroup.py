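"""Clustering, Epi/Mes label assignment and the compound covariate classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from emtsig import (
    BCCP,
    SubgroupAssignment,
    assign_subgroup_labels,
    bccp_posterior,
    fit_bccp,
    hierarchical_cluster_two_way,
    loocv_misclassification,
    predict_bccp,
)
from emtsig.signature import EMTSignature

from conftest import make_expr


def toy_signature(epi=("E1", "E2"), mes=("M1", "M2")):
    entries = pd.DataFrame(
        [{"gene": g, "orientation": "epithelial", "anchor": "CDH1", "r": 0.9, "q": 1e-4}
         for g in epi]
        + [{"gene": g, "orientation": "mesenchymal", "anchor": "VIM", "r": 0.9, "q": 1e-4}
           for g in mes]
    )
    return EMTSignature(entries=entries, r_min=0.5, q_max=0.05)


def two_block_cohort(n_per=10, sep=3.0, seed=0):
    """n_per Epi then n_per Mes samples over a 4-gene toy signature."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    group = np.array([0] * n_per + [1] * n_per)  # 1 = Mes
    rows = []
    for gene in ["E1", "E2", "M1", "M2"]:
        shift = sep * (1 - group) if gene.startswith("E") else sep * group
        rows.append(8 + shift + rng.normal(0, 0.5, n))
    expr = make_expr(rows, ["E1", "E2", "M1", "M2"], [f"s{i}" for i in range(n)])
    truth = pd.Series(np.where(group == 1, "Mes", "Epi"),
                      index=expr.samples, name="label")
    return expr, truth


class TestClustering:
    def test_duplicated_samples_land_in_same_cluster(self):
        expr, _ = two_block_cohort()
        expr.values["s0_dup"] = expr.values["s0"]
        res = hierarchical_cluster_two_way(expr, toy_signature())
        assert res.sample_clusters["s0"] == res.sample_clusters["s0_dup"]
        d = squareform(pdist(expr.values.T.to_numpy(), metric="correlation"))
        i = list(expr.samples).index("s0")
        j = list(expr.samples).index("s0_dup")
        assert d[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_at_maximum_distance(self):
        sig = toy_signature()
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expr(np.column_stack([profile, profile[::-1], profile, profile[::-1]]),
                         ["E1", "E2", "M1", "M2"], ["a", "b", "c", "d"])
        d = pdist(expr.values.T.to_numpy(), metric="correlation")
        assert squareform(d)[0, 1] == pytest.approx(2.0)
        res = hierarchical_cluster_two_way(expr, sig)
        assert res.sample_clusters["a"] != res.sample_clusters["b"]

    def test_merge_heights_monotone_under_complete_linkage(self):
        expr, _ = two_block_cohort(n_per=15, seed=3)
        res = hierarchical_cluster_two_way(expr, toy_signature())
        heights = res.sample_linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self):
        expr, _ = two_block_cohort(n_per=3)
        with pytest.raises(ValueError, match="k="):
            hierarchical_cluster_two_way(expr, toy_signature(), k=7)

    def test_too_few_signature_genes_rejected(self):
        expr, _ = two_block_cohort()
        sig = toy_signature(epi=("E1",), mes=("ABSENT",))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="signature gene"):
                hierarchical_cluster_two_way(expr, sig)


class TestLabelAssignment:
    def test_high_mes_contrast_cluster_labelled_mes(self):
        expr, truth = two_block_cohort(seed=5)
        res = hierarchical_cluster_two_way(expr, toy_signature())
        labels = assign_subgroup_labels(res, expr, toy_signature()).labels
        assert (labels == truth).all()

    def test_labels_invariant_under_cluster_id_swap(self):
        expr, _ = two_block_cohort(seed=5)
        res = hierarchical_cluster_two_way(expr, toy_signature())
        swapped = res.sample_clusters.map({1: 2, 2: 1})
        a = assign_subgroup_labels(res.sample_clusters, expr, toy_signature()).labels
        b = assign_subgroup_labels(swapped, expr, toy_signature()).labels
        assert (a == b).all()

    def test_exact_tie_raises(self):
        sig = toy_signature()
        # two clusters that mirror each other exactly -> equal contrast
        base = np.array([[1.0, 2.0], [2.0, 1.0], [1.0, 2.0], [2.0, 1.0]])
        expr = make_expr(np.hstack([base, base[:, ::-1]]),
                         ["E1", "E2", "M1", "M2"], ["a", "b", "c", "d"])
        member = pd.Series([1, 2, 2, 1], index=expr.samples)
        with pytest.raises(ValueError, match="tie|equal"):
            assign_subgroup_labels(member, expr, sig)


class TestBCCP:
    def test_t_weight_and_gaussian_means_propagate_sign(self):
        expr, truth = two_block_cohort(seed=7)
        sig = toy_signature(epi=("E1",), mes=("M1",))
        model = fit_bccp(expr, truth, sig)
        assert model.weights["M1"] > 0 > model.weights["E1"]
        assert model.mu_mes > model.mu_epi

    def test_degenerate_constant_genes_raise(self):
        expr = make_expr(np.full((4, 8), 5.0), ["E1", "E2", "M1", "M2"],
                         [f"s{i}" for i in range(8)])
        labels = pd.Series(["Epi"] * 4 + ["Mes"] * 4, index=expr.samples)
        with pytest.raises(ValueError):
            fit_bccp(expr, labels, toy_signature())

    def test_posterior_closed_form_and_degenerate_priors(self):
        expr, truth = two_block_cohort(seed=7)
        model = fit_bccp(expr, truth, toy_signature())
        mid = 0.5 * (model.mu_mes + model.mu_epi)
        assert bccp_posterior(model, mid) == pytest.approx(0.5, abs=1e-12)

        from dataclasses import replace
        sure = replace(model, priors=(1.0, 0.0))
        assert bccp_posterior(sure, -100.0) == 1.0

    def test_posterior_matches_brute_force_densities(self):
        """Log-space posterior equals direct normal-density Bayes rule."""
        from scipy.stats import norm

        expr, truth = two_block_cohort(seed=7)
        model = fit_bccp(expr, truth, toy_signature())
        rng = np.random.default_rng(0)
        for c in rng.normal(0, 5, 50):
            num = model.priors[0] * norm.pdf(c, model.mu_mes, model.sigma)
            den = num + model.priors[1] * norm.pdf(c, model.mu_epi, model.sigma)
            assert bccp_posterior(model, c) == pytest.approx(num / den, abs=1e-12)

    def test_compound_covariate_is_linear(self):
        expr, truth = two_block_cohort(seed=7)
        model = fit_bccp(expr, truth, toy_signature())
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(4, 3)), index=["E1", "E2", "M1", "M2"],
                         columns=["a", "b", "c"])
        w = model.weights
        cx = w @ x.loc[w.index]
        assert (w @ (2 * x.loc[w.index])).values == pytest.approx((2 * cx).values)

    def test_predict_on_training_matches_apparent_labels(self):
        expr, truth = two_block_cohort(n_per=20, seed=8)
        model = fit_bccp(expr, truth, toy_signature())
        pred = predict_bccp(model, expr)
        assert (pred.labels == truth).all()
        assert pred.posterior.between(0, 1).all()

    def test_predict_rejects_mostly_missing_genes(self, small_cohort, small_signature):
        model = fit_bccp(small_cohort.expression,
                         SubgroupAssignment(small_cohort.true_labels, "truth"),
                         small_signature)
        keep = model.genes[: max(1, int(0.4 * len(model.genes)))]
        reduced = small_cohort.expression.restrict(
            keep + [g for g in ("CDH1",) if g not in keep])
        with pytest.raises(ValueError, match="50%"):
            predict_bccp(model, reduced)

    def test_summary_mentions_model_dimensions(self):
        expr, truth = two_block_cohort(seed=7)
        model = fit_bccp(expr, truth, toy_signature())
        text = model.summary()
        assert "genes in model" in text and "sigma" in text

    def test_model_round_trips_through_json(self, tmp_path):
        from emtsig import BCCPResults

        expr, truth = two_block_cohort(seed=7)
        model = fit_bccp(expr, truth, toy_signature())
        path = tmp_path / "model.json"
        model.save(path)
        back = BCCPResults.load(path)
        assert back.genes == model.genes
        assert back.sigma == pytest.approx(model.sigma)
        c = 1.234
        assert back.posterior(c) == pytest.approx(model.posterior(c))


class TestLOOCV:
    def test_separable_toy_has_zero_error(self):
        # 2 per class, identical within-class profiles, distinct between
        base = np.array([[9, 9, 1, 1], [9, 9, 1, 1], [1, 1, 9, 9], [1, 1, 9, 9]], float)
        base = base + np.random.default_rng(0).normal(0, 0.01, base.shape)
        expr = make_expr(base, ["E1", "E2", "M1", "M2"], ["a", "b", "c", "d"])
        labels = pd.Series(["Epi", "Epi", "Mes", "Mes"], index=expr.samples)
        with pytest.raises(ValueError, match="< 2 samples"):
            loocv_misclassification(expr, labels, toy_signature())
        # with 3 per class every fold keeps >= 2 per class
        expr6 = make_expr(np.hstack([base, base[:, [0, 2]]]),
                          ["E1", "E2", "M1", "M2"], ["a", "b", "c", "d", "e", "f"])
        labels6 = pd.Series(["Epi", "Epi", "Mes", "Mes", "Epi", "Mes"], index=expr6.samples)
        assert loocv_misclassification(expr6, labels6, toy_signature()) == 0.0

    def test_permuted_labels_give_chance_error(self):
        expr, truth = two_block_cohort(n_per=50, sep=3.0, seed=4)
        rng = np.random.default_rng(0)
        permuted = pd.Series(rng.permutation(truth.to_numpy()), index=truth.index)
        rate = loocv_misclassification(expr, permuted, toy_signature())
        assert rate == pytest.approx(0.5, abs=0.12)
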