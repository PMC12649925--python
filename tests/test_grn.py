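"""GRN inference: RF importance, recursive elimination, GMM, layer selection,
metabolite linking and network bookkeeping."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from drynet import grn, synthetic
from drynet.datatypes import ExpressionMatrix, HierarchicalNetwork


def _expr_from_array(values, ids):
    values = np.asarray(values, dtype=float)
    cols = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {"timepoint": range(len(cols)), "replicate": 0, "group": "g"}, index=cols
    )
    return ExpressionMatrix(
        values=pd.DataFrame(np.clip(values, 0, None), index=ids, columns=cols),
        metadata=meta,
    )


# -------------------------------------------------------- rf_importance
class TestRfImportance:
    def test_planted_single_regulator_dominates(self):
        """Target copies TF_1; TF_1 wins the importance ranking in >=95% of seeds."""
        rng = np.random.default_rng(0)
        wins = 0
        for seed in range(20):
            x = rng.uniform(1, 10, size=(6, 24))
            tfs = pd.DataFrame(x, index=[f"tf{i}" for i in range(6)])
            y = x[1] + rng.normal(scale=0.05, size=24)
            imp = grn.rf_importance(y, tfs, n_trees=500, seed=seed)
            wins += imp.idxmax() == "tf1"
        assert wins >= 19

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(1)
        tfs = pd.DataFrame(rng.uniform(size=(5, 12)), index=[f"t{i}" for i in range(5)])
        imp = grn.rf_importance(rng.uniform(size=12), tfs, n_trees=50, seed=0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_tf_row_order(self):
        """Canonical internal ordering: permuting input rows permutes output only."""
        rng = np.random.default_rng(2)
        tfs = pd.DataFrame(rng.uniform(size=(6, 15)), index=[f"t{i}" for i in range(6)])
        y = rng.uniform(size=15)
        imp1 = grn.rf_importance(y, tfs, n_trees=100, seed=7)
        perm = ["t3", "t0", "t5", "t1", "t4", "t2"]
        imp2 = grn.rf_importance(y, tfs.loc[perm], n_trees=100, seed=7)
        pd.testing.assert_series_equal(imp1.sort_index(), imp2.sort_index())

    def test_constant_target_uniform_with_warning(self):
        tfs = pd.DataFrame(np.random.default_rng(3).uniform(size=(4, 10)),
                           index=list("abcd"))
        with pytest.warns(UserWarning, match="constant"):
            imp = grn.rf_importance(np.ones(10), tfs, n_trees=10, seed=0)
        np.testing.assert_allclose(imp.values, 0.25)

    def test_too_few_samples_raises(self):
        tfs = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            grn.rf_importance(np.ones(4), tfs)


# ------------------------------------------------------------ bwerf_rank
class TestBwerfRank:
    def test_smallest_instance_single_iteration(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 5, size=(3, 8))
        expr = _expr_from_array(vals, ["g", "tf_a", "tf_b"])
        table = grn.bwerf_rank(expr, ["tf_a", "tf_b"], ["g"], n_trees=50, seed=0)
        assert set(table["tf"]) == {"tf_a", "tf_b"}
        assert (table["iterations_survived"] == 1).all()
        imp = grn.rf_importance(
            expr.values.loc["g"].values, expr.values.loc[["tf_a", "tf_b"]],
            n_trees=50, seed=None or 0,
        )
        # aggregation over a single iteration reduces to that one RF call:
        # same two importances (seed differs inside bwerf, so compare sums)
        assert table["importance"].sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("m", [2, 3, 5, 8, 16, 50])
    def test_iteration_count_half_drop(self, m):
        """With drop_fraction=0.5 the elimination runs ceil(log2 m) rounds."""
        rng = np.random.default_rng(5)
        ids = [f"t{i}" for i in range(m)]
        expr = _expr_from_array(rng.uniform(1, 5, size=(m + 1, 10)), ["g"] + ids)
        table = grn.bwerf_rank(expr, ids, ["g"], drop_fraction=0.5, n_trees=20, seed=1)
        assert table["iterations_survived"].max() == math.ceil(math.log2(m))

    def test_importance_invariants(self):
        rng = np.random.default_rng(6)
        ids = [f"t{i}" for i in range(8)]
        expr = _expr_from_array(rng.uniform(1, 5, size=(10, 12)), ["g1", "g2"] + ids)
        table = grn.bwerf_rank(expr, ids, ["g1", "g2"], drop_fraction=0.3, n_trees=30, seed=2)
        assert (table["importance"] >= 0).all()
        # every candidate TF has a record for every gene (>= 1 iteration)
        assert len(table) == 16

    def test_absent_pathway_gene_raises_naming_it(self):
        expr = _expr_from_array(np.ones((3, 8)) + np.random.default_rng(0).uniform(size=(3, 8)), ["a", "b", "c"])
        with pytest.raises(KeyError, match="ghost"):
            grn.bwerf_rank(expr, ["a", "b"], ["ghost"])


# -------------------------------------------------------------- GMM / EM
def brute_force_em(x, means, variances, weights, tol=1e-10, max_iter=500):
    """Independent plain-loop EM for 1-D Gaussian mixtures."""
    x = np.asarray(x, float)
    means, variances, weights = map(lambda a: np.array(a, float), (means, variances, weights))
    k = len(means)
    lls = []
    for _ in range(max_iter + 1):
        dens = np.zeros((len(x), k))
        for j in range(k):
            dens[:, j] = weights[j] * np.exp(-0.5 * (x - means[j]) ** 2 / variances[j]) / np.sqrt(2 * np.pi * variances[j])
        tot = dens.sum(axis=1)
        lls.append(float(np.log(tot).sum()))
        if len(lls) > 1 and lls[-1] - lls[-2] < tol:
            break
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum((resp * (x[:, None] - means) ** 2).sum(axis=0) / nk, 1e-10)
    return lls


class TestGmm:
    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        fit = grn.gmm_fit_1d(x, seed=0)
        assert (np.diff(fit.log_likelihood_trace) >= -1e-9).all()

    def test_recovers_separated_mixture(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(10, 0.1, 100)])
        fit = grn.gmm_fit_1d(x, n_init=5, seed=1)
        means = np.sort(fit.means)
        assert abs(means[0] - 0) < 0.1 and abs(means[1] - 10) < 0.1
        np.testing.assert_allclose(np.sort(fit.weights), [0.5, 0.5], atol=0.05)

    def test_single_component_matches_sample_moments(self):
        rng = np.random.default_rng(9)
        x = rng.normal(3, 2, 200)
        fit = grn.gmm_fit_1d(x, n_components=1, n_init=1, seed=0)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-8)
        assert fit.variances[0] == pytest.approx(x.var(), rel=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_em_oracle(self, seed):
        """Same start, independent EM implementations: final log-likelihoods
        agree to 1e-6 and both traces are monotone."""
        rng = np.random.default_rng(100 + seed)
        x = np.concatenate([
            rng.normal(rng.uniform(-2, 0), rng.uniform(0.5, 1.5), 60),
            rng.normal(rng.uniform(1, 4), rng.uniform(0.5, 1.5), 40),
        ])
        init = (
            np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)]),
            np.full(2, x.var()),
            np.array([0.5, 0.5]),
        )
        fit = grn.gmm_fit_1d(x, init_params=init)
        oracle = brute_force_em(x, *init)
        assert abs(fit.log_likelihood - oracle[-1]) < 1e-6
        assert (np.diff(fit.log_likelihood_trace) >= -1e-9).all()
        assert (np.diff(oracle) >= -1e-9).all()

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            grn.gmm_fit_1d([1.0, 2.0, 3.0], n_components=2)


# ------------------------------------------------------- layer selection
class TestSelectLayerTfs:
    def test_separable_scores_select_high_component(self):
        scores = pd.Series(
            [0.01] * 20 + [0.9] * 5,
            index=[f"t{i}" for i in range(25)],
        )
        fit = grn.gmm_fit_1d(scores.values, n_init=5, seed=0)
        sel = grn.select_layer_tfs(scores, fit)
        assert sel == {f"t{i}" for i in range(20, 25)}

    def test_degenerate_identical_scores_fallback(self):
        scores = pd.Series(np.full(10, 0.5), index=[f"t{i}" for i in range(10)])
        fit = grn.gmm_fit_1d(scores.values + np.random.default_rng(0).normal(0, 1e-12, 10), n_init=2, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            sel = grn.select_layer_tfs(scores, fit)
        assert len(sel) == 5

    def test_posterior_monotone_in_score(self):
        """Holding the fit, a higher score never has lower high-component posterior."""
        rng = np.random.default_rng(10)
        scores = pd.Series(
            np.concatenate([rng.normal(0.1, 0.02, 30), rng.normal(1.0, 0.1, 10)]),
            index=[f"t{i}" for i in range(40)],
        )
        fit = grn.gmm_fit_1d(scores.values, n_init=5, seed=3)
        hi = int(np.argmax(fit.means))
        lo = 1 - hi
        # posterior for the higher-mean component, as a function of score x,
        # is monotone increasing iff selected set is upward-closed in score
        sel = grn.select_layer_tfs(scores, fit)
        if fit.variances[hi] <= fit.variances[lo] * 1.001:
            thresh = min(scores[t] for t in sel) if sel else np.inf
            assert all(t in sel for t in scores.index if scores[t] > thresh)

    def test_empty_scores_raise(self):
        fit = grn.gmm_fit_1d(np.arange(10.0), seed=0)
        with pytest.raises(ValueError):
            grn.select_layer_tfs(pd.Series(dtype=float), fit)


# -------------------------------------------------------- build_hierarchy
@pytest.fixture(scope="module")
def small_build():
    expr, truth = synthetic.simulate_hierarchy_expression(
        10, 5, 4, 8, timepoints=6, replicates=3, noise_sd=0.6, seed=42
    )
    tfs = sorted(truth.layer_assignments) + sorted(truth.decoy_tfs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = grn.build_hierarchy(
            expr, tfs, truth.pathway_genes, n_layers=2,
            drop_fraction=0.3, n_trees=100, seed=0,
        )
    return expr, truth, net


class TestBuildHierarchy:

    def test_layers_disjoint_edges_adjacent(self, small_build):
        _, _, net = small_build
        all_nodes = [n for layer in net.layers for n in layer]
        assert len(all_nodes) == len(set(all_nodes))
        layer_of = {g: 0 for g in net.pathway_genes}
        for i, layer in enumerate(net.layers, 1):
            layer_of.update({t: i for t in layer})
        for reg, tgt, w in net.tf_edges:
            assert layer_of[reg] == layer_of[tgt] + 1
            assert w >= 0

    def test_single_layer_is_recursion_base(self):
        expr, truth = synthetic.simulate_hierarchy_expression(
            6, 4, 3, 5, timepoints=6, replicates=2, noise_sd=0.6, seed=7
        )
        tfs = sorted(truth.layer_assignments) + sorted(truth.decoy_tfs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = grn.build_hierarchy(
                expr, tfs, truth.pathway_genes, n_layers=1,
                drop_fraction=0.3, n_trees=60, seed=1,
            )
        assert len(net.layers) == 1
        assert {t for t, _, _ in net.tf_edges} <= set(net.layers[0])
        assert {t for _, t, _ in net.tf_edges} <= set(truth.pathway_genes)

    def test_deterministic_given_seed(self):
        expr, truth = synthetic.simulate_hierarchy_expression(
            5, 3, 2, 4, timepoints=6, replicates=2, noise_sd=0.6, seed=3
        )
        tfs = sorted(truth.layer_assignments) + sorted(truth.decoy_tfs)
        kwargs = dict(n_layers=1, drop_fraction=0.4, n_trees=50, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = grn.build_hierarchy(expr, tfs, truth.pathway_genes, **kwargs)
            b = grn.build_hierarchy(expr, tfs, truth.pathway_genes, **kwargs)
        assert a.layers == b.layers and a.tf_edges == b.tf_edges

    def test_pool_exhaustion_warns_and_truncates(self):
        rng = np.random.default_rng(11)
        ids = ["g1", "g2", "ta", "tb", "tc"]
        expr = _expr_from_array(rng.uniform(1, 5, size=(5, 12)), ids)
        with pytest.warns(UserWarning):
            net = grn.build_hierarchy(
                expr, ["ta", "tb", "tc"], ["g1", "g2"], n_layers=4,
                drop_fraction=0.5, n_trees=20, seed=0,
            )
        assert len(net.layers) < 4


# ------------------------------------------------------ link_metabolites
class TestLinkMetabolites:
    def _mats(self, gene_vals, met_vals):
        from conftest import make_metabolite_matrix

        n_t = gene_vals.shape[1]
        expr = _expr_from_array(gene_vals, [f"g{i}" for i in range(gene_vals.shape[0])])
        metab = make_metabolite_matrix(met_vals, timepoints=list(range(n_t)))
        return expr, metab

    def test_proportional_metabolite_kept_with_r_one(self):
        g = np.linspace(1, 10, 8)[None, :]
        m = (2 * g + 3)
        expr, metab = self._mats(g, m)
        edges = grn.link_metabolites(expr, metab, r_min=0.9, alpha=0.05)
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(1.0)

    def test_toy_fixture_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        g = rng.uniform(1, 10, size=(4, 6))
        m = rng.uniform(1, 10, size=(3, 6))
        expr, metab = self._mats(g, m)
        edges = grn.link_metabolites(expr, metab, r_min=0.5, alpha=0.5)
        from scipy import stats as ss

        from drynet.transcript import bh_fdr

        ps, rs = np.zeros((4, 3)), np.zeros((4, 3))
        for i in range(4):
            for j in range(3):
                rs[i, j], ps[i, j] = ss.pearsonr(g[i], m[j])
        fdr = bh_fdr(ps.ravel()).reshape(ps.shape)
        expected = {
            (f"g{i}", f"m{j}")
            for i in range(4) for j in range(3)
            if abs(rs[i, j]) >= 0.5 and fdr[i, j] < 0.5
        }
        assert {(e[0], e[1]) for e in edges} == expected

    def test_null_kept_fraction_matches_tail_probability(self):
        """Independent pairs at r_min=0.8, n=6: kept fraction tracks the
        null tail P(|r| >= 0.8) with no FDR gate (alpha=1)."""
        rng = np.random.default_rng(13)
        n_g, n_m, n_t = 60, 50, 6
        expr, metab = self._mats(rng.normal(10, 1, (n_g, n_t)), rng.normal(10, 1, (n_m, n_t)))
        edges = grn.link_metabolites(expr, metab, r_min=0.8, alpha=1.0000001)
        frac = len(edges) / (n_g * n_m)
        # P(|r|>=0.8) at n=6 from the t transform
        t_crit = 0.8 * np.sqrt(4 / (1 - 0.64))
        from scipy import stats as ss

        p_tail = 2 * ss.t.sf(t_crit, df=4)
        assert abs(frac - p_tail) < 3 * np.sqrt(p_tail / (n_g * n_m)) + 0.01

    def test_too_few_matched_raises(self):
        g = np.ones((1, 2)) * [[1, 2]]
        expr, metab = self._mats(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            grn.link_metabolites(expr, metab)


# ------------------------------------------------------- network summary
class TestNetworkSummary:
    def test_empty_network_all_zero(self):
        net = HierarchicalNetwork(layers=[], tf_edges=[], pathway_genes=[])
        s = grn.network_summary(net)
        assert s["n_tfs"] == 0 and s["n_tf_edges"] == 0 and s["n_metabolite_edges"] == 0

    def test_known_composition(self):
        net = HierarchicalNetwork(
            layers=[["a", "b"], ["c"]],
            tf_edges=[("a", "g1", 0.5), ("b", "g1", 0.3), ("c", "a", 0.9)],
            pathway_genes=["g1", "g2"],
            gene_metabolite_edges=[("g1", "m1", 0.95, 0.001)],
        )
        s = grn.network_summary(net, regulation_status={"a": "up", "b": "down", "c": "up"})
        assert s["tfs_per_layer"] == [2, 1]
        assert s["n_functional_genes"] == 2
        assert s["n_tf_edges"] == 3
        assert s["n_metabolite_edges"] == 1
        assert s["regulation_by_layer"] == [{"up": 1, "down": 1, "ns": 0}, {"up": 1, "down": 0, "ns": 0}]

    def test_edge_count_consistency(self):
        net = HierarchicalNetwork(
            layers=[["a", "b"]],
            tf_edges=[("a", "g1", 0.5), ("b", "g2", 0.3), ("a", "g2", 0.1)],
            pathway_genes=["g1", "g2"],
        )
        s = grn.network_summary(net)
        per_target = {}
        for _, t, _ in net.tf_edges:
            per_target[t] = per_target.get(t, 0) + 1
        assert s["n_tf_edges"] == sum(per_target.values())
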