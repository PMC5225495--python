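"""Edgewise logistic, multinomial logit, and the network-based statistic."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from phasedyn.inference import (
    DesignMatrix,
    edgewise_pairwise_logistic,
    metastability_multinomial,
    nbs,
    node_contribution,
    NBSResult,
)
from phasedyn.static_fc import edge_columns, edge_index, index_to_pair

from conftest import make_design_frame


def _design(rng, labels, reference=None):
    frame = make_design_frame(rng, list(labels))
    return DesignMatrix(
        outcome=frame["group"],
        covariates=frame[["sex", "age", "headcoil", "motion"]],
        reference=reference or sorted(set(labels))[0],
    )


class TestEdgewiseLogistic:
    def test_degenerate_edge_flagged(self, rng):
        labels = ["A"] * 8 + ["B"] * 8
        y = rng.standard_normal((16, 3))
        y[:, 1] = 4.2  # no information
        em = pd.DataFrame(y, columns=edge_columns(3))
        res = edgewise_pairwise_logistic(em, _design(rng, labels), ("A", "B"))
        assert res.loc[1, "status"] == "degenerate"
        assert np.isnan(res.loc[1, "coef"])

    def test_planted_effect_has_smallest_p(self):
        hits = 0
        for r in range(20):
            rng = np.random.default_rng(700 + r)
            labels = ["A"] * 20 + ["B"] * 20
            y = rng.standard_normal((40, 45))
            y[20:, 0] += 3.0
            em = pd.DataFrame(y, columns=edge_columns(10))
            res = edgewise_pairwise_logistic(em, _design(rng, labels), ("A", "B"))
            hits += res["p"].idxmin() == 0
        assert hits >= 19

    def test_null_p_values_uniform_under_label_permutation(self, rng):
        labels = np.array(["A"] * 26 + ["B"] * 26)
        y = rng.standard_normal((52, 325))
        perm = rng.permutation(52)
        em = pd.DataFrame(y, columns=edge_columns(26))
        res = edgewise_pairwise_logistic(em, _design(rng, labels[perm]), ("A", "B"))
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_missing_class_rejected(self, rng):
        labels = ["A"] * 10 + ["B"] * 10
        em = pd.DataFrame(rng.standard_normal((20, 3)), columns=edge_columns(3))
        with pytest.raises(ValueError, match="present"):
            edgewise_pairwise_logistic(em, _design(rng, labels), ("A", "C"))

    def test_bonferroni_column_caps_at_one(self, rng):
        labels = ["A"] * 12 + ["B"] * 12
        em = pd.DataFrame(rng.standard_normal((24, 6)), columns=edge_columns(4))
        res = edgewise_pairwise_logistic(em, _design(rng, labels), ("A", "B"))
        ok = res["p"].notna()
        assert np.all(res.loc[ok, "p_bonferroni"] <= 1.0)
        assert np.all(res.loc[ok, "p_bonferroni"] >= res.loc[ok, "p"])


class TestMultinomial:
    def test_ordered_metric_gives_negative_significant_coefficients(self, rng):
        labels = ["SCI"] * 26 + ["MCI"] * 26 + ["AD"] * 26
        metric = np.concatenate(
            [rng.normal(0.15, 0.02, 26), rng.normal(0.12, 0.02, 26),
             rng.normal(0.09, 0.02, 26)]
        )
        fit = metastability_multinomial(metric, _design(rng, labels, "SCI"))
        assert fit.reference == "SCI"
        assert fit.summary.loc["AD", "coef"] < 0
        assert fit.summary.loc["MCI", "coef"] < 0
        assert fit.summary.loc["AD", "p"] < 0.05
        assert 0 < fit.pseudo_r2 < 1
        assert fit.log_likelihood < 0

    def test_duplicating_subjects_keeps_coefficients_shrinks_se(self, rng):
        labels = ["A"] * 15 + ["B"] * 15 + ["C"] * 15
        metric = rng.normal(0, 1, 45) + np.repeat([0.0, 0.7, 1.4], 15)
        design = _design(rng, labels, "A")
        fit = metastability_multinomial(metric, design)
        dup = DesignMatrix(
            outcome=pd.concat([design.outcome] * 2, ignore_index=True),
            covariates=pd.concat([design.covariates] * 2, ignore_index=True),
            reference="A",
        )
        fit2 = metastability_multinomial(np.tile(metric, 2), dup)
        assert np.allclose(
            fit2.summary["coef"], fit.summary["coef"], rtol=1e-4, atol=1e-6
        )
        assert np.all(fit2.summary["se"] < fit.summary["se"])

    def test_two_class_fit_matches_binary_logistic(self, rng):
        labels = ["A"] * 20 + ["B"] * 20
        metric = rng.normal(0, 1, 40) + np.repeat([0.0, 0.8], 20)
        design = _design(rng, labels, "A")
        fit = metastability_multinomial(metric, design)
        x = np.column_stack(
            [np.ones(40), design.covariates.to_numpy(float), metric]
        )
        y = (design.outcome == "B").astype(float).to_numpy()
        ref = sm.Logit(y, x).fit(disp=0)
        assert np.allclose(fit.params["B"].to_numpy(), ref.params, atol=1e-6)

    def test_single_class_rejected(self, rng):
        labels = ["A"] * 12
        with pytest.raises(ValueError):
            metastability_multinomial(rng.normal(0, 1, 12), _design(rng, labels, "A"))

    def test_tiny_class_rejected(self, rng):
        labels = ["A"] * 10 + ["B"] * 10 + ["C"]
        with pytest.raises(ValueError, match="fewer than 2"):
            metastability_multinomial(rng.normal(0, 1, 21), _design(rng, labels, "A"))


class TestNBS:
    def test_planted_component_recovered(self):
        recovered = 0
        # 5-edge star at node 1: still connected if one edge dips below
        # the primary threshold
        planted = [edge_index(1, k, 10) for k in (2, 3, 4, 5, 6)]
        for r in range(10):
            rng = np.random.default_rng(300 + r)
            labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
            y = rng.standard_normal((30, 45))
            for e in planted:
                y[10:20, e - 1] += 1.0
                y[20:, e - 1] += 2.0
            res = nbs(y, _design(rng, labels, "A"), n_perm=500, seed=r)
            sig = [c for c in res.components if c["p"] < 0.05]
            found = max(
                (len(set(c["edges"]) & set(planted)) for c in sig), default=0
            )
            recovered += found >= 4
        assert recovered >= 8

    def test_tiny_instance_matches_exhaustive_enumeration(self, rng):
        """Intercept-only NBS p equals brute-force label enumeration."""
        labels = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        y = rng.standard_normal((9, 6))
        y[labels == "C", 0] += 3.0
        y[labels == "C", 1] += 3.0
        design = DesignMatrix(
            outcome=pd.Series(labels),
            covariates=pd.DataFrame(index=range(9)),
            reference="A",
        )
        res = nbs(y, design, exhaustive=True, seed=None)
        assert res.components, "expected a suprathreshold component"

        thr = stats.f.isf(0.05, 2, 6)

        def max_component(lbls):
            lbls = np.asarray(lbls)
            g = nx.Graph()
            for e in range(6):
                f = stats.f_oneway(*(y[lbls == k, e] for k in "ABC")).statistic
                if f > thr:
                    i, j = index_to_pair(e + 1, 4)
                    g.add_edge(i, j)
            return max(
                (g.subgraph(c).number_of_edges() for c in nx.connected_components(g)),
                default=0,
            )

        null = np.array([max_component(p) for p in set(permutations(labels))])
        for comp in res.components:
            oracle_p = float((null >= comp["size"]).mean())
            assert comp["p"] == pytest.approx(oracle_p, abs=1e-12)

    def test_all_null_cohort_rarely_significant(self):
        rejections = 0
        for r in range(10):
            rng = np.random.default_rng(900 + r)
            labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
            y = rng.standard_normal((24, 45))
            res = nbs(y, _design(rng, labels, "A"), n_perm=200, seed=r)
            rejections += any(c["p"] < 0.05 for c in res.components)
        assert rejections <= 3

    def test_seed_determinism_and_permutation_stability(self, rng):
        labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        y = rng.standard_normal((24, 45))
        y[16:, :5] += 1.5
        design = _design(rng, labels, "A")
        r1 = nbs(y, design, n_perm=300, seed=5)
        r2 = nbs(y, design, n_perm=300, seed=5)
        assert [c["p"] for c in r1.components] == [c["p"] for c in r2.components]

    def test_no_suprathreshold_edges_reports_status(self, rng):
        labels = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        y = np.tile(np.linspace(0, 1, 18)[:, None], (1, 6))
        y += 1e-6 * rng.standard_normal(y.shape)
        design = DesignMatrix(
            outcome=pd.Series(labels),
            covariates=pd.DataFrame(index=range(18)),
            reference="A",
        )
        # group factor orthogonal to the linear trend is absorbed by noise;
        # force emptiness with an extreme threshold instead
        res = nbs(y, design, primary_p=1e-12, n_perm=100, seed=0)
        assert res.status == "no suprathreshold edges"
        assert res.components == []
        assert np.all(res.node_f_sums == 0)

    def test_rank_deficient_covariates_rejected(self, rng):
        labels = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        frame = make_design_frame(rng, labels)
        frame["dup"] = frame["age"]
        design = DesignMatrix(
            outcome=frame["group"],
            covariates=frame[["age", "dup"]],
            reference="A",
        )
        with pytest.raises(ValueError, match="rank"):
            nbs(rng.standard_normal((18, 6)), design, n_perm=100, seed=0)

    def test_small_groups_rejected(self, rng):
        labels = ["A"] * 2 + ["B"] * 8 + ["C"] * 8
        with pytest.raises(ValueError, match="3 subjects"):
            nbs(rng.standard_normal((18, 6)), _design(rng, labels, "A"),
                n_perm=100, seed=0)


class TestNodeContribution:
    def _result(self, n_nodes, comps, f):
        return NBSResult(
            f_stats=np.asarray(f, dtype=float),
            threshold_f=1.0,
            components=comps,
            node_f_sums=np.zeros(n_nodes),
            n_permutations=100,
            seed=0,
            n_nodes=n_nodes,
        )

    def test_single_edge_component(self):
        f = np.zeros(6)
        f[edge_index(2, 3, 4) - 1] = 10.0
        res = self._result(4, [{"edges": [edge_index(2, 3, 4)], "size": 1,
                                "p": 0.01, "nodes": [2, 3]}], f)
        sums = node_contribution(res)
        assert sums[1] == 10.0 and sums[2] == 10.0
        assert sums[0] == 0.0 and sums[3] == 0.0

    def test_star_additivity_and_handshake(self):
        # star at node 1 of a 4-node graph: edges (1,2),(1,3),(1,4)
        f = np.zeros(6)
        edges = [edge_index(1, k, 4) for k in (2, 3, 4)]
        for e, val in zip(edges, (2.0, 3.0, 4.0)):
            f[e - 1] = val
        res = self._result(4, [{"edges": edges, "size": 3, "p": 0.001,
                                "nodes": [1, 2, 3, 4]}], f)
        sums = node_contribution(res)
        assert sums[0] == pytest.approx(9.0)
        assert sums.sum() == pytest.approx(2 * 9.0)

    def test_non_significant_components_contribute_zero(self):
        f = np.full(6, 5.0)
        res = self._result(4, [{"edges": [1], "size": 1, "p": 0.5, "nodes": [1, 2]}], f)
        assert np.all(node_contribution(res) == 0)

    def test_average_over_metrics(self):
        f = np.zeros(6)
        f[0] = 8.0  # edge (1,2)
        comp = [{"edges": [1], "size": 1, "p": 0.01, "nodes": [1, 2]}]
        res1 = self._result(4, comp, f)
        res2 = self._result(4, [], f)
        avg = node_contribution(res1, others=[res2])
        assert avg[0] == pytest.approx(4.0)
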