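"""Network-inference stage: filtering, MI estimator, permutation test, DPI,
edge signing and regulon assembly, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonsurv import inference as inf
from regulonsurv.matrix import ExpressionMatrix
from regulonsurv.stats import bh_adjust
from regulonsurv.synthetic import generate_planted_network, simulate_expression

from .oracles import bh_bruteforce, dpi_bruteforce, mi_bruteforce


def _matrix(data: dict, condition: str = "orthograft") -> ExpressionMatrix:
    df = pd.DataFrame(data).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, pd.Series(condition, index=df.columns))


class TestExpressionFilter:
    def test_all_below_threshold_removed(self):
        m = _matrix({"g1": [0.5, 0.5], "g2": [0.5, 0.5]})
        assert inf.filter_by_min_expression(m, 1.0).n_genes == 0

    def test_max_over_samples_rule(self):
        m = _matrix({"gA": [0.2, 1.0], "gB": [0.9, 0.99]})
        out = inf.filter_by_min_expression(m, 1.0)
        assert list(out.genes) == ["gA"]

    def test_zero_threshold_keeps_everything(self):
        m = _matrix({"g1": [0.1, 0.2], "g2": [0.0, 0.0]})
        assert inf.filter_by_min_expression(m, 0.0).n_genes == 2


class TestRescale:
    def test_minmax_formula(self):
        m = _matrix({"g": [2.0, 4.0, 6.0]})
        out = inf.rescale_zero_one(m)
        np.testing.assert_allclose(out.values.loc["g"], [0.0, 0.5, 1.0])

    def test_already_unit_range_unchanged(self):
        m = _matrix({"g": [0.0, 1.0]})
        np.testing.assert_allclose(inf.rescale_zero_one(m).values.loc["g"], [0.0, 1.0])

    def test_constant_gene_dropped(self):
        m = _matrix({"g1": [3.0, 3.0, 3.0], "g2": [1.0, 2.0, 3.0]})
        out = inf.rescale_zero_one(m)
        assert list(out.genes) == ["g2"]


class TestMutualInformation:
    def test_dependent_binary_reaches_ln2(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert inf.estimate_mutual_information(x, x) == pytest.approx(np.log(2))

    def test_identity_on_distinct_values_reaches_ln_b(self):
        x = np.random.default_rng(0).permutation(16).astype(float)
        assert inf.estimate_mutual_information(x, x) == pytest.approx(np.log(4))

    def test_independent_vectors_sit_inside_permutation_null(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        obs = inf.estimate_mutual_information(x, y)
        null = [
            inf.estimate_mutual_information(rng.permutation(x), y) for _ in range(200)
        ]
        assert obs < np.quantile(null, 0.95)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            inf.estimate_mutual_information([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            inf.estimate_mutual_information([1, 2, 3], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.integers(5, 60))
    def test_symmetry_nonnegativity_and_bruteforce_equality(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        mi_xy = inf.estimate_mutual_information(x, y)
        mi_yx = inf.estimate_mutual_information(y, x)
        assert mi_xy >= 0
        assert mi_xy == pytest.approx(mi_yx, abs=1e-12)
        assert mi_xy == pytest.approx(mi_bruteforce(x, y), abs=1e-10)


class TestCandidateEdges:
    def test_null_matrix_reports_few_pairs(self):
        net = generate_planted_network(5, 10, 0, 0, seed=2, beta=0.0)
        m = simulate_expression(net, 40, sigma=1.0, seed=2, n_decoys=20)
        r = inf.rescale_zero_one(m)
        edges = inf.infer_candidate_edges(r, set(net.regulator_ids), n_perm=200, seed=3)
        n_pairs = len(net.regulator_ids) * (r.n_genes - 1)
        assert len(edges) / n_pairs <= 0.05

    def test_planted_edge_recovered_with_small_q(self):
        net = generate_planted_network(1, 5, 0, 0, seed=4, beta=1.0)
        m = simulate_expression(net, 60, sigma=0.5, seed=4, n_decoys=30)
        r = inf.rescale_zero_one(m)
        edges = inf.infer_candidate_edges(r, {"TF000"}, n_perm=1000, seed=5)
        found = set(zip(edges["regulator"], edges["target"]))
        for pair in net.edge_pairs():
            assert pair in found
        assert (edges["q"] <= 0.05).all()

    def test_no_regulators_in_matrix_yields_empty_table(self):
        m = _matrix({"g1": np.arange(6.0), "g2": np.arange(6.0)[::-1]})
        edges = inf.infer_candidate_edges(m, {"TFX"}, n_perm=100, seed=1)
        assert edges.empty


class TestDPI:
    @staticmethod
    def _edges(rows):
        return pd.DataFrame(rows, columns=["regulator", "target", "mi"])

    def test_weakest_edge_of_chain_removed(self):
        edges = self._edges([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.3)])
        out = inf.apply_dpi(edges, tolerance=0.0)
        assert set(zip(out["regulator"], out["target"])) == {("A", "B"), ("B", "C")}

    def test_no_triangles_untouched(self):
        edges = self._edges([("A", "B", 0.9), ("C", "D", 0.1)])
        pd.testing.assert_frame_equal(inf.apply_dpi(edges, 0.0), edges)

    def test_tolerance_one_disables_pruning(self):
        edges = self._edges([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.3)])
        pd.testing.assert_frame_equal(inf.apply_dpi(edges, 1.0), edges)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 1.0))
    def test_matches_exhaustive_triple_scan(self, seed, tolerance):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(8)]
        rows = []
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.5:
                    rows.append((a, b, float(rng.uniform(0.01, 1.0))))
        edges = self._edges(rows)
        out = inf.apply_dpi(edges, tolerance)
        survivors = {frozenset((r, t)) for r, t in zip(out["regulator"], out["target"])}
        assert survivors == dpi_bruteforce(rows, tolerance)


class TestSignEdges:
    def _signed(self, x, y):
        m = _matrix({"r": x, "t": y})
        edges = pd.DataFrame({"regulator": ["r"], "target": ["t"], "mi": [1.0],
                              "p": [0.001], "q": [0.01]})
        return inf.sign_edges(m, edges)

    def test_monotone_pair_positive(self):
        assert self._signed([1, 2, 3, 4], [10, 20, 30, 40])["sign"].tolist() == [1]

    def test_antimonotone_pair_negative(self):
        assert self._signed([1, 2, 3, 4], [40, 30, 20, 10])["sign"].tolist() == [-1]

    def test_hand_computed_spearman_sign(self):
        # rho = 0.6 > 0 for y = (2, 1, 4, 3)
        assert self._signed([1, 2, 3, 4], [2, 1, 4, 3])["sign"].tolist() == [1]

    def test_zero_correlation_edge_dropped(self):
        out = self._signed([1, 2, 3, 4], [1, 2, 2, 1])
        assert out.empty


class TestAssembleRegulons:
    def test_empty_edge_list(self):
        rs = inf.assemble_regulons(pd.DataFrame(columns=["regulator", "target", "sign"]))
        assert len(rs) == 0 and rs.summary()["n_regulons"] == 0

    def test_single_regulon_grouping(self):
        edges = pd.DataFrame(
            {"regulator": ["R"] * 3, "target": ["a", "b", "c"], "sign": [1, -1, 1]}
        )
        rs = inf.assemble_regulons(edges)
        assert len(rs) == 1 and rs["R"].size == 3


class TestBH:
    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 25))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_q_order_respects_p_order(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
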