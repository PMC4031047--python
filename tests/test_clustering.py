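"""Selectivity vectors, null covariance, Mahalanobis metric, clustering."""

import io

import numpy as np
import pandas as pd
import pytest

from migselect.clustering import (
    NullCovariance,
    TStatVector,
    build_tstat_vector,
    estimate_null_covariance,
    hierarchical_cluster,
    mahalanobis_distance,
    pairwise_mahalanobis,
)
from migselect.constants import CHARACTERISTICS


def effects_frame(betas_with, ses_with, betas_without, ses_without):
    rows = []
    for c, name in enumerate(CHARACTERISTICS):
        rows.append({"characteristic": name, "stratum": "with",
                     "beta": betas_with[c], "se": ses_with[c]})
        rows.append({"characteristic": name, "stratum": "without",
                     "beta": betas_without[c], "se": ses_without[c]})
    return pd.DataFrame(rows)


def vec(snp_id, t):
    return TStatVector(snp_id=snp_id, t=np.asarray(t, dtype=float))


class TestTStatVector:
    def test_direct_formula(self):
        eff = effects_frame(
            [0.3] * 10, [0.04] * 10, [0.1] * 10, [0.03] * 10
        )
        t = build_tstat_vector("rs1", eff).t
        assert t == pytest.approx(np.full(10, 4.0))  # 0.2 / 0.05

    def test_equal_betas_zero_vector(self):
        eff = effects_frame([0.2] * 10, [0.05] * 10, [0.2] * 10, [0.04] * 10)
        assert np.all(build_tstat_vector("rs1", eff).t == 0.0)

    def test_doubling_ses_halves_entries(self):
        rng = np.random.default_rng(0)
        bw, bo = rng.normal(size=10), rng.normal(size=10)
        sw, so = rng.uniform(0.02, 0.1, 10), rng.uniform(0.02, 0.1, 10)
        t1 = build_tstat_vector("rs1", effects_frame(bw, sw, bo, so)).t
        t2 = build_tstat_vector("rs1", effects_frame(bw, 2 * sw, bo, 2 * so)).t
        assert t2 == pytest.approx(t1 / 2)

    def test_missing_characteristic_rejected(self):
        eff = effects_frame([0.1] * 10, [0.05] * 10, [0.0] * 10, [0.05] * 10)
        eff = eff[eff["characteristic"] != "nausea"]
        with pytest.raises(ValueError, match="nausea"):
            build_tstat_vector("rs1", eff)


class TestNullCovariance:
    def test_iid_normal_recovers_identity(self):
        rng = np.random.default_rng(1)
        mat = rng.standard_normal((5000, 10))
        cov = estimate_null_covariance(mat)
        assert np.abs(cov.sigma - np.eye(10)).max() < 0.05

    def test_duplicated_vector_degenerate(self):
        mat = np.tile(np.arange(10.0), (40, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            cov = estimate_null_covariance(mat)
        assert np.allclose(cov.sigma, 0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((100, 10))
        a = estimate_null_covariance(mat).sigma
        b = estimate_null_covariance(mat[rng.permutation(100)]).sigma
        assert a == pytest.approx(b)

    def test_guard_on_panel_size(self):
        with pytest.raises(ValueError, match="at least 30"):
            estimate_null_covariance(np.zeros((10, 10)))


class TestMahalanobis:
    def test_zero_iff_equal(self):
        cov = NullCovariance(np.eye(10), 100)
        x = vec("a", np.arange(10))
        assert mahalanobis_distance(x, x, cov) == 0.0

    def test_identity_covariance_is_euclidean(self):
        rng = np.random.default_rng(3)
        cov = NullCovariance(np.eye(10), 100)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert mahalanobis_distance(x, y, cov) == pytest.approx(
            np.linalg.norm(x - y)
        )

    def test_diagonal_two_dim_example(self):
        d = mahalanobis_distance(
            np.array([1.0, 2.0]), np.zeros(2), np.diag([1.0, 4.0])
        )
        assert d == pytest.approx(np.sqrt(2.0))

    def test_symmetry_random(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(10, 10))
        cov = NullCovariance(A @ A.T + 0.5 * np.eye(10), 100)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            assert mahalanobis_distance(x, y, cov) == pytest.approx(
                mahalanobis_distance(y, x, cov)
            )

    def test_whitening_equivalence(self):
        """Distance under Sigma equals Euclidean distance after whitening
        by the inverse Cholesky factor."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(10, 10))
        sigma = A @ A.T + 0.5 * np.eye(10)
        L = np.linalg.cholesky(sigma)
        cov = NullCovariance(sigma, 100)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            white = np.linalg.solve(L, x - y)
            assert mahalanobis_distance(x, y, cov) == pytest.approx(
                np.linalg.norm(white)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_distance(np.zeros(3), np.zeros(3), np.eye(4))


class TestHierarchicalCluster:
    def test_identical_pairs_merge_at_zero(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=10)
        b = a + 20.0
        vecs = [vec("a1", a), vec("a2", a), vec("b1", b), vec("b2", b)]
        cov = NullCovariance(np.eye(10), 100)
        dist = pairwise_mahalanobis(vecs, cov)
        res = hierarchical_cluster(dist)
        assert np.allclose(res.linkage[:2, 2], 0.0)

    def test_three_point_complete_linkage(self):
        dist = pd.DataFrame(
            [[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        res = hierarchical_cluster(dist, method="complete")
        # A,B merge first at height 1; final merge at the max distance 10
        assert res.linkage[0, 2] == pytest.approx(1.0)
        assert res.linkage[1, 2] == pytest.approx(10.0)
        assert res.leaf_order.index("C") in (0, 2)

    def test_single_snp_tree(self):
        dist = pd.DataFrame([[0.0]], index=["only"], columns=["only"])
        res = hierarchical_cluster(dist)
        assert res.leaf_order == ["only"]
        assert res.newick == "only;"

    def test_leaf_order_scale_invariant(self):
        rng = np.random.default_rng(7)
        mat = np.abs(rng.normal(size=(6, 6)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = list("ABCDEF")
        d1 = pd.DataFrame(mat, index=labels, columns=labels)
        d2 = pd.DataFrame(5.0 * mat, index=labels, columns=labels)
        assert hierarchical_cluster(d1).leaf_order == (
            hierarchical_cluster(d2).leaf_order
        )

    def test_nan_rejected(self):
        dist = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 0.0]], index=list("AB"), columns=list("AB")
        )
        with pytest.raises(ValueError, match="non-finite"):
            hierarchical_cluster(dist)

    def test_newick_parses_with_all_leaves(self):
        import dendropy

        rng = np.random.default_rng(8)
        mat = np.abs(rng.normal(size=(5, 5)))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = [f"rs{i}" for i in range(5)]
        res = hierarchical_cluster(pd.DataFrame(mat, index=labels, columns=labels))
        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(labels)
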