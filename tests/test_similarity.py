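import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncdis.core import BinaryProfileMatrix, DiseaseDAG, EntityIndex, ValidationError
from lncdis.similarity import (
    SimilarityNetworkSet,
    bicor_network,
    biweight_midcorrelation,
    build_similarity_sets,
    gip_bandwidth,
    gip_kernel,
    semantic_similarity,
)


def bicor_reference(x, y, c=9.0):
    """Straight-from-formula biweight midcorrelation (independent oracle)."""

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestBicor:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=20)
        assert biweight_midcorrelation(x, x) == pytest.approx(1.0)
        assert biweight_midcorrelation(x, -x) == pytest.approx(-1.0)

    def test_matches_reference_and_beats_pearson_on_outlier(self):
        x = [1, 2, 3, 4, 100]
        y = [1, 2, 3, 4, 5]
        got = biweight_midcorrelation(x, y)
        assert got == pytest.approx(bicor_reference(x, y), abs=1e-12)
        pearson = np.corrcoef(x, y)[0, 1]
        assert got > pearson  # robust to the single outlier

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=12),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance_and_range(self, xs, a, b):
        # round to avoid float-pathological scales (a MAD of ~1e-75 is not
        # representable once shifted by an O(1) offset)
        x = np.round(np.asarray(xs), 3)
        if np.ptp(x) == 0:
            return
        y = np.sin(np.arange(len(x)))  # fixed non-constant partner
        r = biweight_midcorrelation(x, y)
        assert -1.0 <= r <= 1.0
        assert biweight_midcorrelation(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert biweight_midcorrelation(-a * x + b, y) == pytest.approx(-r, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            biweight_midcorrelation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_mad_zero_falls_back_to_pearson(self):
        # median absolute deviation is 0 but the vector is not constant
        x = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 9.0, 1.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        assert np.median(np.abs(x - np.median(x))) == 0
        got = biweight_midcorrelation(x, y)
        expected = np.corrcoef(x, y)[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)


class TestBicorNetwork:
    def test_identical_rows_fully_correlated(self):
        rows = EntityIndex("lncRNA", ["a", "b"])
        cols = EntityIndex("sample", ["s0", "s1", "s2", "s3"])
        from lncdis.core import LabeledMatrix

        expr = LabeledMatrix(rows, cols, np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]]))
        S = bicor_network(expr)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_independent_rows_nearly_uncorrelated(self, rng):
        from lncdis.core import LabeledMatrix

        rows = EntityIndex("lncRNA", ["a", "b"])
        cols = EntityIndex("sample", [f"s{i}" for i in range(1000)])
        expr = LabeledMatrix(rows, cols, rng.normal(size=(2, 1000)))
        S = bicor_network(expr)
        assert abs(S.values[0, 1]) < 0.1

    def test_matches_pairwise_oracle(self, rng):
        from lncdis.core import LabeledMatrix

        rows = EntityIndex("lncRNA", [f"l{i}" for i in range(4)])
        cols = EntityIndex("sample", [f"s{i}" for i in range(6)])
        X = rng.normal(size=(4, 6))
        S = bicor_network(LabeledMatrix(rows, cols, X)).values
        for i in range(4):
            for j in range(4):
                expected = 1.0 if i == j else bicor_reference(X[i], X[j])
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self, rng):
        from lncdis.core import LabeledMatrix

        rows = EntityIndex("lncRNA", ["a", "b"])
        cols = EntityIndex("sample", ["s0", "s1"])
        with pytest.raises(ValidationError):
            bicor_network(LabeledMatrix(rows, cols, rng.normal(size=(2, 2))))


def _profiles(values, kind="lncRNA", colkind="miRNA"):
    r, c = np.asarray(values).shape
    return BinaryProfileMatrix(
        EntityIndex(kind, [f"r{i}" for i in range(r)]),
        EntityIndex(colkind, [f"c{i}" for i in range(c)]),
        np.asarray(values, dtype=float),
    )


class TestGip:
    def test_bandwidth_arithmetic(self):
        bw = gip_bandwidth(_profiles(np.eye(3)), 0.5)
        assert bw.mean_sq_norm == pytest.approx(1.0)
        assert bw.alpha == pytest.approx(0.5)
        # row squared norms {1, 2, 3} -> mean 2
        p = _profiles([[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        assert gip_bandwidth(p, 0.5).alpha == pytest.approx(0.25)
        assert gip_bandwidth(p, 1.0).alpha == pytest.approx(0.5)  # linear in alpha'

    def test_multiply_convention_matches_printed_form(self):
        p = _profiles([[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        assert gip_bandwidth(p, 0.5, convention="multiply").alpha == pytest.approx(1.0)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValidationError, match="kernel undefined"):
            gip_bandwidth(_profiles(np.zeros((2, 3))))

    def test_closed_form_entry(self):
        p = _profiles([[1, 0, 0], [0, 1, 0]])
        bw = gip_bandwidth(p, 0.5)
        assert bw.alpha == pytest.approx(0.5)
        S = gip_kernel(p, bw)
        assert S.values[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-12)
        assert np.all(np.diag(S.values) == 1.0)

    def test_matches_entrywise_loop_oracle(self, rng):
        P = (rng.random((5, 8)) < 0.4).astype(float)
        P[P.sum(axis=1) == 0, 0] = 1  # no empty profiles
        prof = _profiles(P)
        bw = gip_bandwidth(prof, 0.5)
        S = gip_kernel(prof, bw).values
        for i in range(5):
            for j in range(5):
                expected = math.exp(-bw.alpha * np.sum((P[i] - P[j]) ** 2))
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        P = (rng.random((6, 5)) < 0.5).astype(float)
        P[P.sum(axis=1) == 0, 0] = 1
        perm = rng.permutation(6)
        prof = _profiles(P)
        S = gip_kernel(prof, gip_bandwidth(prof, 0.5)).values
        prof_p = _profiles(P[perm])
        S_p = gip_kernel(prof_p, gip_bandwidth(prof_p, 0.5)).values
        np.testing.assert_allclose(S_p, S[np.ix_(perm, perm)], atol=1e-12)

    def test_kernel_invariants(self, rng):
        P = (rng.random((7, 9)) < 0.3).astype(float)
        P[P.sum(axis=1) == 0, 0] = 1
        prof = _profiles(P)
        S = gip_kernel(prof, gip_bandwidth(prof, 0.5)).values
        assert np.allclose(S, S.T)
        assert np.all(S > 0) and np.all(S <= 1)
        assert np.all(np.diag(S) == 1.0)


def _dag(edges):
    import networkx as nx

    g = nx.DiGraph()
    for child, parent in edges:
        g.add_edge(child, parent, relation="is_a")
    return DiseaseDAG(g)


class TestWangSimilarity:
    def test_self_similarity_one(self):
        dag = _dag([("d0", "root"), ("d1", "root")])
        idx = EntityIndex("disease", ["d0", "d1"])
        S = semantic_similarity(dag, idx)
        assert np.all(np.diag(S.values) == 1.0)

    def test_hand_computed_three_node_dag(self):
        # two depth-1 siblings share only the root: (0.5+0.5)/(1.5+1.5) = 1/3
        dag = _dag([("d0", "root"), ("d1", "root")])
        idx = EntityIndex("disease", ["d0", "d1"])
        S = semantic_similarity(dag, idx)
        assert S.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_forest_zero_cross_similarity(self):
        dag = _dag([("d0", "rootA"), ("d1", "rootB")])
        S = semantic_similarity(dag, EntityIndex("disease", ["d0", "d1"]))
        assert S.values[0, 1] == 0.0

    def test_missing_disease_listed(self):
        dag = _dag([("d0", "root")])
        with pytest.raises(ValidationError, match="dX"):
            semantic_similarity(dag, EntityIndex("disease", ["d0", "dX"]))

    def test_deeper_shared_ancestry_scores_higher(self):
        # siblings under a shared mid node are closer than cousins
        dag = _dag(
            [("d0", "mid"), ("d1", "mid"), ("mid", "root"), ("d2", "root")]
        )
        idx = EntityIndex("disease", ["d0", "d1", "d2"])
        S = semantic_similarity(dag, idx).values
        assert S[0, 1] > S[0, 2]
        assert np.all(S >= 0) and np.all(S <= 1)


class TestBuildSets:
    def test_full_bundle_membership(self, tiny_bundle):
        lnc, dis = build_similarity_sets(
            expression=tiny_bundle.expression,
            lnc_mirna=tiny_bundle.lnc_mirna,
            lnc_protein=tiny_bundle.lnc_protein,
            dis_mirna=tiny_bundle.dis_mirna,
            dag=tiny_bundle.dag,
            lnc_index=tiny_bundle.lnc_index,
            dis_index=tiny_bundle.dis_index,
        )
        assert set(lnc.members) == {"LncSm1", "LncSm2", "LncSm3"}
        assert set(dis.members) == {"DisSm1", "DisSm2"}

    def test_omitted_expression_skips_member(self, tiny_bundle):
        lnc, _ = build_similarity_sets(
            expression=None,
            lnc_mirna=tiny_bundle.lnc_mirna,
            lnc_protein=tiny_bundle.lnc_protein,
            dis_mirna=tiny_bundle.dis_mirna,
            dag=tiny_bundle.dag,
            lnc_index=tiny_bundle.lnc_index,
            dis_index=tiny_bundle.dis_index,
        )
        assert set(lnc.members) == {"LncSm2", "LncSm3"}

    def test_all_members_satisfy_invariants(self, tiny_bundle):
        lnc, dis = build_similarity_sets(
            expression=tiny_bundle.expression,
            lnc_mirna=tiny_bundle.lnc_mirna,
            lnc_protein=tiny_bundle.lnc_protein,
            dis_mirna=tiny_bundle.dis_mirna,
            dag=tiny_bundle.dag,
            lnc_index=tiny_bundle.lnc_index,
            dis_index=tiny_bundle.dis_index,
        )
        for s in {**lnc.members, **dis.members}.values():
            assert np.allclose(s.values, s.values.T, atol=1e-10)
            lo, hi = s.value_range
            assert s.values.min() >= lo - 1e-12 and s.values.max() <= hi + 1e-12

    def test_no_source_rejected(self):
        with pytest.raises(ValidationError):
            build_similarity_sets()
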