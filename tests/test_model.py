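import numpy as np
import pytest

from lncdis import AssociationModel, RunConfig
from lncdis.core import ValidationError
from lncdis.embedding import build_normalized_relations, forward_embeddings
from lncdis.model import (
    build_training_mask,
    gradient_step,
    loss,
    loss_gradients,
)


def loss_reference(params, network, rel, mask):
    """Independent nested-loop evaluation of the five-term objective."""
    cache = forward_embeddings(params, rel)
    Lp, Dp, Gp = cache["Lp"], cache["Dp"], cache["Gp"]
    A = network.A.values
    total = 0.0
    C = params["E_ld1"] @ params["E_ld2"].T
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if mask[i, j]:
                total += (A[i, j] - Lp[i] @ C @ Dp[j]) ** 2
    B = params["E_ll"] @ params["E_ll"].T
    LTS = network.LTS.values
    for i in range(LTS.shape[0]):
        for j in range(LTS.shape[1]):
            total += (LTS[i, j] - Lp[i] @ B @ Lp[j]) ** 2
    B = params["E_dd"] @ params["E_dd"].T
    DTS = network.DTS.values
    for i in range(DTS.shape[0]):
        for j in range(DTS.shape[1]):
            total += (DTS[i, j] - Dp[i] @ B @ Dp[j]) ** 2
    C = params["E_lg1"] @ params["E_lg2"].T
    Alg = network.A_lg.values
    for i in range(Alg.shape[0]):
        for j in range(Alg.shape[1]):
            total += (Alg[i, j] - Lp[i] @ C @ Gp[j]) ** 2
    C = params["E_gd1"] @ params["E_gd2"].T
    Agd = network.A_gd.values
    for i in range(Agd.shape[0]):
        for j in range(Agd.shape[1]):
            total += (Agd[i, j] - Gp[i] @ C @ Dp[j]) ** 2
    return total


@pytest.fixture()
def tiny_model(tiny_network, tiny_config):
    return AssociationModel(tiny_network, tiny_config)


class TestLoss:
    def test_matches_nested_loop_oracle(self, tiny_model, rng):
        params = tiny_model.init_params(rng)
        mask = rng.random(tiny_model.network.A.shape) < 0.5
        got = loss(params, tiny_model.network, tiny_model.rel, mask)
        expected = loss_reference(params, tiny_model.network, tiny_model.rel, mask)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_nonnegative(self, tiny_model, rng):
        for _ in range(3):
            params = tiny_model.init_params(rng)
            assert loss(params, tiny_model.network, tiny_model.rel) >= 0.0

    def test_perfect_reconstruction_gives_zero(self, tiny_bundle, rng):
        """Contrived targets equal to the model's own reconstruction (zeroed
        cross-relation decoders + similarity targets computed from the
        parameters) make the loss exactly zero."""
        from lncdis.core import (
            AssociationMatrix,
            EntityIndex,
            HeteroNetwork,
            SimilarityMatrix,
        )
        from lncdis.embedding import init_embedding_params
        from lncdis.model import init_mapping_params

        m, n, k = 5, 4, 3
        d, d_low = 4, 2
        params = init_embedding_params(m, n, k, d, d_low, rng)
        params.update(init_mapping_params(d_low, d_low, rng, True))
        # zero aggregation so embeddings do not depend on the network
        for key in list(params):
            if key.startswith(("W_", "b_")) and key not in ("W0", "b0"):
                params[key] = np.zeros_like(params[key])
        for key in ("E_ld1", "E_lg1", "E_gd1"):
            params[key] = np.zeros_like(params[key])

        li = EntityIndex("lncRNA", [f"l{i}" for i in range(m)])
        di = EntityIndex("disease", [f"d{i}" for i in range(n)])
        gi = EntityIndex("gene", [f"g{i}" for i in range(k)])
        zeroA = AssociationMatrix(li, di, np.zeros((m, n)))
        zeroLg = AssociationMatrix(li, gi, np.zeros((m, k)))
        zeroGd = AssociationMatrix(gi, di, np.zeros((k, n)))
        probe = HeteroNetwork(
            A=zeroA,
            LTS=SimilarityMatrix(li, np.eye(m)),
            DTS=SimilarityMatrix(di, np.eye(n)),
            A_lg=zeroLg,
            A_gd=zeroGd,
        )
        rel = build_normalized_relations(probe, "none")
        cache = forward_embeddings(params, rel)
        Lp, Dp = cache["Lp"], cache["Dp"]
        LTS = Lp @ params["E_ll"] @ params["E_ll"].T @ Lp.T
        DTS = Dp @ params["E_dd"] @ params["E_dd"].T @ Dp.T
        target = HeteroNetwork(
            A=zeroA,
            LTS=SimilarityMatrix(li, LTS, value_range=(-10, 10)),
            DTS=SimilarityMatrix(di, DTS, value_range=(-10, 10)),
            A_lg=zeroLg,
            A_gd=zeroGd,
        )
        total = loss(params, target, build_normalized_relations(target, "none"))
        assert total == pytest.approx(0.0, abs=1e-18)


class TestGradients:
    def test_matches_central_finite_differences(self, tiny_model, rng):
        params = tiny_model.init_params(rng)
        mask = np.ones(tiny_model.network.A.shape, bool)
        _, grads = loss_gradients(params, tiny_model.network, tiny_model.rel, mask)
        h = 1e-6
        for key, arr in params.items():
            g = grads[key]
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[ix]
                arr[ix] = orig + h
                lp = loss(params, tiny_model.network, tiny_model.rel, mask)
                arr[ix] = orig - h
                lm = loss(params, tiny_model.network, tiny_model.rel, mask)
                arr[ix] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - g[ix]) <= 1e-5 * max(abs(fd), abs(g[ix]), 1.0), key

    def test_zero_learning_rate_leaves_params(self, tiny_model, rng):
        params = tiny_model.init_params(rng)
        new, _ = gradient_step(params, tiny_model.network, 0.0, tiny_model.rel)
        for key in params:
            np.testing.assert_array_equal(new[key], params[key])

    def test_symmetric_decoder_blocks_symmetric(self, tiny_model, rng):
        params = tiny_model.init_params(rng)
        rel = tiny_model.rel
        cache = forward_embeddings(params, rel)
        R = cache["Lp"] @ params["E_ll"] @ params["E_ll"].T @ cache["Lp"].T
        np.testing.assert_allclose(R, R.T, atol=1e-12)


class TestTraining:
    def test_same_seed_identical_trace(self, tiny_model):
        r1 = tiny_model.fit(seed=5)
        r2 = tiny_model.fit(seed=5)
        assert r1.trace.total == r2.trace.total
        np.testing.assert_array_equal(r1.scores(), r2.scores())

    def test_loss_monotone_with_backtracking(self, tiny_model):
        res = tiny_model.fit(seed=5, max_iterations=100)
        diffs = np.diff(res.trace.total)
        assert np.all(diffs <= 1e-12)

    def test_final_below_initial(self, tiny_model):
        res = tiny_model.fit(seed=5)
        assert res.final_loss < res.trace.total[0]

    def test_divergence_guard(self, tiny_network):
        cfg = RunConfig(
            embed_dim=6, embed_dim_low=3, learning_rate=50.0,
            backtracking=False, max_iterations=2000, random_seed=0,
        )
        with pytest.raises(ValidationError, match="diverged|non-finite"):
            AssociationModel(tiny_network, cfg).fit()


class TestScores:
    def test_matches_loop_oracle(self, tiny_model, rng):
        res = tiny_model.fit(seed=5, max_iterations=20)
        S = res.scores()
        Lp, Dp = res.embeddings.lnc_embedding, res.embeddings.dis_embedding
        C = res.params["E_ld1"] @ res.params["E_ld2"].T
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                assert S[i, j] == pytest.approx(Lp[i] @ C @ Dp[j], abs=1e-10)

    def test_rank_bounded_by_decoder(self, tiny_model):
        res = tiny_model.fit(seed=5, max_iterations=20)
        q = tiny_model.config.q
        rank = np.linalg.matrix_rank(res.scores())
        assert rank <= min(tiny_model.config.embed_dim_low, q)


class TestTopK:
    def test_full_k_is_permutation(self, tiny_model):
        res = tiny_model.fit(seed=5, max_iterations=20)
        net = tiny_model.network
        d0 = net.dis_index.names[0]
        out = res.top_k(d0, k=len(net.lnc_index), exclude_known=False)
        assert sorted(out["lncRNA"]) == sorted(net.lnc_index.names)

    def test_order_and_tie_break(self, tiny_model):
        res = tiny_model.fit(seed=5, max_iterations=20)
        S = res.scores()
        S[:, 0] = [3.0, 1.0, 1.0, 2.0, 0.5, 0.4, 0.3, 0.2]
        res._scores = S
        out = res.top_k(0, k=4, exclude_known=False)
        names = list(tiny_model.network.lnc_index.names)
        assert list(out["lncRNA"])[:2] == [names[0], names[3]]
        # scores tie between index 1 and 2 -> lexicographically smaller first
        assert list(out["lncRNA"])[2:] == sorted([names[1], names[2]])

    def test_known_excluded(self, tiny_model):
        res = tiny_model.fit(seed=5, max_iterations=20)
        net = tiny_model.network
        j = 0
        known = {net.lnc_index.names[i] for i in np.nonzero(net.A.values[:, j])[0]}
        out = res.top_k(j, k=len(net.lnc_index))
        assert known.isdisjoint(set(out["lncRNA"]))


class TestTrainingMask:
    def test_balanced_sampling(self, tiny_network, rng):
        A = tiny_network.A.values
        mask = build_training_mask(A, 1.0, rng)
        n_pos = int(A.sum())
        assert mask.sum() == 2 * n_pos
        assert np.all(mask[A == 1])

    def test_forbidden_entries_never_sampled(self, tiny_network, rng):
        A = tiny_network.A.values
        forbidden = np.zeros_like(A, dtype=bool)
        forbidden[0, :] = True
        for _ in range(5):
            mask = build_training_mask(A, 1.0, rng, forbidden)
            assert not mask[0, :].any()


def test_summary_mentions_fit_facts(tiny_model):
    res = tiny_model.fit(seed=5, max_iterations=20)
    text = res.summary()
    assert "final loss" in text and "seed: 5" in text
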