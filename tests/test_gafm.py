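"""GAFM model: embeddings, interactions, attention, forward, loss.

The vectorized batch path is checked against an independent
brute-force recomputation that enumerates pairs with explicit loops.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haibrid import (
    GAFMParameters,
    apply_gate,
    attention_scores,
    average_attention,
    bce_loss,
    embed,
    encode,
    forward,
    forward_batch,
    init_parameters,
    load_checkpoint,
    pairwise_interactions,
    save_checkpoint,
)
from haibrid.gafm import InteractionImportance, _batch_backward, _batch_forward


def brute_force_forward(x, params):
    """Independent oracle: explicit loops over active positions/pairs."""
    active = [i for i in range(len(x)) if x[i] != 0]
    logit = params.bias if params.use_bias else 0.0
    logit += sum(params.W[i] * x[i] for i in range(len(x)))
    pairs = [
        (i, j)
        for ai, i in enumerate(active)
        for j in active[ai + 1:]
        if params.gamma is None or (i, j) in params.gamma
    ]
    if pairs:
        raws = []
        for i, j in pairs:
            t = (params.V[i] * x[i]) * (params.V[j] * x[j])
            h = np.maximum(params.attn_W.T @ t + params.attn_b, 0.0)
            raws.append(float(params.attn_p @ h))
        raws = np.array(raws)
        a = np.exp(raws - raws.max())
        a /= a.sum()
        for w, (i, j) in zip(a, pairs):
            logit += w * float((params.V[i] * x[i]) @ (params.V[j] * x[j]))
    return logit


def random_params(width, k, hidden, seed, gamma=None):
    rng = np.random.default_rng(seed)
    return GAFMParameters(
        W=rng.normal(0, 1, width),
        bias=float(rng.normal()),
        V=rng.normal(0, 1, (width, k)),
        attn_W=rng.normal(0, 1, (k, hidden)),
        attn_b=rng.normal(0, 1, hidden),
        attn_p=rng.normal(0, 1, hidden),
        gamma=gamma,
    )


class TestEmbedAndInteractions:
    def test_all_zero_sample_has_no_embeddings(self):
        p = random_params(4, 2, 3, 0)
        assert embed(np.zeros(4), p) == []

    def test_binary_sample_selects_embedding_rows(self):
        p = random_params(4, 2, 3, 0)
        emb = embed(np.array([0, 1, 0, 1.0]), p)
        assert [i for i, _ in emb] == [1, 3]
        np.testing.assert_array_equal(emb[0][1], p.V[1])
        np.testing.assert_array_equal(emb[1][1], p.V[3])

    def test_real_valued_slot_scales_embedding(self):
        p = random_params(2, 2, 3, 0)
        p.V[1] = np.array([2.0, -1.0])
        emb = embed(np.array([0, 0.9]), p)
        np.testing.assert_allclose(emb[0][1], [1.8, -0.9])

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 0), (3, 3), (5, 10)])
    def test_pair_count_is_n_choose_2(self, n, expected):
        embs = [(i, np.ones(2)) for i in range(n)]
        assert len(pairwise_interactions(embs)) == expected

    def test_interaction_is_elementwise_product(self):
        embs = [(0, np.array([1.0, 2.0])), (1, np.array([3.0, 4.0]))]
        (pair, t), = pairwise_interactions(embs)
        assert pair == (0, 1)
        np.testing.assert_array_equal(t, [3.0, 8.0])


class TestAttention:
    def test_singleton_softmax_is_one(self):
        p = random_params(4, 2, 3, 1)
        out = attention_scores([((0, 1), np.ones(2))], p)
        assert out.normalized.tolist() == [1.0]

    def test_identical_interactions_share_attention(self):
        p = random_params(4, 2, 3, 1)
        t = np.array([0.3, -0.7])
        out = attention_scores([((0, 1), t), ((0, 2), t)], p)
        np.testing.assert_allclose(out.normalized, [0.5, 0.5])

    def test_hand_computed_tiny_network(self):
        """k=1, hidden 1, all weights 1, biases 0, interactions {2, 6}:
        softmax(relu(2), relu(6)) = (e^2, e^6) / (e^2 + e^6)."""
        p = GAFMParameters(
            W=np.zeros(4), bias=0.0, V=np.ones((4, 1)),
            attn_W=np.ones((1, 1)), attn_b=np.zeros(1), attn_p=np.ones(1),
        )
        out = attention_scores(
            [((0, 1), np.array([2.0])), ((0, 2), np.array([6.0]))], p
        )
        expected = np.exp([2.0, 6.0]) / np.exp([2.0, 6.0]).sum()
        np.testing.assert_allclose(out.normalized, expected)
        np.testing.assert_allclose(out.normalized, [0.0180, 0.9820],
                                   atol=5e-5)


class TestForward:
    def test_empty_sample_gives_bias_logit(self):
        p = random_params(4, 2, 3, 2)
        p.bias = 0.0
        logit, prob = forward(np.zeros(4), p)
        assert logit == 0.0 and prob == 0.5

    def test_hand_computed_logit(self):
        """W.X = 0.3 plus a single retained pair with <e1,e2> = 0.6
        (singleton softmax, attention 1) gives logit 0.9."""
        p = GAFMParameters(
            W=np.array([0.1, 0.2, 0.0]), bias=0.0,
            V=np.array([[0.6], [1.0], [0.0]]),
            attn_W=np.ones((1, 2)), attn_b=np.zeros(2), attn_p=np.ones(2),
        )
        x = np.array([1.0, 1.0, 0.0])
        logit, prob = forward(x, p)
        assert logit == pytest.approx(0.9)
        assert prob == pytest.approx(1 / (1 + math.exp(-0.9)))

    def test_empty_gate_reduces_to_logistic(self):
        p = random_params(6, 3, 4, 3, gamma=frozenset())
        x = np.array([1, 0, 1, 1, 0, 1.0])
        logit, _ = forward(x, p)
        assert logit == pytest.approx(p.bias + float(p.W @ x))

    def test_zero_embeddings_reduce_to_logistic(self):
        p = random_params(6, 3, 4, 4)
        p.V[:] = 0.0
        x = np.array([1, 1, 0, 1, 0, 0.0])
        logit, _ = forward(x, p)
        assert logit == pytest.approx(p.bias + float(p.W @ x))

    def test_width_mismatch_raises(self):
        p = random_params(4, 2, 3, 0)
        with pytest.raises(ValueError):
            forward(np.zeros(5), p)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_forward_matches_brute_force(self, seed):
        """Oracle equivalence on random samples and parameters."""
        rng = np.random.default_rng(seed)
        width = int(rng.integers(4, 10))
        k = int(rng.integers(1, 4))
        p = random_params(width, k, int(rng.integers(1, 5)), seed)
        if rng.random() < 0.3:
            all_pairs = [(i, j) for i in range(width)
                         for j in range(i + 1, width)]
            keep = rng.random(len(all_pairs)) < 0.5
            p.gamma = frozenset(
                pr for pr, m in zip(all_pairs, keep) if m
            )
        x = (rng.random(width) < 0.5).astype(float)
        x[rng.integers(0, width)] *= rng.random()  # a real-valued slot
        logit, _ = forward(x, p)
        assert abs(logit - brute_force_forward(x, p)) < 1e-8


class TestBatchPath:
    def test_batch_matches_per_sample_forward(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 3, 4, seed=5, scale=0.5)
        logits, probs = forward_batch(ds, p)
        for i in range(0, ds.n_samples, 37):
            li, pi = forward(ds.X[i], p)
            assert logits[i] == pytest.approx(li, abs=1e-10)

    def test_batch_matches_per_sample_with_gate(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 4, seed=6, scale=0.5)
        imp = average_attention(ds, p)
        p.gamma = apply_gate(imp, np.median(list(imp.mean.values())))
        logits, _ = forward_batch(ds, p)
        for i in range(0, ds.n_samples, 53):
            li, _ = forward(ds.X[i], p)
            assert logits[i] == pytest.approx(li, abs=1e-10)

    def test_per_sample_attention_sums_to_one(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 3, 4, seed=7, scale=0.3)
        cache = _batch_forward(ds, p)
        sums = cache.attn.sum(axis=1)
        has_pairs = cache.pair_mask.any(axis=1)
        np.testing.assert_allclose(sums[has_pairs], 1.0, atol=1e-12)

    def test_record_order_does_not_change_outputs(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 3, seed=8, scale=0.3)
        logits, _ = forward_batch(ds, p)
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        logits_p, _ = forward_batch(ds.subset(perm), p)
        np.testing.assert_allclose(logits_p, logits[perm], atol=1e-12)

    def test_gradients_match_finite_differences(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 3, seed=9, scale=0.2)
        y = ds.y.astype(float)
        idx = np.arange(48)
        cache = _batch_forward(ds, p, idx)
        grads = _batch_backward(ds, p, cache, y[idx], idx)

        def loss():
            return bce_loss(forward_batch(ds, p, idx)[1], y[idx])

        rng = np.random.default_rng(1)
        eps = 1e-6
        for key in ("W", "V", "attn_W", "attn_b", "attn_p"):
            arr = getattr(p, key)
            coords = [tuple(c) for c in np.ndindex(arr.shape)]
            for ci in rng.choice(len(coords), size=min(5, len(coords)),
                                 replace=False):
                c = coords[ci]
                old = arr[c]
                arr[c] = old + eps
                up = loss()
                arr[c] = old - eps
                down = loss()
                arr[c] = old
                num = (up - down) / (2 * eps)
                # central differences can straddle a ReLU kink, so the
                # tolerance is looser than the analytic precision
                assert np.asarray(grads[key])[c] == pytest.approx(
                    num, abs=5e-6
                ), key


class TestAverageAttentionAndGate:
    def test_mean_of_single_sample_equals_sample_attention(self):
        rng = np.random.default_rng(0)
        import pandas as pd
        from haibrid import build_dictionary
        d = build_dictionary({
            "features": [
                {"name": "a", "levels": ["x", "y"]},
                {"name": "b", "levels": ["u", "v"]},
            ],
            "cadx": {"name": "c", "mode": "binary"},
        })
        ds = encode(pd.DataFrame(
            {"a": ["x"], "b": ["v"], "cadx_score": [0.9], "label": [1]}
        ), d)
        p = init_parameters(d.total_width, 2, 3, seed=3, scale=0.5)
        imp = average_attention(ds, p)
        out = attention_scores(
            pairwise_interactions(embed(ds.X[0], p)), p
        )
        for pair, a in zip(out.pairs, out.normalized):
            assert imp.mean[pair] == pytest.approx(float(a))

    def test_mean_is_arithmetic_over_coactive_samples(self):
        imp = InteractionImportance(
            mean={(1, 2): 0.3}, count={(1, 2): 2}, n_samples=2
        )
        assert imp.mean[(1, 2)] == pytest.approx((0.2 + 0.4) / 2)

    def test_total_divisor_scales_by_n(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 3, seed=4)
        co = average_attention(ds, p, divisor="coactive")
        tot = average_attention(ds, p, divisor="total")
        for pair in tot.mean:
            expected = co.mean[pair] * co.count[pair] / ds.n_samples
            assert tot.mean[pair] == pytest.approx(expected)

    def test_never_coactive_pairs_absent(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 3, seed=4)
        imp = average_attention(ds, p)
        assert all(c > 0 for c in imp.count.values())

    @pytest.mark.parametrize("eps,expected", [
        (0.1, {(1, 2)}),
        (-math.inf, {(1, 2), (1, 3)}),
        (0.9, set()),
    ])
    def test_gate_thresholding(self, eps, expected):
        imp = InteractionImportance(
            mean={(1, 2): 0.5, (1, 3): 0.05},
            count={(1, 2): 3, (1, 3): 2},
            n_samples=5,
        )
        assert apply_gate(imp, eps) == frozenset(expected)

    def test_gate_monotone_in_epsilon(self, small_cohort):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 3, seed=5, scale=0.4)
        imp = average_attention(ds, p)
        values = sorted(imp.mean.values())
        previous = None
        for eps in (-math.inf, values[len(values) // 4],
                    values[len(values) // 2], values[-1]):
            gamma = apply_gate(imp, eps)
            if previous is not None:
                assert gamma <= previous
            previous = gamma


class TestLoss:
    @pytest.mark.parametrize("p,y,expected", [
        (0.5, 0, math.log(2)),
        (0.5, 1, math.log(2)),
        (0.9, 0, -math.log(0.1)),
    ])
    def test_closed_form_values(self, p, y, expected):
        assert bce_loss(p, y) == pytest.approx(expected, rel=1e-9)

    def test_perfect_prediction_clips_to_near_zero(self):
        assert bce_loss(1.0, 1) < 1e-10
        assert bce_loss(0.0, 0) < 1e-10


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path):
        p = random_params(7, 3, 4, 11, gamma=frozenset({(0, 3), (2, 5)}))
        path = tmp_path / "model.json"
        save_checkpoint(p, path)
        q = load_checkpoint(path)
        assert (q.W == p.W).all() and (q.V == p.V).all()
        assert (q.attn_W == p.attn_W).all()
        assert (q.attn_b == p.attn_b).all()
        assert (q.attn_p == p.attn_p).all()
        assert q.bias == p.bias and q.gamma == p.gamma
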