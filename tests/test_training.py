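"""Two-step training, ranking/selection, and the baseline models."""

import math

import numpy as np
import pandas as pd
import pytest

from haibrid import (
    TrainingConfig,
    build_dictionary,
    encode,
    fit_baselines,
    forward_batch,
    init_parameters,
    max_combination,
    rank_and_select,
    train_step1,
    train_step2,
    two_step_train,
)
from haibrid.gafm import InteractionImportance, average_attention
from haibrid.training import SingleClassError, resolve_epsilon
from dataclasses import replace as dc_replace


def separable_dataset():
    """20 samples, 2 binary features, linearly separable labels."""
    d = build_dictionary({
        "features": [
            {"name": "a", "levels": ["lo", "hi"]},
            {"name": "b", "levels": ["lo", "hi"]},
        ],
        "cadx": {"name": "c", "mode": "binary"},
    })
    rows = []
    for i in range(20):
        hi = i % 2 == 1
        rows.append({
            "a": "hi" if hi else "lo",
            "b": "hi" if hi else "lo",
            "cadx_score": 0.8 if hi else 0.2,
            "label": int(hi),
        })
    return encode(pd.DataFrame(rows), d)


class TestTrainStep1:
    def test_separable_toy_reaches_low_loss(self):
        ds = separable_dataset()
        cfg = TrainingConfig(
            embedding_dim=2, attention_hidden=2, max_epochs=300,
            batch_size=20, learning_rate=0.05, seed=0, restarts=1,
        )
        _, history = train_step1(ds, cfg)
        assert history[-1] < 0.1

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds = separable_dataset()
        cfg = TrainingConfig(
            embedding_dim=2, attention_hidden=2, max_epochs=3,
            learning_rate=0.0, seed=0,
        )
        init = init_parameters(ds.width, 2, 2, seed=1)
        trained, _ = train_step1(ds, cfg, params=init)
        assert (trained.W == init.W).all()
        assert (trained.V == init.V).all()

    def test_same_seed_reproduces_trajectory(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(
            embedding_dim=2, attention_hidden=2, max_epochs=6, seed=9,
        )
        a, ha = train_step1(ds, cfg)
        b, hb = train_step1(ds, cfg)
        assert ha == hb
        assert (a.W == b.W).all() and (a.V == b.V).all()

    def test_single_class_rejected(self, toy_dictionary):
        rec = pd.DataFrame({
            "shape": ["taller", "wider"], "margin": ["smooth", "smooth"],
            "cadx_score": [0.5, 0.5], "label": [1, 1],
        })
        ds = encode(rec, toy_dictionary)
        with pytest.raises(SingleClassError):
            train_step1(ds, TrainingConfig(max_epochs=1))


class TestTrainStep2:
    def test_requires_gate(self, small_cohort, fast_config):
        _, _, ds = small_cohort
        p = init_parameters(ds.width, 2, 4, seed=0)
        with pytest.raises(ValueError):
            train_step2(ds, fast_config, p)

    def test_empty_gate_matches_reference_logistic_fit(self):
        """With no retained pairs the model is plain logistic
        regression; coefficients should approach an independent
        (scikit-learn) fit."""
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(0)
        ds = separable_dataset()
        # non-separable noisy variant to keep coefficients finite
        d = ds.dictionary
        rows = []
        for i in range(300):
            a = rng.random() < 0.5
            b = rng.random() < 0.5
            p = 1 / (1 + math.exp(-(-0.4 + 1.2 * a + 0.7 * b)))
            rows.append({
                "a": "hi" if a else "lo", "b": "hi" if b else "lo",
                "cadx_score": None, "label": int(rng.random() < p),
            })
        ds = encode(pd.DataFrame(rows), d)
        cfg = TrainingConfig(
            embedding_dim=2, attention_hidden=2, max_epochs=400,
            batch_size=300, learning_rate=0.05, seed=0, tol=1e-9,
            patience=50,
        )
        p0 = init_parameters(ds.width, 2, 2, seed=0)
        p0.gamma = frozenset()
        fitted, _ = train_step2(ds, cfg, p0)
        ref = LogisticRegression(C=np.inf, max_iter=2000).fit(ds.X, ds.y)
        ours = forward_batch(ds, fitted)[1]
        theirs = ref.predict_proba(ds.X)[:, 1]
        assert np.abs(ours - theirs).max() < 0.02

    def test_open_gate_continues_step1(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(embedding_dim=2, attention_hidden=2,
                             max_epochs=4, seed=1, learning_rate=0.0)
        p1, _ = train_step1(ds, cfg)
        imp = average_attention(ds, p1, divisor="total")
        open_gate = frozenset(imp.mean)
        p2, _ = train_step2(ds, cfg, dc_replace(p1.copy(), gamma=open_gate))
        # zero learning rate isolates the gate's effect on the forward pass
        l1 = forward_batch(ds, p1)[0]
        l2 = forward_batch(ds, p2)[0]
        np.testing.assert_allclose(l1, l2, atol=1e-12)


class TestRankAndSelect:
    @staticmethod
    def importance():
        return InteractionImportance(mean={}, count={}, n_samples=1)

    def make_params(self, W):
        p = init_parameters(len(W), 2, 2, seed=0, scale=0.0)
        p.W = np.asarray(W, dtype=float)
        p.gamma = frozenset()
        return p

    def test_uniform_coefficients_share_weight(self):
        cfg = TrainingConfig(top_k=4)
        sel = rank_and_select(
            self.make_params([0.3, 0.3, 0.3, 0.3]), self.importance(), cfg
        )
        assert [e.weight for e in sel.entries] == pytest.approx([0.25] * 4)

    def test_closed_form_two_feature_softmax(self):
        cfg = TrainingConfig(top_k=2)
        sel = rank_and_select(
            self.make_params([1.0, 0.0]), self.importance(), cfg
        )
        e = math.e
        assert sel.entries[0].weight == pytest.approx(e / (e + 1))
        assert sel.entries[1].weight == pytest.approx(1 / (e + 1))

    def test_weights_sum_to_one_and_ranks_are_permutation(self):
        rng = np.random.default_rng(0)
        cfg = TrainingConfig(top_k=15)
        sel = rank_and_select(
            self.make_params(rng.normal(0, 1, 30)), self.importance(), cfg
        )
        assert sum(e.weight for e in sel.entries) == pytest.approx(1.0,
                                                                   abs=1e-9)
        assert sorted(e.rank for e in sel.entries) == list(range(1, 16))
        weights = [e.weight for e in sel.entries]
        assert weights == sorted(weights, reverse=True)

    def test_top_k_caps_at_available(self):
        cfg = TrainingConfig(top_k=50)
        sel = rank_and_select(
            self.make_params([0.1, 0.2, 0.3]), self.importance(), cfg
        )
        assert sel.K == 3

    def test_signed_share_mode_preserves_sign(self):
        cfg = TrainingConfig(top_k=2, weight_mode="signed_share")
        sel = rank_and_select(
            self.make_params([0.6, -0.2]), self.importance(), cfg
        )
        weights = {e.identity: e.weight for e in sel.entries}
        assert weights[0] == pytest.approx(0.75)
        assert weights[1] == pytest.approx(-0.25)


class TestTwoStep:
    def test_deterministic_selection(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(embedding_dim=2, attention_hidden=2,
                             max_epochs=8, seed=4)
        r1 = two_step_train(ds, cfg)
        r2 = two_step_train(ds, cfg)
        assert r1.epsilon == r2.epsilon
        assert r1.params.gamma == r2.params.gamma
        s1 = rank_and_select(r1.params, r1.importance, cfg,
                             coefficients=r1.coefficients)
        s2 = rank_and_select(r2.params, r2.importance, cfg,
                             coefficients=r2.coefficients)
        assert [(e.identity, e.weight) for e in s1.entries] == \
            [(e.identity, e.weight) for e in s2.entries]

    def test_adaptive_epsilon_is_mean_plus_sd_of_attention(self,
                                                           small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(embedding_dim=2, attention_hidden=2,
                             max_epochs=4, seed=5, restarts=1)
        res = two_step_train(ds, cfg)
        p1, _ = train_step1(ds, cfg)
        imp1 = average_attention(ds, p1, divisor=cfg.attention_average)
        values = np.array(list(imp1.mean.values()))
        assert res.epsilon == pytest.approx(
            float(values.mean() + values.std())
        )

    def test_explicit_epsilon_respected(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(embedding_dim=2, attention_hidden=2,
                             max_epochs=4, seed=5, gate_epsilon=1e9)
        res = two_step_train(ds, cfg)
        assert res.params.gamma == frozenset()


class TestBaselines:
    def test_lr1_with_large_top_k_equals_lr0(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(top_k=ds.width, max_epochs=2,
                             embedding_dim=2, attention_hidden=2, seed=0)
        models = fit_baselines(ds, cfg)
        np.testing.assert_allclose(
            models.predict_lr0(ds.X), models.predict_lr1(ds.X), atol=1e-6
        )

    def test_afm_is_ungated(self, small_cohort):
        _, _, ds = small_cohort
        cfg = TrainingConfig(max_epochs=2, embedding_dim=2,
                             attention_hidden=2, seed=0)
        models = fit_baselines(ds, cfg)
        assert models.afm.gamma is None

    def test_max_combination_elementwise(self):
        out = max_combination([0.3, 0.9, 0.5], [0.8, 0.1, 0.5])
        np.testing.assert_array_equal(out, [0.8, 0.9, 0.5])
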