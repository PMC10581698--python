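"""Training machinery: loss closed forms, pair sampling, epoch/seed
bookkeeping, validation weighting, determinism."""

import numpy as np
import pandas as pd
import pytest

from tmrcanet.features import WindowSpec
from tmrcanet.network import ModelConfig, build_model, receptive_field
from tmrcanet.simulate import DemographicModel, SimulationConfig
from tmrcanet.training import (
    Adam,
    TaskUncertainty,
    TrainConfig,
    class_weights_from_labels,
    huber,
    make_epoch,
    multitask_loss,
    relatedness_pairing,
    train,
    uniform_pairing,
    validation_score,
)
from tmrcanet.training import ValidationSet, _stream_rngs


def tiny_model_config(L=32, kernels=(3, 3)):
    rf = receptive_field(kernels)
    return ModelConfig(
        window=WindowSpec(L=L, context=(rf - 1) // 2), channels=(4, 4), kernels=kernels
    )


def tiny_train_config(**kw):
    base = dict(
        sim=SimulationConfig(
            DemographicModel.constant(10_000),
            n_haplotypes=8,
            region_length=150_000,
            seed=0,
        ),
        model=tiny_model_config(),
        epochs=2,
        sims_per_epoch=3,
        val_sims=2,
        seed=123,
    )
    base.update(kw)
    return TrainConfig(**base)


class TestMultitaskLoss:
    def test_zero_residual_huber_term_zero(self):
        t = np.array([100.0, 200.0, 50.0])
        out = np.zeros((1, 2, 3))
        out[0, 0] = np.log(t)
        b = np.zeros(3)
        unc = TaskUncertainty(0.0, 0.0)
        loss, d_out, dsr, dsc, hub, bce = multitask_loss(
            out, t, b, unc, return_grads=True
        )
        assert hub == 0.0
        assert loss == pytest.approx(bce)  # only the classification term

    def test_huber_closed_form_below_delta(self):
        r = 0.5
        assert huber(np.array([r]))[0] == pytest.approx(0.125)

    def test_class_weight_inverse_frequency(self):
        b = np.array([0] * 9 + [1])
        w0, w1 = class_weights_from_labels(b)
        assert w1 / w0 == pytest.approx(9.0)

    def test_nonpositive_tmrca_rejected(self):
        out = np.zeros((1, 2, 2))
        with pytest.raises(ValueError):
            multitask_loss(out, np.array([10.0, 0.0]), np.zeros(2), TaskUncertainty())

    def test_uncertainty_terms_enter_loss(self):
        out = np.zeros((1, 2, 2))
        t = np.array([np.e, np.e])  # log t = 1, residual -1, huber 0.5
        b = np.zeros(2)
        l0 = multitask_loss(out, t, b, TaskUncertainty(0.0, 0.0))
        l1 = multitask_loss(out, t, b, TaskUncertainty(1.0, 0.0))
        # exp(-1)*huber + 0.5 vs huber: recompute explicitly
        bce = l0 - 0.5
        assert l1 == pytest.approx(np.exp(-1) * 0.5 + bce + 0.5)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        out = rng.normal(size=(2, 2, 5))
        t = np.exp(rng.normal(size=(2, 5)) + 5)
        b = (rng.random((2, 5)) < 0.3).astype(float)
        unc = TaskUncertainty(0.3, -0.2)
        w = class_weights_from_labels(b)
        loss, d_out, dsr, dsc, *_ = multitask_loss(
            out, t, b, unc, class_weights=w, return_grads=True
        )
        eps = 1e-7
        for idx in [(0, 0, 1), (1, 1, 3), (0, 1, 0)]:
            op, om = out.copy(), out.copy()
            op[idx] += eps
            om[idx] -= eps
            num = (
                multitask_loss(op, t, b, unc, class_weights=w)
                - multitask_loss(om, t, b, unc, class_weights=w)
            ) / (2 * eps)
            assert num == pytest.approx(d_out[idx], rel=1e-4, abs=1e-8)
        num_sr = (
            multitask_loss(out, t, b, TaskUncertainty(0.3 + eps, -0.2), class_weights=w)
            - multitask_loss(out, t, b, TaskUncertainty(0.3 - eps, -0.2), class_weights=w)
        ) / (2 * eps)
        assert num_sr == pytest.approx(dsr, rel=1e-5)


class TestPairing:
    def test_relatedness_matches_literal_procedure_2n4(self):
        # with 4 haplotypes the first random pair fixes the matching;
        # re-execute the quoted procedure literally for many seeds
        m = np.array(
            [
                [0, 10, 20, 30],
                [10, 0, 40, 50],
                [20, 40, 0, 60],
                [30, 50, 60, 0],
            ],
            dtype=float,
        )
        for seed in range(20):
            pairs = relatedness_pairing(m, seed=seed)
            rng = np.random.default_rng(seed)
            first = sorted(rng.choice(4, size=2, replace=False).tolist())
            rest = sorted(set(range(4)) - set(first))
            assert pairs[0] == tuple(first)
            assert sorted(pairs[1]) == rest

    def test_forced_argmin_chain(self):
        # matrix where 0's closest is 2, and 2's closest among the rest is 3
        m = np.full((6, 6), 100.0)
        np.fill_diagonal(m, 0.0)
        m[0, 2] = m[2, 0] = 1.0
        m[2, 3] = m[3, 2] = 2.0
        m[0, 1] = m[1, 0] = 5.0
        # force the first pair to be (0, 1) by scanning seeds
        for seed in range(100):
            rng = np.random.default_rng(seed)
            if sorted(rng.choice(6, size=2, replace=False).tolist()) == [0, 1]:
                pairs = relatedness_pairing(m, seed=seed)
                assert pairs[0] == (0, 1)
                # anchor is 0 or 1; closest remaining to either is 2 (via 0)
                # or 4/5 ties -> lowest index; then partner of the chosen one
                assert all(len(set(p)) == 2 for p in pairs)
                break
        else:
            pytest.fail("no seed produced first pair (0, 1)")

    def test_all_equal_matrix_valid_matching(self):
        m = np.ones((8, 8)) - np.eye(8)
        pairs = relatedness_pairing(m, seed=3)
        flat = [h for p in pairs for h in p]
        assert sorted(flat) == list(range(8))

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            relatedness_pairing(np.ones((5, 5)), seed=0)

    def test_uniform_pairing_is_perfect_matching(self):
        pairs = uniform_pairing(10, np.random.default_rng(0))
        flat = [h for p in pairs for h in p]
        assert sorted(flat) == list(range(10))

    def test_relatedness_enriches_recent_tmrca(self):
        # statistical property: relatedness matchings have lower mean TMRCA
        rng = np.random.default_rng(42)
        m = rng.gamma(2.0, 10_000.0, size=(20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        rel = [
            np.mean([m[p] for p in relatedness_pairing(m, seed=s)]) for s in range(100)
        ]
        uni = [
            np.mean([m[p] for p in uniform_pairing(20, np.random.default_rng(s))])
            for s in range(100)
        ]
        assert np.mean(rel) < np.mean(uni)


class TestEpochs:
    def test_epoch_has_one_seed_per_simulation(self):
        cfg = tiny_train_config(sims_per_epoch=5)
        rngs = _stream_rngs(cfg.seed)
        X, t, b, seeds = make_epoch(cfg, "uniform", rngs["train_sims"])
        assert len(seeds) == 5
        assert len(set(seeds)) == 5
        assert X.shape[0] == t.shape[0] == b.shape[0]
        assert X.shape[1:] == (6, cfg.model.window.L1)

    def test_no_seed_reuse_across_epochs(self):
        cfg = tiny_train_config(sims_per_epoch=4)
        rngs = _stream_rngs(cfg.seed)
        _, _, _, s1 = make_epoch(cfg, "uniform", rngs["train_sims"])
        _, _, _, s2 = make_epoch(cfg, "relatedness", rngs["train_sims"])
        assert not (set(s1) & set(s2))

    def test_validation_stream_disjoint_from_training(self):
        cfg = tiny_train_config()
        rngs = _stream_rngs(cfg.seed)
        train_draws = rngs["train_sims"].integers(1, 2**31 - 1, size=100)
        val_draws = rngs["validation"].integers(1, 2**31 - 1, size=100)
        assert not (set(train_draws.tolist()) & set(val_draws.tolist()))


class TestValidation:
    def test_uniform_weights_reduce_to_plain_huber(self):
        cfg = tiny_model_config()
        model = build_model(cfg, seed=0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 6, cfg.window.L1))
        log_t = rng.normal(size=(4, cfg.window.L)) + 9
        vs_plain = ValidationSet(X=X, log_t=log_t, weights=np.ones_like(log_t))
        score = validation_score(model, vs_plain)
        manual = np.mean(
            [
                huber(model.forward(X[i : i + 1])[0, 0] - log_t[i]).mean()
                for i in range(4)
            ]
        )
        assert score == pytest.approx(manual)

    def test_validation_set_weights_and_selection(self):
        # 40 candidate pairs at 5% -> exactly 2 retained (floor rule)
        assert int(np.floor(0.05 * 40)) == 2
        cfg = tiny_train_config(val_sims=2)
        from tmrcanet.training import build_validation_set

        rngs = _stream_rngs(cfg.seed)
        vs = build_validation_set(cfg, rngs["validation"])
        assert vs.X.shape[0] >= 1
        assert vs.weights.shape == vs.log_t.shape
        assert vs.weights.mean() == pytest.approx(1.0)

    def test_too_few_pairs_falls_back_to_closest_with_warning(self):
        sim = SimulationConfig(
            DemographicModel.constant(10_000),
            n_haplotypes=4,
            region_length=150_000,
            seed=0,
        )
        cfg = tiny_train_config(sim=sim, val_sims=1)  # 6 candidates, 5% -> 0
        from tmrcanet.training import build_validation_set

        rngs = _stream_rngs(cfg.seed)
        with pytest.warns(UserWarning, match="closest pair"):
            vs = build_validation_set(cfg, rngs["validation"])
        assert vs.X.shape[0] >= 1


class TestTrainLoop:
    def test_learning_signal(self):
        cfg = tiny_train_config(epochs=6, sims_per_epoch=4)
        res = train(cfg)
        h = res.history
        assert res.best_val <= h["val_score"].iloc[0]
        assert len(h) == 6
        assert list(h["mode"][:2]) == ["uniform", "relatedness"]

    def test_full_determinism(self):
        cfg = tiny_train_config(epochs=2)
        r1 = train(cfg)
        r2 = train(cfg)
        pd.testing.assert_frame_equal(r1.history, r2.history)
        for a, b in zip(r1.model.parameters(), r2.model.parameters()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_finetune_rejects_mismatched_config(self):
        donor = train(tiny_train_config(epochs=1))
        from tmrcanet.training import finetune

        bad = tiny_train_config(model=tiny_model_config(L=16), epochs=1)
        with pytest.raises(ValueError, match="mismatch"):
            finetune(donor, bad)

    def test_adam_converges_on_quadratic(self):
        class P:
            def __init__(self):
                self.value = np.array([5.0, -3.0])
                self.grad = np.zeros(2)

        p = P()
        opt = Adam([( [p], 0.1 )])
        for _ in range(500):
            p.grad = 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-3
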