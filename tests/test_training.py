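"""Training protocol: splits, freezing, plateau schedule, staged training."""

import numpy as np
import pytest

from dcnet.config import (
    AugmentConfig,
    DecoderConfig,
    EncoderConfig,
    LossConfig,
    PhantomConfig,
    TrainConfig,
)
from dcnet.encoder import count_parameters
from dcnet.model import DCNet
from dcnet.phantom import generate_arrays
from dcnet.training import (
    SGD,
    SchedulerState,
    cross_validate,
    evaluate_dsc,
    freeze,
    plateau_step,
    split_dataset,
    three_stage_train,
    train_stage,
)


class TestSplit:
    def test_sizes_and_disjointness(self):
        train, val = split_dataset(range(40), 30, 10, seed=3)
        assert len(train) == 30 and len(val) == 10
        assert not set(train) & set(val)
        assert set(train) | set(val) == set(range(40))

    def test_deterministic_under_seed(self):
        assert split_dataset(range(50), 30, 10, 7) == split_dataset(
            range(50), 30, 10, 7)
        assert split_dataset(range(50), 30, 10, 7) != split_dataset(
            range(50), 30, 10, 8)

    def test_insufficient_scans_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            split_dataset(range(30), 30, 10)


class TestPlateau:
    def test_decay_after_exactly_ten_flat_epochs(self):
        state = SchedulerState(current_lr=1e-4, patience=10)
        plateau_step(state, 0.5)  # first epoch establishes the best
        for i in range(9):
            plateau_step(state, 0.5)
            assert state.current_lr == 1e-4, f"decayed early at {i}"
        plateau_step(state, 0.5)  # tenth non-improving epoch
        assert state.current_lr == pytest.approx(1e-5)

    def test_improvement_resets_counter(self):
        state = SchedulerState(current_lr=1e-4, patience=10)
        plateau_step(state, 0.5)
        for _ in range(9):
            plateau_step(state, 0.5)
        plateau_step(state, 0.6)  # improvement on epoch 9
        assert state.current_lr == 1e-4
        assert state.epochs_since_improvement == 0

    def test_twenty_flat_epochs_decay_twice(self):
        state = SchedulerState(current_lr=1e-4, patience=10)
        plateau_step(state, 0.5)
        for _ in range(20):
            plateau_step(state, 0.5)
        assert state.current_lr == pytest.approx(1e-6)

    def test_nonfinite_dsc_rejected(self):
        with pytest.raises(ValueError):
            plateau_step(SchedulerState(current_lr=1e-4), np.nan)


class TestFreeze:
    def test_frozen_decoder_parameters_bitwise_unchanged(self, tiny_model, rng):
        frozen = freeze(tiny_model, "decoder")
        before = {id(p): p.data.copy() for p in frozen}
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        g = (rng.random((2, 1, 32, 32)) < 0.1).astype(np.float32)
        opt = SGD(tiny_model.parameters(), lr=0.01)
        from dcnet.losses import integrated_loss

        tiny_model.train()
        loss = integrated_loss(tiny_model(x), g)
        opt.zero_grad()
        loss.backward()
        opt.step()
        for p in frozen:
            assert np.array_equal(p.data, before[id(p)])
        # encoder did move
        assert any(
            not np.array_equal(p.data, p.data * 0 + p.data)
            or p.grad is not None
            for p in tiny_model.encoder.parameters()
        )

    def test_freeze_none_keeps_everything_trainable(self, tiny_model):
        freeze(tiny_model, "decoder")
        freeze(tiny_model, "none")
        assert all(p.requires_grad for p in tiny_model.parameters())

    def test_freeze_encoder_count_additivity(self, tiny_model):
        total = count_parameters(tiny_model)
        freeze(tiny_model, "encoder")
        enc = sum(p.data.size for p in tiny_model.encoder.parameters())
        assert count_parameters(tiny_model) == total - enc
        freeze(tiny_model, "none")

    def test_unknown_part_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="unknown part"):
            freeze(tiny_model, "stem")


@pytest.fixture(scope="module")
def tiny_data():
    cfg = PhantomConfig(image_size=32, n_pairs=20, seed=42,
                        tumor_area_range=(0.02, 0.2))
    images, masks = generate_arrays(cfg)
    return images[:14], masks[:14], images[14:], masks[14:]


def _tiny_model(seed=0, variant="A"):
    enc = EncoderConfig(growth_rate=4, layers_per_block=2, stem_channels=4,
                        bottleneck_width=4,
                        transition_out_channels=(8, 8, 8, 8, 8), drop_rate=0.1)
    dec = DecoderConfig(skip_channels=4, fusion_channels=8)
    model, loss_cfg = DCNet.from_variant(variant, seed=seed, encoder_cfg=enc,
                                         decoder_cfg=dec)
    return model, loss_cfg


class TestStages:
    def test_history_length_and_stage_freezing(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model()
        cfg = TrainConfig(epochs_per_stage=2, batch_size=4, seed=0)
        dec_before = [p.data.copy() for p in model.decoder.parameters()]
        hist = train_stage(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg,
                           stage=1)
        assert len(hist) == 2
        for p, before in zip(model.decoder.parameters(), dec_before):
            assert np.array_equal(p.data, before)

    def test_invalid_stage_and_empty_data(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model()
        cfg = TrainConfig(epochs_per_stage=1, batch_size=4)
        with pytest.raises(ValueError, match="stage"):
            train_stage(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg, stage=4)
        with pytest.raises(ValueError, match="empty"):
            train_stage(model, tr_i[:0], tr_m[:0], va_i, va_m, cfg, loss_cfg,
                        stage=1)

    def test_three_stages_run_in_order(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model(seed=1)
        cfg = TrainConfig(epochs_per_stage=1, batch_size=4, seed=1)
        result = three_stage_train(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg)
        assert list(result.history["stage"]) == [1, 2, 3]
        assert len(result.history) == 3
        assert result.best_val_dsc == result.history["val_dsc"].max()

    def test_checkpoint_restores_best_state(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model(seed=2)
        cfg = TrainConfig(epochs_per_stage=1, batch_size=4, seed=2)
        result = three_stage_train(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg)
        result.restore_best(model)
        state = model.state_dict()
        assert all(np.array_equal(state[k], v)
                   for k, v in result.best_state.items())

    def test_training_reduces_loss_on_phantoms(self, tiny_data):
        """Smoke test: a short staged run decreases the training loss."""
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model(seed=3)
        cfg = TrainConfig(epochs_per_stage=4, batch_size=4, seed=3, lr=1e-2,
                          augment=False)
        result = three_stage_train(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg)
        losses = result.history["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_determinism_identical_histories(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        histories = []
        for _ in range(2):
            model, loss_cfg = _tiny_model(seed=5)
            cfg = TrainConfig(epochs_per_stage=1, batch_size=4, seed=5)
            res = three_stage_train(model, tr_i, tr_m, va_i, va_m, cfg,
                                    loss_cfg)
            histories.append(res.history)
        assert histories[0].equals(histories[1])

    def test_per_level_losses_logged(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        model, loss_cfg = _tiny_model(seed=6)
        cfg = TrainConfig(epochs_per_stage=1, batch_size=4, seed=6)
        result = three_stage_train(model, tr_i, tr_m, va_i, va_m, cfg, loss_cfg)
        for k in range(6):
            assert f"J{k}" in result.history.columns


class TestCrossValidate:
    def test_four_trials_feed_mann_whitney(self, tiny_data):
        tr_i, tr_m, va_i, va_m = tiny_data
        images = np.concatenate([tr_i, va_i])
        masks = np.concatenate([tr_m, va_m])
        enc = EncoderConfig(growth_rate=2, layers_per_block=1, stem_channels=2,
                            bottleneck_width=2,
                            transition_out_channels=(4, 4, 4, 4, 4),
                            drop_rate=0.0)
        cfg = TrainConfig(epochs_per_stage=1, batch_size=4, seed=0,
                          n_cv_trials=4, n_train=14, n_val=6, augment=False)
        # patch the variant builder onto a miniature architecture via config
        import dcnet.training as T

        orig = DCNet.from_variant.__func__

        def small_variant(cls, variant, seed=0, **kw):
            return orig(cls, variant, seed=seed, encoder_cfg=enc,
                        decoder_cfg=DecoderConfig(skip_channels=2,
                                                  fusion_channels=4))

        DCNet.from_variant = classmethod(small_variant)
        try:
            scores = cross_validate(images, masks, cfg)
        finally:
            DCNet.from_variant = classmethod(orig)
        assert len(scores) == 4
        assert all(0.0 <= s <= 1.0 for s in scores)
        from dcnet.metrics import mann_whitney_exact

        p = mann_whitney_exact(scores, scores)
        assert 0.0 < p <= 1.0

    def test_too_few_trials_rejected(self, tiny_data):
        tr_i, tr_m, *_ = tiny_data
        with pytest.raises(ValueError):
            cross_validate(tr_i, tr_m, TrainConfig(n_cv_trials=1))


def test_sgd_momentum_update_matches_closed_form():
    from dcnet.nn import Parameter

    p = Parameter(np.array([1.0]))
    opt = SGD([p], lr=0.1, momentum=0.5)
    p.grad = np.array([2.0])
    opt.step()  # v = -0.2 -> p = 0.8
    assert np.allclose(p.data, 0.8)
    p.grad = np.array([1.0])
    opt.step()  # v = 0.5*(-0.2) - 0.1 = -0.2 -> p = 0.6
    assert np.allclose(p.data, 0.6)


def test_evaluate_dsc_on_perfect_predictor(tiny_data):
    """A model stub that outputs the mask itself scores DSC 1."""
    _, _, va_i, va_m = tiny_data

    class Oracle:
        def predict_proba(self, images, batch_size=8):
            return va_m.astype(np.float32)

    assert evaluate_dsc(Oracle(), va_i, va_m) == 1.0
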