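"""Adversarial training loop: losses, logging, checkpoints, determinism."""

import os

import numpy as np
import pytest

import maskgan as mg
from maskgan.errors import EmptyDataset, InvalidConfig, ShapeMismatch


class TestTotalLoss:
    def test_zero_case(self):
        cfg = mg.TrainingConfig()
        assert mg.total_loss(0.0, 0.0, cfg) == 0.0

    def test_published_weights(self):
        # lambda1 = 100, lambda2 = 1 by default
        assert mg.total_loss(1.0, 1.0, mg.TrainingConfig()) == 101.0

    def test_degenerate_weights(self):
        cfg = mg.TrainingConfig(lambda1=0.0)
        assert mg.total_loss(5.0, 2.0, cfg) == 2.0


class TestTrainingConfig:
    def test_defaults_are_published_values(self):
        cfg = mg.TrainingConfig()
        assert cfg.learning_rate == 0.0002
        assert cfg.adam_momentum == 0.5
        assert cfg.lambda1 == 100.0 and cfg.lambda2 == 1.0
        assert cfg.exponential_decay == 0.99
        assert cfg.batch_size == 1 and cfg.epochs == 10
        assert cfg.dropout == 0.5
        assert cfg.loss_log_every == 100 and cfg.checkpoint_every == 500

    @pytest.mark.parametrize("kwargs", [
        dict(learning_rate=-1.0), dict(epochs=0), dict(dropout=1.0),
        dict(batch_size=2), dict(loss_log_every=0),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidConfig):
            mg.TrainingConfig(**kwargs)


class TestTrainLoop:
    def _run(self, phantom16, tiny_gen_cfg, tiny_disc_cfg, **kwargs):
        defaults = dict(epochs=2, loss_log_every=1, checkpoint_every=500,
                        seed=5)
        defaults.update(kwargs)
        tcfg = mg.TrainingConfig(**defaults)
        return mg.train([phantom16], tiny_gen_cfg, tiny_disc_cfg, tcfg)

    def test_smoke_two_iterations(self, phantom16, tiny_gen_cfg, tiny_disc_cfg):
        gen, disc, records = self._run(phantom16, tiny_gen_cfg, tiny_disc_cfg)
        assert len(records) == 2
        assert all(np.isfinite([r.generator_loss, r.discriminator_loss,
                                r.total_loss]).all() for r in records)
        assert [r.iteration for r in records] == [1, 2]

    def test_log_and_checkpoint_frequencies(self, tmp_path, phantom16,
                                            tiny_gen_cfg, tiny_disc_cfg):
        ds = [phantom16] * 4
        tcfg = mg.TrainingConfig(epochs=5, loss_log_every=5,
                                 checkpoint_every=10, seed=1)
        ckdir = str(tmp_path / "ck")
        _, _, records = mg.train(ds, tiny_gen_cfg, tiny_disc_cfg, tcfg,
                                 checkpoint_dir=ckdir)
        # 20 iterations: records at 5, 10, 15, 20; checkpoints at 10, 20
        assert [r.iteration for r in records] == [5, 10, 15, 20]
        assert len(os.listdir(ckdir)) == 2

    def test_records_below_frequency_absent(self, phantom16, tiny_gen_cfg,
                                            tiny_disc_cfg):
        _, _, records = self._run(phantom16, tiny_gen_cfg, tiny_disc_cfg,
                                  loss_log_every=100)
        assert records == []

    def test_total_is_weighted_combination(self, phantom16, tiny_gen_cfg,
                                           tiny_disc_cfg):
        _, _, records = self._run(phantom16, tiny_gen_cfg, tiny_disc_cfg)
        cfg = mg.TrainingConfig()
        for r in records:
            assert r.total_loss == pytest.approx(
                mg.total_loss(r.generator_loss, r.discriminator_loss, cfg))

    def test_strict_modes_run(self, phantom16, tiny_gen_cfg, tiny_disc_cfg):
        _, _, records = self._run(phantom16, tiny_gen_cfg, tiny_disc_cfg,
                                  strict_l1_generator=True,
                                  strict_original_input=True)
        assert len(records) == 2

    def test_empty_dataset_rejected(self, tiny_gen_cfg, tiny_disc_cfg):
        with pytest.raises(EmptyDataset):
            mg.train([], tiny_gen_cfg, tiny_disc_cfg, mg.TrainingConfig())

    def test_mismatched_sizes_rejected(self, phantom16, tiny_gen_cfg):
        with pytest.raises(InvalidConfig):
            mg.train([phantom16], tiny_gen_cfg,
                     mg.DiscriminatorConfig.toy(64), mg.TrainingConfig())


@pytest.fixture(scope="module")
def trained(phantom16, tiny_gen_cfg, tiny_disc_cfg):
    tcfg = mg.TrainingConfig(epochs=3, loss_log_every=100,
                             checkpoint_every=500, seed=2)
    gen, _, _ = mg.train([phantom16], tiny_gen_cfg, tiny_disc_cfg, tcfg)
    return gen


class TestSynthesize:

    def test_output_range_and_determinism(self, trained, phantom16):
        slc, mask = phantom16
        am = mg.make_attention_map(slc, mask)
        out1 = mg.synthesize(trained, am)
        out2 = mg.synthesize(trained, am)
        assert out1.pixels.min() >= 0 and out1.pixels.max() <= 4096
        np.testing.assert_array_equal(out1.pixels, out2.pixels)

    def test_shape_mismatch(self, trained):
        am = mg.make_attention_map(
            mg.CtSlice(np.full((8, 8), 100.0)),
            mg.TumorMask(np.zeros((8, 8))))
        with pytest.raises(ShapeMismatch):
            mg.synthesize(trained, am)

    def test_checkpoint_round_trip_bitwise(self, tmp_path, trained, phantom16,
                                           tiny_disc_cfg):
        slc, mask = phantom16
        am = mg.make_attention_map(slc, mask)
        disc = mg.build_discriminator(tiny_disc_cfg, seed=0)
        path = str(tmp_path / "model.npz")
        mg.save_checkpoint(path, trained, disc)
        gen2, disc2 = mg.load_checkpoint(path)
        np.testing.assert_array_equal(mg.synthesize(trained, am).pixels,
                                      mg.synthesize(gen2, am).pixels)
        for a, b in zip(disc.parameters(), disc2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)


class TestSeedDeterminism:
    def test_identical_seeds_identical_records(self, phantom16, tiny_gen_cfg,
                                               tiny_disc_cfg):
        tcfg = mg.TrainingConfig(epochs=4, loss_log_every=1,
                                 checkpoint_every=500, seed=7)
        runs = [mg.train([phantom16] * 2, tiny_gen_cfg, tiny_disc_cfg, tcfg)
                for _ in range(2)]
        assert [r for *_, r in runs][0] == [r for *_, r in runs][1]

    def test_different_seeds_differ(self, phantom16, tiny_gen_cfg,
                                    tiny_disc_cfg):
        recs = []
        for seed in (1, 2):
            tcfg = mg.TrainingConfig(epochs=2, loss_log_every=1,
                                     checkpoint_every=500, seed=seed)
            *_, r = mg.train([phantom16], tiny_gen_cfg, tiny_disc_cfg, tcfg)
            recs.append(r)
        assert recs[0] != recs[1]
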