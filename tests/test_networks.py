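"""Generator and discriminator architecture, forward passes and gradients."""

import numpy as np
import pytest

import maskgan as mg
from maskgan import nn
from maskgan.discriminator import BlockSpec, DiscriminatorConfig
from maskgan.errors import InvalidConfig, ShapeMismatch
from maskgan.nn import Tensor


class TestAutodiffGradients:
    """Finite-difference checks of the hand-written backward passes."""

    @pytest.mark.parametrize("op", ["conv", "dilated", "transpose"])
    def test_conv_ops_against_numerical_gradient(self, rng, op):
        x = rng.normal(size=(1, 2, 6, 6)).astype(np.float64)
        if op == "transpose":
            w = rng.normal(size=(2, 3, 4, 4))
            f = lambda xt, wt: nn.conv_transpose2d(xt, wt, stride=2, padding=1)
        elif op == "dilated":
            w = rng.normal(size=(3, 2, 3, 3))
            f = lambda xt, wt: nn.conv2d(xt, wt, stride=2, padding=2, dilation=2)
        else:
            w = rng.normal(size=(3, 2, 3, 3))
            f = lambda xt, wt: nn.conv2d(xt, wt, stride=1, padding=1)

        xt, wt = Tensor(x, requires_grad=True), Tensor(w, requires_grad=True)
        loss = nn.tsum(f(xt, wt) * f(xt, wt))
        loss.backward()

        def scalar(xa, wa):
            return float(nn.tsum(f(Tensor(xa), Tensor(wa))
                                 * f(Tensor(xa), Tensor(wa))).data)

        eps = 1e-2
        for _ in range(4):
            idx = tuple(rng.integers(s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (scalar(xp, w) - scalar(xm, w)) / (2 * eps)
            assert xt.grad[idx] == pytest.approx(num, rel=2e-2, abs=1e-2)
        for _ in range(4):
            idx = tuple(rng.integers(s) for s in w.shape)
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            num = (scalar(x, wp) - scalar(x, wm)) / (2 * eps)
            assert wt.grad[idx] == pytest.approx(num, rel=2e-2, abs=1e-2)


class TestGeneratorConfig:
    def test_canonical_size_chain(self):
        cfg = mg.GeneratorConfig()
        assert cfg.encoder_sides() == [256, 128, 64, 32, 16, 8, 4, 2, 1]
        assert cfg.encoder_channels() == [64, 128, 256, 512, 1024,
                                          1024, 1024, 1024, 1024]

    def test_toy_config_consistent(self):
        cfg = mg.GeneratorConfig.toy(16, base_channels=4, max_channels=16,
                                     dilation_blocks=1)
        assert cfg.depth == 4
        assert cfg.encoder_sides()[-1] == 1

    @pytest.mark.parametrize("kwargs", [
        dict(input_size=96, depth=9),
        dict(input_size=512, depth=8),
        dict(input_size=512, depth=9, dilation_blocks=10),
        dict(input_size=512, depth=9, dropout_rate=1.5),
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(InvalidConfig):
            mg.GeneratorConfig(**kwargs)


@pytest.fixture(scope="module")
def small_gen():
    cfg = mg.GeneratorConfig(input_size=32, depth=5, base_channels=8,
                             max_channels=32, dilation_blocks=2)
    return mg.build_generator(cfg, seed=0)


class TestGeneratorForward:

    def test_output_shape_and_determinism(self, small_gen, rng):
        img = rng.normal(size=(32, 32))
        out1 = mg.generator_forward(small_gen, img, img)
        out2 = mg.generator_forward(small_gen, img, img)
        assert out1.shape == (32, 32)
        assert np.isfinite(out1).all()
        np.testing.assert_array_equal(out1, out2)

    def test_encoder_pyramid_sides(self, small_gen, rng):
        img = Tensor(rng.normal(size=(1, 1, 32, 32)))
        small_gen.eval()
        _, feats = small_gen(img, img, return_features=True)
        sides = [f.shape[2] for f in feats["image"]]
        assert sides == [16, 8, 4, 2, 1]

    def test_seeded_build_deterministic(self, rng):
        cfg = mg.GeneratorConfig(input_size=16, depth=4, base_channels=4,
                                 max_channels=8, dilation_blocks=1)
        g1, g2 = mg.build_generator(cfg, seed=5), mg.build_generator(cfg, seed=5)
        img = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(mg.generator_forward(g1, img, img),
                                      mg.generator_forward(g2, img, img))

    def test_shape_mismatch(self, small_gen):
        with pytest.raises(ShapeMismatch):
            mg.generator_forward(small_gen, np.zeros((16, 16)),
                                 np.zeros((16, 16)))

    def test_attention_vs_skip_scales(self, small_gen):
        # sides 2..16 at depth 5: attention wherever side^2 <= 1024
        assert small_gen.uses_attention_at(1)   # side 2
        assert small_gen.uses_attention_at(4)   # side 16
        cfg = mg.GeneratorConfig(input_size=128, depth=7, base_channels=4,
                                 max_channels=16, dilation_blocks=2)
        g = mg.build_generator(cfg, seed=0)
        assert g.uses_attention_at(5)        # side 32 -> 1024 positions
        assert not g.uses_attention_at(6)    # side 64 -> plain skip

    def test_gradient_reaches_every_parameter(self):
        cfg = mg.GeneratorConfig(input_size=16, depth=4, base_channels=4,
                                 max_channels=8, dilation_blocks=1,
                                 dropout_rate=0.0)
        gen = mg.build_generator(cfg, seed=1)
        rng = np.random.default_rng(0)
        img = Tensor(rng.normal(size=(1, 1, 16, 16)))
        target = Tensor(rng.normal(size=(1, 1, 16, 16)))
        out = gen(img, img)
        loss = nn.tmean(nn.absolute(out - target))
        gen.zero_grad()
        loss.backward()
        for p in gen.parameters():
            assert p.grad is not None and np.any(p.grad != 0)


class TestGeneratorL1Loss:
    def test_identity_zero(self, rng):
        x = rng.normal(size=(8, 8))
        assert mg.generator_l1_loss(x, x) == 0.0

    def test_unit_difference(self):
        assert mg.generator_l1_loss(np.ones((4, 4)), np.zeros((4, 4))) == 1.0

    def test_hand_case(self):
        real = np.array([[0.0, 2.0], [4.0, 6.0]])
        synth = np.array([[1.0, 1.0], [5.0, 5.0]])
        assert mg.generator_l1_loss(real, synth) == 1.0


class TestDiscriminatorConfig:
    def test_canonical_chain(self):
        cfg = mg.DiscriminatorConfig()
        assert cfg.output_sides() == [256, 128, 64, 32, 31, 30]
        assert cfg.output_side == 30
        assert cfg.patch_count == 900

    def test_canonical_receptive_field(self):
        assert mg.receptive_field(mg.DiscriminatorConfig()) == 142

    def test_pointwise_blocks_receptive_field_one(self):
        cfg = DiscriminatorConfig(input_size=8, blocks=tuple(
            [BlockSpec(1, 1, 0, 4, "relu", batchnorm=False)] * 5
            + [BlockSpec(1, 1, 0, 1, "sigmoid", batchnorm=False)]))
        assert mg.receptive_field(cfg) == 1

    @pytest.mark.parametrize("n_blocks", [5, 7])
    def test_wrong_block_count_rejected(self, n_blocks):
        blocks = tuple([BlockSpec(4, 2, 1, 8)] * (n_blocks - 1)
                       + [BlockSpec(4, 1, 1, 1, "sigmoid")])
        with pytest.raises(InvalidConfig):
            DiscriminatorConfig(input_size=512, blocks=blocks)

    def test_final_block_must_be_sigmoid(self):
        blocks = tuple([BlockSpec(4, 2, 1, 8)] * 6)
        with pytest.raises(InvalidConfig):
            DiscriminatorConfig(input_size=512, blocks=blocks)


class TestDiscriminatorForward:
    def test_toy_map_shape_and_range(self, rng):
        cfg = mg.DiscriminatorConfig.toy(64, base_channels=4)
        disc = mg.build_discriminator(cfg, seed=0)
        img = rng.normal(size=(64, 64))
        pmap, score = mg.discriminator_score(disc, img, img)
        assert pmap.values.shape == (2, 2)
        assert np.all(pmap.values > 0) and np.all(pmap.values < 1)
        assert score == pytest.approx(pmap.values.mean())

    def test_score_is_brute_force_mean(self, rng, tiny_disc_cfg):
        disc = mg.build_discriminator(tiny_disc_cfg, seed=3)
        img = rng.normal(size=(16, 16))
        pmap, score = mg.discriminator_score(disc, img, 0.5 * img)
        assert score == pytest.approx(
            sum(float(v) for v in pmap.values.ravel()) / pmap.values.size)

    def test_shape_mismatch(self, tiny_disc_cfg):
        disc = mg.build_discriminator(tiny_disc_cfg, seed=0)
        with pytest.raises(ShapeMismatch):
            mg.discriminator_score(disc, np.zeros((8, 8)), np.zeros((8, 8)))


class TestDiscriminatorLoss:
    def test_perfect_discrimination_near_zero(self):
        real = np.full((3, 3), 1.0 - 1e-9)
        fake = np.full((3, 3), 1e-9)
        assert mg.discriminator_loss(real, fake) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half(self):
        maps = np.full((30, 30), 0.5)
        assert mg.discriminator_loss(maps, maps) == pytest.approx(
            2.0 * np.log(0.5), abs=1e-9)

    def test_permutation_invariant(self, rng):
        real = rng.uniform(0.1, 0.9, (5, 5))
        fake = rng.uniform(0.1, 0.9, (5, 5))
        perm = rng.permutation(25)
        shuffled = mg.discriminator_loss(real.ravel()[perm].reshape(5, 5),
                                         fake.ravel()[perm].reshape(5, 5))
        assert mg.discriminator_loss(real, fake) == pytest.approx(shuffled)


def probe_receptive_field(cfg: DiscriminatorConfig, input_size: int) -> int:
    """Gradient-probing oracle: perturb one input pixel at a time along the
    center row and record which output units change.

    Uses an all-ones linear convolution stack with the config's geometry —
    no learned weights, normalization or activations — so a pixel influences
    an output unit iff its response there is nonzero.  The receptive field
    is the *extent* of the influence (strided layers can leave holes inside
    it), so each unit's field is measured first-to-last influencing pixel;
    border units see clipped fields, hence the maximum over units.
    """
    row = input_size // 2
    n = input_size
    x = np.zeros((n, 1, input_size, input_size), dtype=np.float32)
    for col in range(n):
        x[col, 0, row, col] = 1.0
    t = Tensor(x)
    for b in cfg.blocks:
        w = Tensor(np.ones((1, 1, b.kernel, b.kernel), dtype=np.float32))
        t = nn.conv2d(t, w, stride=b.stride, padding=b.padding)
    hit = t.data[:, 0] != 0                 # (probe pixel, out_r, out_c)
    any_hit = hit.any(axis=0)
    first = hit.argmax(axis=0)              # first influencing pixel per unit
    last = n - 1 - hit[::-1].argmax(axis=0)
    spans = (last - first + 1)[any_hit]
    return int(spans.max())


class TestReceptiveFieldOracle:
    def test_probe_matches_recursion_on_known_configs(self, tiny_disc_cfg):
        small = DiscriminatorConfig(input_size=64, blocks=(
            BlockSpec(4, 2, 1, 4, "relu", batchnorm=False),
            BlockSpec(4, 2, 1, 4, "relu"),
            BlockSpec(3, 1, 1, 4, "relu"),
            BlockSpec(3, 1, 1, 4, "relu"),
            BlockSpec(3, 1, 1, 4, "relu"),
            BlockSpec(3, 1, 1, 1, "sigmoid", batchnorm=False),
        ))
        for cfg, size in [(small, 128), (tiny_disc_cfg, 128)]:
            assert probe_receptive_field(cfg, size) == mg.receptive_field(cfg)
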