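"""Reconstruction-network architecture contract, block partition,
normalization round trips and training oracles."""

import numpy as np
import pytest

from brainwave.fcernn import (
    Fcernn,
    FcernnSpec,
    NormStats,
    ShapeError,
    TrainConfig,
    build_fcernn,
    load_run,
    partition_volume,
    predict_volume,
    save_run,
    train_fcernn,
)
from brainwave.nn import BatchNorm, ConvNd, ConvTransposeNd, ReLU, Reshape

TINY_SPEC = FcernnSpec(
    block_shape=(4, 4, 4),
    reshape_side=1,
    encoder_channels=(8, 8, 16, 16, 32, 32, 64, 64),
    decoder_channels=(32, 16, 8),
)


class TestArchitecture:
    def test_default_build_output_shape(self):
        m = build_fcernn(FcernnSpec())
        y = m.predict(np.zeros((2, 2, 180), dtype=np.float32))
        assert y.shape == (2, 2, 8, 8, 8)

    def test_no_fully_connected_layers(self):
        m = build_fcernn(FcernnSpec())
        allowed = (ConvNd, ConvTransposeNd, BatchNorm, ReLU, Reshape)
        assert all(isinstance(l, allowed) for l in m.net.layers)

    def test_encoder_convs_carry_bn_and_relu(self):
        m = build_fcernn(FcernnSpec())
        layers = m.net.layers
        for i, l in enumerate(layers):
            if isinstance(l, ConvNd):  # encoder 1-D convolutions
                assert isinstance(layers[i + 1], BatchNorm)
                assert isinstance(layers[i + 2], ReLU)
        # decoder deconvolutions activate with ReLU; the head is linear
        deconv_idx = [i for i, l in enumerate(layers) if isinstance(l, ConvTransposeNd)]
        for i in deconv_idx[:-1]:
            assert isinstance(layers[i + 1], ReLU)
        assert deconv_idx[-1] == len(layers) - 1

    def test_default_channel_progression(self):
        spec = FcernnSpec()
        assert spec.encoder_channels == (32, 32, 64, 64, 128, 128, 256, 256)
        m = build_fcernn(spec)
        convs = [l for l in m.net.layers if isinstance(l, ConvNd)]
        assert tuple(c.w.data.shape[0] for c in convs) == spec.encoder_channels

    def test_parameter_count_below_ten_million(self):
        assert build_fcernn(FcernnSpec()).n_params < 10**7

    def test_parameter_count_independent_of_grid_through_blocks(self):
        # same block shape -> same parameter count regardless of how many
        # blocks tile the (arbitrarily large) output volume
        a = build_fcernn(FcernnSpec(block_shape=(8, 8, 8)))
        b = build_fcernn(FcernnSpec(block_shape=(8, 8, 8)))
        assert a.n_params == b.n_params

    def test_zero_input_gives_finite_output(self):
        m = build_fcernn(FcernnSpec())
        y = m.predict(np.zeros((3, 2, 180), dtype=np.float32))
        assert np.all(np.isfinite(y))

    def test_shape_trace_attached(self):
        m = build_fcernn(FcernnSpec())
        assert any("reshape" in line for line in m.shape_trace)

    def test_unreachable_block_raises_shape_error(self):
        with pytest.raises(ShapeError):
            build_fcernn(FcernnSpec(block_shape=(1, 1, 1), reshape_side=2))


class TestPartition:
    def test_eight_blocks_of_32(self):
        boxes = partition_volume((64, 64, 64), 8)
        assert len(boxes) == 8
        assert all(hi - lo == 32 for box in boxes for lo, hi in box)

    def test_identity_partition(self):
        boxes = partition_volume((64, 64, 64), 1)
        assert boxes == [((0, 64), (0, 64), (0, 64))]

    def test_exhaustive_cover_and_disjoint(self):
        boxes = partition_volume((16, 16, 16), 8)
        seen = np.zeros((16, 16, 16), dtype=int)
        for (x0, x1), (y0, y1), (z0, z1) in boxes:
            seen[x0:x1, y0:y1, z0:z1] += 1
        assert np.all(seen == 1)

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_non_cube_count_rejected(self, n):
        with pytest.raises(ValueError):
            partition_volume((16, 16, 16), n)

    def test_indivisible_axis_rejected(self):
        with pytest.raises(ValueError):
            partition_volume((15, 15, 15), 8)


class TestNormalization:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        eps = rng.uniform(1, 90, size=(4, 6, 6, 6))
        sig = rng.uniform(0, 2.3, size=(4, 6, 6, 6))
        vec = rng.normal(size=(4, 360))
        stats = NormStats.from_training(vec, eps, sig)
        vol = stats.normalize_targets(eps[0], sig[0])
        e, s = stats.denormalize(vol)
        np.testing.assert_allclose(e, eps[0], rtol=1e-10)
        np.testing.assert_allclose(s, sig[0], rtol=1e-10)

    def test_targets_in_unit_interval(self):
        rng = np.random.default_rng(1)
        eps = rng.uniform(1, 90, size=(4, 6, 6, 6))
        sig = rng.uniform(0, 2.3, size=(4, 6, 6, 6))
        stats = NormStats.from_training(rng.normal(size=(4, 360)), eps, sig)
        vol = stats.normalize_targets(eps, sig)
        assert vol.min() >= 0 and vol.max() <= 1

    def test_degenerate_stats_rejected(self):
        with pytest.raises(ValueError):
            NormStats(
                target_min=np.array([1.0, 0.0]),
                target_max=np.array([1.0, 2.0]),
                input_mean=np.zeros(360),
                input_scale=1.0,
            )


class TestAssembly:
    def test_identity_stubs_reproduce_volume(self):
        # bypassing the networks with per-block stubs, assembly must invert
        # the partition exactly
        rng = np.random.default_rng(2)
        full = (16, 16, 16)
        eps = rng.uniform(1, 90, size=full)
        sig = rng.uniform(0, 2.3, size=full)
        stats = NormStats.from_training(rng.normal(size=(2, 360)),
                                        eps[None], sig[None])
        target = stats.normalize_targets(eps, sig)
        boxes = partition_volume(full, 8)

        class Stub:
            def __init__(self, box):
                (x0, x1), (y0, y1), (z0, z1) = box
                self.block = target[:, x0:x1, y0:y1, z0:z1]

            def predict(self, x):
                return self.block[None]

        models = [Stub(b) for b in boxes]
        e, s = predict_volume(models, boxes, rng.normal(size=360), stats, full)
        np.testing.assert_allclose(e, np.maximum(eps, 1.0), rtol=1e-5)
        np.testing.assert_allclose(s, sig, rtol=1e-4, atol=1e-6)

    def test_outputs_physically_clamped(self):
        rng = np.random.default_rng(3)
        stats = NormStats.from_training(
            rng.normal(size=(2, 360)),
            rng.uniform(1, 90, size=(2, 4, 4, 4)),
            rng.uniform(0, 2, size=(2, 4, 4, 4)),
        )

        class NegStub:
            def predict(self, x):
                return np.full((1, 2, 4, 4, 4), -5.0, dtype=np.float32)

        boxes = partition_volume((4, 4, 4), 1)
        e, s = predict_volume([NegStub()], boxes, rng.normal(size=360), stats, (4, 4, 4))
        assert e.min() >= 1.0
        assert s.min() >= 0.0

    def test_missing_block_model_rejected(self):
        boxes = partition_volume((4, 4, 4), 8)
        stats = NormStats(
            target_min=np.array([1.0, 0.0]), target_max=np.array([90.0, 2.0]),
            input_mean=np.zeros(360), input_scale=1.0,
        )
        with pytest.raises(ValueError):
            predict_volume([], boxes, np.zeros(360), stats, (4, 4, 4))


@pytest.fixture(scope="module")
def toy_training_problem():
    rng = np.random.default_rng(9)
    S, n = 6, 4
    inputs = rng.normal(size=(S, 360))
    eps = rng.uniform(1, 90, size=(S, n, n, n))
    sig = rng.uniform(0, 2.3, size=(S, n, n, n))
    stats = NormStats.from_training(inputs, eps, sig)
    blocks = partition_volume((n, n, n), 1)
    return inputs, eps, sig, stats, blocks


class TestTraining:
    def test_memorizes_two_samples(self, toy_training_problem):
        inputs, eps, sig, stats, blocks = toy_training_problem
        model = build_fcernn(TINY_SPEC, seed=0)
        hist = train_fcernn(
            [model], blocks, inputs[:2], eps[:2], sig[:2], stats,
            TrainConfig(epochs=500, batch_size=2, lr=3e-3), seed=0,
        )
        assert hist[0][-1] < 1e-3

    def test_loss_decreases(self, toy_training_problem):
        inputs, eps, sig, stats, blocks = toy_training_problem
        model = build_fcernn(TINY_SPEC, seed=1)
        hist = train_fcernn(
            [model], blocks, inputs, eps, sig, stats,
            TrainConfig(epochs=50, batch_size=6, lr=1e-3), seed=1,
        )[0]
        assert hist[-1] < hist[0]

    def test_deterministic_given_seed(self, toy_training_problem):
        inputs, eps, sig, stats, blocks = toy_training_problem
        finals = []
        for _ in range(2):
            model = build_fcernn(TINY_SPEC, seed=2)
            hist = train_fcernn(
                [model], blocks, inputs, eps, sig, stats,
                TrainConfig(epochs=10, batch_size=3, lr=1e-3), seed=5,
            )
            finals.append(hist[0][-1])
        assert finals[0] == pytest.approx(finals[1], abs=1e-6)

    def test_block_independence(self, toy_training_problem):
        # other blocks' predictions are bit-identical when one block's
        # model is replaced: there is no information exchange
        inputs, eps, sig, stats, _ = toy_training_problem
        blocks = partition_volume((4, 4, 4), 8)
        spec = FcernnSpec(
            block_shape=(2, 2, 2), reshape_side=1,
            encoder_channels=(4, 4, 8, 8, 8, 8, 16, 16), decoder_channels=(8, 8, 8),
        )
        models = [build_fcernn(spec, seed=i) for i in range(8)]
        train_fcernn(models, blocks, inputs, eps, sig, stats,
                     TrainConfig(epochs=2, batch_size=3), seed=0)
        e1, s1 = predict_volume(models, blocks, inputs[0], stats, (4, 4, 4))
        models[3] = build_fcernn(spec, seed=99)  # replace one block
        e2, s2 = predict_volume(models, blocks, inputs[0], stats, (4, 4, 4))
        (x0, x1), (y0, y1), (z0, z1) = blocks[3]
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[x0:x1, y0:y1, z0:z1] = True
        np.testing.assert_array_equal(e1[~mask], e2[~mask])
        assert not np.array_equal(e1[mask], e2[mask])

    def test_checkpoint_round_trip(self, toy_training_problem, tmp_path):
        inputs, eps, sig, stats, blocks = toy_training_problem
        model = build_fcernn(TINY_SPEC, seed=3)
        hist = train_fcernn([model], blocks, inputs, eps, sig, stats,
                            TrainConfig(epochs=2, batch_size=3), seed=0)
        save_run(tmp_path / "run", [model], blocks, stats, hist)
        models2, blocks2, stats2 = load_run(tmp_path / "run")
        assert blocks2 == blocks
        x = stats.normalize_inputs(inputs[:1])
        np.testing.assert_allclose(model.predict(x), models2[0].predict(x), rtol=1e-6)
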