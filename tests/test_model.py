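"""Subsets, losses, training, decomposition and the slice-wise driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from zsa2a import (ArtifactPredictor, TrainConfig, TrainingDivergedError,
                   ZSA2A, consistency_loss, decompose, fit,
                   multi_subset_losses, predict_artifact, residual_loss,
                   run_zsa2a_slicewise, sample_subset, total_loss)
from zsa2a.recon import ReconImage

from conftest import zero_model
from test_nn import conv_oracle

R1 = np.array([[1.0, 2.0], [3.0, 4.0]])
R2 = np.ones((2, 2))


class TestSampleSubset:
    @pytest.mark.parametrize("n,m", [(512, 400), (1024, 800)])
    def test_unique_in_range(self, n, m):
        sub = sample_subset(n, m, seed=3)
        assert sub.m == m
        assert len(np.unique(sub.indices)) == m
        assert sub.indices.min() >= 0 and sub.indices.max() < n

    def test_full_set_when_m_equals_n(self):
        sub = sample_subset(64, 64, seed=1)
        assert np.array_equal(sub.indices, np.arange(64))

    def test_labels_give_independent_draws(self):
        a = sample_subset(512, 400, seed=5, label=1)
        b = sample_subset(512, 400, seed=5, label=2)
        assert not np.array_equal(a.indices, b.indices)

    def test_deterministic(self):
        a = sample_subset(128, 100, seed=9, label=1)
        b = sample_subset(128, 100, seed=9, label=1)
        assert np.array_equal(a.indices, b.indices)

    def test_m_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            sample_subset(10, 11, seed=0)


class TestLosses:
    def test_worked_example(self):
        # hand-computed 2x2 case with g = 0
        assert residual_loss(zero_model, R1, R2) == pytest.approx(3.5)
        assert consistency_loss(zero_model, R1, R2) == pytest.approx(3.5)
        assert total_loss(zero_model, R1, R2) == pytest.approx(7.0)

    def test_zero_cases(self, rng):
        x = rng.normal(size=(6, 6))
        assert residual_loss(zero_model, x, x) == 0.0
        assert consistency_loss(lambda v: v, R1, R2) == 0.0  # g = identity
        assert consistency_loss(zero_model, x, x) == 0.0
        assert total_loss(zero_model, x, x) == 0.0

    def test_residual_reduces_to_mse_of_difference(self, rng):
        x = rng.normal(size=(5, 5))
        e = rng.normal(size=(5, 5))
        assert residual_loss(zero_model, x + e, x) == pytest.approx(np.mean(e ** 2))

    def test_total_is_sum(self, rng):
        net = ArtifactPredictor(
            __import__("zsa2a.nn", fromlist=["TinyConvNet"]).TinyConvNet(4, seed=2))
        a, b = rng.normal(size=(2, 8, 8))
        t = total_loss(net, a, b)
        assert t == pytest.approx(residual_loss(net, a, b)
                                  + consistency_loss(net, a, b), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_loss(zero_model, np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            consistency_loss(zero_model, np.zeros((2, 2)), np.zeros((3, 2)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(arrays(float, (4, 4), elements=st.floats(-10, 10)),
           arrays(float, (4, 4), elements=st.floats(-10, 10)))
    def test_nonnegative(self, a, b):
        assert residual_loss(zero_model, a, b) >= 0
        assert consistency_loss(zero_model, a, b) >= 0


class TestMultiSubset:
    def test_two_images_reduce_to_total(self, rng):
        a, b = rng.normal(size=(2, 4, 4))
        assert multi_subset_losses(zero_model, [a, b]) == pytest.approx(
            total_loss(zero_model, a, b))

    def test_three_copies_zero(self, rng):
        x = rng.normal(size=(4, 4))
        assert multi_subset_losses(zero_model, [x, x, x]) == 0.0

    def test_three_distinct_pairwise_mean(self, rng):
        imgs = [rng.normal(size=(2, 2)) for _ in range(3)]
        pairs = [(0, 1), (0, 2), (1, 2)]
        want = np.mean([total_loss(zero_model, imgs[i], imgs[j])
                        for i, j in pairs])
        assert multi_subset_losses(zero_model, imgs) == pytest.approx(want)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            multi_subset_losses(zero_model, [np.zeros((2, 2))])


class TestPredictArtifact:
    def test_zero_weights_zero_output(self, rng):
        model = ArtifactPredictor.zeros()
        out = model.predict(rng.normal(size=(8, 8)))
        assert np.all(out == 0)

    def test_shape_contract(self, rng):
        from zsa2a.nn import TinyConvNet
        model = ArtifactPredictor(TinyConvNet(4, seed=1))
        x = rng.normal(size=(7, 9))
        assert model.predict(x).shape == x.shape

    def test_matches_convolution_oracle(self, rng):
        from zsa2a.nn import TinyConvNet
        net = TinyConvNet(hidden_channels=3, seed=4)
        model = ArtifactPredictor(net)
        x = rng.normal(size=(4, 4))
        want = conv_oracle(x, net)
        assert np.allclose(predict_artifact(model, x), want, atol=1e-6)


class TestTrainConfig:
    @pytest.mark.parametrize("kw", [dict(iterations=0), dict(gamma=0.0),
                                    dict(gamma=1.5), dict(n_subsets=1),
                                    dict(lr=-1.0)])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)

    def test_defaults_match_standard_settings(self):
        cfg = TrainConfig()
        assert (cfg.iterations, cfg.lr, cfg.step_size, cfg.gamma) == \
            (3000, 0.01, 1000, 0.6)


class TestFit:
    def test_history_length_equals_iterations(self, rng):
        a, b = rng.normal(size=(2, 8, 8))
        _, losses = fit((a, b), TrainConfig(iterations=40, seed=0))
        assert len(losses) == 40

    def test_total_equals_residual_plus_consistency(self, rng):
        a, b = rng.normal(size=(2, 8, 8))
        _, losses = fit((a, b), TrainConfig(iterations=30, seed=0))
        assert np.allclose(losses.total,
                           losses.residual + losses.consistency, rtol=1e-9)
        assert np.all(losses.total >= 0)

    def test_seeded_determinism(self, rng):
        a, b = rng.normal(size=(2, 8, 8))
        cfg = TrainConfig(iterations=25, seed=7)
        p1, _ = fit((a, b), cfg)
        p2, _ = fit((a, b), cfg)
        assert all(np.array_equal(p1.parameters[k], p2.parameters[k])
                   for k in p1.parameters)

    def test_equal_inputs_drive_prediction_to_zero(self, rng):
        x = rng.normal(size=(16, 16))
        model = ZSA2A(x, x, config=TrainConfig(iterations=250, seed=1))
        res = model.fit()
        assert res.losses.residual[-1] <= res.losses.residual[0]
        init = ArtifactPredictor(
            __import__("zsa2a.nn", fromlist=["TinyConvNet"]).TinyConvNet(48, seed=1))
        assert np.abs(res.predict(x)).mean() < np.abs(init.predict(x)).mean()

    def test_divergence_raises_with_history(self, rng):
        a, b = rng.normal(size=(2, 8, 8)) * 1e4
        with pytest.raises(TrainingDivergedError) as exc:
            fit((a, b), TrainConfig(iterations=400, seed=0, lr=1e38))
        assert len(exc.value.history) >= 1

    def test_summary_mentions_key_settings(self, rng):
        a, b = rng.normal(size=(2, 8, 8))
        res = ZSA2A(a, b, config=TrainConfig(iterations=20, seed=3)).fit()
        text = res.summary()
        assert "21313" in text and "20" in text


class TestDecompose:
    def test_zero_model_identity(self, rng):
        x = rng.normal(size=(8, 8))
        dec = decompose(x, ArtifactPredictor.zeros())
        assert np.array_equal(dec.clean.values, x)
        assert np.all(dec.artifact.values == 0)

    def test_conservation_bitwise(self, rng):
        from zsa2a.nn import TinyConvNet
        model = ArtifactPredictor(TinyConvNet(8, seed=2))
        x = rng.normal(size=(16, 16))
        dec = decompose(x, model)
        # construction form: artifact == source - clean, bitwise
        assert np.array_equal(dec.source.values - dec.clean.values,
                              dec.artifact.values)
        assert dec.conservation_error() == 0.0
        # addition form: exact to the final rounding
        resid = dec.clean.values + dec.artifact.values - x
        assert np.abs(resid).max() <= 2 * np.spacing(np.abs(x).max())

    def test_shape_mismatch_rejected(self, rng):
        bad = lambda v: np.zeros((3, 3))
        with pytest.raises(ValueError):
            decompose(rng.normal(size=(5, 5)), bad)


class TestSlicewise:
    def test_driver_contract(self, rng):
        shape = (12, 12, 3)
        vols = [ReconImage(rng.normal(size=shape)) for _ in range(3)]
        cfg = TrainConfig(iterations=15, seed=2, hidden_channels=8)
        dec, hists = run_zsa2a_slicewise(*vols, config=cfg, return_losses=True)
        assert dec.clean.shape == shape and dec.artifact.shape == shape
        assert len(hists) == 3 and all(len(h) == 15 for h in hists)
        assert np.array_equal(dec.source.values - dec.clean.values,
                              dec.artifact.values)

    def test_constant_volume_gives_tiny_artifact(self):
        const = ReconImage(np.full((12, 12, 2), 5.0))
        cfg = TrainConfig(iterations=300, seed=0, hidden_channels=8)
        dec = run_zsa2a_slicewise(const, const, const, config=cfg)
        assert np.abs(dec.artifact.values).mean() < 0.01 * np.abs(
            const.values).mean()

    def test_grid_mismatch_rejected(self, rng):
        a = ReconImage(rng.normal(size=(8, 8, 2)))
        b = ReconImage(rng.normal(size=(8, 8, 3)))
        with pytest.raises(ValueError):
            run_zsa2a_slicewise(a, a, b)

    def test_2d_input_rejected(self, rng):
        a = ReconImage(rng.normal(size=(8, 8)))
        with pytest.raises(ValueError):
            run_zsa2a_slicewise(a, a, a)

    def test_seeded_determinism(self, rng):
        vols = [ReconImage(rng.normal(size=(10, 10, 2))) for _ in range(3)]
        cfg = TrainConfig(iterations=20, seed=11, hidden_channels=8)
        d1 = run_zsa2a_slicewise(*vols, config=cfg)
        d2 = run_zsa2a_slicewise(*vols, config=cfg)
        assert np.array_equal(d1.clean.values, d2.clean.values)
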