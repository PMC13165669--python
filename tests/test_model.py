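"""Network architecture: block semantics, spectral attention, shape contracts."""

import dataclasses

import numpy as np
import pytest

from radarecg import autodiff as ad
from radarecg.autodiff import Tensor
from radarecg.model import (CNN_SCALES, CnnBlock, GatedFeedForward, Grmm,
                            GrmmLayer, Mfem, ModelConfig, RadarEcgNet, SaBlock,
                            TcnBlock, branch_receptive_field_s,
                            count_parameters, load_checkpoint, mse_loss,
                            receptive_field, rmse_loss, save_checkpoint,
                            spectral_mask)

RNG = np.random.default_rng(0)
TINY = ModelConfig(channels_branch=4, fusion_channels=8, d_model=8, n_heads=2,
                   d_head=4, m_layers=1, tcn_channels=8, tcn_dilations=(1, 2),
                   n_tcnsa_blocks=2, dropout=0.0)


class TestReceptiveFields:
    @pytest.mark.parametrize("scale,blocks,samples,seconds", [
        ("S", 4, 9, 0.10),    # 1 + 4*(3-1)*1, ~0.1 s
        ("M", 4, 25, 0.25),   # 1 + 4*(7-1)*1
        ("L", 4, 49, 0.50),   # 1 + 4*(7-1)*2, ~0.5 s
    ])
    def test_branch_receptive_field(self, scale, blocks, samples, seconds):
        assert receptive_field(scale, blocks) == samples
        assert branch_receptive_field_s(scale, blocks) == pytest.approx(seconds)

    def test_dilated_block_extent(self):
        k, _, d, _ = CNN_SCALES["L"]
        assert (k - 1) * d + 1 == 13


class TestCnnBlock:
    def test_boxcar_impulse_response(self):
        # raw convolution semantics: all-ones S kernel over an impulse
        w = Tensor(np.ones((1, 1, 3)))
        x = np.zeros((1, 1, 20))
        x[0, 0, 10] = 1.0
        y = ad.conv1d(Tensor(x), w, padding=1).data[0, 0]
        assert np.array_equal(np.flatnonzero(y), [9, 10, 11])

    @pytest.mark.parametrize("scale", ["S", "M", "L"])
    def test_length_preserving(self, scale):
        blk = CnnBlock(1, 3, scale, RNG)
        y = blk(Tensor(RNG.standard_normal((2, 1, 1000))))
        assert y.shape == (2, 3, 1000)

    def test_shift_equivariance_of_prepool_features(self):
        cfg = dataclasses.replace(TINY, dropout=0.0)
        mfem = Mfem(cfg, np.random.default_rng(1))
        mfem.eval()
        x = RNG.standard_normal((1, 1, 1000))
        shift = 4
        xs = np.roll(x, shift, axis=-1)
        f = mfem.features(Tensor(x)).data
        fs = mfem.features(Tensor(xs)).data
        core = slice(100, 900)
        assert np.allclose(np.roll(f, shift, axis=-1)[..., core],
                           fs[..., core], atol=1e-8)


class TestGrmm:
    def test_deterministic_without_dropout(self):
        cfg = dataclasses.replace(TINY, dropout=0.0)
        g = Grmm(cfg, np.random.default_rng(2))
        g.eval()
        x = Tensor(RNG.standard_normal((2, 1, 1000)))
        assert np.array_equal(g(x).data, g(x).data)

    def test_attention_rows_sum_to_one(self):
        scores = Tensor(RNG.standard_normal((2, 2, 7, 7)))
        s = ad.softmax(scores, axis=-1)
        assert np.abs(s.data.sum(axis=-1) - 1.0).max() < 1e-6

    def test_saturated_gate_reduces_to_residual_norm(self):
        # force the gate to 1: the gated FFN must return its input, so the
        # layer reduces to LN(XM + Dropout(XM)) = LN(2*XM) with dropout off
        layer = GrmmLayer(8, 2, 4, 0.0, np.random.default_rng(3))
        layer.eval()
        layer.ffn.wg2.b.data[:] = 50.0     # sigmoid saturates at 1
        x = Tensor(RNG.standard_normal((2, 5, 8)))
        xm = layer.ln1(x + layer.mhsa(x))
        expected = layer.ln2(xm + xm).data
        assert np.allclose(layer(x).data, expected, atol=1e-10)

    def test_output_length_and_channels(self):
        g = Grmm(TINY, np.random.default_rng(4))
        g.eval()
        y = g(Tensor(RNG.standard_normal((3, 1, 1000))))
        assert y.shape == (3, TINY.fusion_channels, 500)


class TestTcnBlock:
    def test_hand_computed_causal_convolution(self):
        blk = TcnBlock(1, 1, 3, 1, RNG)
        w = Tensor(np.ones((1, 1, 3)))
        x = Tensor(np.array([[[1.0, 2.0, 3.0, 4.0]]]))
        y = ad.conv1d(x, w, padding=(2, 0), dilation=1).data[0, 0]
        assert np.array_equal(y, [1.0, 3.0, 6.0, 9.0])

    def test_causality(self):
        blk = TcnBlock(1, 4, 3, 2, np.random.default_rng(5))
        blk.eval()
        a = RNG.standard_normal((1, 1, 50))
        b = a.copy()
        t0 = 30
        b[..., t0 + 1:] += RNG.standard_normal(49 - t0)
        ya = blk(Tensor(a)).data
        yb = blk(Tensor(b)).data
        assert np.allclose(ya[..., :t0 + 1], yb[..., :t0 + 1], atol=1e-12)
        assert not np.allclose(ya[..., t0 + 1:], yb[..., t0 + 1:])

    def test_impulse_response_support(self):
        k, d = 3, 4
        blk = TcnBlock(1, 1, k, d, np.random.default_rng(6))
        blk.eval()
        blk.res = None          # isolate the convolution path
        base = blk(Tensor(np.zeros((1, 1, 40)))).data
        x = np.zeros((1, 1, 40))
        x[0, 0, 5] = 1.0
        y = blk(Tensor(x)).data - base
        support = np.flatnonzero(np.abs(y[0, 0]) > 1e-12)
        assert support.min() >= 5
        assert support.max() <= 5 + (k - 1) * d


class TestSaBlock:
    def make(self, channels=1, fs=100.0):
        return SaBlock(channels, fs, (0.5, 40.0), 0.1, np.random.default_rng(7))

    def test_allpass_configuration_doubles_input(self):
        sa = self.make()
        y = Tensor(RNG.standard_normal((2, 1, 1000)))
        out = sa(y, unit_weights=True, mask_override=np.ones(501))
        assert np.abs(out.data - 2.0 * y.data).max() < 1e-9

    def test_out_of_band_tone_scaled_by_floor(self):
        sa = self.make()
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 45.0 * t)[None, None, :]
        out = sa(Tensor(x), unit_weights=True, residual=False).data[0, 0]
        ratio = (np.abs(np.fft.rfft(out))[450]
                 / np.abs(np.fft.rfft(x[0, 0]))[450])
        assert ratio == pytest.approx(0.1, abs=1e-12)

    def test_in_band_tone_and_phase_preserved(self):
        sa = self.make()
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 5.0 * t + 0.63)[None, None, :]
        out = sa(Tensor(x), unit_weights=True, residual=False).data
        assert np.abs(out - x).max() < 1e-6

    def test_output_is_real_and_length_preserving(self):
        sa = self.make(channels=3)
        y = Tensor(RNG.standard_normal((2, 3, 500)))
        out = sa(y)
        assert out.data.shape == (2, 3, 500)
        assert np.isrealobj(out.data)

    def test_mask_band_respects_nyquist(self):
        m = spectral_mask(500, 50.0, (0.5, 40.0), 0.1)
        f = np.fft.rfftfreq(500, d=1.0 / 50.0)
        assert m.shape == f.shape and f.max() == 25.0
        assert np.all(m[f < 0.5] == 0.1) and np.all(m[f >= 0.5] == 1.0)


class TestRadarEcgNet:
    @pytest.mark.parametrize("ablation", ["full", "model1", "model2",
                                          "model3", "model4"])
    def test_shape_contract_and_gradient_flow(self, ablation):
        net = RadarEcgNet(TINY.with_ablation(ablation), seed=1)
        x = Tensor(RNG.standard_normal((4, 1000)))
        y = net(x)
        assert y.shape == (4, 1000)
        loss = rmse_loss(y, Tensor(np.zeros((4, 1000))))
        net.zero_grad()
        loss.backward()
        for p in net.parameters():
            assert p.grad is not None and np.any(p.grad != 0.0)

    def test_ablation_routing_matches_variant_table(self):
        full = RadarEcgNet(TINY, seed=0)
        m1 = RadarEcgNet(TINY.with_ablation("model1"), seed=0)
        m2 = RadarEcgNet(TINY.with_ablation("model2"), seed=0)
        m3 = RadarEcgNet(TINY.with_ablation("model3"), seed=0)
        m4 = RadarEcgNet(TINY.with_ablation("model4"), seed=0)
        assert m1.grmm is None and m1.mfem is not None
        assert m2.mfem is None and m2.grmm is not None
        assert m3.fusion is None and m3.mfem is not None and m3.grmm is not None
        assert all(b.sa is None for b in m4.blocks)
        assert all(b.sa is not None for b in full.blocks)

    def test_parameter_count_monotonicity(self):
        n_full = count_parameters(RadarEcgNet(TINY, seed=0))
        for abl in ("model1", "model2"):
            assert n_full > count_parameters(
                RadarEcgNet(TINY.with_ablation(abl), seed=0))

    def test_decoder_causality_without_spectral_attention(self):
        cfg = TINY.with_ablation("model4")
        net = RadarEcgNet(cfg, seed=2)
        net.eval()
        x = RNG.standard_normal((1, 1000))
        f = net.encode(Tensor(x.reshape(1, 1, 1000)))
        f2_data = f.data.copy()
        t0 = 250
        f2_data[..., t0 + 1:] += 1.0

        def decode_pre_upsample(feat):
            y = net.dec_in(feat)
            f_fs = y
            for b in net.blocks:
                y = b(y)
            return (y + f_fs).data

        ya = decode_pre_upsample(Tensor(f.data))
        yb = decode_pre_upsample(Tensor(f2_data))
        assert np.allclose(ya[..., :t0 + 1], yb[..., :t0 + 1], atol=1e-10)

    def test_wrong_input_length_rejected(self):
        net = RadarEcgNet(TINY, seed=0)
        with pytest.raises(ValueError):
            net(Tensor(np.zeros((2, 999))))

    def test_checkpoint_round_trip(self, tmp_path):
        net = RadarEcgNet(TINY, seed=3)
        net.eval()
        x = Tensor(RNG.standard_normal((2, 1000)))
        y0 = net(x).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path, seed=3)
        net2, seed = load_checkpoint(path)
        net2.eval()
        assert seed == 3
        assert np.allclose(net2(x).data, y0, atol=1e-12)

    def test_single_epoch_decreases_loss(self):
        rng = np.random.default_rng(4)
        with ad.use_dtype(np.float32):
            net = RadarEcgNet(TINY, seed=5)
            X = Tensor(rng.standard_normal((32, 1000)))
            Y = Tensor(rng.standard_normal((32, 1000)) * 0.1)
            opt = ad.Adam(net.parameters(), lr=1e-3)
            first = None
            for _ in range(8):
                loss = rmse_loss(net(X), Y)
                if first is None:
                    first = float(loss.data)
                opt.zero_grad()
                loss.backward()
                opt.step()
            final = float(rmse_loss(net(X), Y).data)
        assert final < first


class TestLosses:
    def test_rmse_examples(self):
        a = Tensor(np.array([[1.0, 2.0, 3.0]]))
        b = Tensor(np.array([[1.0, 1.0, 1.0]]))
        assert float(rmse_loss(a, b).data) == pytest.approx(1.2910, abs=1e-4)
        assert float(rmse_loss(a, a).data) == pytest.approx(0.0, abs=1e-5)

    def test_constant_offset(self):
        a = Tensor(np.full((2, 10), 1.5))
        b = Tensor(np.zeros((2, 10)))
        assert float(rmse_loss(a, b).data) == pytest.approx(1.5, abs=1e-6)

    def test_mse_is_squared_scale(self):
        a = Tensor(np.full((1, 4), 2.0))
        b = Tensor(np.zeros((1, 4)))
        assert float(mse_loss(a, b).data) == pytest.approx(4.0)
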