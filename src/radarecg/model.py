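"""Multi-scale + global-attention encoder with a spectral-attention TCN decoder.

The network maps a 10-s, 100 Hz radar-derived cardiac mechanical signal
(length L = 1000) to the synchronized ECG waveform.  Encoder: two parallel
branches —

* **MFEM** (multi-scale feature extraction): three stacks of 1-D conv blocks
  with small / medium / large receptive fields (kernel, padding, dilation,
  stride = 3,1,1,1 / 7,3,1,1 / 7,6,2,1), capturing ~0.1 s wave details,
  ~0.25 s QRS-scale morphology and ~0.5 s rhythm context; branch outputs are
  channel-concatenated, fused by a two-stage convolution and max-pooled to
  length l = L/2;
* **GRMM** (global relation modeling): a lightweight transformer — learnable
  positional encoding, multi-head self-attention and a sigmoid-gated
  feed-forward stage, then time-pooled to length l;

a convolutional fusion unit merges the two streams.  Decoder: stacked blocks
pairing a causal dilated temporal convolution (TCN) with spectral attention
(SA) — an FFT-domain amplitude mask that keeps the clinically relevant
0.5-40 Hz ECG band at unit gain and floors everything else at 0.1, modulated
by a learned per-bin channel attention, recombined with the original phase —
followed by a residual connection and 2x linear-interpolation upsampling back
to length L.

Ablation toggles reproduce the reduced variants: encoder MFEM-only,
GRMM-only, sequential MFEM->GRMM, and a decoder without SA.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ModelConfig", "CnnBlock", "Mfem", "Grmm", "FusionUnit", "TcnBlock",
           "SaBlock", "RadarEcgNet", "rmse_loss", "mse_loss", "receptive_field",
           "branch_receptive_field_s", "CNN_SCALES", "save_checkpoint",
           "load_checkpoint", "count_parameters"]

#: (kernel, padding, dilation, stride) per branch scale.
CNN_SCALES = {"S": (3, 1, 1, 1), "M": (7, 3, 1, 1), "L": (7, 6, 2, 1)}


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter plus the ablation toggles."""

    L: int = 1000                 # input length (10 s at 100 Hz)
    l: int = 500                  # encoder output length
    channels_branch: int = 16     # per-branch conv width
    n_blocks_s: int = 4
    n_blocks_m: int = 4
    n_blocks_l: int = 4
    fusion_channels: int = 32     # encoder output channels
    d_model: int = 64             # GRMM embedding width
    n_heads: int = 4
    d_head: int = 16
    m_layers: int = 2             # GRMM depth
    dropout: float = 0.1
    grmm_pool_pre: int = 1        # time pooling applied before attention (1 = none)
    tcn_channels: int = 64
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4)
    n_tcnsa_blocks: int = 3
    mask_band: tuple[float, float] = (0.5, 40.0)   # Hz
    mask_floor: float = 0.1
    fs_effective: float = 50.0    # Hz of the sequence entering SA (length l over 10 s)
    loss: str = "rmse"            # "rmse" (root form) or "mse"
    use_mfem: bool = True
    use_grmm: bool = True
    parallel: bool = True
    use_sa: bool = True

    def validate(self) -> None:
        counts = (self.channels_branch, self.n_blocks_s, self.n_blocks_m,
                  self.n_blocks_l, self.fusion_channels, self.d_model,
                  self.n_heads, self.d_head, self.m_layers, self.tcn_channels,
                  self.tcn_kernel, self.n_tcnsa_blocks, self.grmm_pool_pre)
        if any(c < 1 for c in counts):
            raise ValueError("all architecture counts must be >= 1")
        if not (0.0 < self.mask_floor < 1.0):
            raise ValueError("mask_floor must lie in (0, 1)")
        if self.L != 2 * self.l:
            raise ValueError("encoder halves the length: L must equal 2*l")
        if not self.parallel and not (self.use_mfem and self.use_grmm):
            raise ValueError("sequential routing needs both encoder branches")
        if self.loss not in ("rmse", "mse"):
            raise ValueError("loss must be 'rmse' or 'mse'")

    def with_ablation(self, name: str) -> "ModelConfig":
        """Named variants: full, model1 (MFEM only), model2 (GRMM only),
        model3 (sequential MFEM->GRMM), model4 (no spectral attention)."""
        table = {
            "full": {},
            "model1": {"use_grmm": False},
            "model2": {"use_mfem": False},
            "model3": {"parallel": False},
            "model4": {"use_sa": False},
        }
        if name not in table:
            raise ValueError(f"unknown ablation {name!r}")
        base = {"use_mfem": True, "use_grmm": True, "parallel": True,
                "use_sa": True}
        base.update(table[name])
        return dataclasses.replace(self, **base)

    @staticmethod
    def desk_scale() -> "ModelConfig":
        """Reduced-width configuration for CPU-scale experiments."""
        return ModelConfig(channels_branch=8, fusion_channels=16, d_model=16,
                           n_heads=2, d_head=8, m_layers=1, grmm_pool_pre=4,
                           tcn_channels=16, tcn_dilations=(1, 2),
                           n_tcnsa_blocks=2, dropout=0.05)


def receptive_field(scale: str, n_blocks: int) -> int:
    """Composite receptive field in samples of a stacked conv branch."""
    k, _, d, _ = CNN_SCALES[scale]
    return 1 + n_blocks * (k - 1) * d


def branch_receptive_field_s(scale: str, n_blocks: int, fs: float = 100.0,
                             round_to: float = 0.05) -> float:
    """Receptive field in seconds, rounded to the nearest ``round_to``."""
    rf = receptive_field(scale, n_blocks) / fs
    return round(rf / round_to) * round_to


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class CnnBlock(ad.Module):
    """Conv1d (scale-specific geometry) + batch norm + ReLU, length-preserving."""

    def __init__(self, c_in: int, c_out: int, scale: str,
                 rng: np.random.Generator):
        super().__init__()
        k, p, d, _ = CNN_SCALES[scale]
        self.conv = ad.Conv1d(c_in, c_out, k, rng, padding=p, dilation=d)
        self.bn = ad.BatchNorm1d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(self.bn(self.conv(x)))


class Mfem(ad.Module):
    """Three parallel multi-scale conv branches, fused and pooled to length l."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels_branch

        def branch(scale: str, n: int) -> ad.Sequential:
            blocks = [CnnBlock(1 if i == 0 else c, c, scale, rng)
                      for i in range(n)]
            return ad.Sequential(*blocks)

        self.branch_s = branch("S", cfg.n_blocks_s)
        self.branch_m = branch("M", cfg.n_blocks_m)
        self.branch_l = branch("L", cfg.n_blocks_l)
        self.fuse1 = ad.Conv1d(3 * c, cfg.fusion_channels, 1, rng)
        self.fuse2 = ad.Conv1d(cfg.fusion_channels, cfg.fusion_channels, 1, rng)

    def features(self, x: Tensor) -> Tensor:
        """Pre-pooling fused features at full input length."""
        cat = ad.concat([self.branch_s(x), self.branch_m(x), self.branch_l(x)],
                        axis=1)
        return self.fuse2(ad.relu(self.fuse1(cat)))

    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool1d_k2(self.features(x))


class MultiHeadSelfAttention(ad.Module):
    def __init__(self, d_model: int, n_heads: int, d_head: int,
                 rng: np.random.Generator):
        super().__init__()
        self.h, self.dh = n_heads, d_head
        self.wq = ad.Linear(d_model, n_heads * d_head, rng)
        self.wk = ad.Linear(d_model, n_heads * d_head, rng)
        self.wv = ad.Linear(d_model, n_heads * d_head, rng)
        self.wo = ad.Linear(n_heads * d_head, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        att = ad.softmax(scores, axis=-1)
        out = att.matmul(v).transpose(0, 2, 1, 3).reshape(B, T, self.h * self.dh)
        return self.wo(out)


class GatedFeedForward(ad.Module):
    """Sigmoid-gated FFN: the gate multiplicatively reweights the features."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.wg1 = ad.Linear(d_model, d_model, rng)
        self.wg2 = ad.Linear(d_model, d_model, rng)

    def gate(self, x: Tensor) -> Tensor:
        return ad.sigmoid(self.wg2(ad.relu(self.wg1(x))))

    def forward(self, x: Tensor) -> Tensor:
        return self.gate(x) * x


class GrmmLayer(ad.Module):
    def __init__(self, d_model: int, n_heads: int, d_head: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.mhsa = MultiHeadSelfAttention(d_model, n_heads, d_head, rng)
        self.ln1 = ad.LayerNorm(d_model)
        self.ffn = GatedFeedForward(d_model, rng)
        self.ln2 = ad.LayerNorm(d_model)
        self.drop1 = ad.Dropout(dropout, np.random.default_rng(rng.integers(2 ** 31)))
        self.drop2 = ad.Dropout(dropout, np.random.default_rng(rng.integers(2 ** 31)))

    def forward(self, x: Tensor) -> Tensor:
        xm = self.ln1(x + self.drop1(self.mhsa(x)))
        return self.ln2(xm + self.drop2(self.ffn(xm)))


class Grmm(ad.Module):
    """Transformer branch: embed, positional encoding, attention layers, pool.

    ``t_in`` is the input length; attention runs at ``t_in // pool_pre`` and
    the output is resized to ``t_out`` (average-pooling down or linear
    upsampling by 2 where needed) with channels projected to ``c_out``.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 c_in: int = 1, t_in: int | None = None,
                 t_out: int | None = None):
        super().__init__()
        t_in = cfg.L if t_in is None else t_in
        self.t_out = cfg.l if t_out is None else t_out
        self.pool_pre = cfg.grmm_pool_pre if t_in % cfg.grmm_pool_pre == 0 else 1
        self.t_att = t_in // self.pool_pre
        d = cfg.d_model
        self.embed = ad.Linear(c_in, d, rng)
        self.pos = Tensor.param(rng.standard_normal((1, self.t_att, d)) * 0.02)
        self.drop = ad.Dropout(cfg.dropout,
                               np.random.default_rng(rng.integers(2 ** 31)))
        self.layers = [GrmmLayer(d, cfg.n_heads, cfg.d_head, cfg.dropout, rng)
                       for _ in range(cfg.m_layers)]
        self.proj = ad.Linear(d, cfg.fusion_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, C_in, T) -> tokens (B, T, C_in)
        tokens = x.transpose(0, 2, 1)
        z = self.embed(tokens)                      # (B, T, d)
        if self.pool_pre > 1:
            B, T, d = z.shape
            z = z.reshape(B, T // self.pool_pre, self.pool_pre, d).mean(axis=2)
        z = self.drop(z + self.pos)
        for layer in self.layers:
            z = layer(z)
        z = self.proj(z).transpose(0, 2, 1)         # (B, c_out, t_att)
        t = z.shape[-1]
        while t > self.t_out:
            if t % 2:
                raise ValueError("cannot pool odd length")
            z = ad.avgpool1d(z, 2)
            t //= 2
        while t < self.t_out:
            z = ad.upsample_linear_2x(z)
            t *= 2
        return z


class FusionUnit(ad.Module):
    """Project each stream, concatenate, compress and fuse (conv + BN + ReLU)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.wm = ad.Conv1d(channels, channels, 1, rng)
        self.wg = ad.Conv1d(channels, channels, 1, rng)
        self.wc = ad.Conv1d(2 * channels, channels, 1, rng)
        self.bn = ad.BatchNorm1d(channels)
        self.wf = ad.Conv1d(channels, channels, 1, rng)

    def forward(self, fm: Tensor, fg: Tensor) -> Tensor:
        if fm.shape[-1] != fg.shape[-1]:
            raise ValueError("fusion inputs must share the temporal length")
        cat = ad.concat([ad.relu(self.wm(fm)), ad.relu(self.wg(fg))], axis=1)
        return self.wf(ad.relu(self.bn(self.wc(cat))))


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------

class TcnBlock(ad.Module):
    """Causal dilated convolution + BN + ReLU with a residual connection."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = ad.Conv1d(c_in, c_out, k, rng,
                              padding=((k - 1) * dilation, 0), dilation=dilation)
        self.bn = ad.BatchNorm1d(c_out)
        self.res = ad.Conv1d(c_in, c_out, 1, rng) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        y = ad.relu(self.bn(self.conv(x)))
        return y + (self.res(x) if self.res is not None else x)


def spectral_mask(n: int, fs: float, band: tuple[float, float],
                  floor: float) -> np.ndarray:
    """Band mask on the real-FFT bin frequencies (bins above the
    Nyquist simply do not exist)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.where((f >= band[0]) & (f <= band[1]), 1.0, floor)


class SaBlock(ad.Module):
    """Spectral attention: FFT -> band mask x learned channel weights -> IFFT.

    The amplitude spectrum is reweighted while the phase is preserved; a
    residual connection adds the block input back, so the all-pass setting
    (mask = 1, weights forced to 1) returns exactly twice the input.
    """

    def __init__(self, channels: int, fs_effective: float,
                 band: tuple[float, float], floor: float,
                 rng: np.random.Generator):
        super().__init__()
        self.fs_effective = fs_effective
        self.band = band
        self.floor = floor
        hidden = max(channels // 2, 4)
        self.conv1 = ad.Conv1d(channels, hidden, 5, rng, padding=2)
        self.bn = ad.BatchNorm1d(hidden)
        self.conv2 = ad.Conv1d(hidden, channels, 5, rng, padding=2)

    def attention_weights(self, amp: Tensor) -> Tensor:
        return ad.sigmoid(self.conv2(ad.relu(self.bn(self.conv1(amp)))))

    def forward(self, y: Tensor, unit_weights: bool = False,
                residual: bool = True, mask_override: np.ndarray | None = None,
                ) -> Tensor:
        n = y.shape[-1]
        re, im = ad.rfft_split(y)
        mask = (mask_override if mask_override is not None
                else spectral_mask(n, self.fs_effective, self.band, self.floor))
        if unit_weights:
            gain = Tensor(np.broadcast_to(mask, re.shape).copy())
        else:
            amp = (re * re + im * im + 1e-12).sqrt()
            gain = self.attention_weights(amp) * Tensor(mask)
        s_hat = ad.irfft_join(re * gain, im * gain, n=n)
        return s_hat + y if residual else s_hat


class TcnSaBlock(ad.Module):
    def __init__(self, channels: int, k: int, dilation: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.tcn = TcnBlock(channels, channels, k, dilation, rng)
        self.sa = (SaBlock(channels, cfg.fs_effective, cfg.mask_band,
                           cfg.mask_floor, rng) if cfg.use_sa else None)

    def forward(self, x: Tensor) -> Tensor:
        y = self.tcn(x)
        return self.sa(y) if self.sa is not None else y


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class RadarEcgNet(ad.Module):
    """Encoder-decoder ECG reconstructor; see the module docstring."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.fusion_channels
        self.mfem = Mfem(cfg, rng) if cfg.use_mfem else None
        if cfg.use_grmm:
            if cfg.parallel or not cfg.use_mfem:
                self.grmm = Grmm(cfg, rng, c_in=1, t_in=cfg.L, t_out=cfg.l)
            else:   # sequential: GRMM consumes MFEM features at length l
                self.grmm = Grmm(cfg, rng, c_in=c, t_in=cfg.l, t_out=cfg.l)
        else:
            self.grmm = None
        self.fusion = (FusionUnit(c, rng)
                       if (cfg.use_mfem and cfg.use_grmm and cfg.parallel)
                       else None)
        self.dec_in = ad.Conv1d(c, cfg.tcn_channels, 1, rng)
        dil = cfg.tcn_dilations
        self.blocks = [TcnSaBlock(cfg.tcn_channels, cfg.tcn_kernel,
                                  dil[i % len(dil)], cfg, rng)
                       for i in range(cfg.n_tcnsa_blocks)]
        self.dec_out = ad.Conv1d(cfg.tcn_channels, 1, 1, rng)

    def encode(self, x: Tensor) -> Tensor:
        if self.mfem is not None and self.grmm is not None:
            if self.cfg.parallel:
                return self.fusion(self.mfem(x), self.grmm(x))
            return self.grmm(self.mfem(x))
        if self.mfem is not None:
            return self.mfem(x)
        return self.grmm(x)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 2 or x.shape[1] != self.cfg.L:
            raise ValueError(f"expected input (batch, {self.cfg.L})")
        B = x.shape[0]
        f = self.encode(x.reshape(B, 1, self.cfg.L))
        f_fs = self.dec_in(f)
        y = f_fs
        for block in self.blocks:
            y = block(y)
        y = y + f_fs
        y = self.dec_out(y)
        return ad.upsample_linear_2x(y).reshape(B, self.cfg.L)


def count_parameters(model: ad.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def rmse_loss(ecg_hat: Tensor, ecg: Tensor) -> Tensor:
    """Per-segment root-mean-square error, averaged over the batch."""
    d = ecg_hat - ecg
    return ((d * d).mean(axis=-1) + 1e-12).sqrt().mean()


def mse_loss(ecg_hat: Tensor, ecg: Tensor) -> Tensor:
    d = ecg_hat - ecg
    return (d * d).mean()


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RadarEcgNet, path, seed: int | None = None) -> None:
    """Single-file parameter store with the embedded config and seed."""
    cfg_json = json.dumps(dataclasses.asdict(model.cfg))
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             __seed__=np.array([-1 if seed is None else seed]), **arrays)


def load_checkpoint(path) -> tuple[RadarEcgNet, int | None]:
    with np.load(path) as z:
        cfg_d = json.loads(bytes(z["__config__"]).decode())
        for key in ("tcn_dilations", "mask_band"):
            cfg_d[key] = tuple(cfg_d[key])
        seed = int(z["__seed__"][0])
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 2)]
    cfg = ModelConfig(**cfg_d)
    model = RadarEcgNet(cfg, seed=0)
    model.load_state_arrays(arrays)
    return model, (None if seed == -1 else seed)
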