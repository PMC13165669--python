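"""Cardiac-motion separation and ECG cleaning.

Radar path: the demodulated chest displacement mixes respiration (~0.1-0.5 Hz
plus harmonics) with the much smaller cardiac micro-motion.  A maximal-overlap
(shift-invariant, non-decimated) discrete wavelet transform with the db4
wavelet splits the trace into additive detail levels; levels are kept when at
least half of their periodogram energy falls inside a cardiac band (default
0.8-10 Hz: fundamental plus harmonics), with a nominal-band fallback when no
level qualifies.  The retained sum is then smoothed by an innovation-adaptive
scalar Kalman filter whose measurement-noise covariance is re-estimated online
with exponential forgetting and whose process noise is loosened around cardiac
transients.

ECG path: a fifth-order least-squares polynomial removes baseline wander, and
MAD-calibrated universal soft thresholding of wavelet detail coefficients
suppresses electrode noise.

All wavelet transforms use reflection boundary handling (signals are
reflect-padded to a power-of-two multiple where the shift-invariant transform
requires it) so segment edges do not ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

__all__ = ["ModwtDecomposition", "AkfConfig", "modwt_decompose",
           "modwt_suppress_respiration", "akf_filter", "ecg_remove_baseline",
           "ecg_wavelet_denoise", "preprocess_radar", "preprocess_ecg"]


class DecompositionError(ValueError):
    """Raised when a wavelet decomposition is infeasible for the input."""


@dataclass
class ModwtDecomposition:
    """Additive shift-invariant wavelet decomposition of one trace.

    ``details[j-1]`` holds level D_j (fine j=1 ... coarse j=J); ``smooth`` is
    S_J.  All components have the input length and sum to the input exactly.
    ``level_band(j)`` is the nominal dyadic frequency interval of D_j.
    """

    details: list[np.ndarray]
    smooth: np.ndarray
    wavelet_name: str
    J: int
    fs: float

    def level_band(self, j: int) -> tuple[float, float]:
        return (self.fs / 2.0 ** (j + 1), self.fs / 2.0 ** j)

    def reconstruct(self) -> np.ndarray:
        return self.smooth + np.sum(self.details, axis=0)


def modwt_decompose(x: np.ndarray, wavelet: str = "db4", J: int = 6,
                    fs: float = 100.0) -> ModwtDecomposition:
    """Shift-invariant additive wavelet decomposition (db4 default, J levels).

    Inputs of arbitrary length are reflect-padded to the next multiple of
    ``2**J`` and the components trimmed back, which preserves exact
    additivity at the retained samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if J < 1:
        raise DecompositionError("J must be >= 1")
    block = 2 ** J
    if n < pywt.Wavelet(wavelet).dec_len or 2 ** J > n:
        raise DecompositionError(f"signal of length {n} too short for J={J}")
    pad = (-n) % block
    if pad:
        xp = np.pad(x, (0, pad), mode="reflect")
    else:
        xp = x
    comps = pywt.mra(xp, wavelet, J, transform="swt")
    # pywt.mra ordering: [S_J, D_J, ..., D_1]
    smooth = comps[0][:n]
    details = [comps[-j][:n] for j in range(1, J + 1)]   # D_1 ... D_J
    return ModwtDecomposition(details=details, smooth=smooth,
                              wavelet_name=wavelet, J=J, fs=fs)


def _band_energy_fraction(level: np.ndarray, fs: float,
                          band: tuple[float, float]) -> float:
    f, p = sps.periodogram(level, fs=fs)
    total = p.sum()
    if total <= 0:
        return 0.0
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].sum() / total)


def modwt_suppress_respiration(x: np.ndarray, wavelet: str = "db4", J: int = 6,
                               cardiac_band: tuple[float, float] = (0.8, 10.0),
                               fs: float = 100.0,
                               ) -> tuple[np.ndarray, list[int]]:
    """Suppress respiration by keeping cardiac-dominated wavelet levels.

    Primary rule: keep detail levels with >= 50% of their periodogram energy
    inside ``cardiac_band``.  Fallback (no level qualifies): keep levels whose
    nominal dyadic band intersects the cardiac band.  The smooth (respiratory
    trend) is always discarded.

    Returns ``(x_cardiac, selected_levels)`` with 1-based level indices.
    """
    dec = modwt_decompose(x, wavelet=wavelet, J=J, fs=fs)
    selected = [j for j in range(1, J + 1)
                if _band_energy_fraction(dec.details[j - 1], fs, cardiac_band) >= 0.5]
    if not selected:
        selected = [j for j in range(1, J + 1)
                    if dec.level_band(j)[0] < cardiac_band[1]
                    and dec.level_band(j)[1] > cardiac_band[0]]
    x_card = np.sum([dec.details[j - 1] for j in selected], axis=0) \
        if selected else np.zeros_like(np.asarray(x, dtype=float))
    return x_card, selected


# ---------------------------------------------------------------------------
# Adaptive Kalman filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AkfConfig:
    """Innovation-adaptive scalar Kalman filter settings.

    The state is the true displacement under a random-walk transition.  The
    measurement-noise covariance r is re-estimated from innovations with
    exponential forgetting (factor close to 1); the process noise q is scaled
    by ``1 + cardiac_freq_weight * b(t)`` where b(t) is the normalized
    amplitude of the input band-passed around ``cardiac_freq_est`` +- 0.3 Hz,
    so the filter tracks more loosely during cardiac transients.
    """

    q0: float = 1e-3
    r0: float = 1e-2
    forgetting: float = 0.99
    cardiac_freq_weight: float = 0.3
    cardiac_freq_est: float = 1.2      # Hz
    fs: float = 100.0

    def validate(self) -> None:
        if not (0.0 < self.forgetting <= 1.0):
            raise ValueError("forgetting must lie in (0, 1]")
        if self.q0 <= 0 or self.r0 <= 0:
            raise ValueError("covariances must be positive")
        if not (0.0 <= self.cardiac_freq_weight <= 1.0):
            raise ValueError("cardiac_freq_weight must lie in [0, 1]")


def _cardiac_envelope(x: np.ndarray, cfg: AkfConfig) -> np.ndarray:
    """Normalized amplitude of x band-passed around the cardiac frequency."""
    lo = max(cfg.cardiac_freq_est - 0.3, 0.05)
    hi = min(cfg.cardiac_freq_est + 0.3, 0.49 * cfg.fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=cfg.fs, output="sos")
    env = np.abs(sps.sosfiltfilt(sos, x))
    m = env.max()
    return env / m if m > 0 else env


def akf_filter(x: np.ndarray, cfg: AkfConfig | None = None) -> np.ndarray:
    """Adaptive Kalman smoothing of a displacement trace.

    With ``forgetting=1`` and ``cardiac_freq_weight=0`` this reduces exactly
    to the fixed-covariance scalar Kalman filter run with (q0, r0).
    """
    cfg = cfg if cfg is not None else AkfConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = x.size
    if cfg.cardiac_freq_weight > 0:
        b = _cardiac_envelope(x, cfg)
    else:
        b = np.zeros(n)
    eps = 1e-12
    xf = np.empty(n)
    state = x[0]
    P = cfg.r0
    r = cfg.r0
    lam = cfg.forgetting
    for k in range(n):
        q_k = cfg.q0 * (1.0 + cfg.cardiac_freq_weight * b[k])
        P_pred = P + q_k
        innov = x[k] - state
        if lam < 1.0:
            r = lam * r + (1.0 - lam) * max(innov * innov - P_pred, eps)
        K = P_pred / (P_pred + r)
        state = state + K * innov
        P = (1.0 - K) * P_pred
        xf[k] = state
    return xf


# ---------------------------------------------------------------------------
# ECG cleaning
# ---------------------------------------------------------------------------

def ecg_remove_baseline(ecg: np.ndarray, order: int = 5) -> np.ndarray:
    """Subtract an order-``order`` least-squares polynomial baseline fit."""
    ecg = np.asarray(ecg, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if ecg.size <= order + 1:
        raise ValueError("signal too short for the requested polynomial order")
    fit = np.polynomial.Polynomial.fit(np.linspace(-1.0, 1.0, ecg.size), ecg, order)
    return ecg - fit(np.linspace(-1.0, 1.0, ecg.size))


def ecg_wavelet_denoise(ecg: np.ndarray, wavelet: str = "db4",
                        J: int = 4) -> np.ndarray:
    """Universal soft-threshold wavelet denoising.

    Noise sd is the MAD of the finest detail coefficients
    (``median(|d1|)/0.6745``); the threshold is ``sigma*sqrt(2 ln N)`` and is
    applied by soft shrinkage to every detail level, leaving the
    approximation untouched.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    coeffs = pywt.wavedec(ecg, wavelet, level=J, mode="symmetric")
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    out = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(out, wavelet, mode="symmetric")[:n]


# ---------------------------------------------------------------------------
# Segment-level pipelines
# ---------------------------------------------------------------------------

def preprocess_radar(x: np.ndarray, fs: float = 100.0,
                     wavelet: str = "db4", J: int = 6,
                     cardiac_band: tuple[float, float] = (0.8, 10.0),
                     akf: AkfConfig | None = None) -> np.ndarray:
    """Displacement -> cardiac mechanical signal (respiration suppressed, AKF-smoothed)."""
    x_card, _ = modwt_suppress_respiration(x, wavelet=wavelet, J=J,
                                           cardiac_band=cardiac_band, fs=fs)
    return akf_filter(x_card, akf if akf is not None else AkfConfig(fs=fs))


def preprocess_ecg(ecg: np.ndarray, order: int = 5, wavelet: str = "db4",
                   J: int = 4) -> np.ndarray:
    """Ground-truth ECG cleaning: baseline removal then wavelet denoising."""
    return ecg_wavelet_denoise(ecg_remove_baseline(ecg, order=order),
                               wavelet=wavelet, J=J)
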