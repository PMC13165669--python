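"""Morphological metrics, ECG wave localization and report aggregation.

Morphology is scored by the Pearson correlation coefficient (PCC), RMSE and
MAE between the reconstructed and ground-truth ECG.  Wave timing is scored by
detecting Q/R/S/T peaks in both traces with the same detector and taking the
absolute time difference between matched peaks; the summary reports the
median and 90th percentile per wave, per-scenario breakdowns and CDF tables.

The default wave detector is a built-in Pan-Tompkins-style R detector
(bandpass, squared derivative, moving-window integration, adaptive threshold
with refractory period) with Q/S as local extrema flanking R and T as the
maximum in a post-R window.  ``detect_waves`` accepts any callable with the
same signature, so an external ECG toolkit can be plugged in for parity
checks; everything in this package uses the built-in detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = ["WaveAnnotation", "EvalReport", "UndefinedMetricError", "pcc",
           "mae", "rmse", "detect_waves", "detect_r_peaks",
           "localization_errors", "summarize", "evaluate_segments",
           "WAVE_NAMES"]

WAVE_NAMES = ("q", "r", "s", "t")


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# Morphological metrics
# ---------------------------------------------------------------------------

def pcc(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length traces."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("inputs must have equal length")
    a = y_hat - y_hat.mean()
    b = y - y.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0.0 or nb == 0.0:
        raise UndefinedMetricError("zero variance input")
    return float((a * b).sum() / (na * nb))


def mae(y_hat: np.ndarray, y: np.ndarray) -> float:
    y_hat, y = np.asarray(y_hat, float), np.asarray(y, float)
    if y_hat.shape != y.shape:
        raise ValueError("inputs must have equal length")
    return float(np.mean(np.abs(y_hat - y)))


def rmse(y_hat: np.ndarray, y: np.ndarray) -> float:
    y_hat, y = np.asarray(y_hat, float), np.asarray(y, float)
    if y_hat.shape != y.shape:
        raise ValueError("inputs must have equal length")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


# ---------------------------------------------------------------------------
# Wave detection
# ---------------------------------------------------------------------------

@dataclass
class WaveAnnotation:
    """Per-beat Q/R/S/T peak times (seconds) for one ECG trace."""

    q_times: np.ndarray
    r_times: np.ndarray
    s_times: np.ndarray
    t_times: np.ndarray

    def times(self, wave: str) -> np.ndarray:
        return getattr(self, f"{wave}_times")

    @property
    def n_beats(self) -> int:
        return len(self.r_times)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style R peak indices.

    Bandpass 5-20 Hz, differentiate, square, 150 ms moving-window integration,
    adaptive-threshold peak picking with a 250 ms refractory period, then
    refinement to the raw-trace extremum within +-40 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    if n < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    sos = sps.butter(3, [5.0, 20.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.250 * fs))
    thr = 0.30 * mwi.max()
    cand, _ = sps.find_peaks(mwi, height=thr, distance=refractory)
    # adaptive refinement: re-threshold against the running peak level
    if cand.size:
        level = np.median(mwi[cand])
        cand = cand[mwi[cand] > 0.25 * level]

    half = int(round(0.040 * fs))
    polarity = 1.0 if np.abs(ecg.max()) >= np.abs(ecg.min()) else -1.0
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        peaks.append(lo + int(np.argmax(polarity * ecg[lo:hi])))
    peaks = sorted(set(peaks))
    # enforce refractory after refinement
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < refractory:
            if polarity * ecg[p] > polarity * ecg[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=int)


def _default_detector(ecg: np.ndarray, fs: float) -> WaveAnnotation:
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    r_idx = detect_r_peaks(ecg, fs)
    q_t, r_t, s_t, t_t = [], [], [], []
    w60 = int(round(0.060 * fs))
    t_lo, t_hi = int(round(0.100 * fs)), int(round(0.400 * fs))
    for r in r_idx:
        lo = max(r - w60, 0)
        hi = min(r + w60 + 1, n)
        if lo >= r or r + 1 >= hi:
            continue
        q = lo + int(np.argmin(ecg[lo:r]))
        s = r + 1 + int(np.argmin(ecg[r + 1:hi]))
        ta, tb = r + t_lo, min(r + t_hi, n)
        if tb <= ta:
            continue
        t = ta + int(np.argmax(ecg[ta:tb]))
        q_t.append(q / fs)
        r_t.append(r / fs)
        s_t.append(s / fs)
        t_t.append(t / fs)
    return WaveAnnotation(np.asarray(q_t), np.asarray(r_t),
                          np.asarray(s_t), np.asarray(t_t))


def detect_waves(ecg: np.ndarray, fs: float,
                 detector: Callable[[np.ndarray, float], WaveAnnotation] | None = None,
                 ) -> WaveAnnotation:
    """Q/R/S/T peak times for one ECG trace.

    Within each detected beat q < r < s < t; a flat or beat-free trace yields
    an empty annotation.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.std() == 0.0:
        empty = np.asarray([], dtype=float)
        return WaveAnnotation(empty, empty.copy(), empty.copy(), empty.copy())
    det = detector if detector is not None else _default_detector
    return det(ecg, fs)


# ---------------------------------------------------------------------------
# Localization errors
# ---------------------------------------------------------------------------

def _match_peaks(ref: np.ndarray, rec: np.ndarray,
                 window: float) -> tuple[list[float], int]:
    """Greedy nearest-pair matching within +-window.

    Candidate (ref, rec) pairs are ranked by |dt| and accepted greedily, each
    peak used at most once.  Returns (absolute errors, miss count of
    unmatched reference peaks).
    """
    pairs = [(abs(rf - rc), i, j)
             for i, rf in enumerate(ref) for j, rc in enumerate(rec)
             if abs(rf - rc) <= window]
    pairs.sort()
    used_ref: set[int] = set()
    used_rec: set[int] = set()
    errors: list[float] = []
    for d, i, j in pairs:
        if i in used_ref or j in used_rec:
            continue
        used_ref.add(i)
        used_rec.add(j)
        errors.append(d)
    return errors, len(ref) - len(used_ref)


def localization_errors(ann_hat: WaveAnnotation, ann_ref: WaveAnnotation,
                        match_window: float = 0.15,
                        ) -> tuple[dict[str, list[float]], dict[str, int]]:
    """Per-wave absolute timing errors between two annotations.

    Reconstructed peaks are matched to reference peaks greedily by proximity
    within ``match_window`` seconds; unmatched reference peaks are counted as
    misses and excluded from the error lists.
    """
    errors: dict[str, list[float]] = {}
    misses: dict[str, int] = {}
    for w in WAVE_NAMES:
        e, m = _match_peaks(ann_ref.times(w), ann_hat.times(w), match_window)
        errors[w] = e
        misses[w] = m
    return errors, misses


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _cdf_table(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": v,
                         "cum_fraction": np.arange(1, v.size + 1) / v.size})


@dataclass
class EvalReport:
    """Aggregated evaluation results.

    ``per_segment`` rows: segment index, subject, scenario, pcc, rmse, mae.
    ``wave_errors``: per-wave pooled absolute timing errors (seconds).
    """

    per_segment: pd.DataFrame
    wave_errors: dict[str, np.ndarray]
    wave_misses: dict[str, int]
    mean_pcc: float
    mean_rmse: float
    mean_mae: float
    wave_stats: pd.DataFrame            # wave, median, p90, n, misses
    per_scenario: pd.DataFrame          # scenario, metric means
    cdf: dict[str, pd.DataFrame]        # metric -> CDF table
    n_excluded: int = 0                 # zero-variance segments left out of PCC

    def to_tables(self) -> dict[str, pd.DataFrame]:
        out = {"per_segment": self.per_segment, "wave_stats": self.wave_stats,
               "per_scenario": self.per_scenario}
        for k, v in self.cdf.items():
            out[f"cdf_{k}"] = v
        return out


def _percentile(values: np.ndarray, q: float) -> float:
    # linear interpolation between closest ranks (numpy default convention)
    return float(np.percentile(values, q)) if len(values) else float("nan")


def summarize(per_segment: pd.DataFrame,
              wave_errors: dict[str, list[float]],
              wave_misses: dict[str, int] | None = None,
              n_excluded: int = 0) -> EvalReport:
    """Build an :class:`EvalReport` from per-segment metrics and wave errors."""
    if len(per_segment) < 1:
        raise ValueError("need at least one segment")
    wave_misses = wave_misses or {w: 0 for w in WAVE_NAMES}
    we = {w: np.asarray(wave_errors.get(w, []), dtype=float) for w in WAVE_NAMES}
    wave_stats = pd.DataFrame([
        {"wave": w, "median": _percentile(we[w], 50.0),
         "p90": _percentile(we[w], 90.0), "n": len(we[w]),
         "misses": wave_misses.get(w, 0)}
        for w in WAVE_NAMES])
    per_scenario = (per_segment.groupby("scenario")[["pcc", "rmse", "mae"]]
                    .mean().reset_index())
    cdf = {m: _cdf_table(per_segment[m].dropna().to_numpy())
           for m in ("pcc", "rmse", "mae")}
    return EvalReport(
        per_segment=per_segment, wave_errors=we, wave_misses=wave_misses,
        mean_pcc=float(per_segment["pcc"].mean()),
        mean_rmse=float(per_segment["rmse"].mean()),
        mean_mae=float(per_segment["mae"].mean()),
        wave_stats=wave_stats, per_scenario=per_scenario, cdf=cdf,
        n_excluded=n_excluded)


def evaluate_segments(y_hat: np.ndarray, segments, fs: float = 100.0,
                      match_window: float = 0.15,
                      detector=None) -> EvalReport:
    """Score reconstructed traces against their segments' ground truth.

    ``y_hat`` is (n_segments, L); targets are the per-segment z-normalized
    clean ECG (same convention as training).  Segments with zero variance in
    either trace are excluded from the morphology aggregates and counted.
    """
    from .training import segment_tensors   # local import to avoid cycle
    _, Y = segment_tensors(list(segments))
    rows = []
    wave_err: dict[str, list[float]] = {w: [] for w in WAVE_NAMES}
    wave_miss: dict[str, int] = {w: 0 for w in WAVE_NAMES}
    n_excluded = 0
    for i, seg in enumerate(segments):
        yh, y = y_hat[i], Y[i]
        try:
            p = pcc(yh, y)
        except UndefinedMetricError:
            n_excluded += 1
            continue
        rows.append({"segment": i, "subject": seg.subject_id,
                     "scenario": seg.scenario, "pcc": p,
                     "rmse": rmse(yh, y), "mae": mae(yh, y)})
        ann_ref = detect_waves(y, fs, detector)
        ann_hat = detect_waves(yh, fs, detector)
        errs, misses = localization_errors(ann_hat, ann_ref, match_window)
        for w in WAVE_NAMES:
            wave_err[w].extend(errs[w])
            wave_miss[w] += misses[w]
    per_segment = pd.DataFrame(rows)
    return summarize(per_segment, wave_err, wave_miss, n_excluded)
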