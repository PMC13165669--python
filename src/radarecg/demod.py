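"""Quadrature demodulation: recover chest displacement from radar I/Q channels.

The baseband channels encode the chest displacement x(t) as a phase
``w(t) = 4 pi x(t) / lambda0 + theta``.  The four-quadrant arctangent of
(Q, I) recovers w(t) wrapped to (-pi, pi]; cumulative +-2*pi correction
(threshold pi) unwraps it, and subtracting the constant offset theta
(estimated as the trace mean) and scaling by lambda0 / (4 pi) yields a
zero-mean displacement in mm.

The literal ratio arctan(Q/I) would lose quadrant information and reintroduce
the detection nulls that quadrature reception exists to avoid, hence the
four-quadrant form.  At 100 Hz sampling and chest motion of a few mm the
inter-sample phase step is far below pi, so unwrapping cannot alias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseTrace", "DegenerateSampleError", "arctan_demodulate",
           "phase_to_displacement", "envelope", "demodulate_displacement"]


class DegenerateSampleError(ValueError):
    """Both channels are zero at some sample; the phase is undefined there."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"i and q are both zero at sample {index}; phase undefined")


@dataclass
class PhaseTrace:
    wrapped: np.ndarray     # rad, in (-pi, pi]
    unwrapped: np.ndarray   # rad
    theta_est: float        # rad, estimated constant phase offset (trace mean)


def arctan_demodulate(i_chan: np.ndarray, q_chan: np.ndarray) -> PhaseTrace:
    """Wrapped and unwrapped echo phase from quadrature channels."""
    i = np.asarray(i_chan, dtype=float)
    q = np.asarray(q_chan, dtype=float)
    if i.shape != q.shape:
        raise ValueError("i and q channels must have the same length")
    dead = np.flatnonzero((i == 0.0) & (q == 0.0))
    if dead.size:
        raise DegenerateSampleError(int(dead[0]))
    wrapped = np.arctan2(q, i)
    unwrapped = np.unwrap(wrapped)
    return PhaseTrace(wrapped=wrapped, unwrapped=unwrapped,
                      theta_est=float(unwrapped.mean()))


def phase_to_displacement(p: PhaseTrace, wavelength: float) -> np.ndarray:
    """Displacement x = (lambda0 / 4 pi) (w - theta), in mm for lambda0 in mm."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / (4.0 * np.pi) * (p.unwrapped - p.theta_est)


def envelope(i_chan: np.ndarray, q_chan: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude A(t) = sqrt(I^2 + Q^2)."""
    i = np.asarray(i_chan, dtype=float)
    q = np.asarray(q_chan, dtype=float)
    if i.shape != q.shape:
        raise ValueError("i and q channels must have the same length")
    return np.hypot(i, q)


def demodulate_displacement(i_chan: np.ndarray, q_chan: np.ndarray,
                            wavelength: float) -> np.ndarray:
    """Convenience wrapper: I/Q -> zero-mean displacement (mm)."""
    return phase_to_displacement(arctan_demodulate(i_chan, q_chan), wavelength)
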