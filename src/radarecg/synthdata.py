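"""Synthetic paired radar/ECG data with subject and scenario structure.

The generator emulates a continuous-wave Doppler radar pointed at a person's
chest while a reference ECG is recorded.  Each 10-s segment couples three
ingredients:

* a synthetic ECG built from five Gaussian bumps (P, Q, R, S, T) riding on an
  accumulated cardiac phase whose beat-to-beat RR intervals follow an
  AR(1)-correlated lognormal law;
* a chest-displacement trace = respiration (scenario-dependent pattern) plus a
  cardiac micro-motion component, modelled as an impulse train at the R-peak
  times convolved with a damped ~20 Hz oscillation (a seismocardiogram-like
  ring);
* quadrature radar channels I/Q obtained by phase-modulating a 94 GHz carrier
  (wavelength 3 mm) with the displacement, plus phase and channel noise.

Seven measurement scenarios mix posture (sitting / lateral decubitus /
supine), antenna orientation (chest, back or chest-side facing the radar) and
breathing pattern (eupnea, intermittent apnea, hypoxic, rapid-shallow); their
dataset proportions default to the empirical mix of the study the simulator
emulates.  All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so subject parameters, scenario noise
and channel noise are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EcgModelParams",
    "ScenarioSpec",
    "RadarSimConfig",
    "SignalSegment",
    "RadarEcgDataset",
    "default_scenarios",
    "generate_ecg",
    "generate_chest_displacement",
    "radar_modulate",
    "generate_dataset",
    "largest_remainder_apportion",
    "SCENARIO_NAMES",
    "SCENARIO_PROPORTIONS",
    "SCENARIO_COUNTS_7521",
    "SubjectProfile",
]

C_MM_PER_S = 2.99792458e11  # speed of light in mm/s

SCENARIO_NAMES = (
    "Sitting-CR-Eu",
    "Lat Decub-BR-Eu",
    "Lat Decub-CR-Eu",
    "Supine-CSR-Eu",
    "Supine-CSR-Ap",
    "Supine-CSR-Hy",
    "Supine-CSR-RSB",
)

#: Empirical per-scenario segment counts in a 7521-segment acquisition
#: campaign, and the derived dataset proportions (37.44%, 15.94%, 14.32%,
#: 12.87%, 7.59%, 6.09%, 5.74% to printed precision).
SCENARIO_COUNTS_7521 = (2816, 1199, 1077, 968, 571, 458, 432)
SCENARIO_PROPORTIONS = tuple(c / 7521 for c in SCENARIO_COUNTS_7521)


class ConfigurationError(ValueError):
    """Raised for invalid generator / simulator configuration."""


class InvalidParameterError(ValueError):
    """Raised when physiological model parameters are non-finite or out of range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcgModelParams:
    """Parameters of the five-Gaussian phase-domain ECG model.

    Each beat spans one cardiac-phase cycle (-pi, pi]; wave ``i`` contributes
    ``a_i * exp(-(phi - theta_i)^2 / (2 b_i^2))``.  Amplitudes are in
    normalized mV, widths and angular positions in radians of cardiac phase.
    """

    wave_amplitudes: tuple[float, ...] = (0.12, -0.10, 1.00, -0.17, 0.30)
    wave_widths: tuple[float, ...] = (0.25, 0.10, 0.10, 0.10, 0.40)
    wave_angles: tuple[float, ...] = (
        -np.pi / 3.0, -np.pi / 12.0, 0.0, np.pi / 12.0, np.pi / 2.0)
    hr_mean: float = 70.0        # beats/min
    hr_sd: float = 2.0           # beats/min
    hrv_corr: float = 0.6        # AR(1) coefficient of log-RR, in [0, 1)

    def validate(self) -> None:
        arrs = (self.wave_amplitudes, self.wave_widths, self.wave_angles)
        for a in arrs:
            if len(a) != 5 or not np.all(np.isfinite(a)):
                raise InvalidParameterError("wave parameters must be five finite reals")
        if not np.all(np.asarray(self.wave_widths) > 0):
            raise InvalidParameterError("wave_widths must be positive")
        if not (40.0 <= self.hr_mean <= 180.0):
            raise InvalidParameterError(f"hr_mean {self.hr_mean} outside [40, 180] bpm")
        if not np.isfinite(self.hr_sd) or self.hr_sd < 0:
            raise InvalidParameterError("hr_sd must be finite and >= 0")
        if not (0.0 <= self.hrv_corr < 1.0):
            raise InvalidParameterError("hrv_corr must lie in [0, 1)")
        amps = np.abs(self.wave_amplitudes)
        if np.argmax(amps) != 2:
            raise InvalidParameterError("R amplitude must be the largest |amplitude|")


@dataclass(frozen=True)
class ScenarioSpec:
    """One posture/orientation/breathing measurement scenario."""

    name: str
    orientation_gain: float      # multiplier on cardiac displacement amplitude
    resp_freq: float             # Hz
    resp_amp: float              # mm
    resp_pattern: str            # eupnea | apnea | hypoxic | rapid_shallow
    hr_shift: float              # bpm added to subject baseline
    proportion: float            # fraction of dataset

    def validate(self) -> None:
        if self.resp_amp < 0:
            raise ConfigurationError("resp_amp must be >= 0")
        if not (0.0 < self.orientation_gain <= 1.0):
            raise ConfigurationError("orientation_gain must lie in (0, 1]")
        if self.resp_pattern not in ("eupnea", "apnea", "hypoxic", "rapid_shallow"):
            raise ConfigurationError(f"unknown resp_pattern {self.resp_pattern!r}")


def default_scenarios() -> list[ScenarioSpec]:
    """The seven default scenarios with their dataset proportions.

    Orientation gains fall with how much cardiac wall motion the antenna
    orientation sees (chest-facing 1.0, chest-side 0.5, back 0.3); the
    low-oxygen states carry heart-rate shifts (+15/+20/+25 bpm for apnea,
    hypoxic and rapid-shallow breathing).
    """
    p = SCENARIO_PROPORTIONS
    return [
        ScenarioSpec("Sitting-CR-Eu", 1.0, 0.25, 4.0, "eupnea", 0.0, p[0]),
        ScenarioSpec("Lat Decub-BR-Eu", 0.3, 0.22, 3.5, "eupnea", 0.0, p[1]),
        ScenarioSpec("Lat Decub-CR-Eu", 1.0, 0.22, 3.5, "eupnea", 0.0, p[2]),
        ScenarioSpec("Supine-CSR-Eu", 0.5, 0.20, 4.0, "eupnea", 0.0, p[3]),
        ScenarioSpec("Supine-CSR-Ap", 0.5, 0.20, 4.0, "apnea", 15.0, p[4]),
        ScenarioSpec("Supine-CSR-Hy", 0.5, 0.20, 4.0, "hypoxic", 20.0, p[5]),
        ScenarioSpec("Supine-CSR-RSB", 0.5, 0.20, 4.0, "rapid_shallow", 25.0, p[6]),
    ]


@dataclass(frozen=True)
class RadarSimConfig:
    """Continuous-wave quadrature radar front-end constants.

    The baseband model is ``I = A cos(4 pi x / lambda0 + theta)``,
    ``Q = A sin(4 pi x / lambda0 + theta)`` with ``x`` the chest displacement
    in mm and ``theta`` a constant phase offset (standoff term plus receiver
    phase) perturbed by residual phase noise.
    """

    carrier_freq: float = 94e9       # Hz
    wavelength: float = 3.0          # mm (printed system value; exact c/f0 = 3.19 mm)
    standoff: float = 1.0            # m
    amplitude: float = 1.0           # unitless channel amplitude A
    attenuation: float = 1.0         # unitless K
    constant_phase: float = 0.4      # rad
    phase_noise_sd: float = 0.02     # rad
    awgn_sd: float = 0.05            # unitless additive channel noise
    fs: float = 100.0                # Hz
    segment_len: int = 1000          # samples (10 s)

    def validate(self, strict_wavelength: bool = False) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be positive")
        if self.fs * 10.0 != self.segment_len:
            raise ConfigurationError("segment_len must equal 10 s at fs")
        if strict_wavelength:
            exact = C_MM_PER_S / self.carrier_freq
            if abs(self.wavelength - exact) / exact > 0.01:
                raise ConfigurationError(
                    f"wavelength {self.wavelength} mm inconsistent with carrier "
                    f"({exact:.3f} mm)")


@dataclass
class SignalSegment:
    """One 10-s, 100 Hz paired record."""

    subject_id: str
    scenario: str
    t: np.ndarray                # seconds, length 1000
    i_chan: np.ndarray
    q_chan: np.ndarray
    displacement: np.ndarray     # mm (true simulated chest motion)
    ecg: np.ndarray              # normalized mV (z-scored)
    r_peak_times: np.ndarray     # seconds, ground truth from the generator
    x_rec: np.ndarray | None = None      # demodulated displacement (mm)
    x_card: np.ndarray | None = None     # preprocessed cardiac signal
    ecg_clean: np.ndarray | None = None  # preprocessed ECG

    def validate(self) -> None:
        n = len(self.t)
        for name in ("i_chan", "q_chan", "displacement", "ecg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"segment array {name} length mismatch")
        rp = np.asarray(self.r_peak_times)
        if rp.size and (np.any(np.diff(rp) <= 0) or rp[0] < 0 or rp[-1] >= self.t[-1] + 0.01):
            raise ValueError("r_peak_times must be strictly increasing within the segment")


@dataclass
class RadarEcgDataset:
    """A collection of segments plus the configuration that generated it."""

    segments: list[SignalSegment]
    scenarios: list[ScenarioSpec]
    radar_config: RadarSimConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s.subject_id for s in self.segments})

    def subset(self, subject_ids: Sequence[str]) -> "RadarEcgDataset":
        keep = set(subject_ids)
        return RadarEcgDataset(
            [s for s in self.segments if s.subject_id in keep],
            self.scenarios, self.radar_config, self.seed)


# ---------------------------------------------------------------------------
# ECG generation
# ---------------------------------------------------------------------------

def _rr_intervals(params: EcgModelParams, duration: float,
                  rng: np.random.Generator) -> np.ndarray:
    """AR(1)-correlated lognormal RR intervals covering at least `duration` s."""
    m = 60.0 / params.hr_mean                       # mean RR (s)
    s = m * params.hr_sd / params.hr_mean           # RR sd via delta method
    if s == 0.0:
        n = int(np.ceil(duration / m)) + 2
        return np.full(n, m)
    sig2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sig2 / 2.0
    sig = np.sqrt(sig2)
    rho = params.hrv_corr
    n = int(np.ceil(duration / (0.6 * m))) + 4      # safely more beats than needed
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    for k in range(1, n):
        z[k] = rho * z[k - 1] + np.sqrt(1.0 - rho * rho) * eps[k]
    return np.exp(mu + sig * z)


def generate_ecg(params: EcgModelParams, duration: float, seed: int,
                 fs: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a z-normalized ECG trace and its ground-truth R-peak times.

    The cardiac phase starts at -pi (beat onset) and advances by 2*pi per RR
    interval; the five Gaussian waves are evaluated on the wrapped phase.  The
    R bump sits at phase 0, so the k-th R peak falls half an RR into beat k.

    Returns ``(ecg, r_peak_times)`` with ``ecg`` sampled at ``fs`` over
    ``duration`` seconds.
    """
    params.validate()
    if not (duration > 0 and np.isfinite(duration)):
        raise InvalidParameterError("duration must be positive and finite")
    rng = np.random.default_rng(seed)
    rr = _rr_intervals(params, duration, rng)
    beat_starts = np.concatenate(([0.0], np.cumsum(rr)))
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # piecewise-linear accumulated phase: phi(beat_starts[k]) = -pi + 2 pi k
    phi = np.interp(t, beat_starts, -np.pi + 2.0 * np.pi * np.arange(len(beat_starts)))
    wrapped = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi

    ecg = np.zeros(n)
    for a, b, th in zip(params.wave_amplitudes, params.wave_widths,
                        params.wave_angles):
        d = wrapped - th
        d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi    # circular distance
        ecg += a * np.exp(-0.5 * (d / b) ** 2)

    # R peak of beat k: phase crosses 2*pi*k, i.e. half-way through the beat
    r_times = beat_starts[:-1] + rr * 0.5
    r_times = r_times[r_times < duration]

    sd = ecg.std()
    if sd > 0:
        ecg = (ecg - ecg.mean()) / sd
    return ecg, r_times


# ---------------------------------------------------------------------------
# Chest displacement
# ---------------------------------------------------------------------------

_RING_FREQ = 20.0     # Hz, cardiac kernel ring frequency
_RING_TAU = 0.050     # s, decay time constant


def _cardiac_kernel(tau: np.ndarray, ring_freq: float = _RING_FREQ,
                    ring_tau: float = _RING_TAU) -> np.ndarray:
    """Damped-oscillation response to one heartbeat, normalized to unit peak."""
    k = np.where(tau >= 0.0,
                 np.exp(-np.maximum(tau, 0.0) / ring_tau)
                 * np.sin(2.0 * np.pi * ring_freq * np.maximum(tau, 0.0)),
                 0.0)
    # peak of exp(-tau/tau_d) sin(2 pi f tau): solve tan(w tau) = w tau_d
    w = 2.0 * np.pi * ring_freq
    tpk = np.arctan(w * ring_tau) / w
    peak = np.exp(-tpk / ring_tau) * np.sin(w * tpk)
    return k / peak


def _respiration(scenario: ScenarioSpec, t: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Scenario-patterned respiration displacement in mm."""
    freq, amp = scenario.resp_freq, scenario.resp_amp
    pattern = scenario.resp_pattern
    if pattern == "hypoxic":
        amp = amp * 1.5        # deeper compensatory breathing
    elif pattern == "rapid_shallow":
        freq, amp = freq * 2.5, amp * 0.4
    phase = rng.uniform(0.0, 2.0 * np.pi)
    resp = amp * np.sin(2.0 * np.pi * freq * t + phase)
    if pattern == "apnea":
        # one breath-hold epoch of 3-6 s placed at random inside the segment
        dur = rng.uniform(3.0, 6.0)
        start = rng.uniform(0.0, max(t[-1] - dur, 0.0))
        resp = resp.copy()
        resp[(t >= start) & (t < start + dur)] = 0.0
    return resp


def generate_chest_displacement(ecg_r_peaks: np.ndarray, scenario: ScenarioSpec,
                                cardiac_amp: float, seed: int,
                                duration: float = 10.0, fs: float = 100.0,
                                ring_freq: float = _RING_FREQ,
                                ring_tau: float = _RING_TAU) -> np.ndarray:
    """Chest displacement (mm): respiration plus orientation-scaled cardiac ring.

    The cardiac component is an impulse train at the R-peak times convolved
    with a decaying ~20 Hz sinusoid (50 ms time constant), evaluated
    analytically at the exact (fractional-sample) peak times.
    """
    scenario.validate()
    if cardiac_amp <= 0:
        raise InvalidParameterError("cardiac_amp must be > 0")
    r = np.asarray(ecg_r_peaks, dtype=float)
    if r.size and (r.min() < 0 or r.max() >= duration):
        raise InvalidParameterError("R peaks must lie inside the segment")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    card = np.zeros(n)
    for tk in r:
        card += _cardiac_kernel(t - tk, ring_freq, ring_tau)
    x = _respiration(scenario, t, rng) + scenario.orientation_gain * cardiac_amp * card
    return x


# ---------------------------------------------------------------------------
# Radar modulation
# ---------------------------------------------------------------------------

def radar_modulate(x: np.ndarray, cfg: RadarSimConfig,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature baseband channels for a displacement trace ``x`` (mm)."""
    cfg.validate()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("displacement must be finite")
    rng = np.random.default_rng(seed)
    theta = cfg.constant_phase + (
        rng.standard_normal(x.shape) * cfg.phase_noise_sd
        if cfg.phase_noise_sd > 0 else 0.0)
    phase = 4.0 * np.pi * x / cfg.wavelength + theta
    i_chan = cfg.amplitude * np.cos(phase)
    q_chan = cfg.amplitude * np.sin(phase)
    if cfg.awgn_sd > 0:
        i_chan = i_chan + rng.standard_normal(x.shape) * cfg.awgn_sd
        q_chan = q_chan + rng.standard_normal(x.shape) * cfg.awgn_sd
    return i_chan, q_chan


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def largest_remainder_apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer apportionment of ``n`` by proportions, largest remainder.

    Ties in the fractional remainders are broken by list order.  The counts
    always sum exactly to ``n``.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ConfigurationError(f"proportions sum to {p.sum():.8f}, not 1")
    quota = n * p / p.sum()
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    # stable sort on -remainder keeps list order among ties
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiological baseline drawn once per dataset."""

    subject_id: str
    hr_mean: float
    hr_sd: float
    hrv_corr: float
    cardiac_amp: float       # mm
    resp_scale: float        # multiplier on scenario respiration amplitude


def _draw_subject(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    return SubjectProfile(
        subject_id=subject_id,
        hr_mean=rng.uniform(55.0, 85.0),
        hr_sd=rng.uniform(1.0, 4.0),
        hrv_corr=rng.uniform(0.3, 0.8),
        cardiac_amp=rng.uniform(0.1, 0.5),
        resp_scale=rng.uniform(0.8, 1.2),
    )


def generate_dataset(n_subjects: int, n_segments: int,
                     scenarios: Sequence[ScenarioSpec] | None = None,
                     cfg: RadarSimConfig | None = None,
                     seed: int = 0) -> RadarEcgDataset:
    """Generate a subject-structured, scenario-labeled paired dataset.

    Scenario segment counts are the largest-remainder apportionment of
    ``n_segments`` by scenario proportion; segments are dealt to subjects
    round-robin so every subject sees every scenario mix.  Deterministic under
    ``seed``.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    for sc in scenarios:
        sc.validate()
    cfg = cfg if cfg is not None else RadarSimConfig()
    cfg.validate()

    counts = largest_remainder_apportion(n_segments, [s.proportion for s in scenarios])

    ss = np.random.SeedSequence(seed)
    subj_ss, seg_ss = ss.spawn(2)
    subj_rngs = [np.random.default_rng(s) for s in subj_ss.spawn(n_subjects)]
    width = max(2, len(str(n_subjects)))
    profiles = [_draw_subject(f"S{k:0{width}d}", subj_rngs[k])
                for k in range(n_subjects)]

    # scenario label list in scenario order, dealt round-robin to subjects
    labels: list[int] = []
    for idx, c in enumerate(counts):
        labels.extend([idx] * int(c))

    seg_seeds = seg_ss.spawn(len(labels))
    duration = cfg.segment_len / cfg.fs
    t = np.arange(cfg.segment_len) / cfg.fs
    segments: list[SignalSegment] = []
    for i, (lab, s_ss) in enumerate(zip(labels, seg_seeds)):
        prof = profiles[i % n_subjects]
        sc = scenarios[lab]
        sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in s_ss.spawn(3)]
        hr = float(np.clip(prof.hr_mean + sc.hr_shift, 40.0, 180.0))
        ep = EcgModelParams(hr_mean=hr, hr_sd=prof.hr_sd, hrv_corr=prof.hrv_corr)
        ecg, r_times = generate_ecg(ep, duration, sub_seeds[0], fs=cfg.fs)
        sc_eff = dataclasses.replace(sc, resp_amp=sc.resp_amp * prof.resp_scale)
        x = generate_chest_displacement(r_times, sc_eff, prof.cardiac_amp,
                                        sub_seeds[1], duration=duration, fs=cfg.fs)
        i_chan, q_chan = radar_modulate(x, cfg, sub_seeds[2])
        segments.append(SignalSegment(
            subject_id=prof.subject_id, scenario=sc.name, t=t.copy(),
            i_chan=i_chan, q_chan=q_chan, displacement=x, ecg=ecg,
            r_peak_times=r_times))
    # stable order: by subject then original index
    segments.sort(key=lambda s: s.subject_id)
    return RadarEcgDataset(segments, scenarios, cfg, seed)
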