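"""Forward simulation of swallowing fNIRS sessions.

Generates complete synthetic recordings — two-wavelength optical
intensity, laryngeal accelerometry, respiratory plethysmography — with
ground-truth swallow events, under a block protocol in which a
participant performs consecutive water swallows in three head positions
(chin-down, chin-neutral, chin-up).  Everything the analysis pipeline
later inverts (hemodynamic response, modified Beer-Lambert attenuation,
swallow apnea, laryngeal movement bursts) is modelled forward here, so
noise-free sessions round-trip exactly through the processing chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolSpec",
    "Channel",
    "ChannelSet",
    "HRFParams",
    "NoiseParams",
    "Schedule",
    "Segment",
    "SessionRecording",
    "ConfigurationError",
    "make_schedule",
    "hrf_kernel",
    "simulate_concentrations",
    "concentrations_to_intensity",
    "simulate_accelerometer",
    "simulate_respiration",
    "generate_session",
    "simulate_cohort_hdr",
    "default_channels",
]

POSITIONS = ("down", "neutral", "up")

FNIRS_RATE = 50.0
ACCEL_RATE = 4000.0
RESP_RATE = 1000.0


class ConfigurationError(ValueError):
    """Raised when a protocol / simulation parameter is invalid."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    """Block protocol: swallows per head position, cadence and rests.

    The default describes four blocks; within each block the participant
    holds each of the three head positions for one contiguous segment of
    eight swallows, one swallow every 38 s, with 5 ml water boluses
    delivered over 3 s by a pump running at 100 ml/min.  Blocks are
    separated by a 210 s rest.
    """

    n_blocks: int = 4
    positions: tuple[str, ...] = POSITIONS
    swallows_per_position_per_block: int = 8
    inter_swallow_interval: float = 38.0
    bolus_volume_ml: float = 5.0
    bolus_duration_s: float = 3.0
    pump_rate_ml_min: float = 100.0
    inter_block_rest: float = 210.0
    lead_in: float = 30.0
    lead_out: float = 40.0
    first_onset_offset: float = 12.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.swallows_per_position_per_block < 1:
            raise ConfigurationError("block and swallow counts must be >= 1")
        for name in ("inter_swallow_interval", "bolus_volume_ml",
                     "bolus_duration_s", "pump_rate_ml_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.inter_block_rest < 0 or self.lead_in < 0 or self.lead_out < 0:
            raise ConfigurationError("rest and lead durations must be >= 0")
        if len(set(self.positions)) != len(self.positions):
            raise ConfigurationError("positions must be distinct labels")

    @property
    def segment_duration(self) -> float:
        return self.swallows_per_position_per_block * self.inter_swallow_interval

    @property
    def block_duration(self) -> float:
        return len(self.positions) * self.segment_duration

    @property
    def session_duration(self) -> float:
        return (self.lead_in
                + self.n_blocks * self.block_duration
                + (self.n_blocks - 1) * self.inter_block_rest
                + self.lead_out)

    @property
    def swallows_per_position(self) -> int:
        return self.n_blocks * self.swallows_per_position_per_block


@dataclass(frozen=True)
class Channel:
    """One emitter-detector pair."""

    emitter: int
    detector: int
    hemisphere: str          # "L" or "R"
    roi: str                 # premotor | precentral | postcentral
    separation_cm: float = 3.0

    @property
    def is_short(self) -> bool:
        return self.separation_cm <= 1.0

    @property
    def name(self) -> str:
        return f"S{self.emitter}D{self.detector}"


@dataclass(frozen=True)
class ChannelSet:
    """Montage: long emitter-detector pairs plus optional short channels.

    The default montage has ten 3 cm pairs, five per hemisphere, over the
    premotor, precentral and postcentral regions, plus one 0.8 cm short
    channel per hemisphere sampling superficial (scalp) hemodynamics.
    """

    long_channels: tuple[Channel, ...]
    short_channels: tuple[Channel, ...] = ()
    wavelengths_nm: tuple[float, float] = (790.0, 830.0)

    def __post_init__(self) -> None:
        for ch in self.long_channels:
            if ch.is_short:
                raise ConfigurationError(
                    f"{ch.name}: separation {ch.separation_cm} cm is a short channel")
            if ch.hemisphere not in ("L", "R"):
                raise ConfigurationError(f"{ch.name}: hemisphere must be L or R")
        for ch in self.short_channels:
            if not ch.is_short:
                raise ConfigurationError(
                    f"{ch.name}: separation {ch.separation_cm} cm is not short")

    @property
    def all_channels(self) -> tuple[Channel, ...]:
        return self.long_channels + self.short_channels

    def hemisphere_index(self, hemisphere: str) -> np.ndarray:
        return np.array([i for i, ch in enumerate(self.long_channels)
                         if ch.hemisphere == hemisphere])


def default_channels(include_short: bool = True) -> ChannelSet:
    rois = ("premotor", "precentral", "precentral", "postcentral", "postcentral")
    long_ch = []
    for h_i, hemi in enumerate(("L", "R")):
        for k, roi in enumerate(rois):
            long_ch.append(Channel(emitter=h_i * 5 + k + 1,
                                   detector=h_i * 5 + k + 1,
                                   hemisphere=hemi, roi=roi))
    short = ()
    if include_short:
        short = (Channel(emitter=11, detector=11, hemisphere="L",
                         roi="scalp", separation_cm=0.8),
                 Channel(emitter=12, detector=12, hemisphere="R",
                         roi="scalp", separation_cm=0.8))
    return ChannelSet(long_channels=tuple(long_ch), short_channels=short)


@dataclass(frozen=True)
class HRFParams:
    """Hemodynamic response kernel timing and per-position amplitudes.

    The kernel is a single gamma variate re-parameterised by its peak
    time and the time at which it has returned to within 5% of baseline;
    swallowing responses peak around 4-6 s and return to baseline by
    20-30 s.  Amplitudes are the peak oxygenated-hemoglobin change per
    swallow in each head position (µM).
    """

    peak_time: float = 5.0
    return_time: float = 25.0
    amplitude_by_position: dict[str, float] = field(
        default_factory=lambda: {"down": 0.6, "neutral": 0.9, "up": 1.4})
    hbr_ratio: float = -1.0 / 3.0

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ConfigurationError("peak_time must be > 0")
        if self.peak_time >= self.return_time:
            raise ConfigurationError("peak_time must be < return_time")


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes (µM) of the physiological and instrumental noise model.

    Cardiac, respiratory and Mayer-wave oscillations ride on every
    channel; a shared superficial component (what short channels see) is
    mixed into the long channels; drift is a random walk; motion produces
    Laplacian single-sample spikes and step shifts persisting to the end
    of the block.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.25
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.15
    mayer_hz: float = 0.1
    mayer_amp: float = 0.2
    drift_scale: float = 0.01
    white_sd: float = 0.1
    cortical_lf_sd: float = 0.8      # shared in-band cerebral fluctuation
    channel_lf_sd: float = 0.3       # channel-specific in-band fluctuation
    motion_spike_rate_per_min: float = 0.5
    motion_spike_amp: float = 3.0
    motion_shift_rate_per_min: float = 0.1
    motion_shift_amp: float = 0.5
    superficial_weight: float = 0.5
    hbr_noise_scale: float = 0.4

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiratory_amp", "mayer_amp",
                     "drift_scale", "white_sd", "superficial_weight",
                     "cortical_lf_sd", "channel_lf_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("cardiac_hz", "respiratory_hz", "mayer_hz"):
            f = getattr(self, name)
            if not 0 < f < FNIRS_RATE / 2:
                raise ConfigurationError(
                    f"{name}={f} outside (0, {FNIRS_RATE / 2}) Hz")

    @classmethod
    def silent(cls) -> "NoiseParams":
        """All noise sources off (for round-trip / oracle checks)."""
        return cls(cardiac_amp=0, respiratory_amp=0, mayer_amp=0,
                   drift_scale=0, white_sd=0, motion_spike_rate_per_min=0,
                   motion_shift_rate_per_min=0, superficial_weight=0,
                   cortical_lf_sd=0, channel_lf_sd=0)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    block: int               # 1-based block index
    position: str
    start: float
    end: float               # half-open [start, end)
    onsets: tuple[float, ...]


@dataclass(frozen=True)
class Schedule:
    protocol: ProtocolSpec
    segments: tuple[Segment, ...]
    rests: tuple[tuple[float, float], ...]
    duration: float

    @property
    def onsets(self) -> np.ndarray:
        return np.concatenate([s.onsets for s in self.segments])

    def events_frame(self) -> pd.DataFrame:
        """Ground-truth events as a tidy table."""
        rows = [
            {"onset": t, "block": s.block, "position": s.position,
             "ordinal": k + 1}
            for s in self.segments for k, t in enumerate(s.onsets)
        ]
        return pd.DataFrame(rows).sort_values("onset").reset_index(drop=True)


def make_schedule(protocol: ProtocolSpec, seed: int) -> Schedule:
    """Lay out blocks, randomised position order per block, planned onsets.

    Each block holds three contiguous position segments; the order of the
    positions is an independent random permutation per block.  Within a
    segment the planned swallow onsets are evenly spaced at the
    inter-swallow interval, the first one ``first_onset_offset`` seconds
    after the segment starts.
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    rests: list[tuple[float, float]] = []
    t = protocol.lead_in
    n_sw = protocol.swallows_per_position_per_block
    for b in range(protocol.n_blocks):
        order = rng.permutation(len(protocol.positions))
        for pos_i in order:
            pos = protocol.positions[pos_i]
            onsets = tuple(
                t + protocol.first_onset_offset + k * protocol.inter_swallow_interval
                for k in range(n_sw))
            seg_end = t + protocol.segment_duration
            segments.append(Segment(block=b + 1, position=pos,
                                    start=t, end=seg_end, onsets=onsets))
            t = seg_end
        if b < protocol.n_blocks - 1:
            rests.append((t, t + protocol.inter_block_rest))
            t += protocol.inter_block_rest
    return Schedule(protocol=protocol, segments=tuple(segments),
                    rests=tuple(rests), duration=t + protocol.lead_out)


# ---------------------------------------------------------------------------
# hemodynamic response kernel
# ---------------------------------------------------------------------------

def _gamma_shape(peak_time: float, return_time: float,
                 return_fraction: float = 0.05) -> float:
    # h(t) = (t/tp)^a exp(a (1 - t/tp)) has unit peak at tp; solve the
    # shape a so that h(return_time) = return_fraction.
    r = return_time / peak_time
    return float(np.log(return_fraction) / (np.log(r) + 1.0 - r))


def hrf_kernel(params: HRFParams, sample_rate: float = FNIRS_RATE,
               duration: float = 40.0) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak gamma-variate hemodynamic kernel.

    Returns ``(t, h)`` with ``h(0) = 0``, peak value 1 at ``peak_time``
    (to within one sample) and ``h < 0.05`` beyond ``return_time``.
    """
    if sample_rate <= 0:
        raise ConfigurationError("sample_rate must be > 0")
    a = _gamma_shape(params.peak_time, params.return_time)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    x = t / params.peak_time
    with np.errstate(divide="ignore"):
        h = np.where(x > 0, np.exp(a * (np.log(np.maximum(x, 1e-300))
                                        + 1.0 - x)), 0.0)
    h[0] = 0.0
    return t, h


# ---------------------------------------------------------------------------
# concentration forward model
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Per-channel ΔHbO / ΔHbR time series in µM at the fNIRS rate."""

    time: np.ndarray                 # seconds, shape (n_t,)
    hbo: np.ndarray                  # µM, shape (n_channels, n_t)
    hbr: np.ndarray                  # µM, shape (n_channels, n_t)
    channels: tuple[Channel, ...]
    sample_rate: float = FNIRS_RATE
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr shapes differ")
        if self.hbo.shape != (len(self.channels), len(self.time)):
            raise ValueError("series shape inconsistent with channels/time")

    def copy(self) -> "ConcentrationSeries":
        return ConcentrationSeries(self.time.copy(), self.hbo.copy(),
                                   self.hbr.copy(), self.channels,
                                   self.sample_rate, list(self.provenance))


def _inband_noise(rng: np.random.Generator, n_t: int, sample_rate: float,
                  sd: float, low: float = 0.01, high: float = 0.5) -> np.ndarray:
    """Band-limited (analysis-band) noise with the requested sd."""
    if sd == 0:
        return np.zeros(n_t)
    from scipy.signal import butter, sosfiltfilt
    sos = butter(3, [low, high], btype="bandpass", fs=sample_rate,
                 output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n_t))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _event_regressor(schedule: Schedule, hrf: HRFParams, t: np.ndarray,
                     sample_rate: float) -> np.ndarray:
    """Noise-free ΔHbO event component: sum of amplitude-scaled kernels."""
    _, kernel = hrf_kernel(hrf, sample_rate)
    x = np.zeros(len(t))
    for seg in schedule.segments:
        amp = hrf.amplitude_by_position[seg.position]
        for onset in seg.onsets:
            i0 = int(round(onset * sample_rate))
            i1 = min(i0 + len(kernel), len(x))
            if i0 < len(x):
                x[i0:i1] += amp * kernel[: i1 - i0]
    return x


def simulate_concentrations(
    schedule: Schedule,
    channels: ChannelSet,
    hrf: HRFParams,
    noise: NoiseParams,
    seed: int,
    sample_rate: float = FNIRS_RATE,
) -> tuple[ConcentrationSeries, pd.DataFrame]:
    """Simulate ΔHbO/ΔHbR for every channel of the montage.

    Long channels carry the event-locked response plus physiological and
    instrumental noise; short channels carry only the superficial
    component.  Returns the series (long + short channels, in montage
    order) and the ground-truth event table.
    """
    rng = np.random.default_rng(seed)
    n_t = int(round(schedule.duration * sample_rate))
    t = np.arange(n_t) / sample_rate
    event_hbo = _event_regressor(schedule, hrf, t, sample_rate)

    # shared superficial signal: slow oscillations + drift, as seen by scalp
    superficial = (
        noise.mayer_amp * np.sin(2 * np.pi * noise.mayer_hz * t + rng.uniform(0, 2 * np.pi))
        + noise.respiratory_amp * np.sin(2 * np.pi * noise.respiratory_hz * t
                                         + rng.uniform(0, 2 * np.pi))
        + noise.drift_scale * np.cumsum(rng.standard_normal(n_t)) / np.sqrt(sample_rate)
    )

    # systemic cerebral low-frequency fluctuation inside the analysis band:
    # shared across cortical (long) channels, absent from scalp channels,
    # with the physiological HbR anti-correlation so it survives the
    # motion-correction chain the way true hemodynamics do
    cortical_lf = _inband_noise(rng, n_t, sample_rate, noise.cortical_lf_sd)

    block_ends = [seg.end for seg in schedule.segments]

    def channel_noise(scale: float) -> np.ndarray:
        out = np.zeros(n_t)
        out += scale * noise.cardiac_amp * np.sin(
            2 * np.pi * noise.cardiac_hz * t + rng.uniform(0, 2 * np.pi))
        out += scale * noise.white_sd * rng.standard_normal(n_t)
        out += scale * noise.drift_scale * np.cumsum(
            rng.standard_normal(n_t)) / np.sqrt(sample_rate)
        # motion: Laplacian spikes and step shifts persisting to block end
        dur_min = schedule.duration / 60.0
        for _ in range(rng.poisson(noise.motion_spike_rate_per_min * dur_min)):
            i = rng.integers(n_t)
            out[i] += rng.laplace(0, scale * noise.motion_spike_amp)
        for _ in range(rng.poisson(noise.motion_shift_rate_per_min * dur_min)):
            t0 = rng.uniform(0, schedule.duration)
            later = [e for e in block_ends if e > t0]
            t1 = later[0] if later else schedule.duration
            i0, i1 = int(t0 * sample_rate), min(int(t1 * sample_rate), n_t)
            out[i0:i1] += rng.normal(0, scale * noise.motion_shift_amp)
        return out

    all_ch = channels.all_channels
    hbo = np.zeros((len(all_ch), n_t))
    hbr = np.zeros((len(all_ch), n_t))
    for i, ch in enumerate(all_ch):
        if ch.is_short:
            hbo[i] = superficial + channel_noise(0.3)
            hbr[i] = noise.hbr_noise_scale * (superficial + channel_noise(0.3))
        else:
            hemo = (event_hbo + cortical_lf
                    + _inband_noise(rng, n_t, sample_rate, noise.channel_lf_sd))
            hbo[i] = (hemo
                      + noise.superficial_weight * superficial
                      + channel_noise(1.0))
            hbr[i] = (hrf.hbr_ratio * hemo
                      + noise.hbr_noise_scale
                      * (noise.superficial_weight * superficial + channel_noise(1.0)))

    series = ConcentrationSeries(time=t, hbo=hbo, hbr=hbr,
                                 channels=all_ch, sample_rate=sample_rate,
                                 provenance=[{"stage": "simulate_concentrations",
                                              "seed": int(seed)}])
    return series, schedule.events_frame()


def concentrations_to_intensity(conc: ConcentrationSeries, optics,
                                i0: float = 1.0) -> np.ndarray:
    """Forward modified Beer-Lambert: concentration -> raw intensity.

    ``I(λ, t) = I0 · exp(−ΔOD(λ, t))`` with
    ``ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)`` (concentration
    in mM, ε in cm⁻¹·mM⁻¹, d in cm).  Returns intensity with shape
    ``(n_wavelengths, n_channels, n_t)``.  Exact inverse of the
    OD-to-concentration solve on noiseless data.
    """
    if i0 <= 0:
        raise ConfigurationError("i0 must be > 0")
    conc_mm = np.stack([conc.hbo, conc.hbr]) * 1e-3      # µM -> mM
    seps = np.array([ch.separation_cm for ch in conc.channels])
    n_wl = optics.extinction.shape[0]
    od = np.zeros((n_wl, len(conc.channels), len(conc.time)))
    for w in range(n_wl):
        coef = optics.extinction[w] * optics.dpf[w]      # (2,) per chromophore
        od[w] = (coef[0] * conc_mm[0] + coef[1] * conc_mm[1]) * seps[:, None]
    return i0 * np.exp(-od)


# ---------------------------------------------------------------------------
# accelerometer / respiration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccelParams:
    baseline_sd: float = 1.0
    burst_amp: float = 10.0          # × baseline_sd
    burst_rise_s: float = 0.25
    burst_duration_s: float = 1.0
    quiet_pre_s: float = 0.6         # laryngeal quiescence before onset
    quiet_decay_rate: float = 20.0   # 1/s amplitude decay during quiescence
    quiet_floor: float = 1e-4        # × baseline_sd


def simulate_accelerometer(events: np.ndarray, duration: float, seed: int,
                           params: AccelParams = AccelParams(),
                           sample_rate: float = ACCEL_RATE) -> np.ndarray:
    """Laryngeal accelerometer: movement noise with a burst per swallow.

    The instantaneous amplitude decays exponentially through the
    pre-swallow quiescent window (the swallow apnea), reaches its minimum
    at the ground-truth onset, then rises into a ~1 s movement burst.
    The smoothed rectified envelope therefore has a trough at the onset
    followed by a rise — the shape the onset detector keys on.
    """
    events = np.asarray(events, dtype=float)
    if events.size and (events.min() < 0 or events.max() > duration):
        raise ConfigurationError("event times must lie within the record")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    amp = np.full(n, params.baseline_sd)
    for onset in events:
        # quiescence: exponential decay toward the floor, minimum at onset
        i0 = max(int((onset - params.quiet_pre_s) * sample_rate), 0)
        i1 = min(int(onset * sample_rate), n)
        tau = t[i0:i1] - (onset - params.quiet_pre_s)
        quiet = np.maximum(np.exp(-params.quiet_decay_rate * tau),
                           params.quiet_floor) * params.baseline_sd
        amp[i0:i1] = np.minimum(amp[i0:i1], quiet)
        # burst: gamma-shaped rise from the floor, unit peak at burst_rise_s
        j1 = min(int((onset + params.burst_duration_s) * sample_rate), n)
        if i1 < j1:
            tb = t[i1:j1] - onset
            shape = (tb / params.burst_rise_s) * np.exp(1 - tb / params.burst_rise_s)
            burst = params.baseline_sd * (params.quiet_floor
                                          + params.burst_amp * shape)
            amp[i1:j1] = np.maximum(amp[i1:j1], burst)
    return amp * rng.standard_normal(n)


@dataclass(frozen=True)
class RespParams:
    breathing_hz: float = 0.25
    amplitude: float = 1.0
    apnea_pre_s: float = 0.5
    apnea_post_s: float = 1.0
    noise_fraction: float = 0.005    # sensor noise as a fraction of amplitude

    @property
    def apnea_duration_s(self) -> float:
        return self.apnea_pre_s + self.apnea_post_s


def simulate_respiration(
    events: np.ndarray, duration: float, seed: int,
    params: RespParams = RespParams(),
    sample_rate: float = RESP_RATE,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Respiratory band signal with a swallow apnea spanning each onset.

    Breathing is quasi-sinusoidal; during each apnea window
    ``[onset − apnea_pre, onset + apnea_post]`` the phase clock is frozen
    so the trace flattens at its current value.  Returns the signal and
    the ground-truth apnea intervals.
    """
    events = np.asarray(events, dtype=float)
    if events.size and (events.min() < 0 or events.max() > duration):
        raise ConfigurationError("event times must lie within the record")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    gate = np.ones(n)
    intervals: list[tuple[float, float]] = []
    for onset in np.sort(events):
        a, b = onset - params.apnea_pre_s, onset + params.apnea_post_s
        gate[(t >= a) & (t < b)] = 0.0
        intervals.append((max(a, 0.0), min(b, duration)))
    phase = (2 * np.pi * params.breathing_hz * np.cumsum(gate) / sample_rate
             + rng.uniform(0, 2 * np.pi))
    signal = params.amplitude * np.sin(phase)
    signal += (params.noise_fraction * params.amplitude
               * rng.standard_normal(n))
    return signal, intervals


# ---------------------------------------------------------------------------
# complete sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionRecording:
    """One participant's multi-rate session plus ground truth."""

    participant: str
    schedule: Schedule
    channels: ChannelSet
    intensity: np.ndarray            # (n_wavelengths, n_channels, n_t)
    accel: np.ndarray                # 4 kHz
    resp: np.ndarray                 # 1 kHz
    truth_events: pd.DataFrame
    truth_apneas: list[tuple[float, float]]
    sample_rates: dict[str, float] = field(
        default_factory=lambda: {"fnirs": FNIRS_RATE, "accel": ACCEL_RATE,
                                 "resp": RESP_RATE})
    seed: int = 0
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    provenance: list = field(default_factory=list)


def generate_session(
    participant: str = "P01",
    protocol: ProtocolSpec | None = None,
    channels: ChannelSet | None = None,
    hrf: HRFParams | None = None,
    noise: NoiseParams | None = None,
    accel_params: AccelParams = AccelParams(),
    resp_params: RespParams = RespParams(),
    seed: int = 0,
    optics=None,
) -> SessionRecording:
    """Generate one complete synthetic session (all streams + ground truth)."""
    from .nirs_core import default_optics

    protocol = protocol or ProtocolSpec()
    channels = channels or default_channels()
    hrf = hrf or HRFParams()
    noise = noise or NoiseParams()
    optics = optics or default_optics()

    rng = np.random.default_rng(seed)
    sched_seed, conc_seed, accel_seed, resp_seed = rng.integers(2**31, size=4)
    schedule = make_schedule(protocol, int(sched_seed))
    conc, truth = simulate_concentrations(schedule, channels, hrf, noise,
                                          seed=int(conc_seed))
    intensity = concentrations_to_intensity(conc, optics)
    onsets = truth["onset"].to_numpy()
    accel = simulate_accelerometer(onsets, schedule.duration,
                                   int(accel_seed), accel_params)
    resp, apneas = simulate_respiration(onsets, schedule.duration,
                                        int(resp_seed), resp_params)
    return SessionRecording(
        participant=participant, schedule=schedule, channels=channels,
        intensity=intensity, accel=accel, resp=resp,
        truth_events=truth, truth_apneas=apneas, seed=seed,
        hrf=hrf, noise=noise,
        provenance=[{"stage": "generate_session", "seed": seed}])


# ---------------------------------------------------------------------------
# summary-level cohort generator
# ---------------------------------------------------------------------------

def simulate_cohort_hdr(
    n_participants: int = 26,
    amplitudes: dict[str, float] | None = None,
    participant_sd: float = 0.5,
    residual_sd: float = 1.0,
    timing_effect: float = 0.0,
    hemisphere_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort-level generator of median-HDR summaries.

    Draws the per-cell median-window OxyHb values directly at the summary
    scale (µM): cell mean = position amplitude (+ optional timing /
    hemisphere shifts), plus a participant random intercept and residual
    noise whose combined spread matches the observed between-participant
    variability of per-cell summaries (~1.1 µM).  Used for inference
    simulations where full-signal cohorts would be needlessly expensive;
    the signal-level generator above is the per-session forward model.
    """
    amplitudes = amplitudes or {"down": 0.6, "neutral": 0.9, "up": 1.4}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        b_i = rng.normal(0.0, participant_sd)
        for pos, amp in amplitudes.items():
            for hemi in ("L", "R"):
                for k, timing in enumerate(("first", "last")):
                    mu = (amp + b_i
                          + timing_effect * k
                          + hemisphere_effect * (hemi == "R"))
                    rows.append({
                        "participant": f"P{i + 1:02d}", "position": pos,
                        "hemisphere": hemi, "timing": timing,
                        "oxyhb": mu + rng.normal(0.0, residual_sd)})
    return pd.DataFrame(rows)
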