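"""Raw intensity to motion-corrected hemoglobin concentration.

Processing chain: optical density conversion, 0.01-0.5 Hz zero-phase
band-pass, modified Beer-Lambert inversion to ΔHbO/ΔHbR (µM),
short-separation regression of superficial physiology, and a
correlation-based signal improvement (CBSI) motion filter that enforces
the physiological anti-correlation of oxy- and deoxyhemoglobin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synthgen import (FNIRS_RATE, Channel, ChannelSet, ConcentrationSeries,
                       ConfigurationError, SessionRecording)

__all__ = [
    "OpticsTable",
    "default_optics",
    "intensity_to_od",
    "bandpass",
    "od_to_conc",
    "short_sep_regress",
    "cbsi",
    "process_session",
]


@dataclass(frozen=True)
class OpticsTable:
    """Extinction coefficients, pathlength factors and geometry.

    ``extinction[w, c]`` is ε in cm⁻¹·mM⁻¹ for wavelength index ``w``
    (790, 830 nm) and chromophore ``c`` (HbO, HbR); ``dpf`` is the
    differential pathlength factor per wavelength.  Separation is
    per-channel geometry and lives on the Channel objects.
    """

    extinction: np.ndarray
    dpf: tuple[float, float] = (6.0, 6.0)
    wavelengths_nm: tuple[float, float] = (790.0, 830.0)

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ConfigurationError("extinction must be a 2x2 matrix")
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("dpf must be > 0")
        cond = np.linalg.cond(ext)
        if not np.isfinite(cond) or cond >= 1e6:
            raise ConfigurationError(
                f"extinction matrix ill-conditioned (cond={cond:.3g})")

    def system_matrix(self, separation_cm: float) -> np.ndarray:
        """d·DPF(λ)·ε(λ, ·) — maps (ΔHbO, ΔHbR) in mM to ΔOD per wavelength."""
        return separation_cm * np.diag(self.dpf) @ np.asarray(self.extinction)


def default_optics() -> OpticsTable:
    # hemoglobin extinction (cm^-1 mM^-1) at 790 / 830 nm from the
    # standard compiled in-vitro spectra (Gratzer/Kollias compilation)
    return OpticsTable(extinction=np.array([[0.7354, 1.1050],
                                            [0.9740, 0.6931]]))


# ---------------------------------------------------------------------------
# optical density
# ---------------------------------------------------------------------------

def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """ΔOD(t) = −ln(I(t)/Ī) per channel and wavelength.

    Ī is the temporal mean of that channel/wavelength, so a constant
    intensity maps to identically zero OD and rescaling the light level
    leaves the output unchanged.
    """
    intensity = np.asarray(intensity, dtype=float)
    bad = intensity <= 0
    if np.any(bad):
        w, c, i = (int(x[0]) for x in np.nonzero(bad))
        raise ValueError(f"non-positive intensity at wavelength index {w}, "
                         f"channel {c}, sample {i}")
    mean = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mean)


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, sample_rate: float = FNIRS_RATE,
             low: float = 0.01, high: float = 0.5,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Order-3 per pass, applied forward and backward (sosfiltfilt), which
    squares the magnitude response and cancels phase.  Removes DC and
    slow drift below ``low`` and cardiac/respiratory oscillations above
    ``high``.
    """
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    if high >= sample_rate / 2:
        raise ConfigurationError(
            f"high={high} Hz must be below Nyquist ({sample_rate / 2} Hz)")
    sos = butter(order, [low, high], btype="bandpass", fs=sample_rate,
                 output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass_response(freq_hz: float, sample_rate: float = FNIRS_RATE,
                      low: float = 0.01, high: float = 0.5,
                      order: int = 3) -> float:
    """Two-pass magnitude response of the band-pass at one frequency."""
    from scipy.signal import sosfreqz
    sos = butter(order, [low, high], btype="bandpass", fs=sample_rate,
                 output="sos")
    _, h = sosfreqz(sos, worN=[freq_hz], fs=sample_rate)
    return float(np.abs(h[0]) ** 2)


# ---------------------------------------------------------------------------
# modified Beer-Lambert inversion
# ---------------------------------------------------------------------------

def od_to_conc(od: np.ndarray, channels: tuple[Channel, ...],
               optics: OpticsTable, time: np.ndarray | None = None,
               sample_rate: float = FNIRS_RATE) -> ConcentrationSeries:
    """Solve the 2x2 modified Beer-Lambert system per channel and sample.

    ``od`` has shape (2 wavelengths, n_channels, n_t); the output
    concentrations are in µM.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[0] != 2:
        raise ValueError("od must have shape (2, n_channels, n_t)")
    n_ch, n_t = od.shape[1], od.shape[2]
    if n_ch != len(channels):
        raise ValueError("channel count mismatch")
    hbo = np.empty((n_ch, n_t))
    hbr = np.empty((n_ch, n_t))
    for i, ch in enumerate(channels):
        a = optics.system_matrix(ch.separation_cm)
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond >= 1e6:
            raise ValueError(f"system matrix for channel {ch.name} "
                             f"ill-conditioned (cond={cond:.3g})")
        conc_mm = np.linalg.solve(a, od[:, i, :])
        hbo[i], hbr[i] = conc_mm * 1e3          # mM -> µM
    t = time if time is not None else np.arange(n_t) / sample_rate
    return ConcentrationSeries(time=t, hbo=hbo, hbr=hbr, channels=channels,
                               sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# short-separation regression
# ---------------------------------------------------------------------------

def _nearest_short_map(long_channels: tuple[Channel, ...],
                       short_channels: tuple[Channel, ...]) -> list[int]:
    """Index of the short channel serving each long channel (same
    hemisphere when available, else the first short channel)."""
    mapping = []
    for ch in long_channels:
        same = [i for i, s in enumerate(short_channels)
                if s.hemisphere == ch.hemisphere]
        mapping.append(same[0] if same else 0)
    return mapping


def short_sep_regress(long: ConcentrationSeries, short: ConcentrationSeries,
                      mapping: list[int] | None = None) -> ConcentrationSeries:
    """Remove superficial physiology by regressing out short channels.

    For each long channel and chromophore, the least-squares coefficient
    of its assigned short channel over the full record is estimated and
    the fitted component subtracted; the residual is orthogonal to the
    regressor.  With no short channels the input is returned unchanged
    with a warning.
    """
    if len(short.channels) == 0:
        warnings.warn("no short channels available; skipping "
                      "short-separation regression", stacklevel=2)
        return long.copy()
    if mapping is None:
        mapping = _nearest_short_map(long.channels, short.channels)
    out = long.copy()
    for i, j in enumerate(mapping):
        for attr in ("hbo", "hbr"):
            s = getattr(short, attr)[j]
            denom = float(s @ s)
            if denom == 0.0:
                warnings.warn(f"short channel {short.channels[j].name} has "
                              f"zero variance; skipping regression for "
                              f"{long.channels[i].name}/{attr}", stacklevel=2)
                continue
            y = getattr(out, attr)
            beta = float(s @ y[i]) / denom
            y[i] = y[i] - beta * s
    out.provenance.append({"stage": "short_sep_regress",
                           "mapping": list(mapping)})
    return out


# ---------------------------------------------------------------------------
# CBSI motion correction
# ---------------------------------------------------------------------------

def cbsi(hbo: np.ndarray, hbr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-based signal improvement.

    Assumes true HbO and HbR are anti-correlated while motion is common
    mode: with α = sd(hbo)/sd(hbr), the corrected pair is
    ``hbo* = (hbo − α·hbr)/2`` and ``hbr* = −hbo*/α``, which is exactly
    anti-correlated and annihilates any common-mode (motion) component.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise ValueError("hbo and hbr must have the same shape")
    sd_o = hbo.std()
    sd_r = hbr.std()
    if sd_r == 0:
        raise ValueError("cbsi undefined: sd(hbr) = 0")
    alpha = sd_o / sd_r
    hbo_c = 0.5 * (hbo - alpha * hbr)
    hbr_c = -hbo_c / alpha
    return hbo_c, hbr_c


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def process_session(session: SessionRecording,
                    optics: OpticsTable | None = None,
                    low: float = 0.01, high: float = 0.5,
                    apply_bandpass: bool = True,
                    apply_short_sep: bool = True,
                    apply_cbsi: bool = True) -> ConcentrationSeries:
    """Raw intensity → motion-corrected long-channel concentrations.

    Order: OD → band-pass → Beer-Lambert → short-separation regression →
    CBSI.  Returns long channels only; provenance records each applied
    stage and its parameters.
    """
    optics = optics or default_optics()
    fs = session.sample_rates["fnirs"]
    od = intensity_to_od(session.intensity)
    prov = [{"stage": "intensity_to_od"}]
    if apply_bandpass:
        od = bandpass(od, fs, low, high)
        prov.append({"stage": "bandpass", "low": low, "high": high})
    conc = od_to_conc(od, session.channels.all_channels, optics,
                      sample_rate=fs)
    prov.append({"stage": "od_to_conc", "dpf": list(optics.dpf)})

    n_long = len(session.channels.long_channels)
    long = ConcentrationSeries(conc.time, conc.hbo[:n_long],
                               conc.hbr[:n_long],
                               session.channels.long_channels, fs)
    short = ConcentrationSeries(conc.time, conc.hbo[n_long:],
                                conc.hbr[n_long:],
                                session.channels.short_channels, fs)
    if apply_short_sep:
        long = short_sep_regress(long, short)
        prov.append({"stage": "short_sep_regress",
                     "n_short": len(short.channels)})
    if apply_cbsi:
        for i in range(len(long.channels)):
            long.hbo[i], long.hbr[i] = cbsi(long.hbo[i], long.hbr[i])
        prov.append({"stage": "cbsi"})
    long.provenance = list(session.provenance) + prov
    return long
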