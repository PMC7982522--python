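"""Acoustic and aerodynamic voice-quality metrics.

Implements the analysis layer: Welch amplitude spectral density, sound
pressure level re 20 µPa, vocal efficiency

    VE = P_r / P_a = 4 pi R² 10^((SPL - 120)/10) / (P_sub · Q̄),

Hillenbrand-style Cepstral Peak Prominence (height of the cepstral peak
at the fundamental quefrency above a linear regression through the
cepstrum), formant extraction from a spectral density, and the glottal
open and speed quotients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .acoustics import AcousticSignal
from .kinematics import AreaWaveform

__all__ = [
    "SpectralDensity",
    "MetricsReport",
    "VEResult",
    "CPPResult",
    "compute_asd",
    "compute_spl",
    "vocal_efficiency",
    "compute_cpp",
    "extract_formants",
    "gaw_quotients",
]

P_REF = 20e-6  # Pa, SPL reference
I_REF = 1e-12  # W/m², intensity reference underlying the VE formula


@dataclass
class SpectralDensity:
    """One-sided amplitude spectral density (Pa/√Hz) with analysis metadata."""

    frequencies: np.ndarray
    amplitude: np.ndarray
    window_meta: dict = field(default_factory=dict)

    @property
    def psd(self) -> np.ndarray:
        return self.amplitude**2

    def total_power(self) -> float:
        """Integrated PSD (≈ time-domain variance, Parseval)."""
        return float(np.trapezoid(self.psd, self.frequencies))

    def dominant_frequency(self, fmax: float | None = None) -> float:
        """Frequency of the largest spectral amplitude (below ``fmax``)."""
        mask = np.ones_like(self.frequencies, dtype=bool)
        if fmax is not None:
            mask = self.frequencies <= fmax
        idx = np.argmax(np.where(mask, self.amplitude, -np.inf))
        return float(self.frequencies[idx])


@dataclass
class VEResult:
    """Vocal efficiency with its power components."""

    ve: float  # dimensionless P_r / P_a
    p_radiated: float  # W
    p_aerodynamic: float  # W

    @property
    def percent(self) -> float:
        return 100.0 * self.ve

    def __float__(self) -> float:
        return self.ve


@dataclass
class CPPResult:
    """Cepstral peak prominence (dB), averaged over analysis frames."""

    cpp_db: float
    peak_quefrency_s: float
    n_frames: int
    low_confidence: bool = False

    def __float__(self) -> float:
        return self.cpp_db


def compute_asd(
    signal: AcousticSignal,
    f0: float = 148.0,
    cycles_per_segment: int = 4,
) -> SpectralDensity:
    """Welch-averaged amplitude spectral density.

    Hann windows of ``cycles_per_segment`` fundamental periods with 50 %
    overlap, giving a frequency resolution of f0 / cycles_per_segment.
    """
    nperseg = int(round(cycles_per_segment * signal.sample_rate / f0))
    if signal.samples.size < nperseg:
        raise ValueError("signal shorter than one analysis window")
    freqs, psd = sps.welch(
        signal.samples,
        fs=signal.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return SpectralDensity(
        freqs,
        np.sqrt(psd),
        window_meta={"window": "hann", "nperseg": nperseg, "overlap": 0.5},
    )


def compute_spl(signal: AcousticSignal, p_ref: float = P_REF) -> float:
    """Sound pressure level 20 log10(rms / p_ref) in dB."""
    rms = signal.rms
    if rms == 0:
        raise ValueError("SPL undefined for an all-zero signal")
    return 20.0 * math.log10(rms / p_ref)


def vocal_efficiency(spl: float, mic_distance: float, p_sub: float, q_mean: float) -> VEResult:
    """Radiated-to-aerodynamic power ratio.

    ``q_mean`` in m³/s; the radiated power assumes spherical spreading
    from the microphone distance and the 1e-12 W/m² reference intensity.
    """
    if mic_distance <= 0:
        raise ValueError("mic_distance must be positive")
    if p_sub <= 0 or q_mean <= 0:
        raise ValueError("p_sub and q_mean must be positive")
    p_r = 4.0 * math.pi * mic_distance**2 * 10.0 ** ((spl - 120.0) / 10.0)
    p_a = p_sub * q_mean
    return VEResult(p_r / p_a, p_r, p_a)


def _frame_indices(n: int, frame_len: int, hop: int) -> range:
    return range(0, n - frame_len + 1, hop)


def compute_cpp(
    signal: AcousticSignal,
    f0_search: tuple[float, float] = (60.0, 300.0),
    window_s: float = 0.040,
    overlap: float = 0.5,
    regression_range_s: tuple[float, float] = (1e-3, 15e-3),
) -> CPPResult:
    """Cepstral peak prominence, Hillenbrand-style.

    Per Hann-windowed frame the dB log-magnitude spectrum is transformed
    back to the quefrency domain (real cepstrum in dB); the cepstral peak
    is searched within the quefrency band of ``f0_search`` and its height
    above a least-squares regression line through the cepstrum (over
    ``regression_range_s``) is the frame CPP.  The mean over frames is
    returned.  If no local peak exists in the band, the band maximum is
    used and the result flagged low-confidence.
    """
    fs = signal.sample_rate
    x = signal.samples
    frame_len = int(round(window_s * fs))
    hop = max(1, int(round(frame_len * (1.0 - overlap))))
    starts = list(_frame_indices(x.size, frame_len, hop))
    if len(starts) < 1:
        raise ValueError("signal shorter than one CPP analysis window")
    if f0_search[0] <= 20.0 or f0_search[1] >= fs / 4:
        raise ValueError("f0 search interval must lie within (20 Hz, fs/4)")

    win = sps.get_window("hann", frame_len)
    # the real cepstrum is circularly symmetric; only the first half of the
    # quefrency axis is non-redundant
    n_half = frame_len // 2 + 1
    q = np.arange(n_half) / fs
    band = (q >= 1.0 / f0_search[1]) & (q <= 1.0 / f0_search[0])
    if not band.any():
        raise ValueError("analysis window too short for the f0 search band")
    reg = (q >= regression_range_s[0]) & (q <= min(regression_range_s[1], q[-1]))
    band_idx = np.flatnonzero(band)

    cpps, qpeaks, low_conf = [], [], False
    for s in starts:
        frame = x[s : s + frame_len] * win
        spec_db = 20.0 * np.log10(np.abs(np.fft.rfft(frame)) + 1e-300)
        ceps = np.fft.irfft(spec_db, n=frame_len)[:n_half]  # dB real cepstrum
        peaks, _ = sps.find_peaks(ceps[band_idx])
        if peaks.size:
            rel = peaks[np.argmax(ceps[band_idx][peaks])]
        else:
            rel = int(np.argmax(ceps[band_idx]))
            low_conf = True
        ipk = band_idx[rel]
        slope, intercept = np.polyfit(q[reg], ceps[reg], 1)
        cpps.append(ceps[ipk] - (slope * q[ipk] + intercept))
        qpeaks.append(q[ipk])

    if low_conf:
        warnings.warn("no cepstral peak found in the f0 band; CPP is low-confidence")
    return CPPResult(
        cpp_db=float(np.mean(cpps)),
        peak_quefrency_s=float(np.median(qpeaks)),
        n_frames=len(starts),
        low_confidence=low_conf,
    )


def extract_formants(
    density: SpectralDensity | tuple[np.ndarray, np.ndarray],
    n_formants: int = 2,
    prominence_rel: float = 0.05,
) -> list[float]:
    """Lowest-frequency local spectral maxima above a prominence threshold.

    Accepts a :class:`SpectralDensity` or a raw ``(frequencies, amplitude)``
    pair (e.g. a vocal-tract transfer function).  Returns up to
    ``n_formants`` peak frequencies in ascending order, warning when fewer
    peaks are found.
    """
    if isinstance(density, SpectralDensity):
        freqs, amp = density.frequencies, density.amplitude
    else:
        freqs, amp = density
    peaks, _ = sps.find_peaks(amp, prominence=prominence_rel * float(np.max(amp)))
    if peaks.size < n_formants:
        warnings.warn(f"found only {peaks.size} spectral peaks, requested {n_formants}")
    return [float(freqs[p]) for p in peaks[:n_formants]]


def gaw_quotients(gaw: AreaWaveform, open_threshold: float = 0.0) -> tuple[float, float]:
    """Open quotient and speed quotient of a periodic GAW.

    "Open" means area > A_min + open_threshold (A_max − A_min).  OQ is the
    open fraction of the cycle; SQ the ratio of opening time (open onset
    to peak) to closing time (peak to open offset) within the open phase.
    Closure is a sustained phase: an isolated single sample touching the
    minimum (e.g. a sine grazing its trough) counts as open.
    """
    if not 0.0 <= open_threshold <= 0.2:
        raise ValueError("open_threshold must be in [0, 0.2]")
    area = gaw.area
    a_min, a_max = gaw.a_min, gaw.a_max
    if a_max == a_min:
        raise ValueError("quotients undefined for a constant waveform")
    level = a_min + open_threshold * (a_max - a_min)
    open_mask = area > level
    closed = ~open_mask
    # reopen isolated closed samples (no closed neighbour, circularly)
    isolated = closed & ~np.roll(closed, 1) & ~np.roll(closed, -1)
    open_mask = open_mask | isolated
    oq = float(open_mask.mean())
    # rotate so the open phase is contiguous within the cycle
    closed = np.flatnonzero(~open_mask)
    shift = (closed[-1] + 1) % area.size if closed.size else 0
    rot = np.roll(area, -shift)
    open_rot = np.flatnonzero(np.roll(open_mask, -shift))
    first, last = open_rot[0], open_rot[-1]
    peak = int(np.argmax(rot))
    if peak <= first or peak >= last:
        raise ValueError("cannot separate opening and closing phases")
    sq = float((peak - first) / (last - peak))
    return oq, sq


@dataclass
class MetricsReport:
    """Per-case summary of aerodynamic and acoustic measures."""

    case_label: str
    spl_db: float
    ve: float  # dimensionless
    cpp_db: float
    formants_hz: list[float]
    q_mean_l_s: float
    r_glottis: float  # Pa·s/l
    w_net_j: float
    oq: float
    sq: float
    f0_detected_hz: float = float("nan")
    cpp_low_confidence: bool = False
    spl_mic_distance_m: float = 0.20

    @property
    def ve_percent(self) -> float:
        return 100.0 * self.ve

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ve_percent"] = self.ve_percent
        return d
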