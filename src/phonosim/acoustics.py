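"""Source-filter acoustic synthesis through an /a/ vocal tract.

The radiated sound is synthesized with the classic source-filter
paradigm: a monopole-type source proportional to the time derivative of
the glottal volume flow, shaped by a cascade of second-order resonators
placed at the /a/ vocal-tract formants (defaults F1 = 1020 Hz,
F2 = 1350 Hz), followed by a +6 dB/octave lip-radiation stage, and
spherical spreading towards virtual microphones on the mouth axis.

Absolute pressure amplitudes depend on a single source-calibration
constant; only level differences and trends across configurations are
physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .flow import FlowSeries

__all__ = [
    "VocalTractFilter",
    "AcousticSignal",
    "source_signal",
    "apply_vocal_tract",
    "lip_radiation",
    "radiate",
    "write_wav",
    "read_wav",
]

#: reference distance (m) at which the source pressure is expressed
SOURCE_REF_DISTANCE = 0.05
#: default source calibration: free-field monopole factor rho / (4 pi r)
#: at the reference distance, in Pa per (m³/s²)
DEFAULT_CALIBRATION = 1.18415 / (4.0 * np.pi * SOURCE_REF_DISTANCE)
#: lip-radiation differentiator normalization frequency (unity gain), Hz
LIP_RADIATION_REF_HZ = 1000.0


@dataclass
class AcousticSignal:
    """Uniformly sampled sound pressure at a named virtual microphone."""

    samples: np.ndarray  # Pa
    sample_rate: float  # Hz
    mic_distance: float  # m from the vocal-tract exit
    label: str = "mic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be at least 8 kHz")
        if self.mic_distance <= 0:
            raise ValueError("mic_distance must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class VocalTractFilter:
    """All-pole /a/ vocal tract as a cascade of two-pole resonators."""

    formant_frequencies: tuple[float, ...] = (1020.0, 1350.0)
    formant_bandwidths: tuple[float, ...] = (130.0, 160.0)
    gain: float = 1.0
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        freqs = tuple(self.formant_frequencies)
        bws = tuple(self.formant_bandwidths)
        if len(freqs) != len(bws):
            raise ValueError("one bandwidth per formant required")
        if any(b <= 0 for b in bws):
            raise ValueError("bandwidths must be positive")
        if list(freqs) != sorted(freqs) or len(set(freqs)) != len(freqs):
            raise ValueError("formant frequencies must be strictly increasing")
        if freqs and freqs[-1] >= self.sample_rate / 2:
            raise ValueError("formants must lie below Nyquist")
        self.formant_frequencies = freqs
        self.formant_bandwidths = bws
        self._cached_sections = None

    @staticmethod
    def _resonator(f: float, bw: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
        """Klatt-style two-pole resonator with unity DC gain."""
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        a = np.array([1.0, -2.0 * r * np.cos(theta), r**2])
        return np.array([a.sum()]), a

    def _sections(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(b, a) per resonator, pole frequencies tuned so the magnitude
        peaks of the *cascade* fall exactly on the formant frequencies
        (neighbouring resonators pull each other's peaks, so the pole
        angles are iterated until the joint response peaks on target)."""
        if getattr(self, "_cached_sections", None) is not None:
            return self._cached_sections
        from scipy.optimize import minimize_scalar

        fs = self.sample_rate
        targets = np.array(self.formant_frequencies, dtype=float)
        bws = np.array(self.formant_bandwidths, dtype=float)
        pole_f = targets.copy()

        def cascade_mag(freq_hz: float, sections) -> float:
            w = 2.0 * np.pi * freq_hz / fs
            h = 1.0
            for b, a in sections:
                _, hi = sps.freqz(b, a, worN=[w])
                h *= abs(hi[0])
            return h

        for _ in range(40):
            sections = [self._resonator(f, b, fs) for f, b in zip(pole_f, bws)]
            errs = np.zeros_like(targets)
            for i, (tgt, bw) in enumerate(zip(targets, bws)):
                res = minimize_scalar(
                    lambda f: -cascade_mag(f, sections),
                    bounds=(tgt - bw, tgt + bw),
                    method="bounded",
                    options={"xatol": 1e-4},
                )
                errs[i] = res.x - tgt
            if np.max(np.abs(errs)) < 1e-3:
                break
            pole_f -= errs
        self._cached_sections = [self._resonator(f, b, fs) for f, b in zip(pole_f, bws)]
        return self._cached_sections

    def frequency_response(self, n_freq: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies Hz, |H|) of the cascade on [0, Nyquist]."""
        freqs = np.linspace(0.0, self.sample_rate / 2, n_freq)
        h = np.full(n_freq, self.gain, dtype=complex)
        for b, a in self._sections():
            _, hi = sps.freqz(b, a, worN=freqs, fs=self.sample_rate)
            h *= hi
        return freqs, np.abs(h)


def source_signal(
    flow: FlowSeries,
    n_cycles: int = 20,
    sample_rate: float = 44100.0,
    calibration: float = DEFAULT_CALIBRATION,
) -> AcousticSignal:
    """Monopole-type source: calibrated dQ/dt tiled over ``n_cycles``.

    The cyclic flow is interpolated onto the audio grid, differentiated
    with a periodic centred difference, and scaled by the calibration
    constant (Pa per m³/s² at the 5 cm reference distance).  Output is
    zero-mean.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if sample_rate < 20 * flow.f0:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is below 20 f0 = {20 * flow.f0} Hz (aliasing)"
        )
    n = int(round(n_cycles * sample_rate / flow.f0))
    t = np.arange(n) / sample_rate
    cyc_phase = np.mod(t * flow.f0, 1.0)
    phase_ext = np.concatenate([flow.phase, [1.0]])
    q_ext = np.concatenate([flow.Q, [flow.Q[0]]])
    q = np.interp(cyc_phase, phase_ext, q_ext)
    dt = 1.0 / sample_rate
    dqdt = (np.roll(q, -1) - np.roll(q, 1)) / (2.0 * dt)
    src = calibration * dqdt
    src -= src.mean()
    return AcousticSignal(src, sample_rate, SOURCE_REF_DISTANCE, label="source")


def apply_vocal_tract(source: AcousticSignal, vt: VocalTractFilter | None = None) -> AcousticSignal:
    """Filter a source signal through the vocal-tract resonator cascade."""
    vt = vt or VocalTractFilter()
    if vt.sample_rate != source.sample_rate:
        vt = VocalTractFilter(
            vt.formant_frequencies, vt.formant_bandwidths, vt.gain, source.sample_rate
        )
    y = source.samples.astype(float)
    for b, a in vt._sections():
        y = sps.lfilter(b, a, y)
    y = vt.gain * y
    return AcousticSignal(y, source.sample_rate, source.mic_distance, label=source.label)


def lip_radiation(signal: AcousticSignal, ref_hz: float = LIP_RADIATION_REF_HZ) -> AcousticSignal:
    """+6 dB/octave first-difference radiation stage, unity gain at ``ref_hz``."""
    x = signal.samples
    y = np.empty_like(x)
    y[0] = 0.0
    y[1:] = x[1:] - x[:-1]
    scale = 1.0 / (2.0 * np.sin(np.pi * ref_hz / signal.sample_rate))
    return AcousticSignal(y * scale, signal.sample_rate, signal.mic_distance, label=signal.label)


def radiate(signal: AcousticSignal, from_distance: float, to_distance: float, label: str | None = None) -> AcousticSignal:
    """Spherical spreading: amplitude scales with from_distance/to_distance."""
    if from_distance <= 0 or to_distance <= 0:
        raise ValueError("distances must be positive")
    return AcousticSignal(
        signal.samples * (from_distance / to_distance),
        signal.sample_rate,
        to_distance,
        label=label or signal.label,
    )


def write_wav(path, signal: AcousticSignal) -> None:
    """Write a float32 PCM WAV file."""
    wavfile.write(path, int(signal.sample_rate), signal.samples.astype(np.float32))


def read_wav(path, mic_distance: float = 1.0, label: str = "wav") -> AcousticSignal:
    """Read a WAV file as an :class:`AcousticSignal` (int PCM is rescaled)."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AcousticSignal(data.astype(float), float(rate), mic_distance, label=label)
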