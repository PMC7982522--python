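"""Prescribed vocal-fold kinematics: GAW, gap modification and wall motion.

The baseline glottal area waveform (GAW) is a smooth skewed raised-cosine
pulse: closed on phase [0.9, 0.1) of the cycle, rising to its maximum
A0max at phase 0.36 (so the opening phase is shorter than the closing
phase, speed quotient < 1) and returning to zero at 0.9.  Per closure
type the waveform is remapped affinely so that its minimum equals the
initial gap area while the maximum is preserved:

    A_i(t) = A_i0 + (A0max - A_i0) / A0max * A_0(t)

Wall motion distributes the oscillatory part of the area over the folds
with a half-sine anterior–posterior envelope; a convergent/divergent
glottal-duct angle schedule emulates the mucosal wave (0° to +5° while
opening on [0.1T, 0.32T], 0° to −10° while closing on [0.32T, 0.9T]).
Left–right asymmetry reduces one fold's amplitude factor; a 50 % single
fold reduction scales the GAW oscillatory maxima to 75 % of symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GCType, LarynxFrame, gap_width_profile

__all__ = [
    "AreaWaveform",
    "MotionField",
    "baseline_gaw",
    "modify_gaw",
    "duct_angle",
    "build_motion",
    "load_gaw_csv",
]

#: cycle-phase interval during which the glottis is closed: [0.9, 1) u [0, 0.1)
CLOSURE_START = 0.9
CLOSURE_END = 0.1
#: default phase of the GAW maximum (before 0.5: opening faster than closing)
DEFAULT_PEAK_PHASE = 0.36

#: duct-angle schedule vertices (phase, degrees); piecewise linear between
#: them, 0° during closure.  Convergent +5° is reached mid-opening, the most
#: divergent −10° mid-closing.
ANGLE_VERTICES_PHASE = np.array([0.1, 0.21, 0.32, 0.61, 0.9])
ANGLE_VERTICES_DEG = np.array([0.0, 5.0, 0.0, -10.0, 0.0])


@dataclass
class AreaWaveform:
    """Glottal area over one cycle on a uniform phase grid in [0, 1)."""

    phase: np.ndarray  # dimensionless t/T
    area: np.ndarray  # mm²
    f0: float = 148.0  # Hz

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.phase.shape != self.area.shape:
            raise ValueError("phase and area must have the same shape")
        if np.any(self.area < 0):
            raise ValueError("glottal area must be non-negative")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def a_max(self) -> float:
        return float(self.area.max())

    @property
    def a_min(self) -> float:
        return float(self.area.min())

    @property
    def period(self) -> float:
        """Cycle period in seconds."""
        return 1.0 / self.f0

    def to_csv(self, path) -> None:
        pd.DataFrame({"phase": self.phase, "area_mm2": self.area}).to_csv(path, index=False)


def load_gaw_csv(path, f0: float = 148.0) -> AreaWaveform:
    """Load a sampled GAW from a two-column CSV (phase, area_mm2)."""
    df = pd.read_csv(path)
    return AreaWaveform(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), f0=f0)


def _baseline_shape(phase: np.ndarray, peak_phase: float) -> np.ndarray:
    """Normalized baseline pulse in [0, 1]: raised cosine with skewed peak."""
    phase = np.mod(phase, 1.0)
    out = np.zeros_like(phase)
    rising = (phase >= CLOSURE_END) & (phase <= peak_phase)
    falling = (phase > peak_phase) & (phase <= CLOSURE_START)
    out[rising] = 0.5 * (1 - np.cos(np.pi * (phase[rising] - CLOSURE_END) / (peak_phase - CLOSURE_END)))
    out[falling] = 0.5 * (1 + np.cos(np.pi * (phase[falling] - peak_phase) / (CLOSURE_START - peak_phase)))
    return out


def baseline_gaw(
    f0: float = 148.0,
    a0_max: float = 44.4997,
    n_samples: int = 2000,
    peak_phase: float = DEFAULT_PEAK_PHASE,
) -> AreaWaveform:
    """Baseline (fully closing) GAW sampled on ``n_samples`` uniform phases.

    The default ``a0_max`` corresponds to the validated frame,
    (2/pi) * 4.66 mm * 15 mm; pass :func:`~phonosim.geometry.baseline_max_area`
    of a custom frame otherwise.  ``n_samples`` divisible by 25 places the
    peak phase exactly on the grid.
    """
    if f0 <= 0 or a0_max <= 0:
        raise ValueError("f0 and a0_max must be positive")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if not CLOSURE_END < peak_phase < 0.5:
        raise ValueError("peak_phase must lie in (0.1, 0.5)")
    phase = np.arange(n_samples) / n_samples
    return AreaWaveform(phase, a0_max * _baseline_shape(phase, peak_phase), f0=f0)


def modify_gaw(base: AreaWaveform, gc: GCType) -> AreaWaveform:
    """Affine gap modification preserving the cycle maximum.

    Maps the baseline wave so the minimum equals the closure type's initial
    gap area: A_i = A_i0 + (A0max - A_i0)/A0max * A_0.
    """
    a0_max = base.a_max
    a_i0 = gc.initial_gap_area
    if a_i0 > a0_max:
        raise ValueError(
            f"initial_gap_area {a_i0} mm² exceeds the baseline maximum {a0_max} mm²"
        )
    area = a_i0 + (a0_max - a_i0) / a0_max * base.area
    return AreaWaveform(base.phase.copy(), area, f0=base.f0)


def duct_angle(phase) -> np.ndarray | float:
    """Glottal-duct angle in degrees at cycle phase t/T (modulo 1).

    Positive = convergent duct (opening phase), negative = divergent
    (closing phase), 0 during closure.
    """
    phase_arr = np.mod(np.asarray(phase, dtype=float), 1.0)
    ang = np.interp(phase_arr, ANGLE_VERTICES_PHASE, ANGLE_VERTICES_DEG, left=0.0, right=0.0)
    ang = np.where((phase_arr < CLOSURE_END) | (phase_arr >= CLOSURE_START), 0.0, ang)
    if np.isscalar(phase):
        return float(ang)
    return ang


@dataclass
class MotionField:
    """Sampled wall kinematics of both folds over one cycle.

    ``displacement`` holds the medial–lateral displacement of each fold
    away from its minimum-gap position, in mm, indexed
    ``(fold, station, phase)`` with fold 0 = upper, fold 1 = lower;
    positive displacement opens the glottis (points along the into-tissue
    wall normal).  ``velocity`` is its time derivative in m/s.
    """

    phase: np.ndarray
    stations: np.ndarray  # mm, anterior–posterior
    displacement: np.ndarray  # (2, S, T) mm
    velocity: np.ndarray  # (2, S, T) m/s
    duct_angle_deg: np.ndarray  # (T,)
    amplitude_factors: tuple[float, float]
    f0: float
    min_width: np.ndarray = field(default=None)  # (S,) mm at minimum opening

    @property
    def width(self) -> np.ndarray:
        """Inter-fold gap width (S, T) in mm."""
        return self.min_width[:, None] + self.displacement.sum(axis=0)

    def gaw(self) -> AreaWaveform:
        """GAW recovered by integrating the width over the stations."""
        dz = self.stations[1] - self.stations[0]
        return AreaWaveform(self.phase.copy(), self.width.sum(axis=0) * dz, f0=self.f0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (fold, z_mm, phase, displacement_mm, velocity_m_s)."""
        folds = np.array(["upper", "lower"])
        f, s, t = np.meshgrid(
            np.arange(2), np.arange(self.stations.size), np.arange(self.phase.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "fold": folds[f.ravel()],
                "z_mm": self.stations[s.ravel()],
                "phase": self.phase[t.ravel()],
                "displacement_mm": self.displacement.ravel(),
                "velocity_m_s": self.velocity.ravel(),
            }
        )


def build_motion(
    gaw: AreaWaveform,
    frame: LarynxFrame,
    gc: GCType | None = None,
    amplitude_factors: tuple[float, float] = (1.0, 1.0),
    n_stations: int = 200,
) -> MotionField:
    """Prescribed elliptic wall motion realizing a (possibly gapped) GAW.

    The oscillatory part of the area, ``gaw.area - gaw.a_min``, is carried
    by a half-sine envelope sin(pi z / L) over the full fold length and
    split evenly between the folds, each then scaled by its amplitude
    factor.  With symmetric factors (1, 1) the integrated width reproduces
    the input GAW exactly and the baseline (no-gap) configuration reaches
    the frame's maximum glottal width; factors (1, 0.5) scale the GAW
    oscillatory maxima to 75 % of symmetric.  The minimum-gap offset is a
    geometric insufficiency and is not scaled by the factors.

    ``gc=None`` denotes the baseline validation configuration (zero
    minimum gap).
    """
    f_up, f_lo = amplitude_factors
    if not (0.0 < f_up <= 1.0) or not (0.0 < f_lo <= 1.0):
        raise ValueError("amplitude factors must lie in (0, 1]")
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")

    length = frame.vf_length
    if gc is None:
        dz = length / n_stations
        z = (np.arange(n_stations) + 0.5) * dz
        min_width = np.zeros(n_stations)
        a_min = float(gaw.a_min)
    else:
        z, min_width = gap_width_profile(gc, frame, n_stations)
        a_min = gc.initial_gap_area
        if abs(gaw.a_min - a_min) > 1e-9 * max(1.0, a_min):
            raise ValueError("gaw minimum does not match the closure type's gap area")

    envelope = np.sin(np.pi * z / length)  # (S,)
    osc_area = gaw.area - a_min  # (T,) mm²
    # per-fold half amplitude; symmetric sum integrates back to osc_area
    half = osc_area[None, :] * (np.pi / (4.0 * length)) * envelope[:, None]  # (S, T)
    displacement = np.stack([f_up * half, f_lo * half])  # (2, S, T) mm

    dt = 1.0 / (gaw.f0 * gaw.phase.size)
    # periodic centred difference, mm -> m
    vel = (np.roll(displacement, -1, axis=2) - np.roll(displacement, 1, axis=2)) / (2 * dt) * 1e-3

    return MotionField(
        phase=gaw.phase.copy(),
        stations=z,
        displacement=displacement,
        velocity=vel,
        duct_angle_deg=np.asarray(duct_angle(gaw.phase), dtype=float),
        amplitude_factors=(f_up, f_lo),
        f0=gaw.f0,
        min_width=min_width,
    )
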