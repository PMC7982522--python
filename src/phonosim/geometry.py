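"""Parametric glottis geometry for the five closure types (GC1–GC5).

The glottis is described by two parameters per closure type: the initial
(minimum-opening) glottal gap area and the fraction of the vocal-fold
length that is closed at minimum opening.  GC1 represents full closure
(with a hairline residual slit of 0.5 mm² kept for numerical robustness),
GC2 and GC3 partial posterior closure (60 % and 30 % of the length
closed), GC4 a fully open triangular posterior gap, and GC5 a rectangular
full-length gap (complete glottal insufficiency).

The anterior–posterior axis is z in [0, vf_length] with z = 0 anterior;
triangular gaps open toward the posterior end (z = vf_length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GCType",
    "LarynxFrame",
    "GC_IDS",
    "make_gc",
    "baseline_max_area",
    "gap_width_profile",
    "closed_fraction_of",
]

GC_IDS = ("GC1", "GC2", "GC3", "GC4", "GC5")

#: closed-length fraction and gap shape per closure type
_CLOSED_FRACTION = {"GC1": 1.0, "GC2": 0.6, "GC3": 0.3, "GC4": 0.0, "GC5": 0.0}
_GAP_SHAPE = {
    "GC1": "none",
    "GC2": "triangular_posterior",
    "GC3": "triangular_posterior",
    "GC4": "triangular_posterior",
    "GC5": "rectangular",
}

#: default initial gap areas in mm².  GC1 is the 0.5 mm² stability floor.
#: GC2–GC4 are increasing placeholder values (the source ex vivo gap-index
#: areas are not published); GC5 is half the baseline maximum GAW area and
#: is filled in by :func:`make_gc` from the larynx frame.
_DEFAULT_GAP_AREA = {"GC1": 0.5, "GC2": 2.0, "GC3": 5.0, "GC4": 10.0, "GC5": None}

#: width below which a station counts as closed, in mm (1e-9 m)
DEFAULT_CLOSED_TOL_MM = 1e-6


@dataclass(frozen=True)
class LarynxFrame:
    """Scalar laryngeal frame dimensions, all in mm.

    Defaults are the validated male-scale configuration: 15 mm vocal-fold
    length, 4.66 mm maximum glottal width, 5 mm ventricular-fold gap and
    171 mm from the vocal folds to the vocal-tract exit.
    """

    vf_length: float = 15.0
    max_glottal_width: float = 4.66
    vef_gap: float = 5.0
    vf_to_mouth: float = 171.0

    def __post_init__(self) -> None:
        for name in ("vf_length", "max_glottal_width", "vef_gap", "vf_to_mouth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class GCType:
    """One glottal-closure configuration.

    Attributes
    ----------
    id : str
        One of ``GC1``..``GC5``.
    closed_fraction : float
        Fraction of the vocal-fold length closed at minimum opening.
    gap_shape : str
        ``triangular_posterior``, ``rectangular`` or ``none`` (GC1, whose
        residual floor area is a uniform hairline slit).
    initial_gap_area : float
        Minimum-opening glottal area in mm².
    """

    id: str
    closed_fraction: float
    gap_shape: str
    initial_gap_area: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.closed_fraction <= 1.0:
            raise ValueError("closed_fraction must be in [0, 1]")
        if self.initial_gap_area < 0:
            raise ValueError("initial_gap_area must be non-negative")


def baseline_max_area(frame: LarynxFrame | None = None) -> float:
    """Maximum area of the baseline glottal area waveform, in mm².

    The motion model opens the glottis with a half-sine anterior–posterior
    envelope whose peak reaches the maximum glottal width d_G, so the peak
    area is the half-sine integral (2/pi) * d_G * L_VF (≈ 44.5 mm² for the
    default frame).
    """
    frame = frame or LarynxFrame()
    return 2.0 / math.pi * frame.max_glottal_width * frame.vf_length


def make_gc(gc_id: str, frame: LarynxFrame | None = None, **overrides: float) -> GCType:
    """Build a :class:`GCType` with documented defaults.

    Parameters
    ----------
    gc_id : str
        One of ``GC1``..``GC5``.
    frame : LarynxFrame, optional
        Needed only to derive GC5's default gap area (half the baseline
        maximum GAW area).
    **overrides
        ``closed_fraction`` and/or ``initial_gap_area`` replacements.
    """
    if gc_id not in GC_IDS:
        raise KeyError(f"unknown glottal closure type {gc_id!r}; expected one of {GC_IDS}")
    area = _DEFAULT_GAP_AREA[gc_id]
    if area is None:  # GC5: half the maximum baseline GAW
        area = 0.5 * baseline_max_area(frame)
    gc = GCType(
        id=gc_id,
        closed_fraction=_CLOSED_FRACTION[gc_id],
        gap_shape=_GAP_SHAPE[gc_id],
        initial_gap_area=area,
    )
    if overrides:
        allowed = {"closed_fraction", "initial_gap_area"}
        unknown = set(overrides) - allowed
        if unknown:
            raise TypeError(f"unknown override(s): {sorted(unknown)}")
        gc = replace(gc, **overrides)  # __post_init__ re-validates
    return gc


def gap_width_profile(
    gc: GCType, frame: LarynxFrame, n_stations: int
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-opening gap width at ``n_stations`` anterior–posterior stations.

    Stations are uniform cell centres of [0, vf_length], so the midpoint-rule
    integral of the returned widths recovers the initial gap area and the
    closed-length fraction is an exact station count for the GC2/GC3
    closure boundaries.

    Returns
    -------
    (z, width) : tuple of ndarray
        Station positions and gap widths, both in mm.
    """
    if n_stations < 2:
        raise ValueError(f"n_stations must be >= 2, got {n_stations}")
    length = frame.vf_length
    dz = length / n_stations
    z = (np.arange(n_stations) + 0.5) * dz
    area = gc.initial_gap_area

    if gc.gap_shape == "rectangular" or gc.gap_shape == "none":
        # GC5 gap, and the GC1 stability floor, are uniform slits
        width = np.full(n_stations, area / length)
    elif gc.gap_shape == "triangular_posterior":
        z_closed = gc.closed_fraction * length
        open_len = length - z_closed
        w_post = 2.0 * area / open_len  # triangle: area = 0.5 * base * height
        width = np.where(z > z_closed, (z - z_closed) / open_len * w_post, 0.0)
    else:  # pragma: no cover - enum guarded in make_gc
        raise ValueError(f"unknown gap shape {gc.gap_shape!r}")
    return z, width


def closed_fraction_of(profile: np.ndarray, tol: float = DEFAULT_CLOSED_TOL_MM) -> float:
    """Fraction of stations whose gap width is at or below ``tol`` (mm).

    Contiguity of the closed region is not assumed.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty width profile")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    return float(np.count_nonzero(profile <= tol) / profile.size)
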