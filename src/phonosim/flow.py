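"""Quasi-steady glottal flow surrogate, resistance and energy transfer.

The volume flow through the time-varying glottal area is modeled as an
incompressible quasi-steady orifice (Bernoulli) flow,

    Q(t) = Cd * A(t) * sqrt(2 (p_inlet - p_outlet) / rho),

a standard reduced-order stand-in for a resolved glottal flow field; it
neglects inertance, viscous losses and turbulence.  The wall-pressure
record blends the inlet pressure (weighted by the convergent duct angle,
pushing the folds apart while they open) with the Bernoulli static
pressure at the minimal section (suction while the duct is divergent),
which yields the physiological positive net energy transfer from flow to
tissue over a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import AreaWaveform, MotionField, duct_angle

__all__ = [
    "FlowConditions",
    "FlowSeries",
    "solve_flow",
    "glottal_resistance",
    "energy_transfer",
]

#: effective inferior–superior depth of the medial fold surface used to
#: convert station line elements into wall area elements, in mm
DEFAULT_CONTACT_DEPTH_MM = 3.0


@dataclass(frozen=True)
class FlowConditions:
    """Driving pressures and air properties (SI units)."""

    p_inlet: float = 775.0  # Pa, subglottal
    p_outlet: float = 0.0  # Pa, mouth
    rho: float = 1.18415  # kg/m³
    nu: float = 1.5666e-5  # m²/s, kinematic viscosity (reporting only)
    discharge_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.p_inlet <= self.p_outlet:
            raise ValueError("p_inlet must exceed p_outlet")
        if not 0.0 < self.discharge_coefficient <= 1.0:
            raise ValueError("discharge_coefficient must be in (0, 1]")
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("rho and nu must be positive")

    @property
    def dp(self) -> float:
        return self.p_inlet - self.p_outlet


@dataclass
class FlowSeries:
    """Volume flow and wall pressure over one cycle."""

    phase: np.ndarray
    Q: np.ndarray  # m³/s, (T,)
    wall_pressure: np.ndarray  # Pa, (T,) uniform over folds and stations
    transglottal_dp: float  # Pa
    f0: float

    @property
    def Q_l_s(self) -> np.ndarray:
        return self.Q * 1e3

    @property
    def q_mean(self) -> float:
        """Cycle-mean flow in m³/s (periodic uniform grid: plain phase mean)."""
        return float(self.Q.mean())

    @property
    def q_mean_l_s(self) -> float:
        return self.q_mean * 1e3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"phase": self.phase, "Q_l_s": self.Q_l_s, "dp_Pa": self.transglottal_dp}
        )


def solve_flow(gaw: AreaWaveform, cond: FlowConditions | None = None) -> FlowSeries:
    """Quasi-steady orifice flow through the glottal area waveform."""
    cond = cond or FlowConditions()
    if np.any(gaw.area < 0):
        raise ValueError("glottal area must be non-negative")
    area_m2 = gaw.area * 1e-6
    u_jet = cond.discharge_coefficient * np.sqrt(2.0 * cond.dp / cond.rho)  # m/s
    Q = area_m2 * u_jet

    # Bernoulli static pressure at the minimal section; with Cd = 1 this
    # equals p_outlet.  Where the glottis carries no flow the static
    # pressure is the stagnant inlet value (walls are at rest there anyway).
    p_static = np.where(Q > 0, cond.p_inlet - 0.5 * cond.rho * u_jet**2, cond.p_inlet)
    ang = np.asarray(duct_angle(gaw.phase), dtype=float)
    conv_weight = np.clip(ang / 5.0, 0.0, 1.0)  # 1 at full convergence
    p_wall = p_static + (cond.p_inlet - p_static) * conv_weight

    return FlowSeries(
        phase=gaw.phase.copy(),
        Q=Q,
        wall_pressure=p_wall,
        transglottal_dp=cond.dp,
        f0=gaw.f0,
    )


def glottal_resistance(flow: FlowSeries, cond: FlowConditions | None = None) -> float:
    """Glottal flow resistance Δp / Q̄ in Pa·s/l (van den Berg)."""
    cond = cond or FlowConditions()
    if flow.q_mean_l_s <= 0:
        raise ZeroDivisionError("glottal resistance undefined for zero mean flow")
    return cond.dp / flow.q_mean_l_s


def energy_transfer(
    motion: MotionField,
    flow: FlowSeries,
    contact_depth_mm: float = DEFAULT_CONTACT_DEPTH_MM,
) -> tuple[np.ndarray, float]:
    """Net aerodynamic-to-tissue energy transfer rate and cycle work.

    Ė_net(t) = Σ_folds Σ_stations p_wall · (v_wall · n̂) · dS with n̂ the
    into-tissue wall normal (positive while the folds open), and
    W_net = ∮ Ė_net dt over one cycle.  Positive W_net means the airflow
    drives the tissue, the physiological situation for phonation.

    Returns
    -------
    (edot, w_net) : (ndarray in W, float in J)
    """
    if motion.phase.size != flow.phase.size:
        raise ValueError("motion and flow phase grids differ")
    if not np.allclose(motion.phase, flow.phase):
        raise ValueError("motion and flow phase grids differ")
    dz = (motion.stations[1] - motion.stations[0]) * 1e-3  # m
    ds = dz * contact_depth_mm * 1e-3  # m² per station element, per fold
    # wall pressure is uniform over folds/stations at each phase
    edot = (motion.velocity.sum(axis=(0, 1)) * flow.wall_pressure) * ds  # (T,) W
    w_net = float(edot.mean() / motion.f0)  # ∮ dt over one period
    return edot, w_net
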