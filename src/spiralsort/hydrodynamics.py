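"""Fluid velocity, dimensionless numbers, and the lift/Dean force balance.

Conventions
-----------
* Volumetric flow rate ``Q`` is given in mL/min, channel dimensions in µm,
  particle diameters ``a_p`` in µm; forces are returned in newtons and
  velocities in m/s.
* ``Re = ρ U_f D_h / μ`` (mean-velocity, hydraulic-diameter Reynolds number),
  ``De = Re √(D_h / 2R)`` (Dean number), ``R_p = Re (a_p / D_h)²`` (particle
  Reynolds number).
* Inertial lift is modelled as ``F_L = C_L ρ U_f² a_p⁴ / (w h)`` — the steep
  quartic size dependence and inverse cross-section dependence that drives
  size-selective focusing.  Dean drag is Stokes drag on the secondary-flow
  velocity, ``F_D = 3π μ U_De a_p``, with the empirical secondary-flow
  correlation ``U_De = 1.8×10⁻⁴ · De^1.63`` (m/s).
* Reporting rounding (half-up): velocities, De and R_p to 2 decimals, Re to
  the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, local_section

__all__ = [
    "FluidProperties",
    "ForceModel",
    "FlowState",
    "ForceBalance",
    "WATER",
    "mean_velocity",
    "reynolds_number",
    "dean_number",
    "particle_reynolds",
    "dean_velocity",
    "lift_force",
    "dean_drag_force",
    "classify_regime",
    "force_ratio_scaling",
    "flow_state",
    "force_balance",
    "dimensionless_table",
    "round_half_up",
]

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
UM = 1e-6
MM = 1e-3

DEAN_DOMINATED = "dean_dominated"
BALANCED = "balanced"
LIFT_DOMINATED = "lift_dominated"


class HydrodynamicsError(ValueError):
    pass


class CurvatureError(HydrodynamicsError):
    """Dean number requested for a straight (zero-radius) channel."""


class IndeterminateRegimeError(HydrodynamicsError):
    """Both lift and Dean forces vanish; no regime can be assigned."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (1.125 → 1.13 at 2 digits), as in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-fluid density (kg/m³) and dynamic viscosity (Pa·s)."""

    density_kg_m3: float = 1000.0
    viscosity_pa_s: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise HydrodynamicsError("fluid density and viscosity must be positive")


#: Water at room temperature — the unique round values reproducing Re = 200
#: at the reference inlet (w=200 µm, h=100 µm, Q=1.8 mL/min).
WATER = FluidProperties()


@dataclass(frozen=True)
class ForceModel:
    """Tunable constants of the reduced-order force model.

    lift_coefficient
        Dimensionless lift prefactor C_L.  Calibrated once against the
        device's simulated flow-rate operating window (see docs/methods.md).
    dean_velocity_coeff, dean_velocity_exponent
        The ``U_De = c·De^m`` secondary-flow correlation (m/s).
    regime_band
        Half-width (as a multiplicative factor) of the "balanced" band:
        F_L/F_D above the band is lift-dominated, below its reciprocal is
        Dean-dominated.
    """

    lift_coefficient: float = 10.0
    dean_velocity_coeff: float = 1.8e-4
    dean_velocity_exponent: float = 1.63
    regime_band: float = 10.0

    def __post_init__(self) -> None:
        if self.lift_coefficient <= 0 or self.dean_velocity_coeff <= 0:
            raise HydrodynamicsError("force-model coefficients must be positive")
        if self.regime_band <= 1:
            raise HydrodynamicsError("regime_band must exceed 1")


@dataclass(frozen=True)
class FlowState:
    """Flow characterisation at one spiral locus (unrounded values)."""

    s: float
    u_f_m_s: float
    re: float
    de: float
    rp: Mapping[float, float]  # particle diameter µm -> R_p

    def __post_init__(self) -> None:
        if min(self.u_f_m_s, self.re, self.de, *self.rp.values(), 0.0) < 0:
            raise HydrodynamicsError("flow-state quantities must be non-negative")
        sizes = sorted(self.rp)
        vals = [self.rp[a] for a in sizes]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise HydrodynamicsError("R_p must increase with particle diameter")


@dataclass(frozen=True)
class ForceBalance:
    """Lift and Dean force magnitudes for one particle size at one locus."""

    a_p_um: float
    lift_n: float
    dean_n: float
    regime: str

    @property
    def ratio(self) -> float:
        return self.lift_n / self.dean_n if self.dean_n > 0 else math.inf


def mean_velocity(q_ml_min: float, width_um: float, height_um: float) -> float:
    """Mean axial velocity U_f = Q/(w·h) in m/s."""
    if q_ml_min < 0:
        raise HydrodynamicsError("flow rate must be non-negative")
    if width_um <= 0 or height_um <= 0:
        raise HydrodynamicsError("cross-section dimensions must be positive")
    return q_ml_min * ML_PER_MIN_TO_M3_PER_S / (width_um * UM * height_um * UM)


def reynolds_number(fluid: FluidProperties, u_f_m_s: float, d_h_um: float) -> float:
    """Channel Reynolds number Re = ρ U_f D_h / μ."""
    if u_f_m_s < 0 or d_h_um <= 0:
        raise HydrodynamicsError("need U_f >= 0 and D_h > 0")
    return fluid.density_kg_m3 * u_f_m_s * d_h_um * UM / fluid.viscosity_pa_s


def dean_number(re: float, d_h_um: float, radius_mm: float) -> float:
    """Dean number De = Re·√(D_h / 2R) for radius of curvature R."""
    if re < 0 or d_h_um <= 0:
        raise HydrodynamicsError("need Re >= 0 and D_h > 0")
    if radius_mm == 0:
        raise CurvatureError("Dean number is undefined at zero radius of curvature")
    if math.isinf(radius_mm):
        return 0.0
    if radius_mm < 0:
        raise HydrodynamicsError("radius of curvature must be positive")
    return re * math.sqrt(d_h_um * UM / (2.0 * radius_mm * MM))


def particle_reynolds(re: float, a_p_um: float, d_h_um: float) -> float:
    """Particle Reynolds number R_p = Re·(a_p/D_h)²."""
    if a_p_um <= 0 or d_h_um <= 0:
        raise HydrodynamicsError("particle and hydraulic diameters must be positive")
    return re * (a_p_um / d_h_um) ** 2


def dean_velocity(de: float, model: ForceModel = ForceModel()) -> float:
    """Mean secondary-flow (Dean) velocity in m/s; 0 at De = 0."""
    if de < 0:
        raise HydrodynamicsError("Dean number must be non-negative")
    return model.dean_velocity_coeff * de ** model.dean_velocity_exponent


def lift_force(
    fluid: FluidProperties,
    u_f_m_s: float,
    a_p_um: float,
    width_um: float,
    height_um: float,
    model: ForceModel = ForceModel(),
) -> float:
    """Inertial lift magnitude F_L = C_L ρ U_f² a_p⁴/(w h), in newtons."""
    if min(u_f_m_s, a_p_um, width_um, height_um) < 0 or a_p_um == 0:
        raise HydrodynamicsError("lift force needs non-negative inputs, a_p > 0")
    return (
        model.lift_coefficient
        * fluid.density_kg_m3
        * u_f_m_s ** 2
        * (a_p_um * UM) ** 4
        / (width_um * UM * height_um * UM)
    )


def dean_drag_force(fluid: FluidProperties, u_de_m_s: float, a_p_um: float) -> float:
    """Stokes drag of the secondary flow, F_D = 3π μ U_De a_p, in newtons."""
    if u_de_m_s < 0 or a_p_um < 0:
        raise HydrodynamicsError("Dean drag needs non-negative inputs")
    return 3.0 * math.pi * fluid.viscosity_pa_s * u_de_m_s * a_p_um * UM


def classify_regime(lift_n: float, dean_n: float, band: float = 10.0) -> str:
    """Classify the force balance into dean_dominated / balanced / lift_dominated.

    The balanced band is ``1/band < F_L/F_D < band``; the two excluded limits
    are the failure modes of a spiral sorter (all sizes collapsing to one
    stream, or Dean mixing destroying focusing).
    """
    if lift_n < 0 or dean_n < 0:
        raise HydrodynamicsError("forces must be non-negative")
    if band <= 1:
        raise HydrodynamicsError("band must exceed 1")
    if lift_n == 0 and dean_n == 0:
        raise IndeterminateRegimeError("both forces vanish; regime undefined")
    if dean_n == 0:
        return LIFT_DOMINATED
    r = lift_n / dean_n
    if r > band:
        return LIFT_DOMINATED
    if r < 1.0 / band:
        return DEAN_DOMINATED
    return BALANCED


def force_ratio_scaling(a_p_um: float, height_um: float) -> float:
    """The cubed size-to-height law F_L/F_D ∝ (a_p/h)³."""
    if a_p_um <= 0 or height_um <= 0:
        raise HydrodynamicsError("diameter and height must be positive")
    return (a_p_um / height_um) ** 3


def flow_state(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    q_ml_min: float,
    s: float,
    sizes_um: Sequence[float] = (7.0, 10.0, 15.0),
) -> FlowState:
    """Evaluate U_f, Re, De and per-size R_p at locus ``s`` (unrounded)."""
    w, r, dh, _ = local_section(geometry, s)
    u = mean_velocity(q_ml_min, w, geometry.height_um)
    re = reynolds_number(fluid, u, dh)
    de = dean_number(re, dh, r)
    rp = {float(a): particle_reynolds(re, a, dh) for a in sizes_um}
    return FlowState(s=float(s), u_f_m_s=u, re=re, de=de, rp=rp)


def force_balance(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    q_ml_min: float,
    s: float,
    a_p_um: float,
    model: ForceModel = ForceModel(),
) -> ForceBalance:
    """Lift/Dean force magnitudes and regime for one size at one locus."""
    w, r, dh, _ = local_section(geometry, s)
    u = mean_velocity(q_ml_min, w, geometry.height_um)
    re = reynolds_number(fluid, u, dh)
    de = dean_number(re, dh, r)
    fl = lift_force(fluid, u, a_p_um, w, geometry.height_um, model)
    fd = dean_drag_force(fluid, dean_velocity(de, model), a_p_um)
    regime = classify_regime(fl, fd, model.regime_band)
    return ForceBalance(a_p_um=a_p_um, lift_n=fl, dean_n=fd, regime=regime)


def dimensionless_table(
    geometry: ChannelGeometry,
    fluid: FluidProperties = WATER,
    q_ml_min: float = 1.8,
    sizes_um: Sequence[float] = (7.0, 10.0, 15.0),
) -> pd.DataFrame:
    """Characterisation table (inlet + each turn) with reporting rounding.

    Columns: position, Uf_m_per_s, Re, De, Rp_<size>um.  Rounding follows the
    printed-table convention: U_f/De/R_p half-up to 2 decimals, Re to the
    nearest integer.
    """
    loci = [("Inlet", 0.0)] + [
        (f"Turn {k}", geometry.turn_position(k)) for k in range(1, geometry.n_turns + 1)
    ]
    rows = []
    for name, s in loci:
        st = flow_state(geometry, fluid, q_ml_min, s, sizes_um)
        row = {
            "position": name,
            "Uf_m_per_s": round_half_up(st.u_f_m_s, 2),
            "Re": int(round_half_up(st.re, 0)),
            "De": round_half_up(st.de, 2),
        }
        for a in sizes_um:
            row[f"Rp_{a:g}um"] = round_half_up(st.rp[float(a)], 2)
        rows.append(row)
    return pd.DataFrame(rows)
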