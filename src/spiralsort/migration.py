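"""One-dimensional lateral migration model along the spiral.

The cross-sectional dynamics are collapsed onto the width coordinate
``x ∈ [0, 1]`` (0 = inner wall, 1 = outer wall).  At every locus the shear-
gradient/wall lift drives a particle toward a size-dependent equilibrium
position near the inner wall, while Dean drag shifts that equilibrium toward
the channel centre; in the Dean-dominated limit the equilibrium is lost and
particles drift to the centre, mixed by the secondary flow.

The overdamped lateral velocity is

    v_lat = (F_L / 3πμa_p) · (x_eq − x) / ξ,

with the restoring-arm constant ξ setting the stiffness of the lift restoring
force, and

    x_eq = x_wall + k·(F_D/F_L),   clipped to (0, 0.5],
    x_wall = 0.2·D_h/w,

so larger particles (larger F_L/F_D ∝ a_p³) sit closer to the inner wall.
Normalizing arc length to ``s ∈ [0, 1]`` gives

    dx/ds = v_lat · L_channel / (U_f(s) · w(s)),

integrated with a fixed-step classical 4th-order Runge–Kutta scheme (the
module is fully deterministic).

High-flow-rate defocusing is captured by the Dean sweep number — the number
of channel widths the secondary flow sweeps a particle through during
transit.  When it exceeds a threshold, lateral mixing destroys focusing
("defocused"), which closes the upper end of the operating window.

The constants ``lift_coefficient`` (in :class:`ForceModel`), ``eq_shift_gain``,
``restoring_arm`` and ``mixing_threshold`` are calibrated once against the
device's printed design constraints (operating window ≈1.5–1.9 mL/min,
≈20 µm adjacent stream spacing at the outlet); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, channel_length_m, local_section
from .hydrodynamics import (
    BALANCED,
    DEAN_DOMINATED,
    LIFT_DOMINATED,
    FluidProperties,
    ForceModel,
    HydrodynamicsError,
    ML_PER_MIN_TO_M3_PER_S,
    UM,
    WATER,
)

__all__ = [
    "MigrationModel",
    "MigrationResult",
    "IntegrationResolutionError",
    "equilibrium_position",
    "simulate_migration",
    "migrate_positions",
    "dean_mixing_number",
    "flow_rate_scan",
    "operating_window",
]

UNFOCUSED = "unfocused"
FOCUSED = "focused"
DEFOCUSED = "defocused"
UNSEPARATED = "unseparated"


class IntegrationResolutionError(RuntimeError):
    """Per-step lateral displacement exceeded 0.25; increase n_steps."""


@dataclass(frozen=True)
class MigrationModel:
    """Constants of the 1-D migration model (see module docstring).

    eq_shift_gain
        k in ``x_eq = x_wall + k·F_D/F_L`` (dimensionless); calibrated so the
        three bead sizes span ≈20 µm at the outlet.
    restoring_arm
        ξ, the lever arm (in channel widths) over which the full lift force
        is developed; sets migration speed, hence the low-flow-rate edge of
        the operating window.
    wall_offset_coeff
        x_wall = coeff·D_h/w, the canonical near-wall equilibrium distance.
    focusing_tol
        A particle is "focused" when it ends within this fraction of the
        width of its local equilibrium.
    mixing_threshold
        Critical Dean sweep number above which streams are defocused.
    min_spacing_um
        Minimum adjacent stream spacing for the scan to call sizes separated.
    """

    force: ForceModel = field(default_factory=ForceModel)
    eq_shift_gain: float = 0.015
    restoring_arm: float = 1.05
    wall_offset_coeff: float = 0.2
    focusing_tol: float = 0.01
    mixing_threshold: float = 16.0
    min_spacing_um: float = 5.0

    def __post_init__(self) -> None:
        if min(self.eq_shift_gain, self.restoring_arm, self.wall_offset_coeff,
               self.focusing_tol, self.mixing_threshold) <= 0:
            raise ValueError("migration-model constants must be positive")


@dataclass(frozen=True)
class MigrationResult:
    """Trajectory and focusing outcome for one particle size."""

    a_p_um: float
    s_grid: np.ndarray
    x: np.ndarray            # lateral position, normalized to [0, 1]
    x_out: float
    focused: bool
    regime_outlet: str | None
    s_focus: float | None    # first arc position from which the particle stays focused


# -- locus coefficient tables ------------------------------------------------


def _locus_coefficients(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    q_ml_min: float,
    model: MigrationModel,
    s: np.ndarray,
):
    """Per-locus scalar coefficients of the force balance, vectorized in s.

    Returns (c_fl, c_fd, x_wall, pref) such that for a particle of diameter
    a (metres): F_L = c_fl·a⁴, F_D = c_fd·a, and dx/ds = (F_L·pref/a)(x_eq−x).
    """
    fm = model.force
    h_m = geometry.height_um * UM
    w_m = geometry.width_um(s) * UM
    r_m = geometry.radius_mm(s) * 1e-3
    dh_m = 2.0 * w_m * h_m / (w_m + h_m)
    q = q_ml_min * ML_PER_MIN_TO_M3_PER_S
    u = q / (w_m * h_m)
    re = fluid.density_kg_m3 * u * dh_m / fluid.viscosity_pa_s
    de = re * np.sqrt(dh_m / (2.0 * r_m))
    u_de = fm.dean_velocity_coeff * de ** fm.dean_velocity_exponent
    c_fl = fm.lift_coefficient * fluid.density_kg_m3 * u ** 2 / (w_m * h_m)
    c_fd = 3.0 * math.pi * fluid.viscosity_pa_s * u_de
    x_wall = model.wall_offset_coeff * dh_m / w_m
    length = channel_length_m(geometry)
    with np.errstate(divide="ignore"):
        pref = length / (3.0 * math.pi * fluid.viscosity_pa_s * u * w_m * model.restoring_arm)
    return c_fl, c_fd, x_wall, pref


def _target(c_fl, c_fd, x_wall, a_m, a4, gain):
    """Shifted equilibrium position, clipped to the inner half of the width."""
    fl = c_fl * a4
    fd = c_fd * a_m
    return np.minimum(x_wall + gain * fd / fl, 0.5)


def equilibrium_position(
    a_p_um: float,
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    q_ml_min: float,
    s: float = 1.0,
    model: MigrationModel = MigrationModel(),
) -> float | None:
    """Equilibrium lateral position at locus ``s``, or None when no
    equilibrium exists (Dean-dominated regime: the particle is unfocused).

    Strictly decreasing in particle diameter; collapses to the near-wall
    position x_wall for all sizes in the lift-dominated limit.
    """
    if q_ml_min <= 0:
        raise HydrodynamicsError("equilibrium position needs a positive flow rate")
    sv = np.asarray([float(s)])
    c_fl, c_fd, x_wall, _ = _locus_coefficients(geometry, fluid, q_ml_min, model, sv)
    a_m = a_p_um * UM
    fl = float(c_fl[0]) * a_m ** 4
    fd = float(c_fd[0]) * a_m
    if fl / fd < 1.0 / model.force.regime_band:
        return None
    return float(_target(c_fl, c_fd, x_wall, a_m, a_m ** 4, model.eq_shift_gain)[0])


# -- integration -------------------------------------------------------------


def migrate_positions(
    a_p_um,
    x0,
    geometry: ChannelGeometry,
    fluid: FluidProperties = WATER,
    q_ml_min: float = 1.8,
    model: MigrationModel = MigrationModel(),
    n_steps: int = 1500,
    return_trajectory: bool = False,
):
    """Integrate the lateral migration of many particles at once.

    Parameters are vectorized over particles (``a_p_um`` and ``x0`` are
    broadcast together).  Returns the final positions ``x_out`` (array), or
    the full trajectory of shape ``(n_steps + 1, n_particles)`` when
    ``return_trajectory`` is set.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100")
    a_um, x0 = np.broadcast_arrays(np.asarray(a_p_um, float), np.asarray(x0, float))
    if np.any(a_um <= 0):
        raise HydrodynamicsError("particle diameters must be positive")
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("initial lateral positions must lie in [0, 1]")
    x = x0.astype(float).copy()
    traj = [x.copy()] if return_trajectory else None
    if q_ml_min == 0:  # no flow, no forces: particles stay put
        if return_trajectory:
            return np.tile(x, (n_steps + 1, 1))
        return x
    # locus coefficients on the RK4 half-step grid; per-particle rows are
    # formed per step to keep memory O(n_particles)
    s_half = np.linspace(0.0, 1.0, 2 * n_steps + 1)
    c_fl, c_fd, x_wall, pref = _locus_coefficients(geometry, fluid, q_ml_min, model, s_half)
    a_m = a_um * UM
    a3 = a_m ** 3          # F_L/(drag·a) ∝ a³ sets the migration rate
    inv_a3 = 1.0 / a3      # F_D/F_L ∝ 1/a³ sets the equilibrium shift
    c_rate = c_fl * pref
    c_shift = model.eq_shift_gain * c_fd / c_fl

    def _row(j, x_now):
        tgt = np.minimum(x_wall[j] + c_shift[j] * inv_a3, 0.5)
        return c_rate[j] * a3 * (tgt - x_now)

    h = 1.0 / n_steps
    for i in range(n_steps):
        j0, j1, j2 = 2 * i, 2 * i + 1, 2 * i + 2
        k1 = _row(j0, x)
        k2 = _row(j1, x + 0.5 * h * k1)
        k3 = _row(j1, x + 0.5 * h * k2)
        k4 = _row(j2, x + h * k3)
        dx = (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.max(np.abs(dx)) > 0.25:
            raise IntegrationResolutionError(
                f"lateral step {np.max(np.abs(dx)):.3f} > 0.25 at s={i * h:.3f}; "
                "increase n_steps"
            )
        x = x + dx
        if return_trajectory:
            traj.append(x.copy())
    if return_trajectory:
        return np.asarray(traj)
    return x


def simulate_migration(
    a_p_um: float,
    geometry: ChannelGeometry,
    fluid: FluidProperties = WATER,
    q_ml_min: float = 1.8,
    model: MigrationModel = MigrationModel(),
    n_steps: int = 2000,
    x0: float = 0.5,
) -> MigrationResult:
    """Integrate one particle's lateral trajectory through the spiral.

    The particle is "focused" when it ends within ``focusing_tol`` of its
    outlet equilibrium position and an equilibrium exists there (regime not
    Dean-dominated).  Larger particles focus at earlier turns (smaller
    ``s_focus``).
    """
    traj = migrate_positions(
        [a_p_um], [x0], geometry, fluid, q_ml_min, model, n_steps, return_trajectory=True
    )[:, 0]
    s_grid = np.linspace(0.0, 1.0, n_steps + 1)
    if q_ml_min == 0:
        return MigrationResult(a_p_um, s_grid, traj, float(traj[-1]), False, None, None)
    from .hydrodynamics import force_balance  # local import to avoid cycle at module load

    fb = force_balance(geometry, fluid, q_ml_min, 1.0, a_p_um, model.force)
    x_eq_out = equilibrium_position(a_p_um, geometry, fluid, q_ml_min, 1.0, model)
    focused = (
        x_eq_out is not None and abs(float(traj[-1]) - x_eq_out) < model.focusing_tol
    )
    s_focus = None
    if focused:
        # equilibrium target along the trajectory, on the full-step grid
        c_fl, c_fd, x_wall, _ = _locus_coefficients(geometry, fluid, q_ml_min, model, s_grid)
        a_m = a_p_um * UM
        tgt = _target(c_fl, c_fd, x_wall, a_m, a_m ** 4, model.eq_shift_gain)
        inside = np.abs(traj - tgt) < model.focusing_tol
        # first index after which the particle never leaves the tolerance band
        idx = n_steps
        for i in range(n_steps, -1, -1):
            if inside[i]:
                idx = i
            else:
                break
        s_focus = float(s_grid[idx])
    return MigrationResult(
        a_p_um=a_p_um,
        s_grid=s_grid,
        x=traj,
        x_out=float(traj[-1]),
        focused=focused,
        regime_outlet=fb.regime,
        s_focus=s_focus,
    )


# -- operating-window scan ---------------------------------------------------


def dean_mixing_number(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    q_ml_min: float,
    model: MigrationModel = MigrationModel(),
    n_grid: int = 201,
) -> float:
    """Dean sweep number: channel widths traversed by the secondary flow
    during transit, ∫ U_De(s)·L/(U_f(s)·w(s)) ds.  Grows ≈ Q^0.63 under the
    default correlation, so it caps the usable flow rate."""
    if q_ml_min == 0:
        return 0.0
    s = np.linspace(0.0, 1.0, n_grid)
    fm = model.force
    h_m = geometry.height_um * UM
    w_m = geometry.width_um(s) * UM
    r_m = geometry.radius_mm(s) * 1e-3
    dh_m = 2.0 * w_m * h_m / (w_m + h_m)
    u = q_ml_min * ML_PER_MIN_TO_M3_PER_S / (w_m * h_m)
    re = fluid.density_kg_m3 * u * dh_m / fluid.viscosity_pa_s
    de = re * np.sqrt(dh_m / (2.0 * r_m))
    u_de = fm.dean_velocity_coeff * de ** fm.dean_velocity_exponent
    length = channel_length_m(geometry)
    return float(np.trapezoid(u_de * length / (u * w_m), s))


def flow_rate_scan(
    geometry: ChannelGeometry,
    fluid: FluidProperties = WATER,
    q_grid_ml_min: Sequence[float] = (),
    sizes_um: Sequence[float] = (15.0, 10.0, 7.0),
    model: MigrationModel = MigrationModel(),
    x0: float = 0.9,
    n_steps: int = 1500,
) -> pd.DataFrame:
    """Classify each flow rate as unfocused / focused / defocused.

    Starts every size from the worst-case lateral position ``x0`` near the
    outer wall.  A flow rate is *focused* when all sizes converge to their
    equilibrium, streams are pairwise separated by at least
    ``min_spacing_um`` at the outlet, and the Dean sweep number is below the
    mixing threshold; below-window rates are *unfocused* (lift too weak),
    above-window rates *defocused* (Dean mixing).
    """
    q_grid = list(q_grid_ml_min)
    if not q_grid:
        raise ValueError("flow-rate grid must be non-empty")
    if any(b <= a for a, b in zip(q_grid, q_grid[1:])):
        raise ValueError("flow-rate grid must be strictly ascending")
    sizes = [float(a) for a in sizes_um]
    w_out = geometry.width_um(1.0)
    rows = []
    for q in q_grid:
        res = [simulate_migration(a, geometry, fluid, q, model, n_steps, x0) for a in sizes]
        focused_all = all(r.focused for r in res)
        x_out = np.array([r.x_out for r in res])
        spacing_um = float(np.min(np.abs(np.diff(np.sort(x_out)))) * w_out) if len(sizes) > 1 else math.nan
        mix = dean_mixing_number(geometry, fluid, q, model)
        if mix > model.mixing_threshold:
            status = DEFOCUSED
        elif not focused_all:
            status = UNFOCUSED
        elif spacing_um >= model.min_spacing_um:
            status = FOCUSED
        else:
            status = UNSEPARATED
        row = {
            "Q_mL_per_min": q,
            "focused_all": focused_all,
            "min_spacing_um": round(spacing_um, 2),
        }
        for a, r in zip(sizes, res):
            row[f"regime_{a:g}um"] = r.regime_outlet
        row["status"] = status
        rows.append(row)
    return pd.DataFrame(rows)


def operating_window(scan: pd.DataFrame) -> tuple[float, float] | None:
    """(Q_low, Q_high) of the contiguous focused-and-separated window, or
    None when no scanned flow rate is focused.  Raises if the focused rows
    are not contiguous on the grid."""
    mask = (scan["status"] == FOCUSED).to_numpy()
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
        raise RuntimeError("focused flow rates are not contiguous on the scan grid")
    q = scan["Q_mL_per_min"].to_numpy()
    return float(q[idx[0]]), float(q[idx[-1]])
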