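"""Spiral-channel and outlet-manifold geometry.

The device is an Archimedean-style spiral of rectangular cross-section with a
constant height and a width that expands from inlet to outlet.  Positions
along the flow path are addressed by the normalized arc coordinate
``s ∈ [0, 1]`` (0 = inlet, 1 = outlet); "turn k" of an ``n``-turn spiral ends
at ``s = k / n``.

All lengths are stored in micrometres internally; spiral radii are accepted
and reported in millimetres, matching the conventions of the microfluidics
literature.  Width and radius profiles default to linear interpolation in
``s``, but an explicit per-turn table may be supplied when a stepped schedule
is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "PositionError",
    "ChannelGeometry",
    "OutletChannel",
    "OutletManifold",
    "hydraulic_diameter",
    "local_section",
    "channel_length_m",
]

UM_PER_MM = 1000.0


class InvalidGeometryError(ValueError):
    """A channel dimension is non-positive or a profile is non-monotone."""


class PositionError(ValueError):
    """Normalized arc position outside [0, 1]."""


def hydraulic_diameter(width_um: float, height_um: float) -> float:
    """Hydraulic diameter D_h = 2wh/(w+h) of a rectangular duct, in µm.

    For a square duct this reduces to the side length.
    """
    w = np.asarray(width_um, dtype=float)
    h = np.asarray(height_um, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise InvalidGeometryError(
            f"duct dimensions must be positive, got width={width_um}, height={height_um}"
        )
    out = 2.0 * w * h / (w + h)
    return float(out) if np.isscalar(width_um) and np.isscalar(height_um) else out


@dataclass(frozen=True)
class ChannelGeometry:
    """Spiral channel with constant height and expanding width.

    Parameters
    ----------
    n_turns:
        Number of spiral turns (≥ 1).
    height_um:
        Channel height, constant along the spiral.
    width_inlet_um, width_outlet_um:
        Channel width at the inlet (s=0) and outlet (s=1).
    radius_inlet_mm, radius_outlet_mm:
        Radius of curvature at inlet and outlet.
    width_table_um, radius_table_mm:
        Optional per-turn schedules: entry ``k`` (0-based) is the value at the
        end of turn ``k+1`` (``s = (k+1)/n_turns``).  When supplied, profiles
        are piecewise-linear through (inlet value, table...).  The last table
        entry must equal the outlet value.
    """

    n_turns: int = 7
    height_um: float = 100.0
    width_inlet_um: float = 200.0
    width_outlet_um: float = 600.0
    radius_inlet_mm: float = 2.0
    radius_outlet_mm: float = 6.2
    width_table_um: tuple[float, ...] | None = None
    radius_table_mm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_turns < 1:
            raise InvalidGeometryError("n_turns must be >= 1")
        for name in ("height_um", "width_inlet_um", "width_outlet_um",
                     "radius_inlet_mm", "radius_outlet_mm"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        if self.width_outlet_um < self.width_inlet_um:
            raise InvalidGeometryError("width must be non-decreasing inlet -> outlet")
        if self.radius_outlet_mm < self.radius_inlet_mm:
            raise InvalidGeometryError("radius must be non-decreasing inlet -> outlet")
        for table, inlet, outlet, name in (
            (self.width_table_um, self.width_inlet_um, self.width_outlet_um, "width_table_um"),
            (self.radius_table_mm, self.radius_inlet_mm, self.radius_outlet_mm, "radius_table_mm"),
        ):
            if table is None:
                continue
            object.__setattr__(self, name, tuple(float(v) for v in table))
            table = getattr(self, name)
            if len(table) != self.n_turns:
                raise InvalidGeometryError(f"{name} must have one entry per turn")
            knots = (inlet,) + table
            if any(b < a for a, b in zip(knots, knots[1:])):
                raise InvalidGeometryError(f"{name} must be non-decreasing")
            if not np.isclose(table[-1], outlet):
                raise InvalidGeometryError(f"last {name} entry must equal the outlet value")

    # -- profile evaluation -------------------------------------------------

    def _knots(self, inlet: float, outlet: float, table: tuple[float, ...] | None):
        if table is None:
            return np.array([0.0, 1.0]), np.array([inlet, outlet])
        s_k = np.arange(self.n_turns + 1) / self.n_turns
        return s_k, np.concatenate([[inlet], table])

    def width_um(self, s):
        """Local channel width at normalized arc position ``s`` (µm)."""
        s = _check_s(s)
        xk, yk = self._knots(self.width_inlet_um, self.width_outlet_um, self.width_table_um)
        return np.interp(s, xk, yk)

    def radius_mm(self, s):
        """Local radius of curvature at ``s`` (mm)."""
        s = _check_s(s)
        xk, yk = self._knots(self.radius_inlet_mm, self.radius_outlet_mm, self.radius_table_mm)
        return np.interp(s, xk, yk)

    def turn_position(self, k: int) -> float:
        """Normalized arc position of the end of turn ``k`` (1-based)."""
        if not 1 <= k <= self.n_turns:
            raise PositionError(f"turn index {k} outside 1..{self.n_turns}")
        return k / self.n_turns


def _check_s(s):
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise PositionError(f"normalized arc position must lie in [0, 1], got {s}")
    return s


def local_section(geometry: ChannelGeometry, s):
    """Cross-section properties at ``s``: (width µm, radius mm, D_h µm, area µm²)."""
    w = geometry.width_um(s)
    r = geometry.radius_mm(s)
    dh = hydraulic_diameter(w, geometry.height_um)
    area = w * geometry.height_um
    if np.isscalar(s) or np.asarray(s).ndim == 0:
        return float(w), float(r), float(dh), float(area)
    return w, r, dh, area


def channel_length_m(geometry: ChannelGeometry, n_grid: int = 512) -> float:
    """Total unrolled channel length in metres.

    Treats ``s`` as the turn fraction, so the length is the integral of the
    local circumference 2πR(s) over the ``n_turns`` turns.
    """
    s = np.linspace(0.0, 1.0, n_grid)
    r_m = geometry.radius_mm(s) * 1e-3
    return float(np.trapezoid(2.0 * np.pi * geometry.n_turns * r_m, s))


# -- outlet manifold --------------------------------------------------------


@dataclass(frozen=True)
class OutletChannel:
    """One collection channel of the outlet manifold."""

    index: int
    width_um: float
    height_um: float
    length_mm: float

    def __post_init__(self) -> None:
        if min(self.width_um, self.height_um, self.length_mm) <= 0:
            raise InvalidGeometryError(f"outlet {self.index}: dimensions must be positive")


@dataclass(frozen=True)
class OutletManifold:
    """Ordered collection channels, Outlet 1 nearest the inner wall.

    The reference blood-sorter device has four outlets (Outlet 4, at the outer
    wall, collects excess plasma), but any number ≥ 2 is accepted so that
    simplified manifolds can be analysed.
    """

    outlets: tuple[OutletChannel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlets", tuple(self.outlets))
        if len(self.outlets) < 2:
            raise InvalidGeometryError("a manifold needs at least two outlets")
        if [o.index for o in self.outlets] != list(range(1, len(self.outlets) + 1)):
            raise InvalidGeometryError("outlet indices must be 1..n in inner-to-outer order")

    def __len__(self) -> int:
        return len(self.outlets)
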