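"""Hydraulic-resistance network of the outlet manifold.

The collection channels branch in parallel from the spiral outlet, so each
branch's flow fraction is its share of the total hydraulic conductance.
Because a branch's resistance is strictly proportional to its length, the
routing can be tuned by changing collection-channel lengths alone — widths,
and hence the sizes of cells a branch can admit, stay fixed.

Flow fractions are converted to *capture windows*: a partition of the
normalized lateral coordinate at the bifurcation such that a focused stream
at position x is collected by the outlet whose window contains x.  The
default mapping assumes uniform lateral flux (window width = flow fraction);
it is isolated here so that a velocity-profile-weighted mapping can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import InvalidGeometryError, OutletChannel, OutletManifold

__all__ = [
    "NetworkSolution",
    "NetworkError",
    "TuningError",
    "rectangular_resistance",
    "solve_flow_split",
    "capture_windows",
    "assign_outlet",
    "tune_lengths",
]


class NetworkError(ValueError):
    pass


class TuningError(NetworkError):
    pass


def rectangular_resistance(
    width_um: float, height_um: float, length_mm: float, viscosity_pa_s: float
) -> float:
    """Hydraulic resistance of a rectangular channel, Pa·s/m³.

    First-order wide-duct approximation R = 12·μ·L / (w·h³·(1 − 0.63·h/w)),
    applied with w and h swapped when height exceeds width so that the
    correction uses the smaller aspect ratio.  Accurate to a few percent for
    the aspect ratios of typical collection channels; exactly proportional to
    length, which is the tuning knob.
    """
    if min(width_um, height_um, length_mm, viscosity_pa_s) <= 0:
        raise NetworkError("resistance needs positive dimensions and viscosity")
    w, h = width_um * 1e-6, height_um * 1e-6
    if h > w:
        w, h = h, w
    length = length_mm * 1e-3
    return 12.0 * viscosity_pa_s * length / (w * h ** 3 * (1.0 - 0.63 * h / w))


@dataclass(frozen=True)
class NetworkSolution:
    """Resistances, flow split and capture windows of a solved manifold."""

    resistances_pa_s_m3: tuple[float, ...]
    fractions: tuple[float, ...]
    flows_ml_min: tuple[float, ...]
    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise NetworkError("flow fractions must sum to 1")


def solve_flow_split(
    manifold: OutletManifold, q_ml_min: float, viscosity_pa_s: float = 1.0e-3
) -> NetworkSolution:
    """Split the spiral outflow over the parallel collection channels.

    All branches see the same junction-to-reservoir pressure drop, so
    fraction_i = (1/R_i) / Σ_j (1/R_j) and the branch flows sum to Q exactly.
    """
    if q_ml_min <= 0:
        raise NetworkError("flow rate must be positive")
    res = np.array(
        [
            rectangular_resistance(o.width_um, o.height_um, o.length_mm, viscosity_pa_s)
            for o in manifold.outlets
        ]
    )
    if np.any(res == 0):
        raise NetworkError("degenerate network: zero branch resistance")
    cond = 1.0 / res
    frac = cond / cond.sum()
    # enforce exact normalization against accumulated float error
    frac = frac / frac.sum()
    return NetworkSolution(
        resistances_pa_s_m3=tuple(res),
        fractions=tuple(frac),
        flows_ml_min=tuple(frac * q_ml_min),
        windows=capture_windows(frac),
    )


def capture_windows(fractions: Sequence[float]) -> tuple[tuple[float, float], ...]:
    """Partition [0, 1] into per-outlet lateral intervals, inner wall first.

    Under the uniform-lateral-flux mapping each window's width equals the
    branch flow fraction; boundaries are the cumulative sums.
    """
    frac = np.asarray(fractions, dtype=float)
    if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
        raise NetworkError("fractions must be non-negative and sum to 1")
    cuts = np.concatenate([[0.0], np.cumsum(frac)])
    cuts[-1] = 1.0
    return tuple((float(a), float(b)) for a, b in zip(cuts[:-1], cuts[1:]))


def assign_outlet(x_out: float, windows: Sequence[tuple[float, float]]) -> int:
    """Outlet index (1-based) whose capture window contains ``x_out``.

    Windows are half-open [lo, hi) except the last, which is closed, so each
    lateral position maps to exactly one outlet.
    """
    x = np.asarray(x_out, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise NetworkError("lateral position must lie in [0, 1]")
    cuts = np.array([w[1] for w in windows[:-1]])
    idx = np.searchsorted(cuts, x, side="right") + 1
    if x.ndim == 0:
        return int(idx)
    return idx.astype(int)


def tune_lengths(
    template: OutletManifold,
    target_fractions: Sequence[float],
    q_ml_min: float = 1.8,
    viscosity_pa_s: float = 1.0e-3,
) -> OutletManifold:
    """Choose collection-channel lengths realizing the target flow split.

    Only lengths differ from the template (widths and heights are preserved —
    the design rule that keeps outlet ports cell-sized).  The template's
    total parallel conductance is preserved too, so the manifold's overall
    back-pressure is unchanged.  Round-trips through
    :func:`solve_flow_split` to the requested fractions within 1e-6.
    """
    frac = np.asarray(target_fractions, dtype=float)
    if len(frac) != len(template):
        raise TuningError("need one target fraction per outlet")
    if np.any(frac <= 0):
        raise TuningError("infeasible target: every outlet needs a positive fraction")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise TuningError("target fractions must sum to 1")
    res_t = np.array(
        [
            rectangular_resistance(o.width_um, o.height_um, o.length_mm, viscosity_pa_s)
            for o in template.outlets
        ]
    )
    g_total = float(np.sum(1.0 / res_t))
    res_per_mm = res_t / np.array([o.length_mm for o in template.outlets])
    new_lengths = 1.0 / (frac * g_total * res_per_mm)
    outlets = tuple(
        OutletChannel(o.index, o.width_um, o.height_um, float(L))
        for o, L in zip(template.outlets, new_lengths)
    )
    return OutletManifold(outlets)
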