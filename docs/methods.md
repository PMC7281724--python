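# Methods

## Scope and model structure

spiralsort is a reduced-order model of a spiral inertial sorter: no
Navier–Stokes solve, no particle–particle or particle–wall interactions, no
deformability lift. The device is collapsed to

* axial flow from continuity, `U_f(s) = Q / (w(s) h)`, on the normalized arc
  coordinate `s ∈ [0, 1]`;
* a scalar secondary-flow (Dean) velocity per locus;
* a one-dimensional lateral migration ODE on the width coordinate
  `x ∈ [0, 1]` (inner wall → outer wall).

These are the standard dimensionless groups of inertial microfluidics:
`D_h = 2wh/(w+h)`, `Re = ρU_fD_h/μ`, `De = Re√(D_h/2R)`,
`R_p = Re(a_p/D_h)²`. Reported tables round half-up: velocities, `De`, `R_p`
to 2 decimals, `Re` to integers.

## Geometry

Width and radius profiles default to **linear** in `s`; "turn k" of an
n-turn spiral ends at `s = k/n`. Published per-turn characterisations of
comparable devices imply stepped, not perfectly linear, schedules, so an
explicit per-turn table (`width_table_um`, `radius_table_mm`) can be supplied
when the schedule is known; only the inlet and outlet sections of the
reference device are unambiguous, and only those are treated as exact.
Channel length is `∫ 2π n R(s) ds ≈ 0.18 m` for the reference spiral. Cross
sections are treated as rectangular (xurography molds produce near-vertical
walls). All lengths are stored in µm; radii are accepted in mm.

## Force balance

* Lift: `F_L = C_L ρ U_f² a_p⁴/(w h)`. The quartic size scaling and the
  inverse dependence on the cross-section are the load-bearing features; the
  prefactor C_L is not separately observable in this model and is calibrated
  (below).
* Dean drag: Stokes drag on the secondary flow, `F_D = 3πμ U_De a_p`, with
  the community-standard correlation `U_De = 1.8×10⁻⁴ De^1.63` m/s (both
  coefficient and exponent are configurable).
* Regime: `F_L/F_D > band` → lift-dominated (all sizes collapse to one
  near-wall position — no separation); `< 1/band` → Dean-dominated (no
  equilibrium, mixing); otherwise balanced. `band = 10` quantifies the
  qualitative "≫/≪" limits and is config-exposed.
* The ratio `F_L/F_D ∝ (a_p/h)³` emerges from the component laws and is
  asserted in tests rather than imposed.

## Migration ODE

Overdamped relaxation toward a shifted equilibrium:

```
x_eq(a_p, s) = x_wall(s) + k·F_D/F_L        clipped to (0, 0.5]
x_wall(s)    = 0.2·D_h(s)/w(s)
dx/ds        = [F_L/(3πμ a_p ξ)]·(x_eq − x)·L/(U_f(s)·w(s))
```

The Dean push toward the channel centre is folded into the equilibrium
shift `k·F_D/F_L` (its linearized effect); the migration *rate* is set by
the lift force alone, which is what fails first at low flow rate. When
`F_D/F_L` is large the target clips at mid-width: particles drift to the
centre and no distinct equilibrium exists (the explicit "unfocused" signal
of `equilibrium_position`).

Integration: classical fixed-step RK4, deterministic, default 1500–2000
steps; halving the step changes terminal positions by < 1e-3. A per-step
lateral displacement above 0.25 raises an integration-resolution error
rather than silently under-resolving the transient. A particle is *focused*
when it ends within 1% of the width of its outlet equilibrium (tolerance
config-exposed).

High-flow-rate defocusing is not captured by the force ratio (which grows
slowly, ∝ Q^0.37, under the De^1.63 correlation). It is modelled by the
**Dean sweep number** `M = ∫ U_De L/(U_f w) ds` — how many channel widths
the secondary circulation sweeps a particle through during transit
(M ∝ Q^0.63). Above a critical M, lateral mixing destroys focusing; this
closes the upper end of the operating window, consistent with the observed
loss of focusing once the secondary flow strengthens at high rates.

## Calibration (done once, frozen as defaults)

Four constants are not derivable from first principles at this level of
reduction and were calibrated once against the reference device's printed
design constraints, then frozen:

| constant | default | calibrated against |
|---|---|---|
| `C_L` (lift prefactor) | 10 | all three bead sizes in the balanced regime across the operating window |
| `ξ` (restoring arm, widths) | 1.05 | low window edge at 1.5 mL/min (7 µm is the last size to focus) |
| `k` (equilibrium-shift gain) | 0.015 | mean adjacent 15/10/7 µm stream spacing ≈ 20 µm at the 600 µm outlet |
| `M_crit` (mixing threshold) | 16 | upper window edge ≈ 2.3 mL/min, between the highest focused (~2.0) and the clearly defocused (~3.1 mL/min, i.e. ~2.6 m/s) conditions |

With these defaults the scanned window is 1.5–2.25 mL/min. Two printed
constraints are in mild tension — a 1.5–1.9 mL/min window on one hand, and
a focused condition at 1.7 m/s (≈ 2.04 mL/min at the inlet section) on the
other; the upper edge is placed to respect the simulated-condition
classification (unfocused at ~0.3 m/s, focused at ~1.7 m/s, defocused at
~2.6 m/s), which slightly widens the window beyond 1.9 mL/min.

## Outlet network

Collection channels are parallel branches from the bifurcation:
`fraction_i = (1/R_i)/Σ(1/R_j)` with the first-order rectangular-duct
resistance `R = 12μL/(w h³ (1 − 0.63 h/w))` (a few % accurate at these
aspect ratios). Capture windows map flow fractions to lateral intervals
under a uniform-lateral-flux assumption — window width equals flow
fraction. The true mapping needs the outlet velocity profile; the choice is
isolated in `capture_windows` so a profile-weighted mapping can be swapped
in. Boundary convention: half-open `[lo, hi)` intervals, last closed, so
every lateral position has exactly one outlet. `tune_lengths` inverts the
split for lengths (the published tuning knob), preserving the template's
total parallel conductance so the manifold back-pressure is unchanged.

The bundled manifold is **reconstructed, not measured**: the four channel
lengths were never published. Window boundaries are set at the simulated
terminal positions of 12.5 / 7.5 / 5.75 µm boundary particles at
1.9 mL/min, realizing the published routing (> 13 µm → Outlet 1, 8–12 µm →
Outlet 2, 6–7 µm → Outlet 3, remainder and excess plasma → Outlet 4). Where
sources disagree on the Outlet-2 range (8–11 vs 8–12 µm) the figure-level
8–12 µm is used. Outlet widths (300 µm) are a plausible choice, not a
measurement; only their resistances matter in this model.

## Synthetic populations and the Monte-Carlo assay

Cell diameters are truncated normals with mean at the printed range midpoint
and SD = range/6 (≈99.7% of mass in range); family and parameters are
config-exposed, since only size histograms were published. Default counts
are 10⁴ per class. Inlet lateral positions are uniform on [0, 1]. Viability
is a Bernoulli annotation (default 0.9, consistent with the >80% viability
observed across outlets) that does not alter the physics — the measurement
is post hoc and no damage mechanism is modelled. A cell-to-volume fraction
above 3% raises a degradation flag only; crowding is not modelled
mechanistically.

**What passing assays do and do not show.** The generator draws sizes from
clean, independent distributions and the migration model is deterministic
given size, so with non-overlapping majority ranges the in-silico separation
is essentially perfect (100% modal-outlet recovery). Real assays see
overlapping size distributions, cell deformability, concentration effects
and dispersion, and reported recoveries near 77% for dendritic cells in
mixed samples. The model reproduces the *direction* of that degradation
(DC recovery at Outlet 1 drops when the overlapping full ranges are used)
but cannot predict wet-lab percentages; they are treated as qualitative
references, never as test targets.

## Metrics

* recovery rate = class count at one outlet / class count over all outlets;
* viability rate = viable events / total events at an outlet;
* fabrication error = `100·|fabricated − desired|/desired` %, reported to
  1 decimal (the xurography process stays below 5%).

## Numerical and determinism notes

* Seeded runs are bit-reproducible (a single `numpy` Generator drives
  sampling; integration is deterministic).
* Flow splits are solved in closed form and checked in tests against a
  general linear junction-network solve (1e-10).
* Degenerate inputs fail loudly: zero-radius Dean number, zero forces at
  regime classification, empty metric denominators, non-monotone geometry
  profiles, unknown config keys.
* Default problem sizes (10⁴ particles/class, ~60-point flow-rate grids,
  1500–2000 integration steps) keep a full assay under ~10 s on one core;
  they are the package's chosen defaults, adequate for ±1% recovery
  resolution.

## Known limitations

* 1-D lateral dynamics; no cross-sectional (height-coordinate) equilibria,
  so the model cannot distinguish top/bottom focusing bands.
* The De^1.63 correlation and the calibrated constants are device-family
  specific; transferring to very different aspect ratios or radii calls for
  recalibration.
* Turn-by-turn printed Dean values of the reference device imply a
  non-uniform radius schedule that was not published; per-turn values other
  than the inlet/outlet sections are therefore not reproduced exactly by
  the default linear profiles.
* The uniform-flux capture-window mapping ignores the outlet velocity
  profile; absolute window boundaries inherit that approximation.
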