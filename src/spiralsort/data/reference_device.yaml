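# Reference blood-sorter device: 7-turn spiral, 100 um height, width expanding
# 200 -> 600 um, radius 2 -> 6.2 mm, operated at 1.9 mL/min with water.
#
# SYNTHETIC / RECONSTRUCTED MANIFOLD: the four collection-channel lengths were
# never published.  They are reconstructed by tuning the hydraulic-resistance
# network so that the capture windows realize the published size routing
# (> 13 um -> Outlet 1, 8-12 um -> Outlet 2, 6-7 um -> Outlet 3, remainder and
# excess plasma -> Outlet 4), with window boundaries at the simulated terminal
# positions of 12.5 / 7.5 / 5.75 um boundary particles at 1.9 mL/min.
device:
  n_turns: 7
  height_um: 100.0
  width_inlet_um: 200.0
  width_outlet_um: 600.0
  radius_inlet_mm: 2.0
  radius_outlet_mm: 6.2
manifold:
  outlets:
    - {index: 1, width_um: 300.0, height_um: 100.0, length_mm: 33.468291}
    - {index: 2, width_um: 300.0, height_um: 100.0, length_mm: 52.425279}
    - {index: 3, width_um: 300.0, height_um: 100.0, length_mm: 37.323745}
    - {index: 4, width_um: 300.0, height_um: 100.0, length_mm: 3.084006}
fluid:
  density_kg_per_m3: 1000.0
  viscosity_pa_s: 0.001
operating:
  flow_rate_ml_per_min: 1.9
  carrier_volume_ml: 1.0
  scan_grid_ml_per_min: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.5, 1.6, 1.7,
                         1.8, 1.9, 2.0, 2.1, 2.2, 2.4, 2.6, 2.8, 3.0, 3.2]
populations:
  # measured majority size ranges of the three blood-cell types
  - {label: RBC, low_um: 6.0, high_um: 7.0, count: 10000, viable_fraction: 0.9}
  - {label: WBC, low_um: 8.0, high_um: 11.0, count: 10000, viable_fraction: 0.9}
  - {label: DC, low_um: 13.0, high_um: 15.0, count: 10000, viable_fraction: 0.9}
seed: 0
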