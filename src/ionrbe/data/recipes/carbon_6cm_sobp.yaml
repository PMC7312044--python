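# Synthetic 6-cm carbon SOBP: six evaluation positions across the window
# with dose-averaged LET rising 16 -> 99 keV/um, plus an entrance-plateau
# voxel.  Fragment species (H, He) carry fixed dose fractions.
name: carbon_6cm_sobp
species: {name: C, Z: 6, A: 12}
entrance_energy_mev_u: 280.0
window_mm: [60.0, 120.0]
window_positions_mm: [65.0, 75.0, 85.0, 95.0, 105.0, 115.0]
window_let_kev_um: [16.0, 21.0, 36.0, 45.0, 66.0, 99.0]
peak_dose_gy: 2.0
plateau_dose_gy: 0.8
plateau_positions_mm: [10.0]
fragments:
  - {name: H, Z: 1, A: 1, dose_fraction: 0.06, energy_mev_u: 150.0}
  - {name: He, Z: 2, A: 4, dose_fraction: 0.045, energy_mev_u: 150.0}
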