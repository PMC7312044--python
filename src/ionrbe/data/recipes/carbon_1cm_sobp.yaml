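# Synthetic homogeneous 1-cm carbon SOBP (mid-window dose-averaged LET
# 125 keV/um) with an entrance-plateau voxel of a high-energy beam
# (dose-averaged LET ~13 keV/um).
name: carbon_1cm_sobp
species: {name: C, Z: 6, A: 12}
entrance_energy_mev_u: 270.0
window_mm: [45.0, 55.0]
window_positions_mm: [50.0]
window_let_kev_um: [125.0]
peak_dose_gy: 2.0
plateau_dose_gy: 2.0
plateau_positions_mm: [10.0]
fragments:
  - {name: H, Z: 1, A: 1, dose_fraction: 0.05, energy_mev_u: 150.0}
  - {name: He, Z: 2, A: 4, dose_fraction: 0.04, energy_mev_u: 150.0}
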