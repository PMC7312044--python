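# Synthetic 6-cm proton SOBP (nominal window 70-130 mm) evaluated at four
# depths with dose-averaged LET 1.4 / 2.7 / 3.9 / 5.5 keV/um.
name: proton_6cm_sobp
species: {name: H, Z: 1, A: 1}
entrance_energy_mev_u: 130.0
window_mm: [30.0, 130.0]
window_positions_mm: [35.0, 100.0, 120.0, 127.0]
window_let_kev_um: [1.4, 2.7, 3.9, 5.5]
peak_dose_gy: 2.0
plateau_dose_gy: 0.0
plateau_positions_mm: []
fragments: []
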