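# Reference cell line for CL-yield scaling (synthetic placeholder values
# standing in for an in-vitro-fitted rodent fibroblast reference):
# photon CL yield in CL/Gy/cell and nucleus volume in um^3
# (cylinder, 6 um radius x 6 um height).
photon_yield_per_gy: 1.0
nucleus_volume_um3: 678.584
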