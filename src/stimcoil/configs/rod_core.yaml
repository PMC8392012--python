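# Tapered mu-metal rod electromagnet for head-fixed electrophysiology,
# as-simulated geometry (tips tapered to a point; straight-cone profile).
kind: rod_core
current_A: 15.0
mode: active
core_diameter_mm: 10.47
core_length_mm: 150.0
relative_permeability: 100000
taper_length_mm: 15.0
tip_radius_mm: 0.2
coil:
  wire_awg: 20
  turns: 308
  inner_diameter_mm: 11.97
  outer_diameter_mm: 31.97
  height_mm: 30.0
  axial_center_mm: 0.0
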