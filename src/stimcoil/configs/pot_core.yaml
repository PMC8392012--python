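# Ferrite half pot core for head-mounted freely-moving-animal stimulation,
# as-simulated geometry.  Centre-post radius and shield thickness are not
# part of the printed envelope; they are inferred at load time to fill the
# envelope with matching post/shield flux areas.
kind: pot_core
current_A: 15.0
mode: active
outer_diameter_mm: 30.0
height_mm: 9.45
channel_depth_mm: 6.5
channel_width_mm: 6.05
relative_permeability: 10000
permeability_tolerance: 0.3
coil:
  wire_awg: 20
  turns: 28
  inner_diameter_mm: 15.2
  outer_diameter_mm: 25.4
  height_mm: 5.8
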