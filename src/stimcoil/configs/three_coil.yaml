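# Three-coil square Merritt stack for multi-well plate stimulation,
# as-simulated geometry.  Total height (top to bottom coil centre) follows
# the h/d = 0.821116 spacing ratio applied to the 150 mm inner side.
kind: merritt3
current_A: 15.0
mode: active
wire_awg: 12
turns_per_coil: 276
inner_side_mm: 150.0
outer_side_mm: 227.47
coil_height_mm: 50.0
total_height_mm: 123.17
ampere_turn_ratio: 1.0
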