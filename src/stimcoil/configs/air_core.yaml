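# Air-core microscope coil, as-simulated geometry (fits the imaging
# incubation chamber around a 35 mm culture dish).
kind: air_core
current_A: 15.0
mode: active
wire_awg: 20
turns: 264
inner_diameter_mm: 45.0
outer_diameter_mm: 85.0
height_mm: 11.5
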