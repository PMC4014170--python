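# Geometry of the 125I model-6711 seed used for transport: a titanium
# capsule enclosing a silver rod carrying the adsorbed iodine.
# Editable fixture; dimensions in cm.

[capsule]
material = "titanium"
outer_diameter_cm = 0.08
length_cm = 0.45
wall_cm = 0.005

[core]
material = "silver"
diameter_cm = 0.05
length_cm = 0.30
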