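# consensus-style TG-43 dataset for the 125I model-6711 seed (point-source formalism)
# editable fixture; dose-rate constant in cGy/(h U), reference radius 1 cm
# dose_rate_constant_cGy_h_U: 0.965
r_cm,g,phi_an
0.5,1.055,0.973
1.0,1.000,0.944
1.5,0.926,0.941
2.0,0.842,0.942
2.5,0.752,0.943
3.0,0.668,0.944
3.5,0.592,0.944
4.0,0.509,0.944
5.0,0.388,0.944
6.0,0.296,0.945
7.0,0.224,0.945
8.0,0.166,0.945
9.0,0.121,0.945
10.0,0.091,0.945
11.0,0.068,0.945
12.0,0.051,0.945
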