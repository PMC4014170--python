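# material: silver
# density_g_cm3: 10.49
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,5.517108e+03,1.732048e-01,5.517281e+03,5.517108e+03
2.097400e+00,4.840837e+03,1.731396e-01,4.841010e+03,4.840838e+03
2.199543e+00,4.247462e+03,1.730713e-01,4.247635e+03,4.247462e+03
2.306661e+00,3.726820e+03,1.729998e-01,3.726993e+03,3.726821e+03
2.418996e+00,3.269998e+03,1.729249e-01,3.270171e+03,3.269999e+03
2.536801e+00,2.869171e+03,1.728464e-01,2.869344e+03,2.869172e+03
2.660343e+00,2.517477e+03,1.727642e-01,2.517650e+03,2.517478e+03
2.789902e+00,2.208892e+03,1.726780e-01,2.209065e+03,2.208893e+03
2.925770e+00,1.938133e+03,1.725879e-01,1.938305e+03,1.938134e+03
3.068255e+00,1.700562e+03,1.724934e-01,1.700735e+03,1.700563e+03
3.217679e+00,1.492112e+03,1.723945e-01,1.492285e+03,1.492113e+03
3.374380e+00,1.309214e+03,1.722910e-01,1.309386e+03,1.309215e+03
3.538712e+00,1.148734e+03,1.721825e-01,1.148906e+03,1.148735e+03
3.711047e+00,1.007926e+03,1.720690e-01,1.008098e+03,1.007927e+03
3.891775e+00,8.843772e+02,1.719502e-01,8.845492e+02,8.843785e+02
4.081305e+00,7.759729e+02,1.718258e-01,7.761448e+02,7.759743e+02
4.280064e+00,6.808565e+02,1.716956e-01,6.810282e+02,6.808579e+02
4.488504e+00,5.973991e+02,1.715594e-01,5.975707e+02,5.974006e+02
4.707094e+00,5.241717e+02,1.714168e-01,5.243431e+02,5.241733e+02
4.936329e+00,4.599203e+02,1.712676e-01,4.600916e+02,4.599219e+02
5.176729e+00,4.035447e+02,1.711115e-01,4.037158e+02,4.035464e+02
5.428835e+00,3.540794e+02,1.709482e-01,3.542503e+02,3.540811e+02
5.693220e+00,3.106774e+02,1.707774e-01,3.108482e+02,3.106792e+02
5.970479e+00,2.725955e+02,1.705987e-01,2.727661e+02,2.725974e+02
6.261242e+00,2.391815e+02,1.704119e-01,2.393519e+02,2.391836e+02
6.566164e+00,2.098634e+02,1.702165e-01,2.100336e+02,2.098655e+02
6.885936e+00,1.841389e+02,1.700123e-01,1.843090e+02,1.841412e+02
7.221282e+00,1.615677e+02,1.697988e-01,1.617375e+02,1.615701e+02
7.572958e+00,1.417633e+02,1.695756e-01,1.419328e+02,1.417657e+02
7.941761e+00,1.243863e+02,1.693425e-01,1.245557e+02,1.243889e+02
8.328525e+00,1.091394e+02,1.690988e-01,1.093085e+02,1.091421e+02
8.734124e+00,9.576145e+01,1.688443e-01,9.593029e+01,9.576423e+01
9.159476e+00,8.402329e+01,1.685785e-01,8.419187e+01,8.402620e+01
9.605543e+00,7.372397e+01,1.683009e-01,7.389227e+01,7.372701e+01
1.007333e+01,6.468711e+01,1.680111e-01,6.485512e+01,6.469028e+01
1.056390e+01,5.675795e+01,1.677086e-01,5.692566e+01,5.676127e+01
1.107837e+01,4.980073e+01,1.673928e-01,4.996813e+01,4.980420e+01
1.161788e+01,4.369631e+01,1.670634e-01,4.386337e+01,4.369993e+01
1.218367e+01,3.834015e+01,1.667198e-01,3.850687e+01,3.834392e+01
1.277702e+01,3.364052e+01,1.663615e-01,3.380689e+01,3.364447e+01
1.339926e+01,2.951697e+01,1.659878e-01,2.968296e+01,2.952109e+01
1.405180e+01,2.589887e+01,1.655984e-01,2.606447e+01,2.590316e+01
1.473613e+01,2.272426e+01,1.651926e-01,2.288945e+01,2.272874e+01
1.545378e+01,1.993879e+01,1.647698e-01,2.010356e+01,1.994346e+01
1.620637e+01,1.749475e+01,1.643295e-01,1.765908e+01,1.749963e+01
1.699562e+01,1.535030e+01,1.638712e-01,1.551417e+01,1.535538e+01
1.782331e+01,1.346870e+01,1.633941e-01,1.363210e+01,1.347400e+01
1.869131e+01,1.181775e+01,1.628977e-01,1.198065e+01,1.182327e+01
1.960157e+01,1.036917e+01,1.623815e-01,1.053155e+01,1.037491e+01
2.055617e+01,9.098145e+00,1.618448e-01,9.259990e+00,9.104129e+00
2.155726e+01,7.982921e+00,1.612870e-01,8.144208e+00,7.989151e+00
2.260709e+01,7.004399e+00,1.607076e-01,7.165106e+00,7.010881e+00
2.370806e+01,6.145820e+00,1.601059e-01,6.305926e+00,6.152564e+00
2.486264e+01,5.392484e+00,1.594813e-01,5.551965e+00,5.399498e+00
2.551300e+01,5.022844e+00,1.591323e-01,5.181977e+00,5.030008e+00
2.551500e+01,4.682922e+01,1.591313e-01,4.698835e+01,4.683638e+01
2.607345e+01,4.412235e+01,1.588333e-01,4.428119e+01,4.412964e+01
2.734323e+01,3.871397e+01,1.581613e-01,3.887213e+01,3.872154e+01
2.867485e+01,3.396852e+01,1.574647e-01,3.412599e+01,3.397640e+01
3.007131e+01,2.980476e+01,1.567430e-01,2.996151e+01,2.981294e+01
3.153578e+01,2.615138e+01,1.559957e-01,2.630738e+01,2.615987e+01
3.307158e+01,2.294583e+01,1.552223e-01,2.310105e+01,2.295463e+01
3.468216e+01,2.013320e+01,1.544222e-01,2.028762e+01,2.014233e+01
3.637119e+01,1.766533e+01,1.535951e-01,1.781892e+01,1.767479e+01
3.814246e+01,1.549997e+01,1.527406e-01,1.565271e+01,1.550977e+01
4.000000e+01,1.360003e+01,1.518582e-01,1.375188e+01,1.361018e+01
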