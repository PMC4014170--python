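# material: air
# density_g_cm3: 0.001205
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,8.315640e+02,1.984339e-01,8.317624e+02,8.315648e+02
2.097400e+00,7.132182e+02,1.983592e-01,7.134166e+02,7.132190e+02
2.199543e+00,6.117189e+02,1.982810e-01,6.119171e+02,6.117197e+02
2.306661e+00,5.246674e+02,1.981990e-01,5.248656e+02,5.246682e+02
2.418996e+00,4.500067e+02,1.981132e-01,4.502048e+02,4.500076e+02
2.536801e+00,3.859728e+02,1.980233e-01,3.861708e+02,3.859737e+02
2.660343e+00,3.310527e+02,1.979291e-01,3.312506e+02,3.310537e+02
2.789902e+00,2.839490e+02,1.978304e-01,2.841468e+02,2.839501e+02
2.925770e+00,2.435490e+02,1.977271e-01,2.437467e+02,2.435501e+02
3.068255e+00,2.088985e+02,1.976189e-01,2.090961e+02,2.088996e+02
3.217679e+00,1.791789e+02,1.975056e-01,1.793764e+02,1.791801e+02
3.374380e+00,1.536885e+02,1.973870e-01,1.538859e+02,1.536898e+02
3.538712e+00,1.318253e+02,1.972628e-01,1.320226e+02,1.318267e+02
3.711047e+00,1.130730e+02,1.971327e-01,1.132702e+02,1.130744e+02
3.891775e+00,9.698894e+01,1.969966e-01,9.718593e+01,9.699041e+01
4.081305e+00,8.319328e+01,1.968541e-01,8.339013e+01,8.319482e+01
4.280064e+00,7.136038e+01,1.967049e-01,7.155709e+01,7.136200e+01
4.488504e+00,6.121094e+01,1.965488e-01,6.140749e+01,6.121263e+01
4.707094e+00,5.250539e+01,1.963854e-01,5.270177e+01,5.250716e+01
4.936329e+00,4.503826e+01,1.962145e-01,4.523448e+01,4.504012e+01
5.176729e+00,3.863335e+01,1.960357e-01,3.882939e+01,3.863529e+01
5.428835e+00,3.313951e+01,1.958486e-01,3.333536e+01,3.314155e+01
5.693220e+00,2.842712e+01,1.956529e-01,2.862277e+01,2.842925e+01
5.970479e+00,2.438499e+01,1.954482e-01,2.458044e+01,2.438722e+01
6.261242e+00,2.091777e+01,1.952342e-01,2.111300e+01,2.092010e+01
6.566164e+00,1.794367e+01,1.950104e-01,1.813868e+01,1.794610e+01
6.885936e+00,1.539253e+01,1.947764e-01,1.558731e+01,1.539508e+01
7.221282e+00,1.320420e+01,1.945318e-01,1.339873e+01,1.320686e+01
7.572958e+00,1.132706e+01,1.942761e-01,1.152133e+01,1.132984e+01
7.941761e+00,9.716842e+00,1.940090e-01,9.910851e+00,9.719758e+00
8.328525e+00,8.335591e+00,1.937299e-01,8.529321e+00,8.338640e+00
8.734124e+00,7.150737e+00,1.934383e-01,7.344175e+00,7.153923e+00
9.159476e+00,6.134347e+00,1.931337e-01,6.327480e+00,6.137677e+00
9.605543e+00,5.262462e+00,1.928157e-01,5.455278e+00,5.265943e+00
1.007333e+01,4.514533e+00,1.924837e-01,4.707017e+00,4.518170e+00
1.056390e+01,3.872932e+00,1.921371e-01,4.065069e+00,3.876732e+00
1.107837e+01,3.322540e+00,1.917754e-01,3.514315e+00,3.326508e+00
1.161788e+01,2.850386e+00,1.913980e-01,3.041784e+00,2.854531e+00
1.218367e+01,2.445346e+00,1.910043e-01,2.636350e+00,2.449674e+00
1.277702e+01,2.097878e+00,1.905938e-01,2.288472e+00,2.102396e+00
1.339926e+01,1.799797e+00,1.901657e-01,1.989963e+00,1.804512e+00
1.405180e+01,1.544081e+00,1.897195e-01,1.733800e+00,1.549001e+00
1.473613e+01,1.324707e+00,1.892546e-01,1.513962e+00,1.329840e+00
1.545378e+01,1.136509e+00,1.887703e-01,1.325279e+00,1.141863e+00
1.620637e+01,9.750555e-01,1.882659e-01,1.163321e+00,9.806384e-01
1.699562e+01,8.365446e-01,1.877407e-01,1.024285e+00,8.423647e-01
1.782331e+01,7.177154e-01,1.871942e-01,9.049095e-01,7.237812e-01
1.869131e+01,6.157703e-01,1.866255e-01,8.023958e-01,6.220904e-01
1.960157e+01,5.283097e-01,1.860341e-01,7.143438e-01,5.348930e-01
2.055617e+01,4.532751e-01,1.854192e-01,6.386943e-01,4.601305e-01
2.155726e+01,3.889005e-01,1.847802e-01,5.736807e-01,3.960370e-01
2.260709e+01,3.336712e-01,1.841163e-01,5.177875e-01,3.410979e-01
2.370806e+01,2.862874e-01,1.834270e-01,4.697144e-01,2.940137e-01
2.486264e+01,2.456344e-01,1.827114e-01,4.283459e-01,2.536696e-01
2.607345e+01,2.107559e-01,1.819690e-01,3.927249e-01,2.191093e-01
2.734323e+01,1.808313e-01,1.811991e-01,3.620305e-01,1.895124e-01
2.867485e+01,1.551569e-01,1.804011e-01,3.355580e-01,1.641750e-01
3.007131e+01,1.331289e-01,1.795743e-01,3.127031e-01,1.424934e-01
3.153578e+01,1.142291e-01,1.787181e-01,2.929472e-01,1.239495e-01
3.307158e+01,9.801326e-02,1.778320e-01,2.758453e-01,1.080987e-01
3.468216e+01,8.410009e-02,1.769154e-01,2.610155e-01,9.455982e-02
3.637119e+01,7.216252e-02,1.759679e-01,2.481304e-01,8.300554e-02
3.814246e+01,6.191994e-02,1.749889e-01,2.369088e-01,7.315508e-02
4.000000e+01,5.313161e-02,1.739780e-01,2.271096e-01,6.476752e-02
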