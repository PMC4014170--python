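# material: titanium
# density_g_cm3: 4.506
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,1.245619e+04,1.827011e-01,1.245637e+04,1.245619e+04
2.097400e+00,1.082590e+04,1.826323e-01,1.082608e+04,1.082590e+04
2.199543e+00,9.408985e+03,1.825603e-01,9.409168e+03,9.408986e+03
2.306661e+00,8.177518e+03,1.824849e-01,8.177701e+03,8.177519e+03
2.418996e+00,7.107229e+03,1.824058e-01,7.107411e+03,7.107229e+03
2.536801e+00,6.177020e+03,1.823230e-01,6.177203e+03,6.177021e+03
2.660343e+00,5.368560e+03,1.822363e-01,5.368742e+03,5.368561e+03
2.789902e+00,4.665912e+03,1.821455e-01,4.666094e+03,4.665913e+03
2.925770e+00,4.055228e+03,1.820503e-01,4.055410e+03,4.055229e+03
3.068255e+00,3.524472e+03,1.819507e-01,3.524654e+03,3.524473e+03
3.217679e+00,3.063182e+03,1.818464e-01,3.063364e+03,3.063183e+03
3.374380e+00,2.662267e+03,1.817372e-01,2.662448e+03,2.662268e+03
3.538712e+00,2.313824e+03,1.816228e-01,2.314006e+03,2.313825e+03
3.711047e+00,2.010986e+03,1.815031e-01,2.011168e+03,2.010987e+03
3.891775e+00,1.747784e+03,1.813777e-01,1.747966e+03,1.747786e+03
4.081305e+00,1.519031e+03,1.812465e-01,1.519212e+03,1.519032e+03
4.280064e+00,1.320217e+03,1.811092e-01,1.320398e+03,1.320219e+03
4.488504e+00,1.147424e+03,1.809655e-01,1.147605e+03,1.147426e+03
4.707094e+00,9.972472e+02,1.808150e-01,9.974281e+02,9.972489e+02
4.936329e+00,8.667255e+02,1.806577e-01,8.669062e+02,8.667273e+02
5.176729e+00,7.532868e+02,1.804930e-01,7.534673e+02,7.532886e+02
5.428835e+00,6.546951e+02,1.803208e-01,6.548754e+02,6.546970e+02
5.693220e+00,5.690073e+02,1.801406e-01,5.691875e+02,5.690093e+02
5.970479e+00,4.945345e+02,1.799521e-01,4.947145e+02,4.945366e+02
6.261242e+00,4.298089e+02,1.797550e-01,4.299886e+02,4.298110e+02
6.566164e+00,3.735546e+02,1.795490e-01,3.737342e+02,3.735569e+02
6.885936e+00,3.246631e+02,1.793335e-01,3.248424e+02,3.246654e+02
7.221282e+00,2.821705e+02,1.791083e-01,2.823496e+02,2.821730e+02
7.572958e+00,2.452395e+02,1.788730e-01,2.454184e+02,2.452420e+02
7.941761e+00,2.131421e+02,1.786270e-01,2.133207e+02,2.131447e+02
8.328525e+00,1.852456e+02,1.783700e-01,1.854240e+02,1.852484e+02
8.734124e+00,1.610003e+02,1.781015e-01,1.611784e+02,1.610032e+02
9.159476e+00,1.399282e+02,1.778211e-01,1.401061e+02,1.399313e+02
9.605543e+00,1.216142e+02,1.775283e-01,1.217917e+02,1.216174e+02
1.007333e+01,1.056971e+02,1.772226e-01,1.058743e+02,1.057004e+02
1.056390e+01,9.186322e+01,1.769035e-01,9.204012e+01,9.186672e+01
1.107837e+01,7.983998e+01,1.765705e-01,8.001655e+01,7.984363e+01
1.161788e+01,6.939037e+01,1.762230e-01,6.956659e+01,6.939418e+01
1.218367e+01,6.030842e+01,1.758606e-01,6.048428e+01,6.031240e+01
1.277702e+01,5.241513e+01,1.754826e-01,5.259061e+01,5.241929e+01
1.339926e+01,4.555494e+01,1.750885e-01,4.573002e+01,4.555928e+01
1.405180e+01,3.959262e+01,1.746777e-01,3.976729e+01,3.959715e+01
1.473613e+01,3.441066e+01,1.742496e-01,3.458490e+01,3.441538e+01
1.545378e+01,2.990692e+01,1.738036e-01,3.008072e+01,2.991185e+01
1.620637e+01,2.599264e+01,1.733392e-01,2.616598e+01,2.599778e+01
1.699562e+01,2.259067e+01,1.728557e-01,2.276353e+01,2.259603e+01
1.782331e+01,1.963396e+01,1.723525e-01,1.980632e+01,1.963955e+01
1.869131e+01,1.706423e+01,1.718289e-01,1.723606e+01,1.707005e+01
1.960157e+01,1.483083e+01,1.712844e-01,1.500211e+01,1.483689e+01
2.055617e+01,1.288974e+01,1.707183e-01,1.306046e+01,1.289605e+01
2.155726e+01,1.120271e+01,1.701299e-01,1.137284e+01,1.120928e+01
2.260709e+01,9.736475e+00,1.695187e-01,9.905993e+00,9.743312e+00
2.370806e+01,8.462145e+00,1.688840e-01,8.631029e+00,8.469259e+00
2.486264e+01,7.354603e+00,1.682252e-01,7.522828e+00,7.362001e+00
2.607345e+01,6.392018e+00,1.675416e-01,6.559560e+00,6.399709e+00
2.734323e+01,5.555418e+00,1.668328e-01,5.722251e+00,5.563411e+00
2.867485e+01,4.828314e+00,1.660980e-01,4.994412e+00,4.836617e+00
3.007131e+01,4.196375e+00,1.653367e-01,4.361711e+00,4.204997e+00
3.153578e+01,3.647145e+00,1.645485e-01,3.811693e+00,3.656095e+00
3.307158e+01,3.169799e+00,1.637326e-01,3.333532e+00,3.179085e+00
3.468216e+01,2.754930e+00,1.628887e-01,2.917818e+00,2.764560e+00
3.637119e+01,2.394359e+00,1.620163e-01,2.556375e+00,2.404342e+00
3.814246e+01,2.080981e+00,1.611149e-01,2.242095e+00,2.091325e+00
4.000000e+01,1.808618e+00,1.601841e-01,1.968802e+00,1.819331e+00
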