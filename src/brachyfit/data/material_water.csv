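# material: water
# density_g_cm3: 0.998
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,8.814750e+02,2.206567e-01,8.816957e+02,8.814759e+02
2.097400e+00,7.552546e+02,2.205736e-01,7.554752e+02,7.552555e+02
2.199543e+00,6.471080e+02,2.204866e-01,6.473285e+02,6.471089e+02
2.306661e+00,5.544471e+02,2.203955e-01,5.546675e+02,5.544481e+02
2.418996e+00,4.750546e+02,2.203000e-01,4.752749e+02,4.750556e+02
2.536801e+00,4.070304e+02,2.202000e-01,4.072506e+02,4.070315e+02
2.660343e+00,3.487468e+02,2.200953e-01,3.489669e+02,3.487480e+02
2.789902e+00,2.988090e+02,2.199856e-01,2.990290e+02,2.988102e+02
2.925770e+00,2.560218e+02,2.198707e-01,2.562417e+02,2.560231e+02
3.068255e+00,2.193615e+02,2.197504e-01,2.195812e+02,2.193628e+02
3.217679e+00,1.879506e+02,2.196244e-01,1.881702e+02,1.879520e+02
3.374380e+00,1.610375e+02,2.194925e-01,1.612570e+02,1.610390e+02
3.538712e+00,1.379782e+02,2.193544e-01,1.381976e+02,1.379797e+02
3.711047e+00,1.182208e+02,2.192097e-01,1.184400e+02,1.182224e+02
3.891775e+00,1.012925e+02,2.190584e-01,1.015115e+02,1.012941e+02
4.081305e+00,8.678819e+01,2.188999e-01,8.700709e+01,8.678990e+01
4.280064e+00,7.436079e+01,2.187340e-01,7.457952e+01,7.436259e+01
4.488504e+00,6.371290e+01,2.185604e-01,6.393146e+01,6.371478e+01
4.707094e+00,5.458970e+01,2.183788e-01,5.480808e+01,5.459167e+01
4.936329e+00,4.677288e+01,2.181887e-01,4.699107e+01,4.677494e+01
5.176729e+00,4.007536e+01,2.179899e-01,4.029335e+01,4.007752e+01
5.428835e+00,3.433688e+01,2.177818e-01,3.455466e+01,3.433914e+01
5.693220e+00,2.942011e+01,2.175642e-01,2.963767e+01,2.942247e+01
5.970479e+00,2.520737e+01,2.173366e-01,2.542471e+01,2.520985e+01
6.261242e+00,2.159787e+01,2.170986e-01,2.181497e+01,2.160046e+01
6.566164e+00,1.850522e+01,2.168497e-01,1.872207e+01,1.850793e+01
6.885936e+00,1.585542e+01,2.165895e-01,1.607201e+01,1.585825e+01
7.221282e+00,1.358505e+01,2.163175e-01,1.380136e+01,1.358801e+01
7.572958e+00,1.163977e+01,2.160333e-01,1.185580e+01,1.164287e+01
7.941761e+00,9.973046e+00,2.157362e-01,1.018878e+01,9.976288e+00
8.328525e+00,8.544983e+00,2.154258e-01,8.760409e+00,8.548373e+00
8.734124e+00,7.321407e+00,2.151016e-01,7.536509e+00,7.324951e+00
9.159476e+00,6.273038e+00,2.147629e-01,6.487801e+00,6.276742e+00
9.605543e+00,5.374788e+00,2.144093e-01,5.589197e+00,5.378658e+00
1.007333e+01,4.605160e+00,2.140401e-01,4.819200e+00,4.609204e+00
1.056390e+01,3.945736e+00,2.136547e-01,4.159391e+00,3.949962e+00
1.107837e+01,3.380737e+00,2.132525e-01,3.593990e+00,3.385151e+00
1.161788e+01,2.896642e+00,2.128328e-01,3.109475e+00,2.901251e+00
1.218367e+01,2.481865e+00,2.123950e-01,2.694260e+00,2.486678e+00
1.277702e+01,2.126481e+00,2.119385e-01,2.338420e+00,2.131505e+00
1.339926e+01,1.821986e+00,2.114625e-01,2.033448e+00,1.827229e+00
1.405180e+01,1.561091e+00,2.109664e-01,1.772058e+00,1.566563e+00
1.473613e+01,1.337555e+00,2.104494e-01,1.548004e+00,1.343263e+00
1.545378e+01,1.146028e+00,2.099108e-01,1.355938e+00,1.151981e+00
1.620637e+01,9.819252e-01,2.093499e-01,1.191275e+00,9.881334e-01
1.699562e+01,8.413211e-01,2.087659e-01,1.050087e+00,8.477930e-01
1.782331e+01,7.208504e-01,2.081582e-01,9.290086e-01,7.275956e-01
1.869131e+01,6.176302e-01,2.075258e-01,8.251561e-01,6.246582e-01
1.960157e+01,5.291904e-01,2.068682e-01,7.360585e-01,5.365109e-01
2.055617e+01,4.534144e-01,2.061845e-01,6.595988e-01,4.610375e-01
2.155726e+01,3.884889e-01,2.054739e-01,5.939628e-01,3.964246e-01
2.260709e+01,3.328603e-01,2.047357e-01,5.375960e-01,3.411188e-01
2.370806e+01,2.851973e-01,2.039691e-01,4.891664e-01,2.937888e-01
2.486264e+01,2.443592e-01,2.031734e-01,4.475327e-01,2.532942e-01
2.607345e+01,2.093689e-01,2.023479e-01,4.117168e-01,2.186578e-01
2.734323e+01,1.793889e-01,2.014917e-01,3.808806e-01,1.890421e-01
2.867485e+01,1.537018e-01,2.006043e-01,3.543061e-01,1.637298e-01
3.007131e+01,1.316929e-01,1.996849e-01,3.313778e-01,1.421062e-01
3.153578e+01,1.128355e-01,1.987329e-01,3.115684e-01,1.236444e-01
3.307158e+01,9.667830e-02,1.977475e-01,2.944259e-01,1.078933e-01
3.468216e+01,8.283472e-02,1.967283e-01,2.795630e-01,9.446584e-02
3.637119e+01,7.097343e-02,1.956747e-01,2.666481e-01,8.303076e-02
3.814246e+01,6.081058e-02,1.945860e-01,2.553966e-01,7.330396e-02
4.000000e+01,5.210297e-02,1.934619e-01,2.455649e-01,6.504200e-02
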