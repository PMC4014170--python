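# material: glass
# density_g_cm3: 2.61
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,3.112188e+03,1.953648e-01,3.112383e+03,3.112188e+03
2.097400e+00,2.676453e+03,1.952913e-01,2.676648e+03,2.676454e+03
2.199543e+00,2.301735e+03,1.952143e-01,2.301930e+03,2.301736e+03
2.306661e+00,1.979488e+03,1.951336e-01,1.979683e+03,1.979489e+03
2.418996e+00,1.702364e+03,1.950491e-01,1.702559e+03,1.702365e+03
2.536801e+00,1.464043e+03,1.949606e-01,1.464238e+03,1.464044e+03
2.660343e+00,1.259092e+03,1.948678e-01,1.259286e+03,1.259093e+03
2.789902e+00,1.082836e+03,1.947707e-01,1.083031e+03,1.082837e+03
2.925770e+00,9.312577e+02,1.946690e-01,9.314524e+02,9.312588e+02
3.068255e+00,8.009015e+02,1.945625e-01,8.010961e+02,8.009027e+02
3.217679e+00,6.887955e+02,1.944509e-01,6.889900e+02,6.887967e+02
3.374380e+00,5.923842e+02,1.943341e-01,5.925785e+02,5.923855e+02
3.538712e+00,5.094700e+02,1.942118e-01,5.096642e+02,5.094713e+02
3.711047e+00,4.381630e+02,1.940838e-01,4.383571e+02,4.381644e+02
3.891775e+00,3.768382e+02,1.939497e-01,3.770321e+02,3.768396e+02
4.081305e+00,3.240977e+02,1.938094e-01,3.242916e+02,3.240993e+02
4.280064e+00,2.787399e+02,1.936626e-01,2.789336e+02,2.787415e+02
4.488504e+00,2.397311e+02,1.935089e-01,2.399246e+02,2.397328e+02
4.707094e+00,2.061824e+02,1.933481e-01,2.063758e+02,2.061842e+02
4.936329e+00,1.773295e+02,1.931798e-01,1.775227e+02,1.773313e+02
5.176729e+00,1.525149e+02,1.930037e-01,1.527079e+02,1.525168e+02
5.428835e+00,1.311734e+02,1.928195e-01,1.313662e+02,1.311754e+02
5.693220e+00,1.128188e+02,1.926268e-01,1.130114e+02,1.128209e+02
5.970479e+00,9.703289e+01,1.924253e-01,9.722532e+01,9.703508e+01
6.261242e+00,8.345623e+01,1.922146e-01,8.364844e+01,8.345852e+01
6.566164e+00,7.177953e+01,1.919942e-01,7.197153e+01,7.178193e+01
6.885936e+00,6.173688e+01,1.917639e-01,6.192864e+01,6.173939e+01
7.221282e+00,5.309956e+01,1.915231e-01,5.329108e+01,5.310218e+01
7.572958e+00,4.567087e+01,1.912714e-01,4.586214e+01,4.567361e+01
7.941761e+00,3.928166e+01,1.910084e-01,3.947267e+01,3.928453e+01
8.328525e+00,3.378645e+01,1.907336e-01,3.397719e+01,3.378945e+01
8.734124e+00,2.906013e+01,1.904465e-01,2.925058e+01,2.906327e+01
9.159476e+00,2.499510e+01,1.901467e-01,2.518524e+01,2.499837e+01
9.605543e+00,2.149880e+01,1.898336e-01,2.168864e+01,2.150223e+01
1.007333e+01,1.849166e+01,1.895067e-01,1.868117e+01,1.849524e+01
1.056390e+01,1.590523e+01,1.891654e-01,1.609440e+01,1.590897e+01
1.107837e+01,1.368064e+01,1.888093e-01,1.386945e+01,1.368454e+01
1.161788e+01,1.176725e+01,1.884378e-01,1.195569e+01,1.177133e+01
1.218367e+01,1.012152e+01,1.880502e-01,1.030957e+01,1.012578e+01
1.277702e+01,8.706011e+00,1.876460e-01,8.893657e+00,8.710459e+00
1.339926e+01,7.488501e+00,1.872245e-01,7.675726e+00,7.493143e+00
1.405180e+01,6.441292e+00,1.867853e-01,6.628077e+00,6.446136e+00
1.473613e+01,5.540557e+00,1.863275e-01,5.726885e+00,5.545611e+00
1.545378e+01,4.765806e+00,1.858507e-01,4.951657e+00,4.771077e+00
1.620637e+01,4.099413e+00,1.853541e-01,4.284767e+00,4.104910e+00
1.699562e+01,3.526221e+00,1.848370e-01,3.711058e+00,3.531951e+00
1.782331e+01,3.033192e+00,1.842989e-01,3.217491e+00,3.039164e+00
1.869131e+01,2.609112e+00,1.837391e-01,2.792851e+00,2.615334e+00
1.960157e+01,2.244337e+00,1.831568e-01,2.427494e+00,2.250819e+00
2.055617e+01,1.930572e+00,1.825515e-01,2.113124e+00,1.937321e+00
2.155726e+01,1.660682e+00,1.819223e-01,1.842605e+00,1.667708e+00
2.260709e+01,1.428531e+00,1.812687e-01,1.609800e+00,1.435843e+00
2.370806e+01,1.228840e+00,1.805900e-01,1.409430e+00,1.236447e+00
2.486264e+01,1.057070e+00,1.798855e-01,1.236956e+00,1.064981e+00
2.551300e+01,9.740818e-01,1.794920e-01,1.153574e+00,9.821616e-01
2.551500e+01,1.044913e+00,1.794908e-01,1.224403e+00,1.052993e+00
2.607345e+01,9.762806e-01,1.791546e-01,1.155435e+00,9.845048e-01
2.734323e+01,8.409758e-01,1.783966e-01,1.019372e+00,8.495225e-01
2.867485e+01,7.244458e-01,1.776109e-01,9.020567e-01,7.333244e-01
3.007131e+01,6.240826e-01,1.767969e-01,8.008795e-01,6.333023e-01
3.153578e+01,5.376409e-01,1.759540e-01,7.135949e-01,5.472109e-01
3.307158e+01,4.631874e-01,1.750816e-01,6.382690e-01,4.731169e-01
3.468216e+01,3.990576e-01,1.741792e-01,5.732368e-01,4.093555e-01
3.637119e+01,3.438183e-01,1.732463e-01,5.170646e-01,3.544937e-01
3.814246e+01,2.962357e-01,1.722824e-01,4.685181e-01,3.072971e-01
4.000000e+01,2.552471e-01,1.712872e-01,4.265342e-01,2.667030e-01
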