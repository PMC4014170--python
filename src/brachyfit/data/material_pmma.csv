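# material: pmma
# density_g_cm3: 1.19
# built by scripts/build_material_tables.py; coherent scattering excluded
energy_kev,mu_pe,mu_incoh,mu_total,mu_en
2.000000e+00,5.467211e+02,2.144063e-01,5.469355e+02,5.467219e+02
2.097400e+00,4.685283e+02,2.143256e-01,4.687427e+02,4.685292e+02
2.199543e+00,4.015189e+02,2.142411e-01,4.017331e+02,4.015198e+02
2.306661e+00,3.440932e+02,2.141525e-01,3.443073e+02,3.440942e+02
2.418996e+00,2.948806e+02,2.140598e-01,2.950947e+02,2.948816e+02
2.536801e+00,2.527065e+02,2.139626e-01,2.529205e+02,2.527075e+02
2.660343e+00,2.165642e+02,2.138608e-01,2.167780e+02,2.165653e+02
2.789902e+00,1.855910e+02,2.137542e-01,1.858047e+02,1.855921e+02
2.925770e+00,1.590476e+02,2.136426e-01,1.592612e+02,1.590488e+02
3.068255e+00,1.363005e+02,2.135257e-01,1.365140e+02,1.363017e+02
3.217679e+00,1.168067e+02,2.134033e-01,1.170201e+02,1.168080e+02
3.374380e+00,1.001009e+02,2.132751e-01,1.003142e+02,1.001023e+02
3.538712e+00,8.578438e+01,2.131409e-01,8.599752e+01,8.578584e+01
3.711047e+00,7.351544e+01,2.130004e-01,7.372844e+01,7.351697e+01
3.891775e+00,6.300122e+01,2.128533e-01,6.321407e+01,6.300282e+01
4.081305e+00,5.399075e+01,2.126993e-01,5.420345e+01,5.399242e+01
4.280064e+00,4.626897e+01,2.125381e-01,4.648151e+01,4.627072e+01
4.488504e+00,3.965156e+01,2.123695e-01,3.986393e+01,3.965339e+01
4.707094e+00,3.398058e+01,2.121930e-01,3.419277e+01,3.398249e+01
4.936329e+00,2.912066e+01,2.120083e-01,2.933267e+01,2.912267e+01
5.176729e+00,2.495582e+01,2.118150e-01,2.516763e+01,2.495791e+01
5.428835e+00,2.138663e+01,2.116129e-01,2.159824e+01,2.138882e+01
5.693220e+00,1.832791e+01,2.114014e-01,1.853931e+01,1.833021e+01
5.970479e+00,1.570665e+01,2.111803e-01,1.591783e+01,1.570905e+01
6.261242e+00,1.346028e+01,2.109490e-01,1.367123e+01,1.346280e+01
6.566164e+00,1.153519e+01,2.107072e-01,1.174590e+01,1.153782e+01
6.885936e+00,9.885427e+00,2.104543e-01,1.009588e+01,9.888181e+00
7.221282e+00,8.471613e+00,2.101901e-01,8.681803e+00,8.474494e+00
7.572958e+00,7.260003e+00,2.099138e-01,7.469917e+00,7.263016e+00
7.941761e+00,6.221679e+00,2.096252e-01,6.431304e+00,6.224829e+00
8.328525e+00,5.331855e+00,2.093236e-01,5.541179e+00,5.335149e+00
8.734124e+00,4.569294e+00,2.090086e-01,4.778303e+00,4.572737e+00
9.159476e+00,3.915795e+00,2.086795e-01,4.124474e+00,3.919394e+00
9.605543e+00,3.355759e+00,2.083359e-01,3.564095e+00,3.359520e+00
1.007333e+01,2.875820e+00,2.079771e-01,3.083797e+00,2.879749e+00
1.056390e+01,2.464521e+00,2.076026e-01,2.672124e+00,2.468627e+00
1.107837e+01,2.112046e+00,2.072118e-01,2.319258e+00,2.116335e+00
1.161788e+01,1.809982e+00,2.068040e-01,2.016786e+00,1.814461e+00
1.218367e+01,1.551120e+00,2.063787e-01,1.757498e+00,1.555796e+00
1.277702e+01,1.329279e+00,2.059351e-01,1.535215e+00,1.334161e+00
1.339926e+01,1.139167e+00,2.054726e-01,1.344639e+00,1.144262e+00
1.405180e+01,9.762439e-01,2.049905e-01,1.181234e+00,9.815603e-01
1.473613e+01,8.366222e-01,2.044881e-01,1.041110e+00,8.421686e-01
1.545378e+01,7.169691e-01,2.039648e-01,9.209340e-01,7.227541e-01
1.620637e+01,6.144288e-01,2.034198e-01,8.178486e-01,6.204611e-01
1.699562e+01,5.265537e-01,2.028524e-01,7.294061e-01,5.328423e-01
1.782331e+01,4.512465e-01,2.022618e-01,6.535083e-01,4.578005e-01
1.869131e+01,3.867097e-01,2.016474e-01,5.883571e-01,3.935385e-01
1.960157e+01,3.314028e-01,2.010084e-01,5.324112e-01,3.385160e-01
2.055617e+01,2.840059e-01,2.003440e-01,4.843500e-01,2.914131e-01
2.155726e+01,2.433877e-01,1.996536e-01,4.430413e-01,2.510986e-01
2.260709e+01,2.085787e-01,1.989363e-01,4.075150e-01,2.166032e-01
2.370806e+01,1.787480e-01,1.981914e-01,3.769395e-01,1.870962e-01
2.486264e+01,1.531837e-01,1.974183e-01,3.506020e-01,1.618656e-01
2.607345e+01,1.312756e-01,1.966161e-01,3.278917e-01,1.403013e-01
2.734323e+01,1.125007e-01,1.957843e-01,3.082850e-01,1.218805e-01
2.867485e+01,9.641101e-02,1.949220e-01,2.913330e-01,1.061550e-01
3.007131e+01,8.262245e-02,1.940286e-01,2.766511e-01,9.274079e-02
3.153578e+01,7.080591e-02,1.931035e-01,2.639094e-01,8.130870e-02
3.307158e+01,6.067936e-02,1.921461e-01,2.528255e-01,7.157663e-02
3.468216e+01,5.200109e-02,1.911558e-01,2.431569e-01,6.330275e-02
3.637119e+01,4.456398e-02,1.901319e-01,2.346959e-01,5.627977e-02
3.814246e+01,3.819051e-02,1.890741e-01,2.272646e-01,5.033000e-02
4.000000e+01,3.272857e-02,1.879818e-01,2.207104e-01,4.530108e-02
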