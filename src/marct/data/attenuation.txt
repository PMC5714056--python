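# marct attenuation table (generated by scripts/make_attenuation_table.py)
# mu_over_rho and muen_over_rho in cm^2/g on the shared energy grid
[energies_keV]
20.00 24.43 29.85 36.47 44.55 54.43 66.49 81.23 99.24 121.24 148.11 180.95 221.06 270.06 329.93 403.07 492.42 601.58 734.93 897.85 1096.88 1340.04 1637.09 2000.00
[material air]
density 0.0012
composition N 0.7552 O 0.232 Ar 0.0128
mu_over_rho 7.837261e-01 5.045630e-01 3.524995e-01 2.687792e-01 2.215060e-01 1.934743e-01 1.755486e-01 1.627785e-01 1.525607e-01 1.435399e-01 1.350430e-01 1.267631e-01 1.186028e-01 1.105562e-01 1.026603e-01 9.496500e-02 8.751354e-02 8.033759e-02 7.345987e-02 6.689491e-02 6.065538e-02 5.475205e-02 4.919641e-02 4.399836e-02
muen_over_rho 6.046461e-01 3.295039e-01 1.821045e-01 1.037310e-01 6.251223e-02 4.125875e-02 3.079731e-02 2.612499e-02 2.453686e-02 2.454227e-02 2.530885e-02 2.636538e-02 2.744045e-02 2.837930e-02 2.909553e-02 2.954348e-02 2.970216e-02 2.956550e-02 2.913765e-02 2.843119e-02 2.746716e-02 2.627469e-02 2.489043e-02 2.335624e-02
[material water]
density 1.0
composition H 0.1119 O 0.8881
mu_over_rho 8.246982e-01 5.359009e-01 3.784524e-01 2.916118e-01 2.424041e-01 2.130409e-01 1.940787e-01 1.804008e-01 1.693195e-01 1.594394e-01 1.500720e-01 1.409086e-01 1.318578e-01 1.229226e-01 1.141493e-01 1.055959e-01 9.731186e-02 8.933333e-02 8.168595e-02 7.438609e-02 6.744796e-02 6.088360e-02 5.470584e-02 4.892569e-02
muen_over_rho 6.255632e-01 3.412369e-01 1.889750e-01 1.080799e-01 6.560469e-02 4.377886e-02 3.311684e-02 2.844358e-02 2.695838e-02 2.711531e-02 2.804886e-02 2.926734e-02 3.048624e-02 3.154283e-02 3.234605e-02 3.284781e-02 3.302622e-02 3.287531e-02 3.240010e-02 3.161483e-02 3.054300e-02 2.921708e-02 2.767784e-02 2.597187e-02
[material solid_water]
density 1.004
composition H 0.0809 C 0.6313 N 0.024 O 0.1984 Cl 0.0013 Ca 0.0641
mu_over_rho 9.772329e-01 6.153300e-01 4.185784e-01 3.106882e-01 2.502476e-01 2.149215e-01 1.928465e-01 1.775924e-01 1.657689e-01 1.556005e-01 1.461927e-01 1.371239e-01 1.282404e-01 1.195099e-01 1.109586e-01 1.026328e-01 9.457516e-02 8.681776e-02 7.938399e-02 7.228892e-02 6.554591e-02 5.916641e-02 5.316275e-02 4.754556e-02
muen_over_rho 7.837156e-01 4.261577e-01 2.344463e-01 1.323340e-01 7.843589e-02 5.043448e-02 3.642553e-02 2.992198e-02 2.742384e-02 2.700940e-02 2.761190e-02 2.863213e-02 2.972858e-02 3.070802e-02 3.146312e-02 3.193705e-02 3.210307e-02 3.195246e-02 3.148854e-02 3.072428e-02 2.968207e-02 2.839322e-02 2.689723e-02 2.523929e-02
[material lung_ln300]
density 0.3
composition H 0.0809 C 0.6313 N 0.024 O 0.1984 Cl 0.0013 Ca 0.0641
mu_over_rho 9.772329e-01 6.153300e-01 4.185784e-01 3.106882e-01 2.502476e-01 2.149215e-01 1.928465e-01 1.775924e-01 1.657689e-01 1.556005e-01 1.461927e-01 1.371239e-01 1.282404e-01 1.195099e-01 1.109586e-01 1.026328e-01 9.457516e-02 8.681776e-02 7.938399e-02 7.228892e-02 6.554591e-02 5.916641e-02 5.316275e-02 4.754556e-02
muen_over_rho 7.837156e-01 4.261577e-01 2.344463e-01 1.323340e-01 7.843589e-02 5.043448e-02 3.642553e-02 2.992198e-02 2.742384e-02 2.700940e-02 2.761190e-02 2.863213e-02 2.972858e-02 3.070802e-02 3.146312e-02 3.193705e-02 3.210307e-02 3.195246e-02 3.148854e-02 3.072428e-02 2.968207e-02 2.839322e-02 2.689723e-02 2.523929e-02
[material adipose]
density 0.92
composition H 0.1 C 0.712 N 0.018 O 0.169 Cl 0.001
mu_over_rho 5.835494e-01 4.051717e-01 3.071931e-01 2.523245e-01 2.203172e-01 2.002418e-01 1.863041e-01 1.753678e-01 1.658023e-01 1.567809e-01 1.479206e-01 1.390761e-01 1.302431e-01 1.214706e-01 1.128293e-01 1.043899e-01 9.620859e-02 8.832480e-02 8.076604e-02 7.354960e-02 6.669014e-02 6.019988e-02 5.409168e-02 4.837651e-02
muen_over_rho 3.866489e-01 2.126922e-01 1.198419e-01 7.085217e-02 4.550181e-02 3.287918e-02 2.714843e-02 2.511581e-02 2.503870e-02 2.594171e-02 2.726672e-02 2.868769e-02 3.000908e-02 3.111626e-02 3.194404e-02 3.245822e-02 3.264433e-02 3.250033e-02 3.203326e-02 3.125831e-02 3.019932e-02 2.888871e-02 2.736697e-02 2.568027e-02
[material liver]
density 1.096
composition H 0.081 C 0.667 N 0.025 O 0.202 Cl 0.002 Ca 0.023
mu_over_rho 7.385551e-01 4.869760e-01 3.496204e-01 2.736370e-01 2.303326e-01 2.042271e-01 1.871044e-01 1.745136e-01 1.641216e-01 1.547222e-01 1.457273e-01 1.368800e-01 1.281152e-01 1.194481e-01 1.109304e-01 1.026223e-01 9.457379e-02 8.682091e-02 7.938923e-02 7.229494e-02 6.555203e-02 5.917229e-02 5.316822e-02 4.755056e-02
muen_over_rho 5.450168e-01 2.977832e-01 1.654683e-01 9.526341e-02 5.850234e-02 3.972231e-02 3.066642e-02 2.682726e-02 2.576160e-02 2.611718e-02 2.713362e-02 2.837655e-02 2.959273e-02 3.063658e-02 3.142634e-02 3.191890e-02 3.209493e-02 3.194968e-02 3.148859e-02 3.072580e-02 2.968431e-02 2.839578e-02 2.689986e-02 2.524187e-02
[material inner_bone]
density 1.147
composition H 0.0687 C 0.5305 N 0.0212 O 0.2562 P 0.0324 Ca 0.091
mu_over_rho 1.239850e+00 7.554929e-01 4.928373e-01 3.495704e-01 2.701595e-01 2.246592e-01 1.971567e-01 1.790235e-01 1.656957e-01 1.547645e-01 1.449939e-01 1.357780e-01 1.268636e-01 1.181638e-01 1.096752e-01 1.014279e-01 9.345529e-02 8.578467e-02 7.843666e-02 7.142482e-02 6.476164e-02 5.845806e-02 5.252607e-02 4.697604e-02
muen_over_rho 1.048651e+00 5.685873e-01 3.109115e-01 1.733532e-01 1.004065e-01 6.214310e-02 4.260995e-02 3.312255e-02 2.900832e-02 2.771416e-02 2.783395e-02 2.858624e-02 2.953213e-02 3.042596e-02 3.113230e-02 3.157919e-02 3.173175e-02 3.157678e-02 3.111509e-02 3.035821e-02 2.932753e-02 2.805361e-02 2.657526e-02 2.493704e-02
[material cortical_bone]
density 1.819
composition H 0.0341 C 0.3141 N 0.0184 O 0.3653 Cl 0.0004 Ca 0.2677
mu_over_rho 2.240313e+00 1.290793e+00 7.777608e-01 5.000614e-01 3.485261e-01 2.643025e-01 2.160965e-01 1.869307e-01 1.677832e-01 1.538414e-01 1.425740e-01 1.326765e-01 1.235191e-01 1.148103e-01 1.064356e-01 9.836411e-02 9.059627e-02 8.314109e-02 7.600929e-02 6.920899e-02 6.274963e-02 5.664035e-02 5.089199e-02 4.551418e-02
muen_over_rho 2.055067e+00 1.109706e+00 6.014989e-01 3.293304e-01 1.840580e-01 1.068460e-01 6.636123e-02 4.557209e-02 3.535133e-02 3.074656e-02 2.906162e-02 2.882191e-02 2.921784e-02 2.980402e-02 3.033793e-02 3.069004e-02 3.079437e-02 3.062086e-02 3.016099e-02 2.942091e-02 2.841869e-02 2.718249e-02 2.574911e-02 2.416133e-02
[material titanium]
density 4.54
composition Ti 1.0
mu_over_rho 7.409705e+00 4.061506e+00 2.257273e+00 1.286183e+00 7.625023e-01 4.783255e-01 3.230479e-01 2.366434e-01 1.871056e-01 1.572313e-01 1.378156e-01 1.239578e-01 1.130942e-01 1.038844e-01 9.564619e-02 8.804055e-02 8.090009e-02 7.414268e-02 6.772942e-02 6.164151e-02 5.587333e-02 5.042550e-02 4.530360e-02 4.051406e-02
muen_over_rho 7.244823e+00 3.900326e+00 2.100388e+00 1.134221e+00 6.161148e-01 3.381787e-01 1.897736e-01 1.108249e-01 6.923240e-02 4.766869e-02 3.678203e-02 3.152039e-02 2.915984e-02 2.822314e-02 2.791423e-02 2.780614e-02 2.767243e-02 2.739619e-02 2.692140e-02 2.622748e-02 2.531652e-02 2.420604e-02 2.292478e-02 2.150860e-02
[material cerrobend]
density 9.76
composition Bi 0.5 Pb 0.267 Sn 0.133 Cd 0.1
mu_over_rho 1.257018e+02 6.767095e+01 3.642685e+01 1.964113e+01 1.062397e+01 5.769818e+00 3.160262e+00 1.754043e+00 9.953507e-01 5.847299e-01 3.610894e-01 2.378208e-01 1.685807e-01 1.284041e-01 1.039217e-01 8.797571e-02 7.672806e-02 6.812239e-02 6.105831e-02 5.494585e-02 4.947202e-02 4.447165e-02 3.986059e-02 3.559658e-02
muen_over_rho 1.255572e+02 6.752963e+01 3.628929e+01 1.950790e+01 1.049563e+01 5.646942e+00 3.043412e+00 1.643729e+00 8.920035e-01 4.886691e-01 2.725066e-01 1.567748e-01 9.498990e-02 6.206680e-02 4.453655e-02 3.516420e-02 3.005985e-02 2.713664e-02 2.527920e-02 2.389602e-02 2.268084e-02 2.148331e-02 2.023959e-02 1.893323e-02
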