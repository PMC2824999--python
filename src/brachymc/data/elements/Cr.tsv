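# element Cr Z=24 A=51.996 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.248824e+02	1.780292e-01	3.028742e-01	0.000000e+00
1.500000e-02	4.164216e+01	1.748304e-01	1.658819e-01	0.000000e+00
2.000000e-02	1.863328e+01	1.717796e-01	1.118305e-01	0.000000e+00
3.000000e-02	5.825819e+00	1.660832e-01	6.337061e-02	0.000000e+00
4.000000e-02	2.510101e+00	1.608697e-01	4.100451e-02	0.000000e+00
5.000000e-02	1.296296e+00	1.560800e-01	2.982146e-02	0.000000e+00
6.000000e-02	7.530938e-01	1.516639e-01	2.236610e-02	0.000000e+00
8.000000e-02	3.184210e-01	1.437879e-01	1.397881e-02	0.000000e+00
1.000000e-01	1.629945e-01	1.369675e-01	9.785167e-03	0.000000e+00
1.500000e-01	4.859611e-02	1.233074e-01	4.939180e-03	0.000000e+00
2.000000e-01	2.093009e-02	1.129884e-01	2.982146e-03	0.000000e+00
3.000000e-01	6.635556e-03	9.824726e-02	1.491073e-03	0.000000e+00
4.000000e-01	3.040685e-03	8.802626e-02	9.039631e-04	0.000000e+00
5.000000e-01	1.715967e-03	8.037850e-02	6.150677e-04	0.000000e+00
6.000000e-01	1.117542e-03	7.435523e-02	4.380027e-04	0.000000e+00
8.000000e-01	5.905265e-04	6.531090e-02	2.609378e-04	0.000000e+00
1.000000e+00	3.839781e-04	5.870868e-02	1.770649e-04	0.000000e+00
1.022000e+00	3.681516e-04	5.808485e-02	1.677457e-04	0.000000e+00
1.170000e+00	2.992350e-04	5.428960e-02	1.351285e-04	7.559902e-06
1.250000e+00	2.886889e-04	5.248544e-02	1.211497e-04	2.116772e-05
1.330000e+00	3.069475e-04	5.082469e-02	1.099666e-04	4.535941e-05
1.400000e+00	3.245267e-04	4.947474e-02	1.006474e-04	7.559902e-05
1.500000e+00	3.456648e-04	4.769244e-02	8.853247e-05	1.360782e-04
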