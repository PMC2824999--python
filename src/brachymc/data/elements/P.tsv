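# element P Z=15 A=30.974 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	5.853979e+01	1.867858e-01	1.241295e-01	0.000000e+00
1.500000e-02	1.663957e+01	1.834296e-01	6.798477e-02	0.000000e+00
2.000000e-02	6.808171e+00	1.802288e-01	4.583243e-02	0.000000e+00
3.000000e-02	1.947186e+00	1.742522e-01	2.597171e-02	0.000000e+00
4.000000e-02	8.111051e-01	1.687823e-01	1.680522e-02	0.000000e+00
5.000000e-02	4.145598e-01	1.637570e-01	1.222198e-02	0.000000e+00
6.000000e-02	2.425152e-01	1.591238e-01	9.166486e-03	0.000000e+00
8.000000e-02	1.058682e-01	1.508603e-01	5.729054e-03	0.000000e+00
1.000000e-01	5.670033e-02	1.437044e-01	4.010338e-03	0.000000e+00
1.500000e-01	1.968555e-02	1.293724e-01	2.024266e-03	0.000000e+00
2.000000e-01	9.601962e-03	1.185459e-01	1.222198e-03	0.000000e+00
3.000000e-01	3.964169e-03	1.030797e-01	6.110991e-04	0.000000e+00
4.000000e-01	1.951597e-03	9.235596e-02	3.704788e-04	0.000000e+00
5.000000e-01	1.437331e-03	8.433203e-02	2.520784e-04	0.000000e+00
6.000000e-01	9.916176e-04	7.801250e-02	1.795104e-04	0.000000e+00
8.000000e-01	8.811078e-04	6.852331e-02	1.069423e-04	0.000000e+00
1.000000e+00	1.007924e-03	6.159635e-02	7.256802e-05	0.000000e+00
1.022000e+00	8.533815e-04	6.094184e-02	6.874865e-05	0.000000e+00
1.170000e+00	6.201796e-04	5.695991e-02	5.538085e-05	4.957341e-06
1.250000e+00	9.141545e-04	5.506701e-02	4.965180e-05	1.388056e-05
1.330000e+00	8.656164e-04	5.332458e-02	4.506856e-05	2.974405e-05
1.400000e+00	9.689143e-04	5.190823e-02	4.124919e-05	4.957341e-05
1.500000e+00	1.269882e-03	5.003826e-02	3.628401e-05	8.923214e-05
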