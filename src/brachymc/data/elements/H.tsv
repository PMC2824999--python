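# element H Z=1 A=1.008 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.630715e-03	3.826391e-01	1.130155e-03	0.000000e+00
1.500000e-02	1.716806e-05	3.757639e-01	6.189772e-04	0.000000e+00
2.000000e-02	1.000000e-09	3.692069e-01	4.172880e-04	0.000000e+00
3.000000e-02	1.000000e-09	3.569636e-01	2.364632e-04	0.000000e+00
4.000000e-02	1.000000e-09	3.457582e-01	1.530056e-04	0.000000e+00
5.000000e-02	1.000000e-09	3.354637e-01	1.112768e-04	0.000000e+00
6.000000e-02	1.000000e-09	3.259722e-01	8.345760e-05	0.000000e+00
8.000000e-02	3.634694e-06	3.090442e-01	5.216100e-05	0.000000e+00
1.000000e-01	1.000000e-09	2.943850e-01	3.651270e-05	0.000000e+00
1.500000e-01	5.632015e-05	2.650252e-01	1.843022e-05	0.000000e+00
2.000000e-01	4.218019e-05	2.428467e-01	1.112768e-05	0.000000e+00
3.000000e-01	3.105574e-05	2.111634e-01	5.563840e-06	0.000000e+00
4.000000e-01	1.012923e-04	1.891953e-01	3.373078e-06	0.000000e+00
5.000000e-01	1.397415e-04	1.727580e-01	2.295084e-06	0.000000e+00
6.000000e-01	8.625029e-05	1.598121e-01	1.634378e-06	0.000000e+00
8.000000e-01	1.259416e-04	1.403731e-01	9.736720e-07	0.000000e+00
1.000000e+00	1.164422e-04	1.261829e-01	6.607060e-07	0.000000e+00
1.022000e+00	8.334798e-05	1.248421e-01	6.259320e-07	0.000000e+00
1.170000e+00	3.015968e-05	1.166849e-01	5.042230e-07	6.770224e-07
1.250000e+00	9.040064e-05	1.128073e-01	4.520620e-07	1.895663e-06
1.330000e+00	7.821821e-05	1.092378e-01	4.103332e-07	4.062135e-06
1.400000e+00	1.031946e-04	1.063363e-01	3.755592e-07	6.770224e-06
1.500000e+00	1.818570e-04	1.025056e-01	3.303530e-07	1.218640e-05
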