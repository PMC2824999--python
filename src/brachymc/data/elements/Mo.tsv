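# element Mo Z=42 A=95.95 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	9.657329e+02	1.688318e-01	8.796328e-01	0.000000e+00
1.500000e-02	3.220245e+02	1.657982e-01	4.817681e-01	0.000000e+00
2.000000e-02	1.440937e+02	1.629051e-01	3.247875e-01	0.000000e+00
3.000000e-02	4.505186e+01	1.575030e-01	1.840462e-01	0.000000e+00
4.000000e-02	1.941096e+01	1.525588e-01	1.190887e-01	0.000000e+00
5.000000e-02	1.002444e+01	1.480166e-01	8.661000e-02	0.000000e+00
6.000000e-02	5.823777e+00	1.438286e-01	6.495750e-02	0.000000e+00
8.000000e-02	2.462393e+00	1.363595e-01	4.059844e-02	0.000000e+00
1.000000e-01	1.260458e+00	1.298914e-01	2.841891e-02	0.000000e+00
1.500000e-01	3.758004e-01	1.169370e-01	1.434478e-02	0.000000e+00
2.000000e-01	1.618552e-01	1.071512e-01	8.661000e-03	0.000000e+00
3.000000e-01	5.131366e-02	9.317158e-02	4.330500e-03	0.000000e+00
4.000000e-01	2.351403e-02	8.347862e-02	2.625366e-03	0.000000e+00
5.000000e-01	1.326981e-02	7.622596e-02	1.786331e-03	0.000000e+00
6.000000e-01	8.642105e-03	7.051387e-02	1.272084e-03	0.000000e+00
8.000000e-01	4.566622e-03	6.193679e-02	7.578375e-04	0.000000e+00
1.000000e+00	2.969356e-03	5.567566e-02	5.142469e-04	0.000000e+00
1.022000e+00	2.846967e-03	5.508406e-02	4.871812e-04	0.000000e+00
1.170000e+00	2.314025e-03	5.148487e-02	3.924516e-04	1.254634e-05
1.250000e+00	2.232471e-03	4.977392e-02	3.518531e-04	3.512976e-05
1.330000e+00	2.373667e-03	4.819897e-02	3.193744e-04	7.527807e-05
1.400000e+00	2.509609e-03	4.691876e-02	2.923087e-04	1.254634e-04
1.500000e+00	2.673073e-03	4.522854e-02	2.571234e-04	2.258342e-04
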