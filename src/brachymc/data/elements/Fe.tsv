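# element Fe Z=26 A=55.845 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.700619e+02	1.795721e-01	3.585372e-01	0.000000e+00
1.500000e-02	5.670729e+01	1.763456e-01	1.963681e-01	0.000000e+00
2.000000e-02	2.537435e+01	1.732684e-01	1.323830e-01	0.000000e+00
3.000000e-02	7.933460e+00	1.675226e-01	7.501702e-02	0.000000e+00
4.000000e-02	3.418196e+00	1.622640e-01	4.854043e-02	0.000000e+00
5.000000e-02	1.765265e+00	1.574328e-01	3.530213e-02	0.000000e+00
6.000000e-02	1.025545e+00	1.529784e-01	2.647660e-02	0.000000e+00
8.000000e-02	4.336180e-01	1.450341e-01	1.654787e-02	0.000000e+00
1.000000e-01	2.219619e-01	1.381546e-01	1.158351e-02	0.000000e+00
1.500000e-01	6.617701e-02	1.243761e-01	5.846915e-03	0.000000e+00
2.000000e-01	2.850209e-02	1.139677e-01	3.530213e-03	0.000000e+00
3.000000e-01	9.036140e-03	9.909875e-02	1.765106e-03	0.000000e+00
4.000000e-01	4.140732e-03	8.878917e-02	1.070096e-03	0.000000e+00
5.000000e-01	2.336762e-03	8.107513e-02	7.281064e-04	0.000000e+00
6.000000e-01	1.521842e-03	7.499966e-02	5.185000e-04	0.000000e+00
8.000000e-01	8.041648e-04	6.587694e-02	3.088936e-04	0.000000e+00
1.000000e+00	5.228922e-04	5.921750e-02	2.096064e-04	0.000000e+00
1.022000e+00	5.013400e-04	5.858827e-02	1.985745e-04	0.000000e+00
1.170000e+00	4.074911e-04	5.476012e-02	1.599628e-04	8.260874e-06
1.250000e+00	3.931296e-04	5.294033e-02	1.434149e-04	2.313045e-05
1.330000e+00	4.179937e-04	5.126518e-02	1.301766e-04	4.956524e-05
1.400000e+00	4.419326e-04	4.990353e-02	1.191447e-04	8.260874e-05
1.500000e+00	4.707181e-04	4.810578e-02	1.048032e-04	1.486957e-04
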