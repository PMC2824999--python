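# element N Z=7 A=14.007 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	3.658350e+00	1.927537e-01	2.789636e-02	0.000000e+00
1.500000e-02	1.031431e+00	1.892903e-01	1.527862e-02	0.000000e+00
2.000000e-02	4.215125e-01	1.859873e-01	1.030019e-02	0.000000e+00
3.000000e-02	1.209435e-01	1.798197e-01	5.836777e-03	0.000000e+00
4.000000e-02	5.084820e-02	1.741751e-01	3.776738e-03	0.000000e+00
5.000000e-02	2.626408e-02	1.689892e-01	2.746718e-03	0.000000e+00
6.000000e-02	1.543209e-02	1.642079e-01	2.060039e-03	0.000000e+00
8.000000e-02	6.932037e-03	1.556804e-01	1.287524e-03	0.000000e+00
1.000000e-01	3.702843e-03	1.482959e-01	9.012670e-04	0.000000e+00
1.500000e-01	1.339102e-03	1.335060e-01	4.549252e-04	0.000000e+00
2.000000e-01	6.917621e-04	1.223336e-01	2.746718e-04	0.000000e+00
3.000000e-01	2.895069e-04	1.063732e-01	1.373359e-04	0.000000e+00
4.000000e-01	1.799449e-04	9.530680e-02	8.325990e-05	0.000000e+00
5.000000e-01	1.068486e-04	8.702650e-02	5.665107e-05	0.000000e+00
6.000000e-01	8.460398e-05	8.050505e-02	4.034243e-05	0.000000e+00
8.000000e-01	7.328787e-05	7.071268e-02	2.403379e-05	0.000000e+00
1.000000e+00	5.929343e-05	6.356440e-02	1.630864e-05	0.000000e+00
1.022000e+00	4.457583e-05	6.288897e-02	1.545029e-05	0.000000e+00
1.170000e+00	2.502482e-05	5.877982e-02	1.244607e-05	2.387341e-06
1.250000e+00	5.571530e-05	5.682644e-02	1.115854e-05	6.684556e-06
1.330000e+00	5.790948e-05	5.502834e-02	1.012852e-05	1.432405e-05
1.400000e+00	7.393172e-05	5.356673e-02	9.270175e-06	2.387341e-05
1.500000e+00	1.118564e-04	5.163702e-02	8.154320e-06	4.297215e-05
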