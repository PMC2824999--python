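# element Ca Z=20 A=40.078 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.774195e+02	1.924748e-01	2.273958e-01	0.000000e+00
1.500000e-02	5.043038e+01	1.890164e-01	1.245429e-01	0.000000e+00
2.000000e-02	2.063387e+01	1.857181e-01	8.396153e-02	0.000000e+00
3.000000e-02	5.901435e+00	1.795595e-01	4.757820e-02	0.000000e+00
4.000000e-02	2.458258e+00	1.739230e-01	3.078590e-02	0.000000e+00
5.000000e-02	1.256427e+00	1.687446e-01	2.238974e-02	0.000000e+00
6.000000e-02	7.350030e-01	1.639702e-01	1.679231e-02	0.000000e+00
8.000000e-02	3.208603e-01	1.554551e-01	1.049519e-02	0.000000e+00
1.000000e-01	1.718446e-01	1.480813e-01	7.346634e-03	0.000000e+00
1.500000e-01	5.966201e-02	1.333128e-01	3.708301e-03	0.000000e+00
2.000000e-01	2.910115e-02	1.221565e-01	2.238974e-03	0.000000e+00
3.000000e-01	1.201441e-02	1.062192e-01	1.119487e-03	0.000000e+00
4.000000e-01	5.914805e-03	9.516887e-02	6.786891e-04	0.000000e+00
5.000000e-01	4.356193e-03	8.690056e-02	4.617884e-04	0.000000e+00
6.000000e-01	3.005346e-03	8.038855e-02	3.288493e-04	0.000000e+00
8.000000e-01	2.670418e-03	7.061034e-02	1.959102e-04	0.000000e+00
1.000000e+00	3.054768e-03	6.347241e-02	1.329391e-04	0.000000e+00
1.022000e+00	2.586387e-03	6.279796e-02	1.259423e-04	0.000000e+00
1.170000e+00	1.879610e-03	5.869475e-02	1.014535e-04	6.811105e-06
1.250000e+00	2.770575e-03	5.674420e-02	9.095833e-05	1.907109e-05
1.330000e+00	2.623468e-03	5.494870e-02	8.256217e-05	4.086663e-05
1.400000e+00	2.936538e-03	5.348921e-02	7.556538e-05	6.811105e-05
1.500000e+00	3.848698e-03	5.156229e-02	6.646955e-05	1.225999e-04
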