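# element Mn Z=25 A=54.938 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.434862e+02	1.755161e-01	3.240005e-01	0.000000e+00
1.500000e-02	4.784559e+01	1.723625e-01	1.774526e-01	0.000000e+00
2.000000e-02	2.140908e+01	1.693548e-01	1.196310e-01	0.000000e+00
3.000000e-02	6.693692e+00	1.637388e-01	6.779088e-02	0.000000e+00
4.000000e-02	2.884031e+00	1.585989e-01	4.386469e-02	0.000000e+00
5.000000e-02	1.489406e+00	1.538768e-01	3.190159e-02	0.000000e+00
6.000000e-02	8.652823e-01	1.495231e-01	2.392619e-02	0.000000e+00
8.000000e-02	3.658562e-01	1.417582e-01	1.495387e-02	0.000000e+00
1.000000e-01	1.872758e-01	1.350341e-01	1.046771e-02	0.000000e+00
1.500000e-01	5.583548e-02	1.215668e-01	5.283701e-03	0.000000e+00
2.000000e-01	2.404805e-02	1.113935e-01	3.190159e-03	0.000000e+00
3.000000e-01	7.624056e-03	9.686041e-02	1.595079e-03	0.000000e+00
4.000000e-01	3.493656e-03	8.678369e-02	9.670169e-04	0.000000e+00
5.000000e-01	1.971595e-03	7.924389e-02	6.579703e-04	0.000000e+00
6.000000e-01	1.284022e-03	7.330564e-02	4.685546e-04	0.000000e+00
8.000000e-01	6.784973e-04	6.438898e-02	2.791389e-04	0.000000e+00
1.000000e+00	4.411794e-04	5.787996e-02	1.894157e-04	0.000000e+00
1.022000e+00	4.229952e-04	5.726493e-02	1.794464e-04	0.000000e+00
1.170000e+00	3.438121e-04	5.352325e-02	1.445541e-04	7.763736e-06
1.250000e+00	3.316950e-04	5.174456e-02	1.296002e-04	2.173846e-05
1.330000e+00	3.526735e-04	5.010726e-02	1.176371e-04	4.658242e-05
1.400000e+00	3.728715e-04	4.877636e-02	1.076679e-04	7.763736e-05
1.500000e+00	3.971586e-04	4.701922e-02	9.470784e-05	1.397473e-04
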