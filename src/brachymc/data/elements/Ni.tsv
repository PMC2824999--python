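# element Ni Z=28 A=58.693 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	2.300818e+02	1.840016e-01	4.260753e-01	0.000000e+00
1.500000e-02	7.672097e+01	1.806955e-01	2.333581e-01	0.000000e+00
2.000000e-02	3.432971e+01	1.775424e-01	1.573201e-01	0.000000e+00
3.000000e-02	1.073341e+01	1.716549e-01	8.914805e-02	0.000000e+00
4.000000e-02	4.624578e+00	1.662665e-01	5.768403e-02	0.000000e+00
5.000000e-02	2.388280e+00	1.613161e-01	4.195203e-02	0.000000e+00
6.000000e-02	1.387490e+00	1.567519e-01	3.146402e-02	0.000000e+00
8.000000e-02	5.866547e-01	1.486117e-01	1.966501e-02	0.000000e+00
1.000000e-01	3.002989e-01	1.415624e-01	1.376551e-02	0.000000e+00
1.500000e-01	8.953285e-02	1.274440e-01	6.948304e-03	0.000000e+00
2.000000e-01	3.856132e-02	1.167789e-01	4.195203e-03	0.000000e+00
3.000000e-01	1.222526e-02	1.015432e-01	2.097601e-03	0.000000e+00
4.000000e-01	5.602119e-03	9.097932e-02	1.271671e-03	0.000000e+00
5.000000e-01	3.161475e-03	8.307500e-02	8.652605e-04	0.000000e+00
6.000000e-01	2.058945e-03	7.684966e-02	6.161704e-04	0.000000e+00
8.000000e-01	1.087978e-03	6.750192e-02	3.670802e-04	0.000000e+00
1.000000e+00	7.074364e-04	6.067821e-02	2.490902e-04	0.000000e+00
1.022000e+00	6.782777e-04	6.003345e-02	2.359801e-04	0.000000e+00
1.170000e+00	5.513068e-04	5.611088e-02	1.900951e-04	9.115770e-06
1.250000e+00	5.318768e-04	5.424619e-02	1.704301e-04	2.552416e-05
1.330000e+00	5.655160e-04	5.252973e-02	1.546981e-04	5.469462e-05
1.400000e+00	5.979037e-04	5.113449e-02	1.415881e-04	9.115770e-05
1.500000e+00	6.368484e-04	4.929240e-02	1.245451e-04	1.640839e-04
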