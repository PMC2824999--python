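# element C Z=6 A=12.011 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	2.159840e+00	1.926735e-01	2.048675e-02	0.000000e+00
1.500000e-02	6.066680e-01	1.892115e-01	1.122044e-02	0.000000e+00
2.000000e-02	2.485258e-01	1.859098e-01	7.564339e-03	0.000000e+00
3.000000e-02	7.216867e-02	1.797449e-01	4.286459e-03	0.000000e+00
4.000000e-02	3.072386e-02	1.741026e-01	2.773591e-03	0.000000e+00
5.000000e-02	1.616399e-02	1.689189e-01	2.017157e-03	0.000000e+00
6.000000e-02	9.647623e-03	1.641395e-01	1.512868e-03	0.000000e+00
8.000000e-02	4.438826e-03	1.556156e-01	9.455424e-04	0.000000e+00
1.000000e-01	2.503963e-03	1.482342e-01	6.618797e-04	0.000000e+00
1.500000e-01	9.155121e-04	1.334504e-01	3.340917e-04	0.000000e+00
2.000000e-01	4.156439e-04	1.222826e-01	2.017157e-04	0.000000e+00
3.000000e-01	1.702665e-04	1.063289e-01	1.008579e-04	0.000000e+00
4.000000e-01	1.317345e-04	9.526712e-02	6.114508e-05	0.000000e+00
5.000000e-01	1.181236e-04	8.699027e-02	4.160387e-05	0.000000e+00
6.000000e-01	7.883246e-05	8.047154e-02	2.962700e-05	0.000000e+00
8.000000e-01	5.910816e-05	7.068324e-02	1.765012e-05	0.000000e+00
1.000000e+00	6.008611e-05	6.353794e-02	1.197687e-05	0.000000e+00
1.022000e+00	4.807838e-05	6.286279e-02	1.134651e-05	0.000000e+00
1.170000e+00	4.492185e-05	5.875535e-02	9.140243e-06	2.045441e-06
1.250000e+00	8.329246e-05	5.680279e-02	8.194701e-06	5.727234e-06
1.330000e+00	8.193839e-05	5.500543e-02	7.438267e-06	1.227265e-05
1.400000e+00	9.567107e-05	5.354443e-02	6.807905e-06	2.045441e-05
1.500000e+00	1.316722e-04	5.161552e-02	5.988435e-06	3.681794e-05
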