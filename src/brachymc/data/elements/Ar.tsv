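# element Ar Z=18 A=39.948 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.079107e+02	1.737910e-01	1.663110e-01	0.000000e+00
1.500000e-02	3.067292e+01	1.706684e-01	9.108726e-02	0.000000e+00
2.000000e-02	1.255000e+01	1.676902e-01	6.140714e-02	0.000000e+00
3.000000e-02	3.589389e+00	1.621294e-01	3.479738e-02	0.000000e+00
4.000000e-02	1.495169e+00	1.570401e-01	2.251595e-02	0.000000e+00
5.000000e-02	7.641882e-01	1.523644e-01	1.637524e-02	0.000000e+00
6.000000e-02	4.470458e-01	1.480534e-01	1.228143e-02	0.000000e+00
8.000000e-02	1.951546e-01	1.403649e-01	7.675893e-03	0.000000e+00
1.000000e-01	1.045198e-01	1.337069e-01	5.373125e-03	0.000000e+00
1.500000e-01	3.628781e-02	1.203719e-01	2.712149e-03	0.000000e+00
2.000000e-01	1.769999e-02	1.102986e-01	1.637524e-03	0.000000e+00
3.000000e-01	7.307442e-03	9.590839e-02	8.187619e-04	0.000000e+00
4.000000e-01	3.597521e-03	8.593071e-02	4.963744e-04	0.000000e+00
5.000000e-01	2.649537e-03	7.846502e-02	3.377393e-04	0.000000e+00
6.000000e-01	1.827921e-03	7.258514e-02	2.405113e-04	0.000000e+00
8.000000e-01	1.624210e-03	6.375611e-02	1.432833e-04	0.000000e+00
1.000000e+00	1.857981e-03	5.731107e-02	9.722798e-05	0.000000e+00
1.022000e+00	1.573100e-03	5.670209e-02	9.211071e-05	0.000000e+00
1.170000e+00	1.143222e-03	5.299718e-02	7.420030e-05	5.534948e-06
1.250000e+00	1.685128e-03	5.123598e-02	6.652440e-05	1.549786e-05
1.330000e+00	1.595654e-03	4.961476e-02	6.038369e-05	3.320969e-05
1.400000e+00	1.786070e-03	4.829695e-02	5.526643e-05	5.534948e-05
1.500000e+00	2.340867e-03	4.655708e-02	4.861399e-05	9.962907e-05
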