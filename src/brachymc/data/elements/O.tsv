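# element O Z=8 A=15.999 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	5.722681e+00	1.928622e-01	3.645656e-02	0.000000e+00
1.500000e-02	1.626636e+00	1.893968e-01	1.996698e-02	0.000000e+00
2.000000e-02	6.655472e-01	1.860919e-01	1.346088e-02	0.000000e+00
3.000000e-02	1.903513e-01	1.799209e-01	7.627833e-03	0.000000e+00
4.000000e-02	7.929130e-02	1.742730e-01	4.935657e-03	0.000000e+00
5.000000e-02	4.052617e-02	1.690843e-01	3.589569e-03	0.000000e+00
6.000000e-02	2.370758e-02	1.643002e-01	2.692177e-03	0.000000e+00
8.000000e-02	1.034938e-02	1.557680e-01	1.682610e-03	0.000000e+00
1.000000e-01	5.542861e-03	1.483793e-01	1.177827e-03	0.000000e+00
1.500000e-01	1.924403e-03	1.335811e-01	5.945223e-04	0.000000e+00
2.000000e-01	9.386601e-04	1.224024e-01	3.589569e-04	0.000000e+00
3.000000e-01	3.875258e-04	1.064330e-01	1.794784e-04	0.000000e+00
4.000000e-01	1.907825e-04	9.536041e-02	1.088088e-04	0.000000e+00
5.000000e-01	1.405094e-04	8.707546e-02	7.403485e-05	0.000000e+00
6.000000e-01	9.693769e-05	8.055034e-02	5.272179e-05	0.000000e+00
8.000000e-01	8.613456e-05	7.075246e-02	3.140873e-05	0.000000e+00
1.000000e+00	9.853180e-05	6.360016e-02	2.131306e-05	0.000000e+00
1.022000e+00	8.342412e-05	6.292435e-02	2.019132e-05	0.000000e+00
1.170000e+00	6.062697e-05	5.881288e-02	1.626523e-05	2.729925e-06
1.250000e+00	8.936511e-05	5.685841e-02	1.458262e-05	7.643790e-06
1.330000e+00	8.462017e-05	5.505929e-02	1.323653e-05	1.637955e-05
1.400000e+00	9.471827e-05	5.359686e-02	1.211479e-05	2.729925e-05
1.500000e+00	1.241401e-04	5.166606e-02	1.065653e-05	4.913865e-05
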