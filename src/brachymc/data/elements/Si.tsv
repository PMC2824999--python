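# element Si Z=14 A=28.085 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	4.652096e+01	1.922665e-01	1.113033e-01	0.000000e+00
1.500000e-02	1.322329e+01	1.888118e-01	6.095998e-02	0.000000e+00
2.000000e-02	5.410383e+00	1.855171e-01	4.109662e-02	0.000000e+00
3.000000e-02	1.547408e+00	1.793651e-01	2.328808e-02	0.000000e+00
4.000000e-02	6.445768e-01	1.737347e-01	1.506876e-02	0.000000e+00
5.000000e-02	3.294464e-01	1.685620e-01	1.095910e-02	0.000000e+00
6.000000e-02	1.927243e-01	1.637927e-01	8.219324e-03	0.000000e+00
8.000000e-02	8.413240e-02	1.552869e-01	5.137077e-03	0.000000e+00
1.000000e-01	4.505916e-02	1.479210e-01	3.595954e-03	0.000000e+00
1.500000e-01	1.564391e-02	1.331685e-01	1.815101e-03	0.000000e+00
2.000000e-01	7.630579e-03	1.220243e-01	1.095910e-03	0.000000e+00
3.000000e-01	3.150284e-03	1.061042e-01	5.479549e-04	0.000000e+00
4.000000e-01	1.550914e-03	9.506586e-02	3.321977e-04	0.000000e+00
5.000000e-01	1.142232e-03	8.680649e-02	2.260314e-04	0.000000e+00
6.000000e-01	7.880283e-04	8.030153e-02	1.609618e-04	0.000000e+00
8.000000e-01	7.002072e-04	7.053391e-02	9.589211e-05	0.000000e+00
1.000000e+00	8.009871e-04	6.340370e-02	6.506965e-05	0.000000e+00
1.022000e+00	6.781734e-04	6.272999e-02	6.164493e-05	0.000000e+00
1.170000e+00	4.928503e-04	5.863122e-02	4.965841e-05	4.762612e-06
1.250000e+00	7.264691e-04	5.668278e-02	4.452134e-05	1.333531e-05
1.330000e+00	6.878964e-04	5.488922e-02	4.041168e-05	2.857567e-05
1.400000e+00	7.699861e-04	5.343131e-02	3.698696e-05	4.762612e-05
1.500000e+00	1.009162e-03	5.150648e-02	3.253482e-05	8.572702e-05
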