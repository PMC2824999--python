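# element S Z=16 A=32.06 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	7.684602e+01	1.924892e-01	1.455442e-01	0.000000e+00
1.500000e-02	2.184300e+01	1.890306e-01	7.971345e-02	0.000000e+00
2.000000e-02	8.937184e+00	1.857320e-01	5.373940e-02	0.000000e+00
3.000000e-02	2.556099e+00	1.795729e-01	3.045233e-02	0.000000e+00
4.000000e-02	1.064749e+00	1.739360e-01	1.970445e-02	0.000000e+00
5.000000e-02	5.441985e-01	1.687573e-01	1.433051e-02	0.000000e+00
6.000000e-02	3.183531e-01	1.639825e-01	1.074788e-02	0.000000e+00
8.000000e-02	1.389748e-01	1.554668e-01	6.717425e-03	0.000000e+00
1.000000e-01	7.443133e-02	1.480924e-01	4.702198e-03	0.000000e+00
1.500000e-01	2.584151e-02	1.333227e-01	2.373490e-03	0.000000e+00
2.000000e-01	1.260463e-02	1.221657e-01	1.433051e-03	0.000000e+00
3.000000e-01	5.203821e-03	1.062272e-01	7.165254e-04	0.000000e+00
4.000000e-01	2.561890e-03	9.517599e-02	4.343935e-04	0.000000e+00
5.000000e-01	1.886805e-03	8.690706e-02	2.955667e-04	0.000000e+00
6.000000e-01	1.301711e-03	8.039457e-02	2.104793e-04	0.000000e+00
8.000000e-01	1.156643e-03	7.061563e-02	1.253919e-04	0.000000e+00
1.000000e+00	1.323117e-03	6.347716e-02	8.508739e-05	0.000000e+00
1.022000e+00	1.120246e-03	6.280266e-02	8.060911e-05	0.000000e+00
1.170000e+00	8.141186e-04	5.869915e-02	6.493511e-05	5.449292e-06
1.250000e+00	1.200024e-03	5.674845e-02	5.821769e-05	1.525802e-05
1.330000e+00	1.136307e-03	5.495281e-02	5.284375e-05	3.269575e-05
1.400000e+00	1.271908e-03	5.349321e-02	4.836546e-05	5.449292e-05
1.500000e+00	1.666993e-03	5.156615e-02	4.254369e-05	9.808725e-05
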