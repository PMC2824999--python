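# element Mg Z=12 A=24.305 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	2.584820e+01	1.904301e-01	8.099284e-02	0.000000e+00
1.500000e-02	7.347188e+00	1.870084e-01	4.435916e-02	0.000000e+00
2.000000e-02	3.006143e+00	1.837452e-01	2.990505e-02	0.000000e+00
3.000000e-02	8.597784e-01	1.776520e-01	1.694619e-02	0.000000e+00
4.000000e-02	3.581428e-01	1.720754e-01	1.096518e-02	0.000000e+00
5.000000e-02	1.830485e-01	1.669520e-01	7.974680e-03	0.000000e+00
6.000000e-02	1.070824e-01	1.622283e-01	5.981010e-03	0.000000e+00
8.000000e-02	4.674604e-02	1.538037e-01	3.738131e-03	0.000000e+00
1.000000e-01	2.503598e-02	1.465082e-01	2.616692e-03	0.000000e+00
1.500000e-01	8.692140e-03	1.318965e-01	1.320806e-03	0.000000e+00
2.000000e-01	4.239739e-03	1.208588e-01	7.974680e-04	0.000000e+00
3.000000e-01	1.750376e-03	1.050908e-01	3.987340e-04	0.000000e+00
4.000000e-01	8.617262e-04	9.415786e-02	2.417325e-04	0.000000e+00
5.000000e-01	6.346524e-04	8.597738e-02	1.644778e-04	0.000000e+00
6.000000e-01	4.378480e-04	7.953455e-02	1.171281e-04	0.000000e+00
8.000000e-01	3.890524e-04	6.986023e-02	6.977845e-05	0.000000e+00
1.000000e+00	4.450482e-04	6.279812e-02	4.734966e-05	0.000000e+00
1.022000e+00	3.768099e-04	6.213084e-02	4.485757e-05	0.000000e+00
1.170000e+00	2.738398e-04	5.807122e-02	3.613527e-05	4.043249e-06
1.250000e+00	4.036442e-04	5.614139e-02	3.239714e-05	1.132110e-05
1.330000e+00	3.822122e-04	5.436496e-02	2.940663e-05	2.425949e-05
1.400000e+00	4.278233e-04	5.292098e-02	2.691454e-05	4.043249e-05
1.500000e+00	5.607156e-04	5.101453e-02	2.367483e-05	7.277848e-05
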