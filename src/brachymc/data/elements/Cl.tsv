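# element Cl Z=17 A=35.45 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	9.268962e+01	1.849620e-01	1.578807e-01	0.000000e+00
1.500000e-02	2.634644e+01	1.816386e-01	8.647005e-02	0.000000e+00
2.000000e-02	1.077979e+01	1.784691e-01	5.829441e-02	0.000000e+00
3.000000e-02	3.083098e+00	1.725508e-01	3.303350e-02	0.000000e+00
4.000000e-02	1.284272e+00	1.671344e-01	2.137462e-02	0.000000e+00
5.000000e-02	6.563978e-01	1.621581e-01	1.554518e-02	0.000000e+00
6.000000e-02	3.839890e-01	1.575701e-01	1.165888e-02	0.000000e+00
8.000000e-02	1.676277e-01	1.493873e-01	7.286802e-03	0.000000e+00
1.000000e-01	8.977709e-02	1.423013e-01	5.100761e-03	0.000000e+00
1.500000e-01	3.116934e-02	1.281092e-01	2.574670e-03	0.000000e+00
2.000000e-01	1.520337e-02	1.173885e-01	1.554518e-03	0.000000e+00
3.000000e-01	6.276711e-03	1.020732e-01	7.772588e-04	0.000000e+00
4.000000e-01	3.090083e-03	9.145420e-02	4.712132e-04	0.000000e+00
5.000000e-01	2.275814e-03	8.350862e-02	3.206193e-04	0.000000e+00
6.000000e-01	1.570089e-03	7.725079e-02	2.283198e-04	0.000000e+00
8.000000e-01	1.395112e-03	6.785425e-02	1.360203e-04	0.000000e+00
1.000000e+00	1.595908e-03	6.099493e-02	9.229949e-05	0.000000e+00
1.022000e+00	1.351211e-03	6.034680e-02	8.744162e-05	0.000000e+00
1.170000e+00	9.819682e-04	5.640375e-02	7.043908e-05	5.563463e-06
1.250000e+00	1.447437e-03	5.452934e-02	6.315228e-05	1.557770e-05
1.330000e+00	1.370583e-03	5.280392e-02	5.732284e-05	3.338078e-05
1.400000e+00	1.534141e-03	5.140140e-02	5.246497e-05	5.563463e-05
1.500000e+00	2.010682e-03	4.954969e-02	4.614974e-05	1.001423e-04
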