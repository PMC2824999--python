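# element Co Z=27 A=58.933 g/mol
# mass attenuation coefficients (cm^2/g); constructed by
# tools/build_xs_tables.py: Klein-Nishina incoherent,
# totals anchored to standard NIST compilations,
# photoelectric by remainder / Z^4.75 scaling.
# energy_MeV	photoelectric	incoherent	coherent	pair
1.000000e-02	1.927912e+02	1.767076e-01	3.804795e-01	0.000000e+00
1.500000e-02	6.428640e+01	1.735325e-01	2.083857e-01	0.000000e+00
2.000000e-02	2.876571e+01	1.705044e-01	1.404847e-01	0.000000e+00
3.000000e-02	8.993793e+00	1.648503e-01	7.960802e-02	0.000000e+00
4.000000e-02	3.875048e+00	1.596755e-01	5.151107e-02	0.000000e+00
5.000000e-02	2.001198e+00	1.549213e-01	3.746260e-02	0.000000e+00
6.000000e-02	1.162612e+00	1.505380e-01	2.809695e-02	0.000000e+00
8.000000e-02	4.915724e-01	1.427205e-01	1.756059e-02	0.000000e+00
1.000000e-01	2.516278e-01	1.359507e-01	1.229241e-02	0.000000e+00
1.500000e-01	7.502178e-02	1.223920e-01	6.204743e-03	0.000000e+00
2.000000e-01	3.231148e-02	1.121497e-01	3.746260e-03	0.000000e+00
3.000000e-01	1.024385e-02	9.751790e-02	1.873130e-03	0.000000e+00
4.000000e-01	4.694154e-03	8.737278e-02	1.135585e-03	0.000000e+00
5.000000e-01	2.649078e-03	7.978180e-02	7.726661e-04	0.000000e+00
6.000000e-01	1.725241e-03	7.380324e-02	5.502319e-04	0.000000e+00
8.000000e-01	9.116440e-04	6.482605e-02	3.277977e-04	0.000000e+00
1.000000e+00	5.927784e-04	5.827285e-02	2.224342e-04	0.000000e+00
1.022000e+00	5.683456e-04	5.765365e-02	2.107271e-04	0.000000e+00
1.170000e+00	4.619535e-04	5.388657e-02	1.697524e-04	8.441752e-06
1.250000e+00	4.456727e-04	5.209581e-02	1.521918e-04	2.363690e-05
1.330000e+00	4.738599e-04	5.044739e-02	1.381433e-04	5.065051e-05
1.400000e+00	5.009983e-04	4.910746e-02	1.264363e-04	8.441752e-05
1.500000e+00	5.336310e-04	4.733839e-02	1.112171e-04	1.519515e-04
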