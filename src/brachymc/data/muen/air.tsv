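# medium air: mass energy-absorption coefficient
# (cm^2/g), Hubbell & Seltzer compilation grid.
# energy_MeV	muen_over_rho
0.010	4.74200e+00
0.015	1.33400e+00
0.020	5.38900e-01
0.030	1.53700e-01
0.040	6.83300e-02
0.050	4.09800e-02
0.060	3.04100e-02
0.080	2.40700e-02
0.100	2.32500e-02
0.150	2.49600e-02
0.200	2.67200e-02
0.300	2.87200e-02
0.400	2.94900e-02
0.500	2.96600e-02
0.600	2.95300e-02
0.800	2.88200e-02
1.000	2.78900e-02
1.250	2.66600e-02
1.500	2.54700e-02
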