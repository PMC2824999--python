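# medium water: mass energy-absorption coefficient
# (cm^2/g), Hubbell & Seltzer compilation grid.
# energy_MeV	muen_over_rho
0.010	4.94400e+00
0.015	1.37400e+00
0.020	5.50300e-01
0.030	1.55700e-01
0.040	6.94700e-02
0.050	4.22300e-02
0.060	3.19000e-02
0.080	2.59700e-02
0.100	2.54600e-02
0.150	2.76400e-02
0.200	2.96700e-02
0.300	3.19200e-02
0.400	3.27900e-02
0.500	3.29900e-02
0.600	3.28400e-02
0.800	3.20600e-02
1.000	3.10300e-02
1.250	2.96500e-02
1.500	2.83300e-02
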