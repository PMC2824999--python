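"""Physical constants and unit conversions used throughout the package."""

#: classical electron radius, cm
R_E = 2.8179403262e-13

#: electron rest energy, MeV
MEC2 = 0.51099895

#: Avogadro constant, 1/mol
N_A = 6.02214076e23

#: MeV -> J
MEV_TO_J = 1.602176634e-13

#: converts a specific energy in MeV/g to Gy (J/kg)
MEV_PER_G_TO_GY = MEV_TO_J * 1e3

#: Co-60 gamma lines used in all simulations (MeV) and photon yield per decay
CO60_LINES = (1.17, 1.33)
CO60_YIELD = 2.0

#: mean Co-60 gamma energy (MeV)
CO60_MEAN_ENERGY = 1.25

#: photon transport cutoff energy (MeV)
CUTOFF_ENERGY = 0.010

#: upper end of the tabulated coefficient range (MeV)
MAX_TABLE_ENERGY = 1.50

#: Gy per photon-history -> cGy/h per Bq, once the per-decay yield is applied
GY_PER_DECAY_TO_CGY_PER_H_PER_BQ = 3600.0 * 100.0
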