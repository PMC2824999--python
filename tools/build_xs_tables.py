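"""Build the per-element photon interaction coefficient tables shipped as package data.

Run from the repository root:

    python tools/build_xs_tables.py

Writes delimited text files under ``src/brachymc/data/elements`` (one per
element) and ``src/brachymc/data/muen`` (mass energy-absorption coefficients
for air and water).  The files are versioned package data; this script exists
so the provenance of every number is explicit and regenerable.

Construction
------------
* Incoherent (Compton): Klein-Nishina total cross section on Z free
  electrons per atom.  No incoherent-scattering-function correction; below
  ~100 keV this overestimates scattering for low-Z media by a few percent,
  and the remainder bookkeeping below folds that excess into the
  photoelectric column so that the *total* attenuation coefficient stays
  anchored to the standard compilations.
* Totals for the anchor elements H, C, N, O and Fe are transcribed from the
  standard NIST photon attenuation compilations (Hubbell & Seltzer grid,
  10 keV - 1.5 MeV).
* Coherent (Rayleigh): smooth Z^3-scaled parametrization anchored to a
  water-shaped energy curve.  The transport engine excludes coherent
  scattering by default, so this column only affects the reported total.
* Photoelectric for anchor elements: total - incoherent - coherent
  (floored at zero).  For non-anchor elements: per-atom Z^4.75 power-law
  scaling from the nearest anchor (O for Z <= 20, Fe for Z >= 24).
* Pair production: zero below the 1.022 MeV threshold; above it a Z^2/A
  scaling of a small water-anchored curve (negligible at Co-60 energies).

Mo has a K edge at 20.0 keV inside the tabulated range; the smooth power-law
scaling ignores it (Mo is 2.1% of the capsule steel and 20 keV photons do not
survive the capsule, so the effect is far below the package's tolerances).
"""

from __future__ import annotations

import math
import pathlib

import numpy as np

HERE = pathlib.Path(__file__).resolve().parent
DATA = HERE.parent / "src" / "brachymc" / "data"

R_E = 2.8179403262e-13  # classical electron radius, cm
MEC2 = 0.51099895  # electron rest energy, MeV
N_A = 6.02214076e23

# Common energy grid (MeV).  Spans the 10 keV transport cutoff to above the
# 1.33 MeV source line.
GRID = np.array(
    [0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100,
     0.150, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.022,
     1.170, 1.250, 1.330, 1.400, 1.500]
)

# Elements needed for the source capsule, phantoms and air.
ELEMENTS = {
    # symbol: (Z, A g/mol)
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Mg": (12, 24.305),
    "Si": (14, 28.085),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "Ca": (20, 40.078),
    "Cr": (24, 51.996),
    "Mn": (25, 54.938),
    "Fe": (26, 55.845),
    "Co": (27, 58.933),
    "Ni": (28, 58.693),
    "Mo": (42, 95.95),
}

# Total mass attenuation coefficients (cm^2/g, coherent included) for the
# anchor elements, transcribed from the standard NIST compilation on the
# grid 10 keV ... 1.5 MeV (values at 1.022/1.17/1.25/1.33/1.4 are log-log
# interpolations of the published decade grid).
ANCHOR_TOTALS = {
    "H": [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091,
          0.2944, 0.2651, 0.2429, 0.2112, 0.1893, 0.1729, 0.1599, 0.1405,
          0.1263, None, None, 0.1129, None, None, 0.1027],
    "C": [2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610,
          0.1514, 0.1347, 0.1229, 0.1066, 0.09546, 0.08715, 0.08058,
          0.07076, 0.06361, None, None, 0.05690, None, None, 0.05179],
    "N": [3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639,
          0.1529, 0.1353, 0.1233, 0.1068, 0.09557, 0.08719, 0.08063,
          0.07081, 0.06364, None, None, 0.05690, None, None, 0.05180],
    "O": [5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678,
          0.1551, 0.1361, 0.1237, 0.1070, 0.09566, 0.08729, 0.08070,
          0.07087, 0.06372, None, None, 0.05697, None, None, 0.05185],
    "Fe": [170.6, 57.08, 25.68, 8.176, 3.629, 1.958, 1.205, 0.5952,
           0.3717, 0.1964, 0.1460, 0.1099, 0.09400, 0.08414, 0.07704,
           0.06699, 0.05995, None, None, 0.05350, None, None, 0.04883],
}

# Water coherent-scattering mass coefficient anchor curve (cm^2/g); a smooth
# water-shaped decline used only to apportion the coherent column.
COH_WATER = np.array(
    [0.0325, 0.0178, 0.0120, 0.0068, 0.0044, 0.0032, 0.0024, 0.0015,
     0.00105, 5.3e-4, 3.2e-4, 1.6e-4, 9.7e-5, 6.6e-5, 4.7e-5, 2.8e-5,
     1.9e-5, 1.8e-5, 1.45e-5, 1.3e-5, 1.18e-5, 1.08e-5, 9.5e-6]
)
# Sum_i w_i Z_i^3 / A_i for water, the scaling denominator of COH_WATER.
COH_WATER_FACTOR = 0.112 * 1 / 1.008 + 0.888 * 512 / 15.999

# Water pair-production mass coefficient above threshold (cm^2/g).
PAIR_WATER = {1.022: 0.0, 1.170: 2.5e-6, 1.250: 7.0e-6, 1.330: 1.5e-5,
              1.400: 2.5e-5, 1.500: 4.5e-5}
# Sum_i w_i Z_i^2 / A_i for water.
PAIR_WATER_FACTOR = 0.112 * 1 / 1.008 + 0.888 * 64 / 15.999

PE_EXPONENT = 4.75  # per-atom photoelectric Z-scaling exponent

# Hubbell & Seltzer mass energy-absorption coefficients (cm^2/g).
MUEN = {
    "water": [
        (0.010, 4.944), (0.015, 1.374), (0.020, 0.5503), (0.030, 0.1557),
        (0.040, 0.06947), (0.050, 0.04223), (0.060, 0.03190),
        (0.080, 0.02597), (0.100, 0.02546), (0.150, 0.02764),
        (0.200, 0.02967), (0.300, 0.03192), (0.400, 0.03279),
        (0.500, 0.03299), (0.600, 0.03284), (0.800, 0.03206),
        (1.000, 0.03103), (1.250, 0.02965), (1.500, 0.02833),
    ],
    "air": [
        (0.010, 4.742), (0.015, 1.334), (0.020, 0.5389), (0.030, 0.1537),
        (0.040, 0.06833), (0.050, 0.04098), (0.060, 0.03041),
        (0.080, 0.02407), (0.100, 0.02325), (0.150, 0.02496),
        (0.200, 0.02672), (0.300, 0.02872), (0.400, 0.02949),
        (0.500, 0.02966), (0.600, 0.02953), (0.800, 0.02882),
        (1.000, 0.02789), (1.250, 0.02666), (1.500, 0.02547),
    ],
}


def sigma_kn(E: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron (cm^2)."""
    a = np.asarray(E, dtype=float) / MEC2
    term = ((1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
            + np.log(1 + 2 * a) / (2 * a) - (1 + 3 * a) / (1 + 2 * a) ** 2)
    return 2 * math.pi * R_E**2 * term


def loglog_fill(energies: np.ndarray, values: list) -> np.ndarray:
    """Fill None entries by log-log interpolation of the given anchors."""
    known = [(e, v) for e, v in zip(energies, values) if v is not None]
    ke = np.log([e for e, _ in known])
    kv = np.log([v for _, v in known])
    return np.exp(np.interp(np.log(energies), ke, kv))


def coherent(Z: int, A: float) -> np.ndarray:
    return COH_WATER * (Z**3 / A) / COH_WATER_FACTOR


def pair(Z: int, A: float) -> np.ndarray:
    ref_e = np.array(sorted(PAIR_WATER))
    ref_v = np.array([PAIR_WATER[e] for e in sorted(PAIR_WATER)])
    out = np.interp(GRID, ref_e, ref_v, left=0.0)
    out[GRID <= 1.022] = 0.0
    return out * (Z**2 / A) / PAIR_WATER_FACTOR


def incoherent(Z: int, A: float) -> np.ndarray:
    return sigma_kn(GRID) * N_A * Z / A


def build_element(sym: str) -> np.ndarray:
    Z, A = ELEMENTS[sym]
    inc = incoherent(Z, A)
    coh = coherent(Z, A)
    pp = pair(Z, A)
    if sym in ANCHOR_TOTALS:
        total = loglog_fill(GRID, ANCHOR_TOTALS[sym])
        pe = np.maximum(total - inc - coh - pp, 1e-9)
    else:
        anchor = "O" if Z <= 20 else "Fe"
        Za, Aa = ELEMENTS[anchor]
        tot_a = loglog_fill(GRID, ANCHOR_TOTALS[anchor])
        pe_a = np.maximum(tot_a - incoherent(Za, Aa) - coherent(Za, Aa)
                          - pair(Za, Aa), 1e-9)
        pe = pe_a * (Z / Za) ** PE_EXPONENT * (Aa / A)
    return np.column_stack([GRID, pe, inc, coh, pp])


def main() -> None:
    el_dir = DATA / "elements"
    el_dir.mkdir(parents=True, exist_ok=True)
    for sym, (Z, A) in ELEMENTS.items():
        table = build_element(sym)
        path = el_dir / f"{sym}.tsv"
        with open(path, "w") as fh:
            fh.write(
                f"# element {sym} Z={Z} A={A} g/mol\n"
                "# mass attenuation coefficients (cm^2/g); constructed by\n"
                "# tools/build_xs_tables.py: Klein-Nishina incoherent,\n"
                "# totals anchored to standard NIST compilations,\n"
                "# photoelectric by remainder / Z^4.75 scaling.\n"
                "# energy_MeV\tphotoelectric\tincoherent\tcoherent\tpair\n"
            )
            for row in table:
                fh.write("\t".join(f"{v:.6e}" for v in row) + "\n")
    mu_dir = DATA / "muen"
    mu_dir.mkdir(parents=True, exist_ok=True)
    for medium, rows in MUEN.items():
        with open(mu_dir / f"{medium}.tsv", "w") as fh:
            fh.write(
                f"# medium {medium}: mass energy-absorption coefficient\n"
                "# (cm^2/g), Hubbell & Seltzer compilation grid.\n"
                "# energy_MeV\tmuen_over_rho\n"
            )
            for e, v in rows:
                fh.write(f"{e:.3f}\t{v:.5e}\n")
    print(f"wrote {len(ELEMENTS)} element tables and {len(MUEN)} mu_en tables")


if __name__ == "__main__":
    main()
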