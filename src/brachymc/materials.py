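"""Materials and photon interaction coefficients.

Elements are backed by per-process mass attenuation coefficient tables
(photoelectric, incoherent, coherent, pair production) shipped as package
data on a common 10 keV - 1.5 MeV grid.  Materials are mixtures defined by
elemental mass fractions and a density; mixture coefficients follow Bragg
additivity, and evaluation at arbitrary energy uses log-log interpolation,
which is the standard choice for smooth photon cross sections away from
absorption edges (all K edges of the constituent elements except Mo lie
below the 10 keV transport cutoff).

Mass energy-absorption coefficients mu_en/rho for air and water (used to
convert fluence to collision kerma) come from the Hubbell & Seltzer
compilation, also shipped as package data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import N_A

PROCESSES = ("photoelectric", "incoherent", "coherent", "pair")

#: pair production is kinematically forbidden below 2 m_e c^2
PAIR_THRESHOLD = 1.022

_LOG_FLOOR = 1e-30


def _loglog_interp(E, grid, values):
    """Log-log interpolation of tabulated coefficients; zeros are preserved."""
    logv = np.log(np.maximum(values, _LOG_FLOOR))
    out = np.exp(np.interp(np.log(E), np.log(grid), logv))
    return np.where(out <= 10 * _LOG_FLOOR, 0.0, out)


@dataclass(frozen=True)
class ElementRecord:
    """Per-element photon interaction data.

    Coefficients are mass attenuation coefficients in cm^2/g on an
    ascending energy grid in MeV, one column per interaction process.
    """

    symbol: str
    Z: int
    A: float
    energy: np.ndarray
    coefficients: dict[str, np.ndarray]  # process -> cm^2/g

    def __post_init__(self):
        if not np.all(np.diff(self.energy) > 0):
            raise ValueError(f"{self.symbol}: energy grid not ascending")
        for name, col in self.coefficients.items():
            if np.any(col < 0):
                raise ValueError(f"{self.symbol}: negative {name} coefficient")
        below = self.energy < PAIR_THRESHOLD
        if np.any(self.coefficients["pair"][below] != 0):
            raise ValueError(f"{self.symbol}: pair production below threshold")

    def mu_over_rho(self, E, process=None):
        """Mass attenuation coefficient (cm^2/g) at energy E (MeV)."""
        E = np.asarray(E, dtype=float)
        _check_range(E, self.energy)
        if process is None:
            total = sum(self.coefficients[p] for p in PROCESSES)
            return _loglog_interp(E, self.energy, total)
        return _loglog_interp(E, self.energy, self.coefficients[process])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(f"# element {self.symbol} Z={self.Z} A={self.A} g/mol\n")
            fh.write("# energy_MeV\t" + "\t".join(PROCESSES) + "\n")
            for i, e in enumerate(self.energy):
                row = [e] + [self.coefficients[p][i] for p in PROCESSES]
                fh.write("\t".join(f"{v:.6e}" for v in row) + "\n")

    @classmethod
    def load(cls, path, symbol, Z, A):
        data = np.loadtxt(path)
        coeffs = {p: np.ascontiguousarray(data[:, i + 1])
                  for i, p in enumerate(PROCESSES)}
        return cls(symbol, Z, A, np.ascontiguousarray(data[:, 0]), coeffs)


def _check_range(E, grid):
    if np.any(E < grid[0] - 1e-12) or np.any(E > grid[-1] + 1e-12):
        raise ValueError(
            f"energy {E} outside tabulated range [{grid[0]}, {grid[-1]}] MeV")


_ELEMENT_INFO = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Mg": (12, 24.305), "Si": (14, 28.085), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "Ar": (18, 39.948),
    "Ca": (20, 40.078), "Cr": (24, 51.996), "Mn": (25, 54.938),
    "Fe": (26, 55.845), "Co": (27, 58.933), "Ni": (28, 58.693),
    "Mo": (42, 95.95),
}

_element_cache: dict[str, ElementRecord] = {}


def get_element(symbol: str) -> ElementRecord:
    if symbol not in _ELEMENT_INFO:
        raise KeyError(f"unknown element {symbol!r}")
    if symbol not in _element_cache:
        Z, A = _ELEMENT_INFO[symbol]
        ref = resources.files("brachymc.data.elements") / f"{symbol}.tsv"
        with resources.as_file(ref) as path:
            _element_cache[symbol] = ElementRecord.load(path, symbol, Z, A)
    return _element_cache[symbol]


@dataclass(frozen=True)
class Material:
    """A mixture of elements with a mass density.

    ``mass_fractions`` are normalized to sum to one.  Linear attenuation
    coefficients are the density times the Bragg-additive mass coefficient.
    """

    name: str
    mass_fractions: dict[str, float]
    density: float  # g/cm^3
    elements: dict[str, ElementRecord] = field(repr=False, default=None)

    @property
    def energy_grid(self) -> np.ndarray:
        return next(iter(self.elements.values())).energy

    def mu_over_rho(self, E, process=None):
        """Mixture mass attenuation coefficient (cm^2/g)."""
        E = np.asarray(E, dtype=float)
        out = np.zeros_like(E, dtype=float)
        for sym, w in self.mass_fractions.items():
            out = out + w * self.elements[sym].mu_over_rho(E, process)
        return out

    def mu_total(self, E):
        """Total linear attenuation coefficient (1/cm)."""
        return self.density * self.mu_over_rho(E)

    def mu_process(self, E, process):
        """Per-process linear attenuation coefficient (1/cm)."""
        return self.density * self.mu_over_rho(E, process)

    def process_probabilities(self, E):
        """Probability of each interaction process at energy E.

        Returns an array over (photoelectric, incoherent, coherent, pair)
        proportional to the per-process attenuation coefficients.
        """
        mus = np.array([self.mu_over_rho(E, p) for p in PROCESSES])
        total = mus.sum(axis=0)
        return mus / total

    def electron_fractions(self) -> dict[str, float]:
        raw = {s: w * self.elements[s].Z / self.elements[s].A
               for s, w in self.mass_fractions.items()}
        norm = sum(raw.values())
        return {s: v / norm for s, v in raw.items()}

    def electrons_per_gram(self) -> float:
        return N_A * sum(w * self.elements[s].Z / self.elements[s].A
                         for s, w in self.mass_fractions.items())


def build_material(composition: dict[str, float], density: float,
                   name: str = "custom") -> Material:
    """Create a :class:`Material` from elemental mass fractions.

    Fractions must lie in [0, 1] and sum to 1 within 1e-3 (they are then
    renormalized exactly).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if not composition:
        raise ValueError("empty composition")
    for sym, w in composition.items():
        if not 0 <= w <= 1:
            raise ValueError(f"mass fraction for {sym} outside [0, 1]: {w}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-3:
        raise ValueError(f"mass fractions sum to {total}, not 1")
    elements = {sym: get_element(sym) for sym in composition}
    fractions = {sym: w / total for sym, w in composition.items()}
    return Material(name, fractions, density, elements)


def mu_total(material: Material, E):
    """Total linear attenuation coefficient (1/cm) of a material at E (MeV)."""
    return material.mu_total(E)


def process_probabilities(material: Material, E):
    return material.process_probabilities(E)


def effective_atomic_number(material: Material, exponent: float = 2.94):
    """Power-law effective atomic number (sum_i f_i Z_i^p)^(1/p).

    ``f_i`` are electron fractions.  The default exponent 2.94 is the
    classic Mayneord choice for photoelectric-dominated response; other
    conventions in the literature differ, so the exponent is configurable.
    """
    fractions = material.electron_fractions()
    acc = sum(f * material.elements[s].Z ** exponent
              for s, f in fractions.items())
    return acc ** (1.0 / exponent)


_muen_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _muen_table(medium: str):
    if medium not in ("air", "water"):
        raise KeyError(f"no mu_en/rho table for medium {medium!r}")
    if medium not in _muen_cache:
        ref = resources.files("brachymc.data.muen") / f"{medium}.tsv"
        with resources.as_file(ref) as path:
            data = np.loadtxt(path)
        _muen_cache[medium] = (np.ascontiguousarray(data[:, 0]),
                               np.ascontiguousarray(data[:, 1]))
    return _muen_cache[medium]


def mu_en_over_rho(medium: str, E):
    """Mass energy-absorption coefficient (cm^2/g) for air or water."""
    grid, values = _muen_table(medium)
    E = np.asarray(E, dtype=float)
    _check_range(E, grid)
    return _loglog_interp(E, grid, values)


# --- standard material definitions ---------------------------------------
# Source components: metallic cobalt core and AISI 316L stainless steel
# capsule/cable.  Phantoms: liquid water and four machinable solids.  Air is
# standard dry air at the density used for the air-kerma phantom (the
# humidity correction to the elemental composition is negligible at Co-60
# energies).

_STANDARD = {
    "cobalt": ({"Co": 1.0}, 8.9),
    "steel316l": ({"C": 0.00026, "Mn": 0.014, "Si": 0.0042, "P": 0.00019,
                   "S": 0.00003, "Cr": 0.168, "Mo": 0.0211, "Ni": 0.1101,
                   "Fe": 0.6821}, 7.8),
    "water": ({"H": 0.112, "O": 0.888}, 0.998),
    "solid_water": ({"H": 0.081, "C": 0.672, "N": 0.024, "O": 0.199,
                     "Cl": 0.001, "Ca": 0.023}, 1.015),
    "rw1": ({"H": 0.132, "C": 0.794, "Mg": 0.009, "O": 0.038,
             "Cl": 0.027}, 0.970),
    "pmma": ({"H": 0.081, "C": 0.600, "O": 0.320}, 1.190),
    "polystyrene": ({"H": 0.077, "C": 0.923}, 1.060),
    "air": ({"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827},
            1.2e-3),
}

_standard_cache: dict[str, Material] = {}

PHANTOM_MEDIA = ("water", "solid_water", "rw1", "pmma", "polystyrene")


def standard_material(name: str) -> Material:
    """Return one of the built-in materials by name."""
    if name not in _STANDARD:
        raise KeyError(f"unknown material {name!r}; "
                       f"choose from {sorted(_STANDARD)}")
    if name not in _standard_cache:
        comp, rho = _STANDARD[name]
        _standard_cache[name] = build_material(comp, rho, name=name)
    return _standard_cache[name]
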