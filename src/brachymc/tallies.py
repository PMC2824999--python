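"""Track-length and point-detector tallies.

Dose scoring uses ring cells: each cell is the solid of revolution about the
z axis of a 0.05 cm x 0.05 cm rectangle centered at (y_i, z_j) in the y-z
half-plane, so its volume is 2*pi*y_i*dy*dz.  On-axis cells (y = 0) are
small disks of radius 0.05 cm instead, since a ring volume vanishes on the
axis.  Fluence is estimated by track length per volume; collision kerma (to
water) is scored continuously in energy as fluence * E * (mu_en/rho)_water
evaluated at the exact photon energy, so the spectrum bin width introduces
no bias in kerma.

Statistical uncertainties are history-by-history: per-cell sums and sums of
squares of the per-history scores.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import materials
from .constants import CO60_YIELD, MEV_PER_G_TO_GY

#: tally cell cross-section half-width (cm): delta_y = delta_z = 0.05 cm
CELL_HALF = 0.025

#: on-axis disk cell radius (cm)
DISK_RADIUS = 0.05

#: radii of the transverse-axis radial dose function profile (cm)
GL_RADII = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.2, 1.4, 1.5,
            1.8, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0, 9.0,
            10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 18.0, 20.0)

#: away (y) and along (z) coordinates of the Cartesian dose-rate lattice (cm)
AWAY_Y = (0.0, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0,
          10.0, 15.0)
ALONG_Z = (-15.0, -10.0, -8.0, -6.0, -5.0, -4.0, -3.0, -2.5, -2.0, -1.5,
           -1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0,
           2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0)

#: on-axis lattice points without a tally cell (inside / too close to the
#: source-cable assembly)
ON_AXIS_EXCLUDED = (-0.25, 0.0, 0.25)

#: point-detector transverse distances for air-kerma scoring (cm)
DETECTOR_DISTANCES = (25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class CellSpec:
    """One ring (or on-axis disk) tally cell."""

    y: float  # ring center radius; 0 for a disk cell
    z: float
    is_disk: bool

    @property
    def r_lo(self) -> float:
        return 0.0 if self.is_disk else self.y - CELL_HALF

    @property
    def r_hi(self) -> float:
        return DISK_RADIUS if self.is_disk else self.y + CELL_HALF

    @property
    def z_lo(self) -> float:
        return self.z - CELL_HALF

    @property
    def z_hi(self) -> float:
        return self.z + CELL_HALF

    @property
    def volume(self) -> float:
        return math.pi * (self.r_hi**2 - self.r_lo**2) * 2 * CELL_HALF


def standard_cell_lattice() -> list[CellSpec]:
    """Cells covering the radial profile and the Cartesian dose lattice.

    The z = 0 row carries every radial-profile radius plus the away-axis
    coordinates; other rows carry the away-axis coordinates, with on-axis
    disk cells only where the lattice defines them.
    """
    cells: dict[tuple, CellSpec] = {}
    z0_radii = sorted(set(GL_RADII) | {y for y in AWAY_Y if y > 0})
    for r in z0_radii:
        cells[(r, 0.0)] = CellSpec(r, 0.0, False)
    for z in ALONG_Z:
        for y in AWAY_Y:
            if y == 0.0:
                if z in ON_AXIS_EXCLUDED:
                    continue
                cells.setdefault((y, z), CellSpec(0.0, z, True))
            else:
                cells.setdefault((y, z), CellSpec(y, z, False))
    return sorted(cells.values(), key=lambda c: (c.z, c.y))


def spectrum_cell_lattice(radii) -> list[CellSpec]:
    """Transverse-axis ring cells for spectrum scoring."""
    return [CellSpec(float(r), 0.0, False) for r in radii]


def spectrum_bin_edges() -> np.ndarray:
    """Fluence spectrum bins: 20 keV wide, with 2 keV bins bracketing the
    1.17 and 1.33 MeV source lines."""
    edges = set(np.round(np.arange(0.010, 1.4101, 0.020), 3))
    for line in (1.17, 1.33):
        edges -= {round(line, 3)}
        edges |= {round(line - 0.001, 4), round(line + 0.001, 4)}
    return np.array(sorted(edges))


def segment_cell_lengths(p0, u, step, r_lo, r_hi, z_lo, z_hi):
    """Track length of the segment p0 + t*u, t in [0, step], inside each
    ring cell (vectorized over cells)."""
    r_lo = np.asarray(r_lo, dtype=float)
    z0 = p0[2]
    uz = u[2]
    # z-slab clipping
    if abs(uz) > 1e-30:
        ta = (z_lo - z0) / uz
        tb = (z_hi - z0) / uz
        t_in = np.minimum(ta, tb)
        t_out = np.maximum(ta, tb)
    else:
        inside = (z_lo <= z0) & (z0 <= z_hi)
        t_in = np.where(inside, 0.0, np.inf)
        t_out = np.where(inside, step, -np.inf)
    t_in = np.maximum(t_in, 0.0)
    t_out = np.minimum(t_out, step)

    a = u[0] * u[0] + u[1] * u[1]
    b = p0[0] * u[0] + p0[1] * u[1]
    c = p0[0] * p0[0] + p0[1] * p0[1]

    def inside_radius_interval(r):
        # {t : dist_to_axis(t) <= r} as an interval (lo, hi); empty if disc<=0
        if a < 1e-30:
            ok = c <= r * r
            lo = np.where(ok, -np.inf, np.inf)
            hi = np.where(ok, np.inf, -np.inf)
            return lo, hi
        disc = b * b - a * (c - r * r)
        root = np.sqrt(np.maximum(disc, 0.0))
        lo = np.where(disc > 0, (-b - root) / a, np.inf)
        hi = np.where(disc > 0, (-b + root) / a, -np.inf)
        return lo, hi

    out_lo, out_hi = inside_radius_interval(r_hi)
    in_lo, in_hi = inside_radius_interval(r_lo)

    def overlap(lo, hi):
        return np.maximum(0.0, np.minimum(hi, t_out) - np.maximum(lo, t_in))

    length = overlap(out_lo, out_hi)
    # subtract the part inside the inner cylinder (rings only)
    has_hole = r_lo > 0
    length = length - np.where(has_hole, overlap(in_lo, in_hi), 0.0)
    return np.maximum(length, 0.0)


class RingTallyGrid:
    """Track-length fluence/kerma accumulator over a set of ring cells.

    The Python implementation is the readable reference used in tests; the
    production engine scores the same estimator in a compiled kernel.
    """

    def __init__(self, cells: list[CellSpec], kerma_medium: str = "water"):
        self.cells = list(cells)
        n = len(self.cells)
        self.r_lo = np.array([c.r_lo for c in self.cells])
        self.r_hi = np.array([c.r_hi for c in self.cells])
        self.z_lo = np.array([c.z_lo for c in self.cells])
        self.z_hi = np.array([c.z_hi for c in self.cells])
        self.volume = np.array([c.volume for c in self.cells])
        if np.any(self.volume <= 0):
            raise ValueError("cell with non-positive volume")
        self.kerma_medium = kerma_medium
        self.fluence_s1 = np.zeros(n)
        self.fluence_s2 = np.zeros(n)
        self.kerma_s1 = np.zeros(n)
        self.kerma_s2 = np.zeros(n)
        self._hist_fluence = np.zeros(n)
        self._hist_kerma = np.zeros(n)
        self.n_histories = 0

    def begin_history(self):
        self._hist_fluence[:] = 0.0
        self._hist_kerma[:] = 0.0

    def score_segment(self, p0, direction, step, energy, weight=1.0):
        """Score one flight segment into every cell it crosses."""
        if step <= 0:
            return
        lengths = segment_cell_lengths(np.asarray(p0), np.asarray(direction),
                                       step, self.r_lo, self.r_hi,
                                       self.z_lo, self.z_hi)
        if not np.any(lengths > 0):
            return
        flu = weight * lengths / self.volume
        muen = float(materials.mu_en_over_rho(self.kerma_medium, energy))
        self._hist_fluence += flu
        self._hist_kerma += flu * energy * muen

    def end_history(self):
        self.fluence_s1 += self._hist_fluence
        self.fluence_s2 += self._hist_fluence**2
        self.kerma_s1 += self._hist_kerma
        self.kerma_s2 += self._hist_kerma**2
        self.n_histories += 1

    def finalize(self, n_histories: int | None = None) -> pd.DataFrame:
        n = self.n_histories if n_histories is None else n_histories
        return finalize_cells(self.cells, self.fluence_s1, self.fluence_s2,
                              self.kerma_s1, self.kerma_s2, n)


def mean_and_rel_sigma(s1, s2, n):
    """History-by-history mean and relative 1-sigma of the mean."""
    if n < 2:
        raise ValueError("need at least 2 histories for an uncertainty")
    mean = s1 / n
    var_mean = np.maximum(s2 / n - mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var_mean) / np.abs(mean), 0.0)
    return mean, rel


def finalize_cells(cells, fl_s1, fl_s2, k_s1, k_s2, n) -> pd.DataFrame:
    """Reduce raw accumulators to per-cell means and uncertainties.

    Means are normalized per source decay (2 photons/decay) and kerma is
    converted from MeV/g to Gy.  Relative uncertainties are unaffected by
    either normalization.
    """
    fl_mean, fl_rel = mean_and_rel_sigma(np.asarray(fl_s1), np.asarray(fl_s2), n)
    k_mean, k_rel = mean_and_rel_sigma(np.asarray(k_s1), np.asarray(k_s2), n)
    return pd.DataFrame({
        "y": [c.y for c in cells],
        "z": [c.z for c in cells],
        "is_disk": [c.is_disk for c in cells],
        "volume": [c.volume for c in cells],
        "fluence": fl_mean * CO60_YIELD,          # 1/cm^2 per decay
        "fluence_rel_1sigma": fl_rel,
        "kerma": k_mean * CO60_YIELD * MEV_PER_G_TO_GY,  # Gy per decay
        "kerma_rel_1sigma": k_rel,
    })


class EnergySpectrumTally:
    """Energy-binned fluence in a cell, normalized to total fluence."""

    def __init__(self, bin_edges: np.ndarray = None):
        self.edges = spectrum_bin_edges() if bin_edges is None else np.asarray(bin_edges)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        self.fluence = np.zeros(len(self.edges) - 1)

    def score(self, energy, amount):
        i = np.searchsorted(self.edges, energy, side="right") - 1
        if 0 <= i < len(self.fluence):
            self.fluence[i] += amount

    def normalized(self) -> np.ndarray:
        total = self.fluence.sum()
        if total <= 0:
            raise ValueError("empty spectrum tally")
        return self.fluence / total


@dataclass
class PointDetector:
    """Next-event fluence/kerma estimator at a transverse-axis point.

    Each source emission or Compton collision adds its expected
    contribution p(Omega) * exp(-optical depth) / d^2 to the detector,
    converted to air kerma at the photon energy along the detector ray.
    """

    y: float  # transverse distance, cm
    kerma_s1: float = 0.0
    kerma_s2: float = 0.0
    _hist: float = 0.0
    n_histories: int = 0

    @property
    def position(self) -> np.ndarray:
        return np.array([0.0, self.y, 0.0])

    def begin_history(self):
        self._hist = 0.0

    def add(self, contribution_kerma: float):
        self._hist += contribution_kerma

    def end_history(self):
        self.kerma_s1 += self._hist
        self.kerma_s2 += self._hist**2
        self.n_histories += 1

    def finalize(self, n: int | None = None):
        n = self.n_histories if n is None else n
        mean, rel = mean_and_rel_sigma(np.array(self.kerma_s1),
                                       np.array(self.kerma_s2), n)
        # MeV/g per photon -> Gy per decay
        return float(mean) * CO60_YIELD * MEV_PER_G_TO_GY, float(rel)


def point_detector_contribution(kind: str, position, energy, direction,
                                detector: PointDetector, geometry,
                                region_materials: dict):
    """Expected air-kerma contribution of one event to a point detector.

    ``kind`` is ``"emission"`` (isotropic, pdf 1/4pi) or ``"compton"``
    (Klein-Nishina pdf at the angle towards the detector, evaluated at the
    pre-collision ``energy`` and ``direction``).  The optical depth is
    traced through every region between the event and the detector.
    Returns the kerma contribution in MeV/g per initial photon.
    """
    from . import compton as _compton
    from .geometry import EXTERIOR

    pos = np.asarray(position, dtype=float)
    vec = detector.position - pos
    d = math.sqrt(vec @ vec)
    if d <= 0:
        raise ValueError("detector coincides with the event position")
    toward = vec / d
    if kind == "emission":
        pdf = 1.0 / (4.0 * math.pi)
        e_det = energy
    elif kind == "compton":
        cos_t = float(np.asarray(direction, dtype=float) @ toward)
        n_elec_weighted = 1.0  # per-electron pdf; material factor cancels
        pdf = (_compton.kn_differential(energy, cos_t)
               / _compton.sigma_kn_total(energy)) * n_elec_weighted
        e_det = _compton.scattered_energy(energy, cos_t)
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    # optical depth along the detector ray
    tau = 0.0
    p = pos.copy()
    remaining = d
    for _ in range(10_000):
        region = geometry.locate(p, direction=toward)
        if region == EXTERIOR:
            break
        mat = region_materials.get(region)
        t, _next = geometry.distance_to_boundary(p, toward)
        step = min(t, remaining)
        if mat is not None:
            tau += float(mat.mu_total(e_det)) * step
        remaining -= step
        if remaining <= 1e-12 or not math.isfinite(t):
            break
        p = p + step * toward
    flu = pdf * math.exp(-tau) / (d * d)
    muen = float(materials.mu_en_over_rho("air", e_det))
    return flu * e_det * muen


# -- tally archive I/O ------------------------------------------------------

ARCHIVE_CELLS = "cells.csv"
ARCHIVE_META = "meta.json"
ARCHIVE_DETECTORS = "detectors.csv"
ARCHIVE_SPECTRA = "spectra.csv"


def save_archive(path, meta: dict, cells: pd.DataFrame = None,
                 detectors: pd.DataFrame = None,
                 spectra: pd.DataFrame = None):
    """Write a tally archive: delimited text tables plus JSON metadata."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / ARCHIVE_META, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    if cells is not None:
        cells.to_csv(path / ARCHIVE_CELLS, index=False, float_format="%.10e")
    if detectors is not None:
        detectors.to_csv(path / ARCHIVE_DETECTORS, index=False,
                         float_format="%.10e")
    if spectra is not None:
        spectra.to_csv(path / ARCHIVE_SPECTRA, index=False,
                       float_format="%.10e")


def load_archive(path) -> dict:
    """Read a tally archive back; inverse of :func:`save_archive`."""
    path = pathlib.Path(path)
    meta_file = path / ARCHIVE_META
    if not meta_file.exists():
        raise FileNotFoundError(f"{path} is not a tally archive (no meta.json)")
    with open(meta_file) as fh:
        out = {"meta": json.load(fh)}
    for key, name in (("cells", ARCHIVE_CELLS),
                      ("detectors", ARCHIVE_DETECTORS),
                      ("spectra", ARCHIVE_SPECTRA)):
        f = path / name
        if f.exists():
            out[key] = pd.read_csv(f)
    return out
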