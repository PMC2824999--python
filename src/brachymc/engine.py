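"""Bridges run configurations to the compiled transport kernels.

Prepares flat log-log coefficient tables, geometry scalars and tally-cell
arrays, invokes the :mod:`brachymc._kernels` history loop, and reduces raw
accumulators to finalized DataFrames (per-decay normalization, 2 photons
per disintegration, history-by-history uncertainties).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import tallies
from .constants import CO60_LINES, CO60_YIELD, MEV_PER_G_TO_GY
from .geometry import CABLE, CAPSULE, CORE, GAP, PHANTOM, Geometry, SourceModel
from .materials import PROCESSES, standard_material
from .transport import RunConfig

_LOG_FLOOR = 1e-30


def _geom_scalars(config: RunConfig):
    src = SourceModel()
    ph = config.phantom_spec()
    shape = 0 if ph.shape == "cylinder" else 1
    return (src.core_radius, src.core_half_length, src.gap_radius,
            src.gap_half_length, src.capsule_radius, src.capsule_half_length,
            src.cable_z_min, shape, ph.radius, ph.half_height)


def _material_tables(mats, include_coherent: bool, include_pair: bool):
    """Log-log per-process linear attenuation tables for the kernel."""
    grid = mats[0].energy_grid
    log_e = np.log(grid)
    n = len(mats)
    per_process = {}
    for proc in PROCESSES:
        arr = np.empty((n, len(grid)))
        for i, m in enumerate(mats):
            arr[i] = m.density * m.mu_over_rho(grid, proc)
        per_process[proc] = arr
    mu_tr = per_process["photoelectric"] + per_process["incoherent"]
    if include_coherent:
        mu_tr = mu_tr + per_process["coherent"]
    if include_pair:
        mu_tr = mu_tr + per_process["pair"]

    def logs(a):
        return np.log(np.maximum(a, _LOG_FLOOR))

    return (log_e, logs(mu_tr), logs(per_process["photoelectric"]),
            logs(per_process["incoherent"]), logs(per_process["coherent"]),
            logs(per_process["pair"]))


def _muen_logs(medium: str):
    from .materials import _muen_table
    grid, vals = _muen_table(medium)
    return np.log(grid), np.log(vals)


def _region_materials(config: RunConfig):
    """Materials indexed for the kernel; region -> index, -1 = vacuum."""
    mats = [standard_material("cobalt"), standard_material("air"),
            standard_material("steel316l")]
    region_mat = np.array([0, 1, 2, 2, -1, -1], dtype=np.int64)
    if config.phantom != "vacuum":
        medium = standard_material(config.phantom)
        if config.phantom == "air":
            region_mat[PHANTOM] = 1
        else:
            mats.append(medium)
            region_mat[PHANTOM] = 3
    return mats, region_mat


def _cell_arrays(cells):
    """Group cells into z slabs; returns kernel arrays plus the cell order."""
    order = sorted(range(len(cells)),
                   key=lambda i: (cells[i].z_lo, cells[i].r_lo))
    slabs: list[tuple[float, float]] = []
    slab_of = []
    for i in order:
        key = (cells[i].z_lo, cells[i].z_hi)
        if not slabs or slabs[-1] != key:
            slabs.append(key)
        slab_of.append(len(slabs) - 1)
    slab_zlo = np.array([s[0] for s in slabs])
    slab_zhi = np.array([s[1] for s in slabs])
    slab_ptr = np.zeros(len(slabs) + 1, dtype=np.int64)
    for s in slab_of:
        slab_ptr[s + 1] += 1
    slab_ptr = np.cumsum(slab_ptr)
    cell_rlo2 = np.array([cells[i].r_lo**2 for i in order])
    cell_rhi2 = np.array([cells[i].r_hi**2 for i in order])
    cell_inv_vol = np.array([1.0 / cells[i].volume for i in order])
    return (slab_zlo, slab_zhi, slab_ptr, cell_rlo2, cell_rhi2,
            cell_inv_vol, order)


def _meta(config: RunConfig) -> dict:
    from . import __version__
    src = SourceModel()
    ph = config.phantom_spec()
    return {
        "config": config.to_dict(),
        "mode": config.mode,
        "seed": int(config.seed),
        "n_histories": int(config.n_histories),
        "package_version": __version__,
        "source": {
            "core_radius_cm": src.core_radius,
            "core_half_length_cm": src.core_half_length,
            "gap_radius_cm": src.gap_radius,
            "capsule_radius_cm": src.capsule_radius,
            "capsule_half_length_cm": src.capsule_half_length,
            "cable_length_cm": src.cable_length,
        },
        "phantom": {"shape": ph.shape, "radius_cm": ph.radius,
                    "half_height_cm": ph.half_height, "medium": ph.medium},
        "cutoff_MeV": 0.010,
        "lines_MeV": list(CO60_LINES),
        "photons_per_decay": CO60_YIELD,
    }


def _run_cells(config: RunConfig, cells, spec_edges,
               kerma_medium: str = "water") -> dict:
    from . import _kernels
    geom = _geom_scalars(config)
    mats, region_mat = _region_materials(config)
    tables = _material_tables(mats, config.include_coherent,
                              config.include_pair)
    lmuen_e, lmuen_v = _muen_logs(kerma_medium)
    (slab_zlo, slab_zhi, slab_ptr, rlo2, rhi2, inv_vol,
     order) = _cell_arrays(cells)
    seed = int(config.seed) % (2**31)
    fl1, fl2, k1, k2, spec = _kernels.run_phantom(
        seed, int(config.n_histories), *geom,
        region_mat, *tables, config.include_coherent, config.include_pair,
        lmuen_e, lmuen_v,
        slab_zlo, slab_zhi, slab_ptr, rlo2, rhi2, inv_vol, len(cells),
        spec_edges, CO60_LINES[0], CO60_LINES[1])
    ordered_cells = [cells[i] for i in order]
    df = tallies.finalize_cells(ordered_cells, fl1, fl2, k1, k2,
                                config.n_histories)
    df = df.sort_values(["z", "y"]).reset_index(drop=True)
    out = {"meta": _meta(config), "cells": df}
    if len(spec_edges) > 0:
        rows = []
        for j, cell in enumerate(ordered_cells):
            total = spec[j].sum()
            for i in range(len(spec_edges) - 1):
                rows.append({
                    "y": cell.y, "z": cell.z,
                    "e_lo": spec_edges[i], "e_hi": spec_edges[i + 1],
                    "fluence": spec[j, i] * CO60_YIELD / config.n_histories,
                    "normalized": spec[j, i] / total if total > 0 else 0.0,
                })
        out["spectra"] = pd.DataFrame(rows)
    return out


def run_dose(config: RunConfig) -> dict:
    """Ring-tally dose run on the standard Cartesian + radial lattice."""
    cells = tallies.standard_cell_lattice()
    return _run_cells(config, cells, np.empty(0))


def run_spectrum(config: RunConfig) -> dict:
    """Energy-spectrum run: transverse ring cells in a spherical phantom."""
    radii = config.spectrum_radii
    if not radii:
        radii = (1.0, 5.0, 20.0) if config.phantom == "water" else (50.0,)
    cells = tallies.spectrum_cell_lattice(radii)
    return _run_cells(config, cells, tallies.spectrum_bin_edges())


def run_airkerma(config: RunConfig) -> dict:
    """Next-event point-detector air-kerma run in the 5 m sphere."""
    from . import _kernels
    geom = _geom_scalars(config)
    mats, region_mat = _region_materials(config)
    tables = _material_tables(mats, config.include_coherent,
                              config.include_pair)
    lmuen_e, lmuen_v = _muen_logs("air")
    det_y = np.array(tallies.DETECTOR_DISTANCES)
    seed = int(config.seed) % (2**31)
    s1, s2 = _kernels.run_airkerma(
        seed, int(config.n_histories), *geom,
        region_mat, *tables, config.include_coherent, config.include_pair,
        lmuen_e, lmuen_v, det_y, CO60_LINES[0], CO60_LINES[1])
    mean, rel = tallies.mean_and_rel_sigma(s1, s2, config.n_histories)
    df = pd.DataFrame({
        "y": det_y,
        # MeV/g per photon -> Gy per decay
        "kerma": mean * CO60_YIELD * MEV_PER_G_TO_GY,
        "kerma_rel_1sigma": rel,
    })
    return {"meta": _meta(config), "detectors": df}


def run(config: RunConfig) -> dict:
    if config.mode == "dose":
        return run_dose(config)
    if config.mode == "airkerma":
        return run_airkerma(config)
    return run_spectrum(config)
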