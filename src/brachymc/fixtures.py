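"""Synthetic tally fixtures with known ground truth.

These generate tally archives whose kerma fields follow closed-form radial
models — inverse square, the bare line-source geometry function, or the
geometry function times exponential attenuation and a polynomial build-up
factor — with reproducible multiplicative lognormal noise.  They exercise
the TG-43 analysis stage without running transport, and they emulate the
statistics of real runs (relative sigma in the 0.04%-2% range) without any
of the spectral or scatter physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tallies, tg43
from .constants import GY_PER_DECAY_TO_CGY_PER_H_PER_BQ
from .materials import standard_material

FIELD_MODELS = ("inverse_square", "line_geometry", "line_geometry_attenuated")


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of an analytic kerma field on the standard lattice.

    ``amplitude`` is the kerma (Gy per decay) that the model would give at
    1 cm on the transverse axis before noise.  ``mu`` (1/cm) and the
    build-up polynomial coefficients only apply to the attenuated model:
    dose(r) ~ G_L(r) * exp(-mu (r-1)) * poly(r)/poly(1).
    """

    field_model: str = "line_geometry"
    amplitude: float = 1e-12
    relative_sigma: float = 0.0
    seed: int = 0
    mu: float = 0.0
    buildup_coefficients: tuple = (1.0,)

    def __post_init__(self):
        if self.field_model not in FIELD_MODELS:
            raise ValueError(f"unknown field model {self.field_model!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


def _field_value(spec: FixtureSpec, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    r = np.hypot(y, z)
    theta = np.arctan2(y, z)
    if spec.field_model == "inverse_square":
        ref = 1.0
        return spec.amplitude * ref / r**2
    geo = tg43.line_geometry_function(r, theta)
    geo0 = tg43.line_geometry_function(1.0)
    base = spec.amplitude * geo / geo0
    if spec.field_model == "line_geometry":
        return base
    poly = np.polynomial.polynomial.polyval(r, spec.buildup_coefficients)
    poly0 = np.polynomial.polynomial.polyval(1.0, spec.buildup_coefficients)
    return base * np.exp(-spec.mu * (r - 1.0)) * poly / poly0


def analytic_field_archive(spec: FixtureSpec) -> dict:
    """Tally archive whose kerma follows the spec's analytic field model.

    Same schema as a real dose run: ``meta`` plus a ``cells`` DataFrame.
    Noise is multiplicative lognormal with the stated relative sigma,
    reproducible from the seed.
    """
    cells = tallies.standard_cell_lattice()
    y = np.array([c.y for c in cells])
    z = np.array([c.z for c in cells])
    kerma = _field_value(spec, y, z)
    rng = np.random.default_rng(spec.seed)
    if spec.relative_sigma > 0:
        sigma_log = math.sqrt(math.log1p(spec.relative_sigma**2))
        noise = rng.lognormal(-0.5 * sigma_log**2, sigma_log, size=len(cells))
        kerma = kerma * noise
    muen_scale = 1.0  # fixture kerma is already the final field
    df = pd.DataFrame({
        "y": y, "z": z,
        "is_disk": [c.is_disk for c in cells],
        "volume": [c.volume for c in cells],
        "fluence": kerma * muen_scale,
        "fluence_rel_1sigma": np.full(len(cells), spec.relative_sigma),
        "kerma": kerma,
        "kerma_rel_1sigma": np.full(len(cells), spec.relative_sigma),
    }).sort_values(["z", "y"]).reset_index(drop=True)
    meta = {
        "mode": "fixture",
        "fixture": {
            "field_model": spec.field_model,
            "amplitude": spec.amplitude,
            "relative_sigma": spec.relative_sigma,
            "seed": spec.seed,
            "mu": spec.mu,
            "buildup_coefficients": list(spec.buildup_coefficients),
        },
        "phantom": {"shape": "cylinder", "radius_cm": 50.0,
                    "half_height_cm": 50.0, "medium": "synthetic"},
        "n_histories": 0,
        "seed": spec.seed,
    }
    return {"meta": meta, "cells": df}


def slab_transmission_experiment(thickness_mfp: float, n: int,
                                 seed: int = 0) -> float:
    """Uncollided fraction of a pencil beam through a uniform slab.

    The slab thickness is given in mean free paths; histories use the
    transport free-path sampler in water at 1.25 MeV, so the expected
    transmitted fraction is exp(-thickness).
    """
    if n < 1:
        raise ValueError("need at least one history")
    if thickness_mfp < 0:
        raise ValueError("thickness must be >= 0")
    from .transport import sample_free_path
    water = standard_material("water")
    energy = 1.25
    mu = float(water.mu_total(energy))
    thickness_cm = thickness_mfp / mu
    rng = np.random.default_rng(seed)
    transmitted = 0
    for _ in range(n):
        if sample_free_path(water, energy, rng) > thickness_cm:
            transmitted += 1
    return transmitted / n


def known_ratio_pair(lambda_target: float):
    """Construct inputs for which the dose rate constant is exactly
    ``lambda_target``: an exact inverse-square air-kerma series and the
    matching transverse kerma rate at 1 cm."""
    if lambda_target <= 0:
        raise ValueError("lambda_target must be positive")
    sk = 3.0e-7  # arbitrary positive scale, cGy cm^2/h/Bq
    y = np.array([25.0, 50.0, 75.0, 100.0])
    series = tg43.AirKermaSeries(y=y, k=sk / y**2,
                                 rel_1sigma=np.zeros_like(y))
    kerma_at_r0 = lambda_target * sk  # cGy/h/Bq at 1 cm
    return series, kerma_at_r0
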