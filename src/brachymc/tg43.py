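"""TG-43 analysis of tally output.

Converts raw tally archives into the standard brachytherapy dosimetry
quantities:

* air-kerma strength per unit activity S_K/A, from the linear fit
  k_air(y) * y^2 = S_K/A + b*y of the point-detector air-kerma rates
  (the slope b describes scattered-photon build-up in the air phantom);
* dose rate constant lambda = D(r0=1 cm, theta0=90 deg) / S_K;
* line-source geometry function G_L(r, theta) = beta / (L r sin theta);
* radial dose function g_L(r) = [D(r)/D(r0)] [G_L(r0)/G_L(r)] on the
  transverse axis, normalized to 1 at r0 = 1 cm, plus its cubic
  polynomial fit;
* Cartesian away-along dose-rate tables per unit S_K, and percent
  phantom-vs-water comparisons.

Uncertainties are propagated to first order (quadrature of relative
1-sigma values), adequate for the sub-2% statistical noise of the runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compton import backscatter_energy  # noqa: F401  (re-exported)
from .constants import GY_PER_DECAY_TO_CGY_PER_H_PER_BQ
from .geometry import SourceModel

#: TG-43 reference point: 1 cm on the transverse axis
R0 = 1.0

#: active length of the line-source geometry function (cm)
ACTIVE_LENGTH = SourceModel().active_length

#: point-source dose rate constant for Co-60 (cGy h^-1 U^-1); with the
#: geometry function at the reference point this predicts the line-source
#: dose rate constant: lambda ~= lambda_point * G_L(1 cm, 90 deg)
LAMBDA_POINT = 1.094


@dataclass(frozen=True)
class AirKermaSeries:
    """Air-kerma rate per unit activity at transverse distances."""

    y: np.ndarray  # cm, ascending
    k: np.ndarray  # cGy h^-1 Bq^-1
    rel_1sigma: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.y) > 0):
            raise ValueError("distances must be ascending")
        if np.any(self.k <= 0):
            raise ValueError("air-kerma rates must be positive")


@dataclass
class TG43Result:
    """Summary TG-43 quantities for one phantom run."""

    phantom: str
    sk_per_a: float          # cGy cm^2 h^-1 Bq^-1
    sk_rel_1sigma: float
    buildup_slope: float     # cGy cm h^-1 Bq^-1
    dose_rate_constant: float            # cGy h^-1 U^-1
    lambda_rel_1sigma: float
    active_length: float = ACTIVE_LENGTH
    gl_table: pd.DataFrame = None        # columns r, g, rel_1sigma
    poly_coefficients: np.ndarray = None  # a0..a3

    def summary_dict(self) -> dict:
        return {
            "phantom": self.phantom,
            "S_K_per_A_cGy_cm2_per_h_per_Bq": self.sk_per_a,
            "S_K_rel_1sigma": self.sk_rel_1sigma,
            "buildup_slope_b": self.buildup_slope,
            "dose_rate_constant_cGy_per_h_per_U": self.dose_rate_constant,
            "dose_rate_constant_rel_1sigma": self.lambda_rel_1sigma,
            "active_length_cm": self.active_length,
            "gl_poly_a0_a1_a2_a3": list(map(float, self.poly_coefficients))
            if self.poly_coefficients is not None else None,
        }


def per_decay_to_activity_units(kerma_gy_per_decay):
    """Gy per decay -> cGy h^-1 Bq^-1 (x3600 s/h x100 cGy/Gy)."""
    return np.asarray(kerma_gy_per_decay) * GY_PER_DECAY_TO_CGY_PER_H_PER_BQ


def activity_units_to_per_decay(k_cgy_per_h_per_bq):
    return np.asarray(k_cgy_per_h_per_bq) / GY_PER_DECAY_TO_CGY_PER_H_PER_BQ


def fit_air_kerma_strength(series: AirKermaSeries):
    """Fit k(y)*y^2 = S_K/A + b*y by ordinary least squares.

    Returns ``(sk_per_a, b, sk_rel_1sigma)``; the intercept uncertainty is
    propagated from the per-point statistical uncertainties through the
    unweighted normal equations.
    """
    y = np.asarray(series.y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two distances")
    v = series.k * y**2
    X = np.column_stack([np.ones_like(y), y])
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular air-kerma fit")
    beta = np.linalg.solve(XtX, X.T @ v)
    hat = np.linalg.solve(XtX, X.T)  # maps v -> beta
    sigma_v = series.rel_1sigma * v
    var_beta0 = float(hat[0] ** 2 @ sigma_v**2)
    sk, b = float(beta[0]), float(beta[1])
    return sk, b, math.sqrt(var_beta0) / sk if sk > 0 else 0.0


def line_geometry_function(r, theta=math.pi / 2, L: float = ACTIVE_LENGTH):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    beta/(L r sin theta) with beta the angle the active segment subtends at
    the field point; on the long axis the limit 1/(r^2 - L^2/4) applies and
    the expression is continuous across the transition.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    yy = r * np.sin(theta)
    zz = r * np.cos(theta)
    on_axis = np.abs(yy) < 1e-12
    if np.any(on_axis & (np.abs(zz) <= L / 2 + 1e-12)):
        raise ValueError("field point on the active segment")
    beta = np.arctan2(yy, zz - L / 2) - np.arctan2(yy, zz + L / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_line = beta / (L * r * np.sin(theta))
    g_axis = 1.0 / (r**2 - L**2 / 4.0)
    out = np.where(on_axis, g_axis, g_line)
    return out if out.ndim else float(out)


def dose_rate_constant(kerma_rate_at_r0: float, sk_per_a: float,
                       kerma_rel_1sigma: float = 0.0,
                       sk_rel_1sigma: float = 0.0):
    """lambda = dose rate to water at (r=1 cm, 90 deg) per unit S_K.

    Inputs are in cGy h^-1 Bq^-1 and cGy cm^2 h^-1 Bq^-1; uncertainties
    combine in quadrature.  Returns ``(lambda, rel_1sigma)``.
    """
    if kerma_rate_at_r0 <= 0 or sk_per_a <= 0:
        raise ValueError("inputs must be positive")
    lam = kerma_rate_at_r0 / sk_per_a
    rel = math.hypot(kerma_rel_1sigma, sk_rel_1sigma)
    return lam, rel


def radial_dose_function(profile: pd.DataFrame,
                         L: float = ACTIVE_LENGTH) -> pd.DataFrame:
    """g_L(r) from a transverse-axis dose profile.

    ``profile`` has columns ``r``, ``dose`` (any fixed normalization) and
    optionally ``rel_1sigma``; it must include the reference radius 1 cm.
    g_L(1) = 1 exactly; uncertainties of the ratio to the reference point
    combine in quadrature.
    """
    r = np.asarray(profile["r"], dtype=float)
    d = np.asarray(profile["dose"], dtype=float)
    rel = np.asarray(profile["rel_1sigma"], dtype=float) \
        if "rel_1sigma" in profile else np.zeros_like(d)
    at_r0 = np.isclose(r, R0)
    if not np.any(at_r0):
        raise ValueError("profile must include the reference radius 1 cm")
    i0 = int(np.argmax(at_r0))
    geo = line_geometry_function(R0, L=L) / line_geometry_function(r, L=L)
    g = (d / d[i0]) * geo
    g_rel = np.hypot(rel, rel[i0])
    g[at_r0] = 1.0
    g_rel[at_r0] = 0.0
    return pd.DataFrame({"r": r, "g": g, "rel_1sigma": g_rel})


def fit_radial_polynomial(gl_table: pd.DataFrame, order: int = 3) -> np.ndarray:
    """Unweighted OLS fit of g_L(r) to a polynomial; returns a0..a_order."""
    r = np.asarray(gl_table["r"], dtype=float)
    g = np.asarray(gl_table["g"], dtype=float)
    if len(r) < order + 2:
        raise ValueError("too few points for a stable polynomial fit")
    V = np.vander(r, order + 1, increasing=True)
    coef, _res, rank, _sv = np.linalg.lstsq(V, g, rcond=None)
    if rank < order + 1:
        raise ValueError("rank-deficient polynomial fit")
    return coef


def transverse_profile(cells: pd.DataFrame) -> pd.DataFrame:
    """Extract the z=0 transverse kerma profile from a ring-tally table.

    Returns columns r, dose (cGy h^-1 Bq^-1) and rel_1sigma.
    """
    sel = cells[(cells["z"] == 0.0) & (cells["y"] > 0)].sort_values("y")
    return pd.DataFrame({
        "r": sel["y"].to_numpy(),
        "dose": per_decay_to_activity_units(sel["kerma"].to_numpy()),
        "rel_1sigma": sel["kerma_rel_1sigma"].to_numpy(),
    })


def air_kerma_series(detectors: pd.DataFrame) -> AirKermaSeries:
    """Point-detector archive table -> AirKermaSeries in activity units."""
    det = detectors.sort_values("y")
    return AirKermaSeries(
        y=det["y"].to_numpy(dtype=float),
        k=per_decay_to_activity_units(det["kerma"].to_numpy()),
        rel_1sigma=det["kerma_rel_1sigma"].to_numpy(dtype=float),
    )


def build_dose_rate_table(cells: pd.DataFrame, sk_per_a: float,
                          sk_rel_1sigma: float = 0.0) -> pd.DataFrame:
    """Cartesian dose rate per unit S_K (cGy h^-1 U^-1) on the away-along
    lattice.  Long format with columns y, z, dose_rate, rel_1sigma."""
    from .tallies import ALONG_Z, AWAY_Y
    if sk_per_a <= 0:
        raise ValueError("S_K/A must be positive")
    lattice = cells[cells["y"].isin(AWAY_Y) & cells["z"].isin(ALONG_Z)]
    rate = per_decay_to_activity_units(lattice["kerma"].to_numpy()) / sk_per_a
    rel = np.hypot(lattice["kerma_rel_1sigma"].to_numpy(), sk_rel_1sigma)
    return pd.DataFrame({
        "y": lattice["y"].to_numpy(),
        "z": lattice["z"].to_numpy(),
        "dose_rate": rate,
        "rel_1sigma": rel,
    }).sort_values(["z", "y"]).reset_index(drop=True)


def dose_table_pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Away-along long table -> the printed layout (z rows, y columns)."""
    return table.pivot(index="z", columns="y", values="dose_rate")


def compare_phantoms(water: pd.DataFrame, solid: pd.DataFrame) -> pd.DataFrame:
    """Percent difference of a solid-phantom dose table vs water.

    Both tables are long-format ``build_dose_rate_table`` outputs on the
    same lattice.  Returns per-point percent difference
    100*(solid - water)/water with propagated 1-sigma (percent points) and
    a flag marking differences beyond two combined sigma.
    """
    w = water.sort_values(["z", "y"]).reset_index(drop=True)
    s = solid.sort_values(["z", "y"]).reset_index(drop=True)
    if len(w) != len(s) or not (np.allclose(w["y"], s["y"])
                                and np.allclose(w["z"], s["z"])):
        raise ValueError("dose tables are on different lattices")
    wv = w["dose_rate"].to_numpy()
    sv = s["dose_rate"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.where(wv > 0, 100.0 * (sv - wv) / wv, np.nan)
        sigma = np.where(wv > 0,
                         100.0 * np.hypot(w["rel_1sigma"], s["rel_1sigma"])
                         * sv / wv, np.nan)
    return pd.DataFrame({
        "y": w["y"], "z": w["z"],
        "percent_diff": diff,
        "sigma_percent": sigma,
        "significant": np.abs(diff) > 2.0 * sigma,
    })


def analyze(air_archive: dict, phantom_archive: dict,
            L: float = ACTIVE_LENGTH) -> TG43Result:
    """Full TG-43 reduction of an air-kerma run plus a phantom dose run."""
    series = air_kerma_series(air_archive["detectors"])
    sk, b, sk_rel = fit_air_kerma_strength(series)
    cells = phantom_archive["cells"]
    profile = transverse_profile(cells)
    at_r0 = np.isclose(profile["r"], R0)
    if not np.any(at_r0):
        raise ValueError("phantom run lacks the 1 cm reference cell")
    d0 = float(profile.loc[at_r0, "dose"].iloc[0])
    d0_rel = float(profile.loc[at_r0, "rel_1sigma"].iloc[0])
    lam, lam_rel = dose_rate_constant(d0, sk, d0_rel, sk_rel)
    gl = radial_dose_function(profile, L=L)
    from .tallies import GL_RADII
    gl = gl[np.isin(np.round(gl["r"], 6), np.round(GL_RADII, 6))]
    gl = gl.reset_index(drop=True)
    coef = fit_radial_polynomial(gl)
    return TG43Result(
        phantom=phantom_archive["meta"]["phantom"]["medium"],
        sk_per_a=sk, sk_rel_1sigma=sk_rel, buildup_slope=b,
        dose_rate_constant=lam, lambda_rel_1sigma=lam_rel,
        active_length=L, gl_table=gl, poly_coefficients=coef)


def write_summary_json(result: TG43Result, path):
    with open(path, "w") as fh:
        json.dump(result.summary_dict(), fh, indent=2)
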