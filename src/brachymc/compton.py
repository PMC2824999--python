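"""Klein-Nishina Compton scattering on free stationary electrons.

At the 1.17/1.33 MeV source energies in low-Z media, electron binding and
Doppler broadening corrections to the free-electron cross section are far
below the package's tolerances, so the plain Klein-Nishina law is used for
both sampling and the next-event point-detector probability density.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import MEC2, R_E


def sigma_kn_total(E):
    """Total Klein-Nishina cross section per electron (cm^2) at E (MeV)."""
    a = np.asarray(E, dtype=float) / MEC2
    term = ((1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
            + np.log(1 + 2 * a) / (2 * a) - (1 + 3 * a) / (1 + 2 * a) ** 2)
    return 2 * math.pi * R_E**2 * term


def kn_differential(E, cos_theta):
    """Klein-Nishina differential cross section dsigma/dOmega (cm^2/sr)."""
    a = np.asarray(E, dtype=float) / MEC2
    cos_theta = np.asarray(cos_theta, dtype=float)
    ratio = 1.0 / (1.0 + a * (1.0 - cos_theta))  # E'/E
    return 0.5 * R_E**2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_theta**2))


def scattered_energy(E, cos_theta):
    """Energy of a photon Compton-scattered through angle theta."""
    a = E / MEC2
    return E / (1.0 + a * (1.0 - cos_theta))


def backscatter_energy(E):
    """Minimum scattered energy: 180-degree backscatter, E/(1 + 2E/mc^2)."""
    return E / (1.0 + 2.0 * E / MEC2)


def sample_cos_theta(E: float, rng: np.random.Generator) -> float:
    """Sample the scattering angle cosine from the Klein-Nishina law.

    Kahn's composition-rejection method, exact for all energies.  Returns
    cos(theta); the scattered energy follows from ``scattered_energy``.
    """
    a = E / MEC2
    lam = 1.0 + 2.0 * a
    while True:
        r1 = rng.random()
        r2 = rng.random()
        r3 = rng.random()
        if r1 <= lam / (lam + 8.0):
            x = 1.0 + 2.0 * a * r2  # x = E/E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = lam / (1.0 + 2.0 * a * r2)
            cos_t = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (cos_t * cos_t + 1.0 / x):
                break
    return 1.0 - (x - 1.0) / a


def rotate_direction(direction, cos_theta, phi):
    """Rotate ``direction`` by polar angle theta and azimuth phi."""
    ux, uy, uz = direction
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta**2))
    cos_phi, sin_phi = math.cos(phi), math.sin(phi)
    if abs(uz) < 0.999999:
        denom = math.sqrt(1.0 - uz * uz)
        vx = sin_theta * (ux * uz * cos_phi - uy * sin_phi) / denom + ux * cos_theta
        vy = sin_theta * (uy * uz * cos_phi + ux * sin_phi) / denom + uy * cos_theta
        vz = -sin_theta * cos_phi * denom + uz * cos_theta
    else:
        sign = 1.0 if uz > 0 else -1.0
        vx = sin_theta * cos_phi
        vy = sign * sin_theta * sin_phi
        vz = sign * cos_theta
    out = np.array([vx, vy, vz])
    return out / math.sqrt(out @ out)


def compton_scatter(E: float, direction, rng: np.random.Generator):
    """Sample a Compton scatter: returns (scattered energy, new direction).

    The scattered energy always lies in [E/(1+2*E/mc^2), E].
    """
    cos_t = sample_cos_theta(E, rng)
    phi = 2.0 * math.pi * rng.random()
    return scattered_energy(E, cos_t), rotate_direction(direction, cos_t, phi)
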