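"""Source and phantom geometry.

The encapsulated HDR source is modeled as nested right circular cylinders
about the z axis, with the origin at the center of the active core:

* active core: metallic cobalt, radius 0.025 cm, half-length 0.175 cm;
* air gap: 0.01 cm thick radially and axially around the core;
* capsule: 316L stainless steel, 0.015 cm thick, flat ends (outer radius
  0.050 cm, outer half-length 0.200 cm);
* cable: solid 316L cylinder, radius 0.050 cm, length 0.2 cm, attached to
  the capsule at negative z.

The surrounding phantom is either a finite cylinder (dose scoring) or a
sphere (air-kerma and spectrum scoring); everything outside is vacuum.
Flat capsule ends are an approximation to the rounded tip of the physical
source; this affects only the near-axis longitudinal dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CO60_LINES

# region identifiers
CORE, GAP, CAPSULE, CABLE, PHANTOM, EXTERIOR = range(6)

REGION_NAMES = {CORE: "core", GAP: "gap", CAPSULE: "capsule",
                CABLE: "cable", PHANTOM: "phantom", EXTERIOR: "exterior"}

_EPS = 1e-9  # boundary nudge, cm


@dataclass(frozen=True)
class SourceModel:
    """Dimensions (cm) of the encapsulated line source."""

    core_radius: float = 0.025
    core_half_length: float = 0.175
    air_gap_thickness: float = 0.010
    capsule_thickness: float = 0.015
    cable_length: float = 0.200

    def __post_init__(self):
        for name in ("core_radius", "core_half_length", "air_gap_thickness",
                     "capsule_thickness", "cable_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gap_radius(self) -> float:
        return self.core_radius + self.air_gap_thickness

    @property
    def gap_half_length(self) -> float:
        return self.core_half_length + self.air_gap_thickness

    @property
    def capsule_radius(self) -> float:
        return self.gap_radius + self.capsule_thickness

    @property
    def capsule_half_length(self) -> float:
        return self.gap_half_length + self.capsule_thickness

    @property
    def cable_z_min(self) -> float:
        return -self.capsule_half_length - self.cable_length

    @property
    def active_length(self) -> float:
        return 2 * self.core_half_length


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom surrounding the source.

    ``medium`` is a material name from :mod:`brachymc.materials`, or
    ``"vacuum"`` for a scatter-free phantom.  A cylinder is bounded by
    ``radius`` and ``half_height``; a sphere by ``radius`` alone.
    """

    shape: str  # "cylinder" | "sphere"
    radius: float
    medium: str
    half_height: float = 0.0

    def __post_init__(self):
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.radius <= 0:
            raise ValueError("phantom radius must be positive")
        if self.shape == "cylinder" and self.half_height <= 0:
            raise ValueError("cylindrical phantom needs a positive half_height")

    @classmethod
    def dose_cylinder(cls, medium: str = "water") -> "PhantomSpec":
        """100 cm diameter x 100 cm height cylinder (full scatter to 20 cm)."""
        return cls("cylinder", 50.0, medium, half_height=50.0)

    @classmethod
    def air_kerma_sphere(cls, medium: str = "air") -> "PhantomSpec":
        """5 m diameter sphere for air-kerma strength scoring."""
        return cls("sphere", 250.0, medium)

    @classmethod
    def spectrum_sphere(cls, medium: str = "water") -> "PhantomSpec":
        """Spectrum-scoring sphere: 100 cm radius for water, 500 cm for
        air or vacuum."""
        radius = 100.0 if medium == "water" else 500.0
        return cls("sphere", radius, medium)


@dataclass
class PhotonState:
    """A photon in flight."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float = 1.0
    alive: bool = True


class Geometry:
    """Point location and ray tracing for source + phantom."""

    def __init__(self, phantom: PhantomSpec, source: SourceModel = None):
        self.source = source or SourceModel()
        self.phantom = phantom

    # -- point location ----------------------------------------------------

    def locate(self, point, direction=None) -> int:
        """Region id containing ``point``.

        Points within 1e-9 cm of a surface are resolved by nudging along
        ``direction`` when given (the region being entered); without a
        direction the innermost region wins by the closed-boundary
        convention below.
        """
        p = np.asarray(point, dtype=float)
        if direction is not None:
            p = p + _EPS * np.asarray(direction, dtype=float)
        x, y, z = p
        r2 = x * x + y * y
        s = self.source
        if r2 <= s.core_radius**2 and abs(z) <= s.core_half_length:
            return CORE
        if r2 <= s.gap_radius**2 and abs(z) <= s.gap_half_length:
            return GAP
        if r2 <= s.capsule_radius**2 and abs(z) <= s.capsule_half_length:
            return CAPSULE
        if r2 <= s.capsule_radius**2 and s.cable_z_min <= z <= -s.capsule_half_length:
            return CABLE
        if self._inside_phantom(x, y, z, r2):
            return PHANTOM
        return EXTERIOR

    def _inside_phantom(self, x, y, z, r2) -> bool:
        ph = self.phantom
        if ph.shape == "cylinder":
            return r2 <= ph.radius**2 and abs(z) <= ph.half_height
        return r2 + z * z <= ph.radius**2

    # -- ray tracing -------------------------------------------------------

    def distance_to_boundary(self, point, direction):
        """Distance to the next region boundary along ``direction``.

        Returns ``(distance, next_region)``; ``next_region`` is
        ``EXTERIOR`` when the ray escapes the phantom.  Distances are to
        the nearest bounding surface crossing; a crossing may leave the
        region unchanged when the quadric extends beyond the actual
        boundary patch, which callers treat as a no-op step.
        """
        p = np.asarray(point, dtype=float)
        u = np.asarray(direction, dtype=float)
        if abs(u @ u - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        t = self._min_crossing(p, u)
        if not math.isfinite(t):
            return math.inf, EXTERIOR
        return t, self.locate(p + t * u, direction=u)

    def _min_crossing(self, p, u) -> float:
        s = self.source
        best = math.inf
        for radius in (s.core_radius, s.gap_radius, s.capsule_radius):
            for t in _ray_cylinder(p, u, radius):
                best = min(best, t)
        planes = (s.core_half_length, -s.core_half_length,
                  s.gap_half_length, -s.gap_half_length,
                  s.capsule_half_length, -s.capsule_half_length,
                  s.cable_z_min)
        for zp in planes:
            t = _ray_plane(p, u, zp)
            if t is not None:
                best = min(best, t)
        ph = self.phantom
        if ph.shape == "cylinder":
            for t in _ray_cylinder(p, u, ph.radius):
                best = min(best, t)
            for zp in (ph.half_height, -ph.half_height):
                t = _ray_plane(p, u, zp)
                if t is not None:
                    best = min(best, t)
        else:
            for t in _ray_sphere(p, u, ph.radius):
                best = min(best, t)
        return best

    def chord_through_phantom(self, point, direction):
        """Straight-line chord length to escape, summing boundary steps."""
        p = np.asarray(point, dtype=float).copy()
        u = np.asarray(direction, dtype=float)
        total = 0.0
        for _ in range(10_000):
            t, region = self.distance_to_boundary(p, u)
            if not math.isfinite(t):
                return total
            total += t
            p = p + t * u
            if region == EXTERIOR:
                return total
        raise RuntimeError("ray tracing did not terminate")

    # -- source sampling ---------------------------------------------------

    def sample_source_photon(self, rng: np.random.Generator) -> PhotonState:
        """Sample a primary photon: position uniform in the active core,
        isotropic direction, energy 1.17 or 1.33 MeV with equal
        probability, statistical weight 1."""
        s = self.source
        r = s.core_radius * math.sqrt(rng.random())
        phi = 2 * math.pi * rng.random()
        z = s.core_half_length * (2 * rng.random() - 1)
        position = np.array([r * math.cos(phi), r * math.sin(phi), z])
        mu = 2 * rng.random() - 1
        psi = 2 * math.pi * rng.random()
        sin_t = math.sqrt(max(0.0, 1 - mu * mu))
        direction = np.array([sin_t * math.cos(psi), sin_t * math.sin(psi), mu])
        energy = CO60_LINES[0] if rng.random() < 0.5 else CO60_LINES[1]
        return PhotonState(position, direction, energy)


def _ray_cylinder(p, u, radius):
    """Positive distances to an infinite cylinder about z of given radius."""
    a = u[0] * u[0] + u[1] * u[1]
    if a < 1e-30:
        return ()
    b = p[0] * u[0] + p[1] * u[1]
    c = p[0] * p[0] + p[1] * p[1] - radius * radius
    disc = b * b - a * c
    if disc <= 0:
        return ()
    root = math.sqrt(disc)
    out = []
    for t in ((-b - root) / a, (-b + root) / a):
        if t > _EPS:
            out.append(t)
    return out


def _ray_plane(p, u, z_plane):
    if abs(u[2]) < 1e-30:
        return None
    t = (z_plane - p[2]) / u[2]
    return t if t > _EPS else None


def _ray_sphere(p, u, radius):
    b = p @ u
    c = p @ p - radius * radius
    disc = b * b - c
    if disc <= 0:
        return ()
    root = math.sqrt(disc)
    return [t for t in (-b - root, -b + root) if t > _EPS]
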