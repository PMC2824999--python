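"""Analog photon transport.

One source photon per history; the two gamma lines are chosen with equal
probability and per-decay quantities are scaled by the yield of 2 photons
per disintegration at tally finalization.  Histories are tracked through
the nested source/phantom geometry with exponential free paths, and
terminated on photoelectric absorption, on falling below the 10 keV cutoff
(no local deposition: scoring is collision kerma via fluence, not energy
deposition), or on escape.  Interactions:

* photoelectric: history terminated (fluorescence omitted; the K edges of
  the constituent elements lie at or below the transport cutoff);
* incoherent: Klein-Nishina scatter on a free electron;
* coherent (disabled by default): direction resampled from the Thomson
  angular law at unchanged energy;
* pair production (above 1.022 MeV): the photon is replaced by two
  back-to-back 0.511 MeV annihilation photons emitted isotropically at the
  collision site (positron range ignored, consistent with the absence of
  electron transport).

This module holds the readable per-history implementation used by the unit
and property tests; :func:`run` executes the same physics through the
compiled engine in :mod:`brachymc.engine` for multi-million-history runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import compton
from .constants import CO60_LINES, CUTOFF_ENERGY, MEC2
from .geometry import (CABLE, CAPSULE, CORE, EXTERIOR, GAP, PHANTOM,
                       Geometry, PhantomSpec, PhotonState)
from .materials import Material, standard_material

PHANTOM_CHOICES = ("water", "pmma", "polystyrene", "solid_water", "rw1",
                   "air", "vacuum")


@dataclass
class RunConfig:
    """Configuration of one simulation run."""

    mode: str = "dose"  # dose | airkerma | spectrum
    phantom: str = "water"
    n_histories: int = 1_000_000
    seed: int = 1
    include_coherent: bool = False
    include_pair: bool = True
    spectrum_radii: tuple = ()  # cm; defaults depend on the medium

    def __post_init__(self):
        if self.mode not in ("dose", "airkerma", "spectrum"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.phantom not in PHANTOM_CHOICES:
            raise ValueError(f"unknown phantom {self.phantom!r}; "
                             f"choose from {PHANTOM_CHOICES}")
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spectrum_radii" in raw:
            raw["spectrum_radii"] = tuple(raw["spectrum_radii"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectrum_radii"] = list(self.spectrum_radii)
        return d

    def phantom_spec(self) -> PhantomSpec:
        if self.mode == "dose":
            return PhantomSpec.dose_cylinder(self.phantom)
        if self.mode == "airkerma":
            return PhantomSpec.air_kerma_sphere(self.phantom)
        return PhantomSpec.spectrum_sphere(self.phantom)


def region_material_map(phantom_medium: str) -> dict[int, Material | None]:
    """Material of each geometry region; ``None`` marks vacuum."""
    medium = None if phantom_medium == "vacuum" else standard_material(phantom_medium)
    return {
        CORE: standard_material("cobalt"),
        GAP: standard_material("air"),
        CAPSULE: standard_material("steel316l"),
        CABLE: standard_material("steel316l"),
        PHANTOM: medium,
    }


def transport_mu(material: Material | None, E, include_coherent=False,
                 include_pair=True) -> float:
    """Linear attenuation coefficient used for free-path sampling (1/cm)."""
    if material is None:
        return 0.0
    mu = (material.mu_process(E, "photoelectric")
          + material.mu_process(E, "incoherent"))
    if include_coherent:
        mu = mu + material.mu_process(E, "coherent")
    if include_pair:
        mu = mu + material.mu_process(E, "pair")
    return float(mu)


def sample_free_path(material: Material, E: float,
                     rng: np.random.Generator) -> float:
    """Exponential free path with mean 1/mu_total (cm)."""
    mu = float(material.mu_total(E))
    return -math.log1p(-rng.random()) / mu


def _sample_thomson_cos(rng: np.random.Generator) -> float:
    # pdf proportional to 1 + cos^2
    while True:
        c = 2.0 * rng.random() - 1.0
        if rng.random() * 2.0 <= 1.0 + c * c:
            return c


def interact(state: PhotonState, material: Material,
             rng: np.random.Generator, include_coherent=False,
             include_pair=True) -> PhotonState | None:
    """Apply one collision to ``state`` in place.

    Returns a secondary photon (the second annihilation quantum of a pair
    event) or ``None``.
    """
    probs = {
        "photoelectric": float(material.mu_process(state.energy, "photoelectric")),
        "incoherent": float(material.mu_process(state.energy, "incoherent")),
    }
    if include_coherent:
        probs["coherent"] = float(material.mu_process(state.energy, "coherent"))
    if include_pair:
        probs["pair"] = float(material.mu_process(state.energy, "pair"))
    total = sum(probs.values())
    xi = rng.random() * total
    acc = 0.0
    for process, p in probs.items():
        acc += p
        if xi <= acc:
            break
    if process == "photoelectric":
        state.alive = False
        return None
    if process == "incoherent":
        e_new, d_new = compton.compton_scatter(state.energy, state.direction, rng)
        state.energy = e_new
        state.direction = d_new
        if e_new < CUTOFF_ENERGY:
            state.alive = False
        return None
    if process == "coherent":
        cos_t = _sample_thomson_cos(rng)
        phi = 2.0 * math.pi * rng.random()
        state.direction = compton.rotate_direction(state.direction, cos_t, phi)
        return None
    # pair production
    mu = 2.0 * rng.random() - 1.0
    psi = 2.0 * math.pi * rng.random()
    sin_t = math.sqrt(max(0.0, 1.0 - mu * mu))
    d = np.array([sin_t * math.cos(psi), sin_t * math.sin(psi), mu])
    state.energy = MEC2
    state.direction = d
    return PhotonState(state.position.copy(), -d, MEC2, state.weight)


def transport_history(geometry: Geometry, region_materials: dict,
                      rng: np.random.Generator, ring_tally=None,
                      detectors=None, include_coherent=False,
                      include_pair=True, source_state: PhotonState = None,
                      max_steps: int = 10_000) -> int:
    """Track one source photon (and any pair secondaries) to termination.

    Flight segments inside the phantom are scored into ``ring_tally``;
    emission and collision events contribute to next-event ``detectors``.
    Returns the number of collisions.
    """
    from .tallies import point_detector_contribution

    state = source_state or geometry.sample_source_photon(rng)
    if detectors:
        for det in detectors:
            det.add(point_detector_contribution(
                "emission", state.position, state.energy, state.direction,
                det, geometry, region_materials))
    stack = [state]
    n_collisions = 0
    while stack:
        s = stack.pop()
        for _ in range(max_steps):
            if not s.alive:
                break
            region = geometry.locate(s.position, direction=s.direction)
            if region == EXTERIOR:
                break
            material = region_materials.get(region)
            mu = transport_mu(material, s.energy, include_coherent, include_pair)
            t_bound, _next = geometry.distance_to_boundary(s.position, s.direction)
            path = math.inf if mu <= 0 else -math.log1p(-rng.random()) / mu
            step = min(path, t_bound)
            if not math.isfinite(step):
                break
            if region == PHANTOM and ring_tally is not None:
                ring_tally.score_segment(s.position, s.direction, step,
                                         s.energy, s.weight)
            s.position = s.position + step * s.direction
            if path < t_bound:
                n_collisions += 1
                if detectors:
                    _score_collision_to_detectors(
                        s, material, detectors, geometry, region_materials,
                        include_coherent, include_pair)
                secondary = interact(s, material, rng, include_coherent,
                                     include_pair)
                if secondary is not None:
                    stack.append(secondary)
    return n_collisions


def _score_collision_to_detectors(state, material, detectors, geometry,
                                  region_materials, include_coherent,
                                  include_pair):
    """Expected next-event contribution of a collision, before sampling its
    outcome: scatter pdf towards the detector weighted by the scatter
    probability (unbiased for analog transport)."""
    from .tallies import point_detector_contribution

    E = state.energy
    p = {proc: float(material.mu_process(E, proc))
         for proc in ("photoelectric", "incoherent")}
    if include_coherent:
        p["coherent"] = float(material.mu_process(E, "coherent"))
    if include_pair:
        p["pair"] = float(material.mu_process(E, "pair"))
    total = sum(p.values())
    for det in detectors:
        contrib = (p["incoherent"] / total) * point_detector_contribution(
            "compton", state.position, E, state.direction, det, geometry,
            region_materials)
        if include_pair and p.get("pair", 0.0) > 0:
            contrib += (p["pair"] / total) * 2.0 * point_detector_contribution(
                "emission", state.position, MEC2, state.direction, det,
                geometry, region_materials)
        det.add(contrib)


def run(config: RunConfig) -> dict:
    """Execute a configured run through the compiled engine.

    Returns a dict with ``meta`` and, depending on the mode, ``cells``
    (ring-tally DataFrame), ``detectors`` (point-detector DataFrame) and
    ``spectra`` (normalized fluence spectra).  Identical configurations and
    seeds give identical outputs.
    """
    from . import engine
    return engine.run(config)
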