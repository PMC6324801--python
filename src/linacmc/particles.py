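"""Particle containers: a scalar ParticleState and a vectorised batch.

The Monte-Carlo engine works on structure-of-arrays batches; ParticleState is
the single-particle view used at API boundaries (phase-space records, head
transmission of individual particles).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHOTON, ELECTRON, POSITRON = 0, 1, 2
KIND_NAMES = {PHOTON: "photon", ELECTRON: "electron", POSITRON: "positron"}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


@dataclass
class ParticleState:
    """One in-flight particle.

    Positions are in cm, energies in MeV, ``direction`` is a unit vector and
    ``weight`` a positive statistical weight.
    """

    kind: str
    energy: float
    position: tuple
    direction: tuple
    weight: float = 1.0

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        d = np.asarray(self.direction, dtype=float)
        if abs(float(d @ d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown particle kind {self.kind!r}")


@dataclass
class ParticleBatch:
    """Structure-of-arrays batch of particles (engine workhorse)."""

    kind: np.ndarray  # uint8 codes
    energy: np.ndarray  # MeV
    x: np.ndarray  # cm
    y: np.ndarray
    z: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    weight: np.ndarray

    def __len__(self):
        return self.energy.size

    @classmethod
    def empty(cls):
        f = lambda: np.empty(0, dtype=np.float64)
        return cls(np.empty(0, dtype=np.uint8), f(), f(), f(), f(), f(), f(), f(), f())

    @classmethod
    def photons(cls, energy, x, y, z, ux, uy, uz, weight):
        n = energy.size
        return cls(np.zeros(n, dtype=np.uint8), energy, x, y, z, ux, uy, uz, weight)

    def copy(self) -> "ParticleBatch":
        return ParticleBatch(*(getattr(self, n).copy() for n in (
            "kind", "energy", "x", "y", "z", "ux", "uy", "uz", "weight")))

    def select(self, mask_or_idx) -> "ParticleBatch":
        m = mask_or_idx
        return ParticleBatch(
            self.kind[m], self.energy[m], self.x[m], self.y[m], self.z[m],
            self.ux[m], self.uy[m], self.uz[m], self.weight[m],
        )

    @staticmethod
    def concatenate(batches) -> "ParticleBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            return ParticleBatch.empty()
        cat = lambda name: np.concatenate([getattr(b, name) for b in batches])
        return ParticleBatch(*(cat(n) for n in (
            "kind", "energy", "x", "y", "z", "ux", "uy", "uz", "weight")))

    def states(self):
        """Materialise as a list of ParticleState (small batches only)."""
        return [
            ParticleState(
                KIND_NAMES[int(self.kind[i])],
                float(self.energy[i]),
                (float(self.x[i]), float(self.y[i]), float(self.z[i])),
                (float(self.ux[i]), float(self.uy[i]), float(self.uz[i])),
                float(self.weight[i]),
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_states(cls, states) -> "ParticleBatch":
        n = len(states)
        b = cls(
            np.empty(n, dtype=np.uint8), *(np.empty(n) for _ in range(8))
        )
        for i, s in enumerate(states):
            b.kind[i] = KIND_CODES[s.kind]
            b.energy[i] = s.energy
            b.x[i], b.y[i], b.z[i] = s.position
            b.ux[i], b.uy[i], b.uz[i] = s.direction
            b.weight[i] = s.weight
        return b


def rotate_directions(ux, uy, uz, theta, phi):
    """Rotate unit vectors by polar angle ``theta`` about themselves.

    Deflects each direction by ``theta`` towards an azimuth ``phi`` measured
    in the plane perpendicular to the incoming direction (standard MC
    direction-change transform, stable near uz = +-1).
    """
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    sin_p = np.sin(phi)
    cos_p = np.cos(phi)
    # orthonormal frame (a, b, u)
    near_pole = np.abs(uz) > 0.999999
    inv = 1.0 / np.sqrt(np.where(near_pole, 1.0, 1.0 - uz**2))
    ax = np.where(near_pole, 1.0, -uy * inv)
    ay = np.where(near_pole, 0.0, ux * inv)
    az = np.zeros_like(uz)
    # b = u x a
    bx = uy * az - uz * ay
    by = uz * ax - ux * az
    bz = ux * ay - uy * ax
    vx = sin_t * (cos_p * ax + sin_p * bx) + cos_t * ux
    vy = sin_t * (cos_p * ay + sin_p * by) + cos_t * uy
    vz = sin_t * (cos_p * az + sin_p * bz) + cos_t * uz
    norm = 1.0 / np.sqrt(vx**2 + vy**2 + vz**2)
    return vx * norm, vy * norm, vz * norm
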