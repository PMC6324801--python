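"""Phase-space files (.bpsf): compact binary format and recycling.

A phase space stores the particles crossing a fixed plane above the jaws so
it can be replayed as a virtual source.  The on-disk layout is little-endian:

    offset  size  field
    0       8     magic  b"BPSF0001"
    8       2     format version (uint16, = 1)
    10      8     plane z position, cm (float64)
    18      8     n_original_histories (uint64)
    26      8     particle count (uint64)
    34      32    source/head configuration hash (raw bytes, caller-defined)
    66      4     CRC32 of bytes 0..65 (uint32)
    70      29*N  records

Each record: kind (uint8: 0 photon, 1 electron, 2 positron), energy MeV
(float32), x, y in mm (float32), direction cosines u, v, w (float32), weight
(float32).  Downward travel means w > 0.  Record fields are stored at
float32 precision; the in-memory PhaseSpace holds float32 so a write/read
round trip is bit-lossless.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .particles import PHOTON, ParticleBatch

MAGIC = b"BPSF0001"
_VERSION = 1
_HEADER_SIZE = 70

RECORD_DTYPE = np.dtype([
    ("kind", "u1"), ("energy", "<f4"), ("x_mm", "<f4"), ("y_mm", "<f4"),
    ("u", "<f4"), ("v", "<f4"), ("w", "<f4"), ("weight", "<f4"),
])


class PSFFormatError(ValueError):
    """Malformed or truncated phase-space file."""


@dataclass
class PhaseSpace:
    """In-memory phase space: header fields plus a structured record array."""

    plane_z: float
    n_original_histories: int
    records: np.ndarray  # RECORD_DTYPE
    config_hash: bytes = b"\x00" * 32

    def __post_init__(self):
        if self.records.dtype != RECORD_DTYPE:
            self.records = self.records.astype(RECORD_DTYPE)
        if np.any(self.records["w"] <= 0):
            raise PSFFormatError("all records must travel downward (w > 0)")
        if np.any(self.records["energy"] <= 0):
            raise PSFFormatError("all record energies must be positive")
        if len(self.config_hash) != 32:
            raise ValueError("config_hash must be 32 bytes")

    def __len__(self):
        return self.records.size

    @classmethod
    def from_batch(cls, batch: ParticleBatch, plane_z: float,
                   n_original_histories: int,
                   config_hash: bytes = b"\x00" * 32) -> "PhaseSpace":
        keep = batch.uz > 0
        batch = batch.select(keep)
        rec = np.empty(len(batch), dtype=RECORD_DTYPE)
        rec["kind"] = batch.kind
        rec["energy"] = batch.energy
        rec["x_mm"] = batch.x * 10.0
        rec["y_mm"] = batch.y * 10.0
        rec["u"] = batch.ux
        rec["v"] = batch.uy
        rec["w"] = batch.uz
        rec["weight"] = batch.weight
        return cls(plane_z, n_original_histories, rec, config_hash)

    def to_batch(self, idx=slice(None)) -> ParticleBatch:
        r = self.records[idx]
        # re-normalise float32-rounded direction cosines
        norm = np.sqrt(r["u"].astype(float)**2 + r["v"].astype(float)**2
                       + r["w"].astype(float)**2)
        return ParticleBatch(
            kind=r["kind"].copy(),
            energy=r["energy"].astype(float),
            x=r["x_mm"].astype(float) / 10.0,
            y=r["y_mm"].astype(float) / 10.0,
            z=np.full(r.size, self.plane_z),
            ux=r["u"] / norm, uy=r["v"] / norm, uz=r["w"] / norm,
            weight=r["weight"].astype(float),
        )

    def spectrum_summary(self) -> dict:
        ph = self.records["kind"] == PHOTON
        out = {"n_records": int(self.records.size),
               "plane_z_cm": float(self.plane_z),
               "n_original_histories": int(self.n_original_histories)}
        for name, mask in (("photon", ph), ("electron", ~ph)):
            w = self.records["weight"][mask].astype(float)
            e = self.records["energy"][mask].astype(float)
            out[f"{name}_weight_per_primary"] = float(
                w.sum() / self.n_original_histories)
            out[f"{name}_mean_energy_mev"] = (
                float((w * e).sum() / w.sum()) if w.sum() > 0 else float("nan"))
        return out


def write_psf(path, ps: PhaseSpace):
    """Write a phase space to the .bpsf binary format."""
    header = bytearray()
    header += MAGIC
    header += np.uint16(_VERSION).tobytes()
    header += np.float64(ps.plane_z).tobytes()
    header += np.uint64(ps.n_original_histories).tobytes()
    header += np.uint64(len(ps)).tobytes()
    header += ps.config_hash
    crc = zlib.crc32(bytes(header))
    header += np.uint32(crc).tobytes()
    assert len(header) == _HEADER_SIZE
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        ps.records.tofile(fh)


def read_psf(path) -> PhaseSpace:
    """Read and validate a .bpsf file; raises PSFFormatError with the byte
    offset of the first inconsistency."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise PSFFormatError(
                f"truncated header: file ends at byte {len(header)}, "
                f"expected {_HEADER_SIZE}")
        if header[:8] != MAGIC:
            raise PSFFormatError("bad magic at byte 0")
        version = int(np.frombuffer(header, "<u2", 1, 8)[0])
        if version != _VERSION:
            raise PSFFormatError(f"unsupported version {version} at byte 8")
        stored_crc = int(np.frombuffer(header, "<u4", 1, 66)[0])
        if zlib.crc32(header[:66]) != stored_crc:
            raise PSFFormatError("header checksum mismatch at byte 66")
        plane_z = float(np.frombuffer(header, "<f8", 1, 10)[0])
        n_orig = int(np.frombuffer(header, "<u8", 1, 18)[0])
        count = int(np.frombuffer(header, "<u8", 1, 26)[0])
        config_hash = header[34:66]
        records = np.fromfile(fh, dtype=RECORD_DTYPE)
    if records.size != count:
        raise PSFFormatError(
            f"record count mismatch: header declares {count}, file holds "
            f"{records.size} (payload starts at byte {_HEADER_SIZE})")
    return PhaseSpace(plane_z, n_orig, records, config_hash)


def export_csv(ps: PhaseSpace, path):
    """Human-readable CSV export for inspection."""
    with open(path, "w") as fh:
        fh.write(f"# plane_z_cm={ps.plane_z} "
                 f"n_original_histories={ps.n_original_histories}\n")
        fh.write("kind,energy_mev,x_mm,y_mm,u,v,w,weight\n")
        for r in ps.records:
            fh.write(f"{int(r['kind'])},{r['energy']:.7g},{r['x_mm']:.7g},"
                     f"{r['y_mm']:.7g},{r['u']:.7g},{r['v']:.7g},"
                     f"{r['w']:.7g},{r['weight']:.7g}\n")


def recycle(ps: PhaseSpace, factor: int, rng, batch: int = 0,
            n_batches: int = 1, jaw_z: float = 30.0, chunk: int = 1_000_000):
    """Yield the phase-space stream recycled ``factor`` times.

    Each record is emitted ``factor`` times; every emission beyond plain
    replay gets an independently re-randomised azimuthal rotation about the
    CAX (position and direction rotated together), exploiting the rotational
    symmetry of the beam line above the jaws.  With ``factor == 1`` the
    stream is the plain record list (rotation disabled).  The equivalent
    history count is ``n_original_histories * factor``.
    """
    if factor < 1:
        raise ValueError("recycle factor must be >= 1")
    if ps.plane_z >= jaw_z:
        raise ValueError(
            "azimuthal-rotation recycling requires a PSF plane above the "
            f"jaws (plane z={ps.plane_z} cm, jaws at z={jaw_z} cm)")
    edges = np.linspace(0, len(ps), n_batches + 1).astype(int)
    lo, hi = edges[batch], edges[batch + 1]
    for start in range(lo, hi, chunk):
        base = ps.to_batch(slice(start, min(start + chunk, hi)))
        for rep in range(factor):
            if factor == 1:
                yield base
                continue
            b = base.copy()
            phi = rng.random(len(b)) * 2.0 * np.pi
            c, s = np.cos(phi), np.sin(phi)
            b.x, b.y = c * b.x - s * b.y, s * b.x + c * b.y
            b.ux, b.uy = c * b.ux - s * b.uy, s * b.ux + c * b.uy
            yield b
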