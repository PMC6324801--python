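"""Voxelised dose scoring, batch uncertainty, and scan-curve extraction.

Coordinates: lateral x, y in cm about the beam central axis (CAX); ``depth``
in cm below the phantom surface (surface at SSD).  Voxels are half-open
boxes [origin + i*delta, origin + (i+1)*delta); the CAX column is the voxel
column whose centre lies nearest the axis, ties broken towards +x/+y.

Grids store raw deposited energy (MeV) per batch; conversion to absorbed
dose per primary electron (Gy/primary) uses the voxel water mass and the
number of simulated primaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

MEV_TO_J = 1.602176634e-13
PHANTOM_HALF_CM = 20.0  # 40 x 40 x 40 cm^3 water phantom
PHANTOM_DEPTH_CM = 40.0


class VoxelSizeError(ValueError):
    """Operation requires a specific voxel size (e.g. surface dose at 1 mm)."""


@dataclass
class ScoringSpec:
    """Defines the scored sub-volume and resolution of a run."""

    voxel_mm: float = 5.0
    x_range: tuple = (-PHANTOM_HALF_CM, PHANTOM_HALF_CM)
    y_range: tuple = (-PHANTOM_HALF_CM, PHANTOM_HALF_CM)
    depth_range: tuple = (0.0, PHANTOM_DEPTH_CM)
    cyl_radius_cm: Optional[float] = 1.0  # CAX cylindrical depth tally
    cyl_voxel_mm: float = 5.0

    def __post_init__(self):
        if self.voxel_mm not in (5.0, 1.0):
            raise VoxelSizeError("voxel size must be 5 mm or 1 mm")

    def grid_shape(self):
        d = self.voxel_mm / 10.0
        nx = int(round((self.x_range[1] - self.x_range[0]) / d))
        ny = int(round((self.y_range[1] - self.y_range[0]) / d))
        nd = int(round((self.depth_range[1] - self.depth_range[0]) / d))
        return nx, ny, nd


def _nearest_index(centers: np.ndarray, value: float) -> int:
    """Index of the centre nearest ``value``; ties broken towards +."""
    d = np.abs(centers - value)
    return int(np.flatnonzero(d <= d.min() + 1e-12)[-1])


@dataclass
class ScanCurve:
    """A 1-D sampled dose curve (depth dose or lateral profile)."""

    positions: np.ndarray  # mm, strictly increasing
    values: np.ndarray  # Gy/primary (raw) or % (normalised)
    kind: str  # "depth" or "lateral"
    normalization: str = "raw"  # raw | dmax | cax | fff_renorm
    uncertainty_pct: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.kind not in ("depth", "lateral"):
            raise ValueError("kind must be 'depth' or 'lateral'")

    def interp(self, positions_mm):
        return np.interp(np.asarray(positions_mm, dtype=float),
                         self.positions, self.values)

    def normalized(self, mode: str = "max") -> "ScanCurve":
        """Return a copy normalised to 100% at the maximum (``max``) or at
        the central-axis position (``cax``, lateral profiles)."""
        if mode == "max":
            ref = float(np.max(self.values))
            label = "dmax" if self.kind == "depth" else "cax"
        elif mode == "cax":
            ref = float(self.interp(0.0))
            label = "cax"
        else:
            raise ValueError("mode must be 'max' or 'cax'")
        if ref <= 0:
            raise ValueError("cannot normalise a non-positive curve")
        return ScanCurve(self.positions, self.values / ref * 100.0, self.kind,
                         label, self.uncertainty_pct, dict(self.meta))

    def smoothed(self, window: int = 5, polyorder: int = 2) -> "ScanCurve":
        from scipy.signal import savgol_filter
        window = min(window, self.values.size - (1 - self.values.size % 2))
        if window < polyorder + 2:
            return self
        v = savgol_filter(self.values, window, polyorder)
        return ScanCurve(self.positions, v, self.kind, self.normalization,
                         self.uncertainty_pct, dict(self.meta))

    # ------------------------- CSV dialect ------------------------- #
    def to_csv(self, path):
        """Two-column water-tank dialect: position mm, dose value."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} normalization={self.normalization}\n")
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key}={val}\n")
            fh.write("position_mm,value\n")
            for p, v in zip(self.positions, self.values):
                fh.write(f"{p:.6g},{v:.8g}\n")

    @classmethod
    def from_csv(cls, path) -> "ScanCurve":
        kind, norm, meta = "depth", "raw", {}
        pos, val = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            if k == "kind":
                                kind = v
                            elif k == "normalization":
                                norm = v
                            else:
                                meta[k] = v
                    continue
                if line.startswith("position"):
                    continue
                p, v = line.split(",")
                pos.append(float(p))
                val.append(float(v))
        return cls(np.array(pos), np.array(val), kind, norm, None, meta)


@dataclass
class DoseGrid:
    """Voxelised energy deposition with per-batch sub-sums."""

    spec: ScoringSpec
    batch_energy: np.ndarray  # (n_batches, nx, ny, nd), deposited MeV
    n_histories: int

    def __post_init__(self):
        if self.batch_energy.ndim != 4:
            raise ValueError("batch_energy must be (batches, nx, ny, nd)")

    @property
    def n_batches(self) -> int:
        return self.batch_energy.shape[0]

    @property
    def voxel_cm(self) -> float:
        return self.spec.voxel_mm / 10.0

    def axis_centers(self, axis: str) -> np.ndarray:
        lo, hi = {"x": self.spec.x_range, "y": self.spec.y_range,
                  "depth": self.spec.depth_range}[axis]
        n = {"x": 0, "y": 1, "depth": 2}[axis]
        size = self.batch_energy.shape[1 + n]
        return lo + (np.arange(size) + 0.5) * self.voxel_cm

    def dose_per_primary(self) -> np.ndarray:
        """Mean absorbed dose per primary electron (Gy) per voxel."""
        mass_kg = self.voxel_cm**3 * 1e-3  # water, 1 g/cm^3
        return (self.batch_energy.sum(axis=0) * MEV_TO_J
                / mass_kg / self.n_histories)

    def to_hdf5(self, path):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("batch_energy", data=self.batch_energy,
                              compression="gzip")
            fh.attrs["n_histories"] = self.n_histories
            fh.attrs["voxel_mm"] = self.spec.voxel_mm
            for name in ("x_range", "y_range", "depth_range"):
                fh.attrs[name] = getattr(self.spec, name)
            fh.attrs["cyl_radius_cm"] = self.spec.cyl_radius_cm or 0.0

    @classmethod
    def from_hdf5(cls, path) -> "DoseGrid":
        with h5py.File(path, "r") as fh:
            spec = ScoringSpec(
                voxel_mm=float(fh.attrs["voxel_mm"]),
                x_range=tuple(fh.attrs["x_range"]),
                y_range=tuple(fh.attrs["y_range"]),
                depth_range=tuple(fh.attrs["depth_range"]),
                cyl_radius_cm=float(fh.attrs["cyl_radius_cm"]) or None,
            )
            return cls(spec, fh["batch_energy"][...],
                       int(fh.attrs["n_histories"]))


@dataclass
class CylindricalTally:
    """Depth tally over a CAX cylinder (low-noise PDD estimator)."""

    radius_cm: float
    voxel_mm: float
    depth_range: tuple
    batch_energy: np.ndarray  # (n_batches, nd) MeV
    n_histories: int

    def depth_centers(self) -> np.ndarray:
        d = self.voxel_mm / 10.0
        n = self.batch_energy.shape[1]
        return self.depth_range[0] + (np.arange(n) + 0.5) * d

    def pdd(self) -> ScanCurve:
        mass_kg = np.pi * self.radius_cm**2 * self.voxel_mm / 10.0 * 1e-3
        mean = self.batch_energy.sum(axis=0) * MEV_TO_J / mass_kg / self.n_histories
        unc = _batch_rel_sigma_pct(self.batch_energy)
        return ScanCurve(self.depth_centers() * 10.0, mean, "depth", "raw",
                         unc, {"tally": f"cyl_r{self.radius_cm:g}cm"})


def _batch_rel_sigma_pct(batch: np.ndarray) -> np.ndarray:
    """Standard error of the mean over batches, relative to the mean, %."""
    nb = batch.shape[0]
    mean = batch.mean(axis=0)
    if nb < 2:
        return np.full(mean.shape, np.nan)
    sem = batch.std(axis=0, ddof=1) / np.sqrt(nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sem / mean * 100.0, 0.0)
    return rel


# ---------------------------------------------------------------------- #
# extraction operations
# ---------------------------------------------------------------------- #
def extract_pdd(grid: DoseGrid, lateral_offset_cm: float = 0.0) -> ScanCurve:
    """Depth-dose along the (possibly shifted) vertical column.

    A nonzero ``lateral_offset_cm`` is applied to *both* x and y (the
    off-axis convention: n cm OAD means an n cm shift along each lateral
    axis, i.e. a geometric radius of n*sqrt(2)).  Raw values in Gy/primary.
    """
    cx = grid.axis_centers("x")
    cy = grid.axis_centers("y")
    off = lateral_offset_cm
    if not (cx[0] - grid.voxel_cm / 2 <= off <= cx[-1] + grid.voxel_cm / 2
            and cy[0] - grid.voxel_cm / 2 <= off <= cy[-1] + grid.voxel_cm / 2):
        raise ValueError(f"lateral offset {off} cm outside scored region")
    ix = _nearest_index(cx, off)
    iy = _nearest_index(cy, off)
    col = grid.batch_energy[:, ix, iy, :]  # (nb, nd)
    mass_kg = grid.voxel_cm**3 * 1e-3
    mean = col.sum(axis=0) * MEV_TO_J / mass_kg / grid.n_histories
    return ScanCurve(grid.axis_centers("depth") * 10.0, mean, "depth", "raw",
                     _batch_rel_sigma_pct(col),
                     {"lateral_offset_cm": off})


def extract_profile(grid: DoseGrid, depth_cm: float, axis: str = "x",
                    average_rows: int = 1, average_slabs: int = 1
                    ) -> ScanCurve:
    """Lateral profile at the voxel layer containing ``depth_cm``.

    By default a single voxel row is used (no perpendicular averaging).  At
    desk-scale history counts the optional ``average_rows``/``average_slabs``
    average the neighbouring perpendicular rows / depth slabs to tame
    Monte-Carlo noise; both default to 1.
    """
    cd = grid.axis_centers("depth")
    if not (grid.spec.depth_range[0] <= depth_cm <= grid.spec.depth_range[1]):
        raise ValueError(f"depth {depth_cm} cm outside scored region")
    idd = _nearest_index(cd, depth_cm)
    perp = "y" if axis == "x" else "x"
    cp = grid.axis_centers(perp)
    ip = _nearest_index(cp, 0.0)

    def around(i, n, size):
        lo = max(0, i - (n - 1) // 2)
        return slice(lo, min(size, lo + n))

    shp = grid.batch_energy.shape
    srow = around(ip, average_rows, shp[2] if axis == "x" else shp[1])
    sslab = around(idd, average_slabs, shp[3])
    if axis == "x":
        block = grid.batch_energy[:, :, srow, :][:, :, :, sslab]
        col = block.mean(axis=(2, 3))
    else:
        block = grid.batch_energy[:, srow, :, :][:, :, :, sslab]
        col = block.mean(axis=(1, 3))
    mass_kg = grid.voxel_cm**3 * 1e-3
    mean = col.sum(axis=0) * MEV_TO_J / mass_kg / grid.n_histories
    return ScanCurve(grid.axis_centers(axis) * 10.0, mean, "lateral", "raw",
                     _batch_rel_sigma_pct(col),
                     {"depth_cm": depth_cm, "axis": axis})


def surface_dose(grid: DoseGrid, cax_radius_mm: float = 0.0) -> float:
    """Surface dose: first-millimetre CAX dose as a percent of CAX dmax.

    Requires a 1 mm grid (the coarse 5 mm grid cannot resolve the air-skin
    boundary and disagrees with the buildup-region result by construction).
    ``cax_radius_mm > 0`` averages each depth layer over a CAX disk of that
    radius, trading lateral resolution for counting statistics.
    """
    if grid.spec.voxel_mm != 1.0:
        raise VoxelSizeError("surface dose requires a 1 mm voxel grid")
    curve = buildup_curve(grid, cax_radius_mm)
    return float(curve.values[0] / np.max(curve.values) * 100.0)


def buildup_curve(grid: DoseGrid, cax_radius_mm: float = 0.0) -> ScanCurve:
    """CAX depth-dose from a 1 mm grid, optionally disk-averaged."""
    if cax_radius_mm <= 0:
        return extract_pdd(grid)
    cx = grid.axis_centers("x")
    cy = grid.axis_centers("y")
    rr = np.hypot(*np.meshgrid(cx, cy, indexing="ij")) * 10.0
    mask = rr <= cax_radius_mm
    col = grid.batch_energy[:, mask, :].sum(axis=1)  # (nb, nd)
    mass_kg = grid.voxel_cm**3 * 1e-3 * mask.sum()
    mean = col.sum(axis=0) * MEV_TO_J / mass_kg / grid.n_histories
    return ScanCurve(grid.axis_centers("depth") * 10.0, mean, "depth", "raw",
                     _batch_rel_sigma_pct(col),
                     {"cax_radius_mm": cax_radius_mm})


def estimate_uncertainty(grid: DoseGrid) -> np.ndarray:
    """Per-voxel relative standard error (%), batch method."""
    if grid.n_batches < 2:
        raise ValueError("uncertainty estimation requires >= 2 batches")
    return _batch_rel_sigma_pct(grid.batch_energy)
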