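"""Synthetic water-tank reference data with known analytic structure.

Emulates scanned beam data: a buildup-then-exponential depth dose with the
inverse-square divergence of an SSD-100 geometry, and lateral profiles built
from error-function penumbrae under a flat top (flattened beam) or a conical
peak (unflattened beam), sampled on a 1 mm grid with additive Gaussian
noise.  Every metric in :mod:`linacmc.metrics` has a closed-form value on
these curves, so the analysis pipeline is testable without measurements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .scoring import ScanCurve

ERF_PENUMBRA_FACTOR = 1.6832425  # (x20 - x80) = factor * sigma, erf edge


@dataclass
class SyntheticBeamModel:
    """Parameters of the emulated beam data."""

    # depth dose
    dmax_mm: float = 19.0
    mu_eff_cm: float = 0.0359  # effective exponential falloff, 1/cm
    ssd_cm: float = 100.0
    # profiles
    field_size_mm: float = 100.0
    penumbra_sigma_mm: float = 4.0  # erf edge scale
    mode: str = "fff"  # "fff" (conical peak) or "flat"
    cone_coeff_per_mm: float = 0.0033  # linear cone 1 - c|x| (fff)
    cone_quadratic: bool = False
    flat_ripple_pct: float = 0.0  # cosine ripple on the flat top
    asymmetry_per_mm: float = 0.0  # multiplies (1 + a x)
    # sampling
    noise_pct: float = 0.3
    step_mm: float = 1.0
    depth_max_mm: float = 320.0
    profile_half_mm: float = 120.0
    profile_depths_cm: tuple = (1.9, 10.0)

    def __post_init__(self):
        if min(self.dmax_mm, self.mu_eff_cm, self.field_size_mm,
               self.penumbra_sigma_mm, self.step_mm) <= 0:
            raise ValueError("scales must be positive")
        if self.noise_pct < 0:
            raise ValueError("noise must be non-negative")
        if self.mode not in ("fff", "flat"):
            raise ValueError("mode must be 'fff' or 'flat'")

    # ----------------------- analytic forms ----------------------- #
    def buildup_rate(self) -> float:
        """Rate b of the buildup term 1 - exp(-b z) placing the maximum of
        the full depth-dose expression at dmax."""
        mu = self.mu_eff_cm
        d = self.dmax_mm / 10.0
        ssd = self.ssd_cm

        def opt(b):
            return b * np.exp(-b * d) / (1.0 - np.exp(-b * d)) \
                - mu - 2.0 / (ssd + d)

        return brentq(opt, 1e-3, 60.0)

    def pdd_analytic(self, depth_mm) -> np.ndarray:
        """Noise-free percentage depth dose (100% at dmax)."""
        z = np.asarray(depth_mm, dtype=float) / 10.0
        b = self.buildup_rate()
        ssd = self.ssd_cm
        raw = (1.0 - np.exp(-b * z)) * np.exp(-self.mu_eff_cm * z) \
            * (ssd / (ssd + z)) ** 2
        dm = self.dmax_mm / 10.0
        ref = (1.0 - np.exp(-b * dm)) * np.exp(-self.mu_eff_cm * dm) \
            * (ssd / (ssd + dm)) ** 2
        return raw / ref * 100.0

    def profile_analytic(self, x_mm, depth_cm: float = 10.0) -> np.ndarray:
        """Noise-free lateral profile (100% at CAX), geometric field-size
        scaling with depth."""
        x = np.asarray(x_mm, dtype=float)
        scale = (self.ssd_cm + depth_cm) / self.ssd_cm
        h = self.field_size_mm / 2.0 * scale
        s = self.penumbra_sigma_mm * np.sqrt(2.0)
        edges = 0.5 * (erf((h - x) / s) + erf((h + x) / s))
        cax = float(0.5 * 2.0 * erf(h / s))
        if self.mode == "fff":
            if self.cone_quadratic:
                shape = 1.0 - self.cone_coeff_per_mm * x**2 \
                    / (self.field_size_mm / 2.0)
            else:
                shape = 1.0 - self.cone_coeff_per_mm * np.abs(x) / scale
        else:
            shape = 1.0 + self.flat_ripple_pct / 100.0 * np.cos(
                2.0 * np.pi * x / max(h, 1.0))
        shape = np.maximum(shape, 0.05)
        asym = 1.0 + self.asymmetry_per_mm * x
        return edges * shape * asym / cax * 100.0


def generate_reference(model: SyntheticBeamModel, seed: int) -> dict:
    """Generate a deterministic set of reference scan curves.

    Returns ``{"pdd": ScanCurve, "profile_<depth>cm": ScanCurve, ...}`` with
    additive Gaussian noise of ``model.noise_pct`` percent points.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z = np.arange(0.5, model.depth_max_mm, model.step_mm)
    pdd_v = model.pdd_analytic(z)
    pdd_v = pdd_v + rng.normal(0.0, model.noise_pct, z.size)
    out = {"pdd": ScanCurve(z, pdd_v, "depth", "dmax",
                            np.full(z.size, model.noise_pct),
                            {"synthetic": True})}
    x = np.arange(-model.profile_half_mm, model.profile_half_mm + 0.5,
                  model.step_mm)
    for depth in model.profile_depths_cm:
        v = model.profile_analytic(x, depth)
        v = v + rng.normal(0.0, model.noise_pct, x.size)
        out[f"profile_{depth:g}cm"] = ScanCurve(
            x, v, "lateral", "cax", np.full(x.size, model.noise_pct),
            {"synthetic": True, "depth_cm": depth})
    return out


PRESETS = {
    "fff10": SyntheticBeamModel(dmax_mm=19.0, mu_eff_cm=0.0359,
                                field_size_mm=100.0, mode="fff"),
    "fff20": SyntheticBeamModel(dmax_mm=19.0, mu_eff_cm=0.0332,
                                field_size_mm=200.0, mode="fff",
                                cone_coeff_per_mm=0.0027,
                                profile_half_mm=220.0),
    "fff40": SyntheticBeamModel(dmax_mm=19.0, mu_eff_cm=0.0322,
                                field_size_mm=400.0, mode="fff",
                                cone_coeff_per_mm=0.0024,
                                profile_half_mm=420.0),
    "flat10": SyntheticBeamModel(dmax_mm=16.0, mu_eff_cm=0.0374,
                                 field_size_mm=100.0, mode="flat",
                                 profile_depths_cm=(1.6, 10.0)),
    "flat20": SyntheticBeamModel(dmax_mm=16.0, mu_eff_cm=0.0332,
                                 field_size_mm=200.0, mode="flat",
                                 profile_half_mm=220.0,
                                 profile_depths_cm=(1.6, 10.0)),
}


def simulator_as_reference(head, source, run, spec=None,
                           profile_depths_cm=(2.0, 10.0),
                           profile_rows: int = 15, profile_slabs: int = 5
                           ) -> dict:
    """Run the full simulator and export its curves in the reference
    dialect (normalised PDD + lateral profiles at the dmax region and at
    10 cm), for self-consistency harnesses such as source-tuning recovery."""
    from .scoring import ScoringSpec, extract_profile
    from .transport import run_simulation

    if spec is None:
        half = head.field_size_cm / 2.0 * 1.3 + 2.0
        spec = ScoringSpec(voxel_mm=5.0, x_range=(-half, half),
                           y_range=(-4.0, 4.0),
                           depth_range=(0.0, 32.0), cyl_radius_cm=3.0)
    res = run_simulation(head, source, run, spec)
    out = {"pdd": res.cax_pdd().normalized("max"), "result": res}
    for depth in profile_depths_cm:
        prof = extract_profile(res.grid, depth, "x",
                               average_rows=profile_rows,
                               average_slabs=profile_slabs).normalized("cax")
        out[f"profile_{depth:g}cm"] = prof
    return out


def write_reference(curves: dict, outdir):
    """Write a curve set in the scan-export CSV dialect."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, curve in curves.items():
        if not isinstance(curve, ScanCurve):
            continue
        p = os.path.join(outdir, f"{name}.csv")
        curve.to_csv(p)
        paths[name] = p
    return paths


def read_reference(indir) -> dict:
    import glob
    import os
    out = {}
    for p in sorted(glob.glob(os.path.join(indir, "*.csv"))):
        out[os.path.splitext(os.path.basename(p))[0]] = ScanCurve.from_csv(p)
    return out
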