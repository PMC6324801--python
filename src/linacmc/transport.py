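"""The Monte-Carlo engine: primaries -> head -> water phantom -> dose.

Vectorised structure-of-arrays transport.  Photons in water are sampled
analog (free path from the total attenuation coefficient, channel choice by
partial coefficients, Klein-Nishina Compton, local pair production with
equal energy split).  Electrons use condensed-history stepping: CSDA energy
loss along steps bounded by the voxel resolution, Gaussian (Highland)
multiple-scattering deflections, and local deposition of the residual energy
once the kinetic energy falls below the production-threshold energy derived
from the range cut (default 1 mm in water).  Radiative loss of electrons in
water is neglected (sub-percent below 10 MeV).

Randomness: one master seed; per-batch and per-chunk child streams are
derived with ``numpy.random.SeedSequence.spawn`` so batches are independent
and every run is reproducible bit-for-bit for a fixed configuration.
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import physics
from .head import (ELECTRON_CUT_MEV, PHOTON_CUT_MEV, HeadConfig, SourceConfig,
                   generate_target_photons, transmit_head_lower,
                   transmit_head_upper)
from .particles import (ELECTRON, PHOTON, POSITRON, ParticleBatch,
                        ParticleState, rotate_directions)
from .scoring import CylindricalTally, DoseGrid, ScanCurve, ScoringSpec

_ANNIHILATION_MEV = 2.0 * physics.ELECTRON_REST_MEV


@dataclass
class RunConfig:
    """Monte-Carlo run parameters."""

    n_histories: int = 1_000_000  # primary electrons
    seed: int = 0
    kill_electrons_above_phantom: bool = False
    cut_range_mm: float = 1.0
    batches: int = 10
    psf_capture: bool = False
    photons_per_electron: Optional[int] = None  # source splitting factor
    theta_cull: Optional[float] = None  # rad; None = auto from field size
    disable_scatter: bool = False  # attenuation-only oracle mode
    water_transport: bool = True
    chunk_primaries: Optional[int] = None

    def __post_init__(self):
        if self.n_histories < self.batches:
            raise ValueError("n_histories must be >= batches")
        if self.cut_range_mm <= 0:
            raise ValueError("cut_range must be positive")


@dataclass
class RunReport:
    """Bookkeeping summary of a simulation run."""

    n_histories: int
    seed: int
    batches: int
    dose_per_primary_10cm: Optional[float]  # Gy/primary at 10 cm CAX depth
    energy_entering: np.ndarray  # per batch, MeV (weighted)
    energy_deposited: np.ndarray
    energy_exiting: np.ndarray
    surface_photon_weight: float
    surface_electron_weight: float
    wall_time_s: float
    warnings: list = field(default_factory=list)

    def energy_balance_error(self) -> float:
        """Relative bookkeeping error |in - (dep + out)| / in, per run."""
        e_in = float(self.energy_entering.sum())
        if e_in == 0:
            return 0.0
        e_out = float(self.energy_deposited.sum() + self.energy_exiting.sum())
        return abs(e_in - e_out) / e_in


@dataclass
class SimulationResult:
    grid: Optional[DoseGrid]
    cyl: Optional[CylindricalTally]
    report: RunReport
    phase_space: Optional[object] = None  # PhaseSpace, set when captured

    def cax_pdd(self) -> ScanCurve:
        """Low-noise CAX depth dose (cylindrical tally when available)."""
        if self.cyl is not None:
            return self.cyl.pdd()
        from .scoring import extract_pdd
        return extract_pdd(self.grid)


# ---------------------------------------------------------------------- #
# water-stage accumulator
# ---------------------------------------------------------------------- #
class _Accumulator:
    def __init__(self, spec: ScoringSpec, n_batches: int):
        self.spec = spec
        nx, ny, nd = spec.grid_shape()
        self.shape = (nx, ny, nd)
        self.grid = np.zeros((n_batches, nx * ny * nd))
        if spec.cyl_radius_cm:
            ncd = int(round((spec.depth_range[1] - spec.depth_range[0])
                            / (spec.cyl_voxel_mm / 10.0)))
            self.cyl = np.zeros((n_batches, ncd))
        else:
            self.cyl = None
        self.e_in = np.zeros(n_batches)
        self.e_dep = np.zeros(n_batches)
        self.e_out = np.zeros(n_batches)

    def deposit(self, b, x, y, d, energy):
        """Score weighted energy deposits at (x, y, depth) in cm."""
        if energy.size == 0:
            return
        sp = self.spec
        self.e_dep[b] += float(energy.sum())
        vox = sp.voxel_mm / 10.0
        ok = ((x >= sp.x_range[0]) & (x < sp.x_range[1])
              & (y >= sp.y_range[0]) & (y < sp.y_range[1])
              & (d >= sp.depth_range[0]) & (d < sp.depth_range[1]))
        if np.any(ok):
            ix = ((x[ok] - sp.x_range[0]) / vox).astype(np.intp)
            iy = ((y[ok] - sp.y_range[0]) / vox).astype(np.intp)
            idd = ((d[ok] - sp.depth_range[0]) / vox).astype(np.intp)
            nx, ny, nd = self.shape
            np.clip(ix, 0, nx - 1, out=ix)
            np.clip(iy, 0, ny - 1, out=iy)
            np.clip(idd, 0, nd - 1, out=idd)
            flat = (ix * ny + iy) * nd + idd
            self.grid[b] += np.bincount(flat, weights=energy[ok],
                                        minlength=self.grid.shape[1])
        if self.cyl is not None:
            cvox = sp.cyl_voxel_mm / 10.0
            okc = (np.hypot(x, y) <= sp.cyl_radius_cm) \
                & (d >= sp.depth_range[0]) & (d < sp.depth_range[1])
            if np.any(okc):
                idd = ((d[okc] - sp.depth_range[0]) / cvox).astype(np.intp)
                np.clip(idd, 0, self.cyl.shape[1] - 1, out=idd)
                self.cyl[b] += np.bincount(idd, weights=energy[okc],
                                           minlength=self.cyl.shape[1])


# ---------------------------------------------------------------------- #
# water transport kernel
# ---------------------------------------------------------------------- #
_PHANTOM_HALF = 20.0
_PHANTOM_DEPTH = 40.0


def _inside(x, y, d):
    return ((np.abs(x) <= _PHANTOM_HALF) & (np.abs(y) <= _PHANTOM_HALF)
            & (d >= 0.0) & (d <= _PHANTOM_DEPTH))


class _ElectronBank:
    __slots__ = ("x", "y", "d", "ux", "uy", "uz", "e", "w", "pos")

    def __init__(self, x, y, d, ux, uy, uz, e, w, pos):
        self.x, self.y, self.d = x, y, d
        self.ux, self.uy, self.uz = ux, uy, uz
        self.e, self.w, self.pos = e, w, pos

    def __len__(self):
        return self.e.size

    @classmethod
    def empty(cls):
        z = np.empty(0)
        return cls(z, z, z, z, z, z, z, z, np.empty(0, dtype=bool))

    @classmethod
    def concat(cls, banks):
        banks = [b for b in banks if len(b)]
        if not banks:
            return cls.empty()
        g = lambda n: np.concatenate([getattr(b, n) for b in banks])
        return cls(g("x"), g("y"), g("d"), g("ux"), g("uy"), g("uz"),
                   g("e"), g("w"), g("pos"))

    def select(self, m):
        return _ElectronBank(self.x[m], self.y[m], self.d[m], self.ux[m],
                             self.uy[m], self.uz[m], self.e[m], self.w[m],
                             self.pos[m])


def _electron_sweeps(bank: _ElectronBank, rng, acc: _Accumulator, b: int,
                     e_threshold: float, step_cm: float):
    """Drain the electron bank; returns annihilation photons as a batch."""
    ann = []
    while len(bank):
        e = bank.e
        r0 = physics.WATER.csda_range(np.clip(e, 5e-4, 25.0))
        terminal = (e <= e_threshold) | (r0 <= step_cm)
        # terminal: deposit everything half a residual range ahead
        if np.any(terminal):
            t = bank.select(terminal)
            rt = np.minimum(r0[terminal], step_cm) * 0.5
            xm, ym, dm = t.x + t.ux * rt, t.y + t.uy * rt, t.d + t.uz * rt
            ins = _inside(xm, ym, dm)
            acc.deposit(b, xm[ins], ym[ins], dm[ins], t.e[ins] * t.w[ins])
            acc.e_out[b] += float((t.e[~ins] * t.w[~ins]).sum())
            if np.any(t.pos):
                p = t.select(t.pos)
                ann.append(_annihilate(p, rng))
        cont = bank.select(~terminal)
        if len(cont):
            r = r0[~terminal]
            e_new = physics.WATER.csda_energy(r - step_cm)
            de = cont.e - e_new
            xm = cont.x + cont.ux * step_cm * 0.5
            ym = cont.y + cont.uy * step_cm * 0.5
            dm = cont.d + cont.uz * step_cm * 0.5
            ins = _inside(xm, ym, dm)
            acc.deposit(b, xm[ins], ym[ins], dm[ins], de[ins] * cont.w[ins])
            acc.e_out[b] += float((de[~ins] * cont.w[~ins]).sum())
            cont.x = cont.x + cont.ux * step_cm
            cont.y = cont.y + cont.uy * step_cm
            cont.d = cont.d + cont.uz * step_cm
            # electrons leaving the phantom carry their residual energy out
            stay = _inside(cont.x, cont.y, cont.d)
            acc.e_out[b] += float((e_new[~stay] * cont.w[~stay]).sum())
            cont = cont.select(stay)
            e_new = e_new[stay]
            if len(cont):
                # Highland multiple scattering over the step
                p = np.sqrt(e_new * (e_new + 2.0 * physics.ELECTRON_REST_MEV))
                beta = p / (e_new + physics.ELECTRON_REST_MEV)
                xr = step_cm / physics.WATER.radiation_length
                th0 = 13.6e-3 / (beta * p * 1e-3) * np.sqrt(xr) * (
                    1.0 + 0.038 * np.log(xr))
                th0 = np.clip(th0, 0.0, 1.2)
                kick = np.abs(rng.normal(0.0, 1.0, len(cont))) * th0
                phi = rng.random(len(cont)) * 2.0 * np.pi
                cont.ux, cont.uy, cont.uz = rotate_directions(
                    cont.ux, cont.uy, cont.uz, kick, phi)
                cont.e = e_new
        bank = cont
    if ann:
        return ParticleBatch.concatenate(ann)
    return ParticleBatch.empty()


def _annihilate(p: _ElectronBank, rng) -> ParticleBatch:
    """Positron termination: two back-to-back 511 keV photons."""
    n = len(p)
    cos_t = rng.uniform(-1.0, 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.random(n) * 2.0 * np.pi
    ux = np.concatenate([sin_t * np.cos(phi), -sin_t * np.cos(phi)])
    uy = np.concatenate([sin_t * np.sin(phi), -sin_t * np.sin(phi)])
    uz = np.concatenate([cos_t, -cos_t])
    return ParticleBatch.photons(
        energy=np.full(2 * n, physics.ELECTRON_REST_MEV),
        x=np.tile(p.x, 2), y=np.tile(p.y, 2), z=np.tile(p.d, 2),  # z = depth
        ux=ux, uy=uy, uz=uz, weight=np.tile(p.w, 2))


def _water_stage(surface: ParticleBatch, rng, run: RunConfig,
                 acc: _Accumulator, b: int, ssd: float):
    """Transport a surface batch through the water phantom."""
    e_threshold = physics.range_cut_to_energy(physics.WATER, run.cut_range_mm)
    step_cm = min(0.1, acc.spec.voxel_mm / 10.0 * 0.5)

    is_ph = surface.kind == PHOTON
    ph = surface.select(is_ph)
    el_in = surface.select(~is_ph)
    acc.e_in[b] += float((surface.energy * surface.weight).sum())

    # photon bank in (x, y, depth)
    px, py, pd = ph.x.copy(), ph.y.copy(), ph.z - ssd
    pux, puy, puz = ph.ux.copy(), ph.uy.copy(), ph.uz.copy()
    pe, pw = ph.energy.copy(), ph.weight.copy()

    electrons = _ElectronBank(
        el_in.x.copy(), el_in.y.copy(), el_in.z - ssd,
        el_in.ux.copy(), el_in.uy.copy(), el_in.uz.copy(),
        el_in.energy.copy(), el_in.weight.copy(),
        el_in.kind == POSITRON)

    n_sweeps = 0
    while (pe.size or len(electrons)) and n_sweeps < 400:
        n_sweeps += 1
        new_electrons = [electrons]
        if pe.size:
            e_cl = np.clip(pe, 0.01, 20.0)
            photo, compton, pair = physics.WATER.channel_mass_coefficients(e_cl)
            mu = photo + compton + pair  # water density 1
            s = -np.log(rng.random(pe.size)) / mu
            px = px + s * pux
            py = py + s * puy
            pd = pd + s * puz
            stay = _inside(px, py, pd)
            acc.e_out[b] += float((pe[~stay] * pw[~stay]).sum())
            px, py, pd = px[stay], py[stay], pd[stay]
            pux, puy, puz = pux[stay], puy[stay], puz[stay]
            pe, pw = pe[stay], pw[stay]
            photo, compton, pair = (photo[stay], compton[stay], pair[stay])
            mu = mu[stay]

            if run.disable_scatter:
                acc.deposit(b, px, py, pd, pe * pw)
                px = np.empty(0); py = np.empty(0); pd = np.empty(0)
                pux = puy = puz = np.empty(0)
                pe = np.empty(0); pw = np.empty(0)
            elif pe.size:
                u = rng.random(pe.size) * mu
                is_pair = u >= photo + compton
                is_photo = u < photo
                is_compton = ~is_pair & ~is_photo

                dep_x, dep_y, dep_d, dep_e = [], [], [], []

                def bank_or_deposit(mask, energy, ux, uy, uz, positron=False):
                    """Secondaries below the production threshold deposit
                    locally; the rest enter the electron bank."""
                    hot = energy > e_threshold
                    cold = mask.copy()
                    cold[mask] = ~hot
                    hotm = mask.copy()
                    hotm[mask] = hot
                    if np.any(cold):
                        dep_x.append(px[cold]); dep_y.append(py[cold])
                        dep_d.append(pd[cold])
                        dep_e.append(energy[~hot] * pw[cold])
                    if np.any(hotm):
                        new_electrons.append(_ElectronBank(
                            px[hotm], py[hotm], pd[hotm],
                            ux[hot], uy[hot], uz[hot],
                            energy[hot], pw[hotm],
                            np.full(int(hot.sum()), positron, dtype=bool)))

                if np.any(is_compton):
                    ci = is_compton
                    e_sc, e_el, theta = physics.sample_compton(pe[ci], rng)
                    phi = rng.random(int(ci.sum())) * 2.0 * np.pi
                    th_e = physics.compton_electron_angle(pe[ci], theta)
                    ex, ey, ez = rotate_directions(pux[ci], puy[ci], puz[ci],
                                                   th_e, phi + np.pi)
                    bank_or_deposit(ci, e_el, ex, ey, ez)
                    nx_, ny_, nz_ = rotate_directions(pux[ci], puy[ci],
                                                      puz[ci], theta, phi)
                    pe[ci] = e_sc
                    pux[ci], puy[ci], puz[ci] = nx_, ny_, nz_

                if np.any(is_photo):
                    bank_or_deposit(is_photo, pe[is_photo],
                                    pux[is_photo], puy[is_photo],
                                    puz[is_photo])

                if np.any(is_pair):
                    pi = is_pair & (pe > _ANNIHILATION_MEV)
                    # below-threshold "pair" labels (interp noise) absorb
                    low = is_pair & ~pi
                    if np.any(low):
                        dep_x.append(px[low]); dep_y.append(py[low])
                        dep_d.append(pd[low]); dep_e.append(pe[low] * pw[low])
                    if np.any(pi):
                        t_half = (pe[pi] - _ANNIHILATION_MEV) * 0.5
                        for positron in (False, True):
                            bank_or_deposit(pi, t_half.copy(), pux[pi],
                                            puy[pi], puz[pi], positron)
                        # below-threshold positrons still annihilate; treat
                        # the cold ones as annihilating in place
                        cold_pos = pi.copy()
                        cold_pos[pi] = t_half <= e_threshold
                        if np.any(cold_pos):
                            nb = int(cold_pos.sum())
                            new_electrons.append(_ElectronBank(
                                px[cold_pos], py[cold_pos], pd[cold_pos],
                                pux[cold_pos], puy[cold_pos], puz[cold_pos],
                                np.full(nb, 1e-4), pw[cold_pos],
                                np.ones(nb, dtype=bool)))

                if dep_e:
                    acc.deposit(b, np.concatenate(dep_x),
                                np.concatenate(dep_y), np.concatenate(dep_d),
                                np.concatenate(dep_e))

                # photons that died (photo, pair) or went sub-cut
                died = is_photo | is_pair
                sub = ~died & (pe <= PHOTON_CUT_MEV)
                if np.any(sub):
                    acc.deposit(b, px[sub], py[sub], pd[sub], pe[sub] * pw[sub])
                keep = ~died & ~sub
                px, py, pd = px[keep], py[keep], pd[keep]
                pux, puy, puz = pux[keep], puy[keep], puz[keep]
                pe, pw = pe[keep], pw[keep]

        electrons = _ElectronBank.concat(new_electrons)
        ann = _electron_sweeps(electrons, rng, acc, b, e_threshold, step_cm)
        electrons = _ElectronBank.empty()
        if len(ann):
            px = np.concatenate([px, ann.x])
            py = np.concatenate([py, ann.y])
            pd = np.concatenate([pd, ann.z])
            pux = np.concatenate([pux, ann.ux])
            puy = np.concatenate([puy, ann.uy])
            puz = np.concatenate([puz, ann.uz])
            pe = np.concatenate([pe, ann.energy])
            pw = np.concatenate([pw, ann.weight])


# ---------------------------------------------------------------------- #
# orchestration
# ---------------------------------------------------------------------- #
def _auto_theta_cull(head: HeadConfig) -> float:
    """Jaw pre-culling angle: photons aimed well outside the jaw aperture
    diagonal can never reach the phantom (air rescatter is negligible), so
    the source samples only the useful cone, with an exact weight factor."""
    half_diag = head.field_size_cm / 2.0 * np.sqrt(2.0)
    return min(float(np.arctan((half_diag + 4.0) / head.ssd)),
               head.target.theta_max)


def _angular_cdf(theta, theta0, exponent):
    beta = 1.0 - exponent
    t = theta / theta0
    return (1.0 + t**2) ** beta - 1.0


def cull_weight_fraction(head: HeadConfig, source: SourceConfig,
                         theta_cull: float) -> float:
    """Weight of the angular distribution inside the sampling cone."""
    t = head.target
    theta0 = t.angular_scale * physics.ELECTRON_REST_MEV / (
        source.mean_energy + physics.ELECTRON_REST_MEV)
    return float(_angular_cdf(theta_cull, theta0, t.angular_exponent)
                 / _angular_cdf(t.theta_max, theta0, t.angular_exponent))


def _surface_batches(head: HeadConfig, source: SourceConfig, run: RunConfig,
                     rng, n_chunk: int, psf_records=None):
    """Generate one chunk of particles at the phantom surface."""
    from dataclasses import replace as _replace

    theta_cull = run.theta_cull
    if theta_cull is None:
        theta_cull = _auto_theta_cull(head)
    frac = cull_weight_fraction(head, source, theta_cull)
    tgt = _replace(head.target, theta_max=theta_cull)
    head_cull = _replace(head, target=tgt,
                         filter_profile=head.filter_profile)
    photons = generate_target_photons(source, head_cull, n_chunk, rng,
                                      run.photons_per_electron)
    photons.weight *= frac
    upper = transmit_head_upper(photons, head_cull, rng)
    if psf_records is not None:
        psf_records.append(upper)
    surface = transmit_head_lower(upper, head_cull, rng)
    if run.kill_electrons_above_phantom:
        surface = surface.select(surface.kind == PHOTON)
    return surface


def run_simulation(head: HeadConfig, source: SourceConfig, run: RunConfig,
                   spec: Optional[ScoringSpec] = None) -> SimulationResult:
    """Full chain: primary electrons -> head -> water phantom dose.

    Deterministic for a fixed (seed, configuration).  Returns the dose grid,
    the optional CAX cylindrical tally, a bookkeeping report, and, when
    ``run.psf_capture`` is set, the phase space collected at the plane above
    the jaws.
    """
    if spec is None:
        spec = ScoringSpec()
    head = head.ensure_filter()
    t0 = time.time()
    acc = _Accumulator(spec, run.batches)
    ss = np.random.SeedSequence(run.seed)
    batch_seeds = ss.spawn(run.batches)
    per_batch = np.full(run.batches, run.n_histories // run.batches)
    per_batch[: run.n_histories % run.batches] += 1

    psf_records = [] if run.psf_capture else None
    w_ph = w_el = 0.0
    m_split = run.photons_per_electron or 1
    chunk = run.chunk_primaries or max(1, int(2_000_000 // m_split))
    for b in range(run.batches):
        rng = np.random.default_rng(batch_seeds[b])
        left = int(per_batch[b])
        while left > 0:
            n = min(chunk, left)
            left -= n
            surface = _surface_batches(head, source, run, rng, n, psf_records)
            w_ph += float(surface.weight[surface.kind == PHOTON].sum())
            w_el += float(surface.weight[surface.kind != PHOTON].sum())
            if run.water_transport:
                _water_stage(surface, rng, run, acc, b, head.ssd)

    grid = DoseGrid(spec, acc.grid.reshape((run.batches,) + acc.shape),
                    run.n_histories)
    cyl = None
    if acc.cyl is not None:
        cyl = CylindricalTally(spec.cyl_radius_cm, spec.cyl_voxel_mm,
                               spec.depth_range, acc.cyl, run.n_histories)
    warn = []
    if run.water_transport and acc.e_dep.sum() == 0.0:
        warn.append("zero dose scored (closed jaws or empty beam?)")
        warnings.warn(warn[-1])
    dose10 = None
    if cyl is not None and acc.cyl.sum() > 0:
        pdd = cyl.pdd()
        dose10 = float(pdd.interp(100.0))
    report = RunReport(
        n_histories=run.n_histories, seed=run.seed, batches=run.batches,
        dose_per_primary_10cm=dose10,
        energy_entering=acc.e_in.copy(), energy_deposited=acc.e_dep.copy(),
        energy_exiting=acc.e_out.copy(),
        surface_photon_weight=w_ph, surface_electron_weight=w_el,
        wall_time_s=time.time() - t0, warnings=warn)

    phase_space = None
    if psf_records is not None:
        from .psf import PhaseSpace
        merged = ParticleBatch.concatenate(psf_records)
        phase_space = PhaseSpace.from_batch(merged, plane_z=head.psf_plane_z,
                                            n_original_histories=run.n_histories)
    return SimulationResult(grid, cyl, report, phase_space)


def run_surface_batch(surface: ParticleBatch, run: RunConfig,
                      spec: Optional[ScoringSpec] = None,
                      ssd: float = 100.0) -> SimulationResult:
    """Water-phantom transport of a prepared surface batch (oracle harness).

    The batch is split evenly over ``run.batches`` for uncertainty
    estimation; ``run.n_histories`` sets the per-primary normalisation.
    """
    if spec is None:
        spec = ScoringSpec()
    t0 = time.time()
    acc = _Accumulator(spec, run.batches)
    ss = np.random.SeedSequence(run.seed)
    batch_seeds = ss.spawn(run.batches)
    edges = np.linspace(0, len(surface), run.batches + 1).astype(int)
    for b in range(run.batches):
        rng = np.random.default_rng(batch_seeds[b])
        part = surface.select(slice(edges[b], edges[b + 1]))
        _water_stage(part, rng, run, acc, b, ssd)
    grid = DoseGrid(spec, acc.grid.reshape((run.batches,) + acc.shape),
                    run.n_histories)
    cyl = None
    if acc.cyl is not None:
        cyl = CylindricalTally(spec.cyl_radius_cm, spec.cyl_voxel_mm,
                               spec.depth_range, acc.cyl, run.n_histories)
    dose10 = None
    if cyl is not None and acc.cyl.sum() > 0:
        dose10 = float(cyl.pdd().interp(100.0))
    report = RunReport(run.n_histories, run.seed, run.batches, dose10,
                       acc.e_in.copy(), acc.e_dep.copy(), acc.e_out.copy(),
                       float(surface.weight[surface.kind == PHOTON].sum()),
                       float(surface.weight[surface.kind != PHOTON].sum()),
                       time.time() - t0)
    return SimulationResult(grid, cyl, report)


def run_from_phase_space(ps, head: HeadConfig, run: RunConfig,
                         spec: Optional[ScoringSpec] = None,
                         recycle_factor: int = 1) -> SimulationResult:
    """Use a phase space recorded above the jaws as the particle source.

    The stream is recycled ``recycle_factor`` times (azimuthal re-rotation);
    the per-primary normalisation uses the equivalent-history count
    n_original_histories * recycle_factor.
    """
    from .psf import recycle

    if spec is None:
        spec = ScoringSpec()
    head = head.ensure_filter()
    n_equiv = ps.n_original_histories * recycle_factor
    t0 = time.time()
    acc = _Accumulator(spec, run.batches)
    ss = np.random.SeedSequence(run.seed)
    batch_seeds = ss.spawn(run.batches)
    w_ph = w_el = 0.0
    for b in range(run.batches):
        rng = np.random.default_rng(batch_seeds[b])
        for part in recycle(ps, recycle_factor, rng, batch=b,
                            n_batches=run.batches):
            surface = transmit_head_lower(part, head, rng)
            if run.kill_electrons_above_phantom:
                surface = surface.select(surface.kind == PHOTON)
            w_ph += float(surface.weight[surface.kind == PHOTON].sum())
            w_el += float(surface.weight[surface.kind != PHOTON].sum())
            _water_stage(surface, rng, run, acc, b, head.ssd)
    grid = DoseGrid(spec, acc.grid.reshape((run.batches,) + acc.shape),
                    n_equiv)
    cyl = None
    if acc.cyl is not None:
        cyl = CylindricalTally(spec.cyl_radius_cm, spec.cyl_voxel_mm,
                               spec.depth_range, acc.cyl, n_equiv)
    dose10 = None
    if cyl is not None and acc.cyl.sum() > 0:
        dose10 = float(cyl.pdd().interp(100.0))
    report = RunReport(n_equiv, run.seed, run.batches, dose10,
                       acc.e_in.copy(), acc.e_dep.copy(), acc.e_out.copy(),
                       w_ph, w_el, time.time() - t0)
    return SimulationResult(grid, cyl, report)


# ---------------------------------------------------------------------- #
# single-particle electron transport (API/spec surface)
# ---------------------------------------------------------------------- #
def transport_electron_in_water(e: ParticleState, rng,
                                deposit_sink: Callable[[tuple, float], None],
                                cut_range_mm: float = 1.0,
                                step_mm: float = 1.0) -> dict:
    """Condensed-history transport of one electron inside the phantom.

    ``deposit_sink((x, y, depth_cm), energy_mev)`` receives every deposit.
    Returns a termination record with the number of steps, total deposited
    energy and the termination reason (``cutoff`` or ``range``).
    """
    if e.kind not in ("electron", "positron"):
        raise ValueError("expected an electron or positron")
    e_threshold = physics.range_cut_to_energy(physics.WATER, cut_range_mm)
    x, y, d = e.position
    ux, uy, uz = e.direction
    energy = e.energy
    step_cm = step_mm / 10.0
    n_steps = 0
    deposited = 0.0
    reason = "cutoff"
    while True:
        r0 = float(physics.WATER.csda_range(max(energy, 5e-4)))
        if energy <= e_threshold or r0 <= step_cm:
            rt = min(r0, step_cm) * 0.5
            deposit_sink((x + ux * rt, y + uy * rt, d + uz * rt), energy)
            deposited += energy
            reason = "cutoff" if energy <= e_threshold else "range"
            break
        e_new = float(physics.WATER.csda_energy(r0 - step_cm))
        de = energy - e_new
        deposit_sink((x + ux * step_cm / 2, y + uy * step_cm / 2,
                      d + uz * step_cm / 2), de)
        deposited += de
        x += ux * step_cm
        y += uy * step_cm
        d += uz * step_cm
        n_steps += 1
        p = np.sqrt(e_new * (e_new + 2.0 * physics.ELECTRON_REST_MEV))
        beta = p / (e_new + physics.ELECTRON_REST_MEV)
        xr = step_cm / physics.WATER.radiation_length
        th0 = float(np.clip(13.6e-3 / (beta * p * 1e-3) * np.sqrt(xr)
                            * (1.0 + 0.038 * np.log(xr)), 0.0, 1.2))
        kick = abs(rng.normal()) * th0
        phi = rng.random() * 2.0 * np.pi
        ux, uy, uz = (float(v[0]) for v in rotate_directions(
            np.array([ux]), np.array([uy]), np.array([uz]),
            np.array([kick]), np.array([phi])))
        energy = e_new
    return {"n_steps": n_steps, "deposited": deposited, "reason": reason}
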