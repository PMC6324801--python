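"""Monte-Carlo engine tests: reproducibility, oracles, bookkeeping."""
import numpy as np
import pytest

from linacmc import head as H
from linacmc import physics
from linacmc.particles import ParticleBatch, ParticleState
from linacmc.scoring import ScoringSpec
from linacmc.transport import (RunConfig, run_simulation, run_surface_batch,
                               transport_electron_in_water)

SMALL_SPEC = ScoringSpec(voxel_mm=5.0, x_range=(-4, 4), y_range=(-4, 4),
                         depth_range=(0, 30), cyl_radius_cm=1.5)


def small_run(seed=5, n=120_000, **kw):
    return RunConfig(n_histories=n, seed=seed, photons_per_electron=4, **kw)


class TestReproducibility:
    def test_identical_seed_gives_bitwise_identical_grid(self, fff_preset):
        head, source = fff_preset
        a = run_simulation(head, source, small_run(), SMALL_SPEC)
        b = run_simulation(head, source, small_run(), SMALL_SPEC)
        assert np.array_equal(a.grid.batch_energy, b.grid.batch_energy)
        assert np.array_equal(a.cyl.batch_energy, b.cyl.batch_energy)

    def test_different_seed_changes_the_grid(self, fff_preset):
        head, source = fff_preset
        a = run_simulation(head, source, small_run(seed=5), SMALL_SPEC)
        b = run_simulation(head, source, small_run(seed=6), SMALL_SPEC)
        assert not np.array_equal(a.grid.batch_energy, b.grid.batch_energy)


class TestPrimaryBeamOracle:
    def test_scatter_off_cone_beam_matches_closed_form(self):
        """Attenuation-only point-source beam: CAX dose follows
        exp(-mu z) x inverse square within Monte-Carlo error."""
        n = 600_000
        g = np.random.default_rng(8)
        theta = np.sqrt(g.random(n)) * 0.03
        phi = g.random(n) * 2 * np.pi
        ux = np.sin(theta) * np.cos(phi)
        uy = np.sin(theta) * np.sin(phi)
        uz = np.cos(theta)
        b = ParticleBatch.photons(
            energy=np.full(n, 2.0), x=100 * ux / uz, y=100 * uy / uz,
            z=np.full(n, 100.0), ux=ux, uy=uy, uz=uz, weight=np.ones(n))
        res = run_surface_batch(
            b, RunConfig(n_histories=n, seed=2, disable_scatter=True),
            SMALL_SPEC)
        pdd = res.cyl.pdd()
        z = pdd.positions / 10.0
        mu = physics.attenuation_coefficient(physics.WATER, 2.0)
        expect = np.exp(-mu * z) * (100.0 / (100.0 + z)) ** 2
        ratio = (pdd.values / pdd.values[0]) / (expect / expect[0])
        unc = pdd.uncertainty_pct / 100.0
        # each point within 5 sigma of its own batch uncertainty
        assert np.all(np.abs(ratio - 1.0) < np.maximum(5 * unc, 0.02) + 0.03)
        # divide out the point-source divergence; the residual decay is mu
        slope = -np.polyfit(z, np.log(pdd.values * (100.0 + z) ** 2), 1)[0]
        assert slope == pytest.approx(mu, rel=0.03)


class TestElectronTransport:
    def test_below_threshold_deposits_locally_in_zero_steps(self):
        deposits = []
        e = ParticleState("electron", 0.1, (0.0, 0.0, 5.0), (0.0, 0.0, 1.0))
        rec = transport_electron_in_water(
            e, np.random.default_rng(0),
            lambda pos, en: deposits.append((pos, en)))
        assert rec["n_steps"] == 0
        assert rec["reason"] == "cutoff"
        assert len(deposits) == 1
        assert deposits[0][1] == pytest.approx(0.1)

    def test_total_deposit_equals_initial_kinetic_energy(self):
        total = []
        e = ParticleState("electron", 2.0, (0.0, 0.0, 5.0), (0.0, 0.0, 1.0))
        rec = transport_electron_in_water(
            e, np.random.default_rng(1), lambda pos, en: total.append(en))
        assert sum(total) == pytest.approx(2.0, rel=1e-9)
        assert rec["deposited"] == pytest.approx(2.0, rel=1e-9)
        assert rec["n_steps"] > 3  # 2 MeV range ~1 cm, 1 mm steps

    def test_track_length_consistent_with_csda_range(self):
        positions = []
        e = ParticleState("electron", 1.0, (0.0, 0.0, 5.0), (0.0, 0.0, 1.0))
        transport_electron_in_water(e, np.random.default_rng(2),
                                    lambda pos, en: positions.append(pos))
        depth_span = max(p[2] for p in positions) - 5.0
        r = float(physics.WATER.csda_range(1.0))
        assert depth_span <= r + 0.11
        assert depth_span > 0.3 * r  # forward-dominated track


class TestBookkeeping:
    def test_energy_balance_closes(self, fff_preset):
        head, source = fff_preset
        res = run_simulation(head, source, small_run(), SMALL_SPEC)
        assert res.report.energy_balance_error() < 1e-3

    def test_weight_accounting_on_surface(self, fff_preset):
        head, source = fff_preset
        res = run_simulation(head, source, small_run(), SMALL_SPEC)
        assert res.report.surface_photon_weight > 0
        # photons vastly outnumber contaminant electrons
        assert res.report.surface_electron_weight \
            < 0.05 * res.report.surface_photon_weight

    def test_zero_dose_run_warns_not_fails(self, fff_preset):
        head, source = fff_preset
        tiny_field = head.with_field(1e-6)  # effectively closed jaws
        with pytest.warns(UserWarning, match="zero dose"):
            res = run_simulation(tiny_field, source,
                                 small_run(n=20_000), SMALL_SPEC)
        assert res.report.energy_deposited.sum() == 0.0


class TestUncertaintyScaling:
    def test_relative_error_scales_as_inverse_sqrt_histories(self,
                                                             fff_preset):
        """Batch uncertainty of the CAX tally follows 1/sqrt(N) over a
        4x history ladder (fit exponent -0.5 +- 0.1)."""
        head, source = fff_preset
        sizes = [100_000, 400_000, 1_600_000]
        errs = []
        for n in sizes:
            res = run_simulation(head, source,
                                 small_run(seed=13, n=n), SMALL_SPEC)
            unc = res.cyl.pdd().uncertainty_pct
            errs.append(np.median(unc[unc > 0]))
        exponent = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        assert exponent == pytest.approx(-0.5, abs=0.1)


class TestElectronKill:
    def test_killing_electrons_lowers_surface_dose(self,
                                                   contamination_reports):
        for key, rep in contamination_reports.items():
            assert rep.surface_dose_killed_pct < rep.surface_dose_full_pct

    def test_dmax_in_buildup_band(self, pdd_runs):
        """Depth of maximum dose lies in the megavoltage buildup band for
        both beam lines (the simplified transport places it deeper than the
        machine's nominal 16-19 mm but within the physical range)."""
        for key, res in pdd_runs.items():
            pdd = res.cax_pdd().smoothed(9)
            dmax = pdd.positions[int(np.argmax(pdd.values))]
            assert 8.0 <= dmax <= 32.0, key
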