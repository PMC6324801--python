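"""Interaction-data and sampler tests against independent oracles."""
import numpy as np
import pytest
from scipy.integrate import quad

from linacmc import physics
from linacmc.physics import (AIR, ELECTRON_REST_MEV, STEEL, TUNGSTEN, WATER,
                             EnergyRangeError, RangeCutError,
                             attenuation_coefficient, range_cut_to_energy,
                             sample_bremsstrahlung, sample_compton)


def rng():
    return np.random.default_rng(20260927)


# ---------------------------------------------------------------------- #
# attenuation tables
# ---------------------------------------------------------------------- #
class TestAttenuation:
    def test_node_value_is_table_times_density(self):
        # 2.0 MeV is a node of every embedded channel table
        photo = WATER.photo_v[np.searchsorted(WATER.photo_e, 2.0)]
        pair = WATER.pair_v[np.searchsorted(WATER.pair_e, 2.0)]
        compton = physics.klein_nishina_total(2.0) * WATER.electrons_per_gram
        expect = (photo + pair + compton) * WATER.density
        assert attenuation_coefficient(WATER, 2.0) == pytest.approx(
            float(expect), rel=1e-12)

    @pytest.mark.parametrize("energy", [0.037, 0.42, 1.7, 6.3])
    def test_against_independent_loglog_interpolation(self, energy):
        # brute-force oracle: manual log-log interpolation of each channel
        def interp(te, tv, e):
            i = np.searchsorted(te, e) - 1
            f = (np.log(e) - np.log(te[i])) / (np.log(te[i + 1])
                                               - np.log(te[i]))
            return np.exp(np.log(tv[i]) * (1 - f) + np.log(tv[i + 1]) * f)

        total = interp(WATER.photo_e, WATER.photo_v, energy)
        total += physics.klein_nishina_total(energy) * WATER.electrons_per_gram
        if energy > WATER.pair_e[0]:
            total += interp(WATER.pair_e, WATER.pair_v, energy)
        assert attenuation_coefficient(WATER, energy) == pytest.approx(
            total * WATER.density, rel=0.005)

    def test_total_monotone_decreasing_in_mev_range(self):
        e = np.linspace(0.1, 4.0, 300)
        mu = attenuation_coefficient(WATER, e)
        assert np.all(np.diff(mu) < 0)

    @pytest.mark.parametrize("material", [WATER, AIR, TUNGSTEN, STEEL])
    def test_channel_sum_equals_total_at_every_node(self, material):
        grid = material.energy_grid
        photo, compton, pair = material.channel_mass_coefficients(grid)
        total = material.mass_attenuation(grid, "total")
        assert np.allclose(total, photo + compton + pair, atol=1e-9)

    @pytest.mark.parametrize("energy", [0.005, 25.0])
    def test_energy_outside_table_raises(self, energy):
        with pytest.raises(EnergyRangeError):
            attenuation_coefficient(WATER, energy)


# ---------------------------------------------------------------------- #
# Compton sampling (Klein-Nishina)
# ---------------------------------------------------------------------- #
class TestCompton:
    def test_energy_conservation_and_kinematics(self):
        e_sc, e_el, theta = sample_compton(np.full(20_000, 3.0), rng())
        np.testing.assert_allclose(e_sc + e_el, 3.0, rtol=1e-12)
        # Compton relation: eps = 1 / (1 + k (1 - cos theta))
        k = 3.0 / ELECTRON_REST_MEV
        eps = 1.0 / (1.0 + k * (1.0 - np.cos(theta)))
        np.testing.assert_allclose(e_sc / 3.0, eps, rtol=1e-9)

    def test_mean_scattered_energy_matches_quadrature(self):
        energy = 1.0
        k = energy / ELECTRON_REST_MEV
        eps0 = 1.0 / (1.0 + 2.0 * k)

        def dsigma(e):  # Klein-Nishina in eps, unnormalised
            t = (1.0 - e) / (k * e)
            return e + 1.0 / e - t * (2.0 - t)

        mean = quad(lambda e: e * dsigma(e), eps0, 1)[0] / quad(
            dsigma, eps0, 1)[0]
        n = 1_000_000
        e_sc, _, _ = sample_compton(energy, rng(), size=n)
        eps = e_sc / energy
        se = eps.std() / np.sqrt(n)
        assert abs(eps.mean() - mean) < 3 * se

    def test_low_energy_limit_is_symmetric_thomson(self):
        # forward/backward scattering counts equalise as E -> 0
        _, _, theta = sample_compton(0.001, rng(), size=200_000)
        fwd = int((theta < np.pi / 2).sum())
        n = theta.size
        assert abs(fwd - n / 2) < 3 * np.sqrt(n) / 2


# ---------------------------------------------------------------------- #
# bremsstrahlung sampling
# ---------------------------------------------------------------------- #
class TestBremsstrahlung:
    def test_photon_energy_bounded_by_electron_energy(self):
        k, _ = sample_bremsstrahlung(np.full(50_000, 8.8), rng())
        assert np.all(k <= 8.8) and np.all(k >= 0.05)

    def test_mean_energy_matches_quadrature(self):
        e0, e_min = 8.8, 0.05
        spec = lambda k: (1 - k / e0 + 0.75 * (k / e0) ** 2) / k
        mean = quad(lambda k: k * spec(k), e_min, e0)[0] / quad(
            spec, e_min, e0)[0]
        n = 1_000_000
        k, _ = sample_bremsstrahlung(np.full(n, e0), rng(), e_min=e_min)
        assert abs(k.mean() - mean) < 3 * k.std() / np.sqrt(n)

    def test_angular_fraction_matches_quadrature(self):
        e0 = 8.8
        theta0 = 0.8 * ELECTRON_REST_MEV / (e0 + ELECTRON_REST_MEV)
        pdf = lambda t: t * (1 + (t / theta0) ** 2) ** -0.24
        frac = quad(pdf, 0, theta0)[0] / quad(pdf, 0, 0.35)[0]
        n = 1_000_000
        _, theta = sample_bremsstrahlung(np.full(n, e0), rng())
        observed = (theta <= theta0).mean()
        assert abs(observed - frac) < 3 * np.sqrt(frac * (1 - frac) / n)

    def test_spectrum_independent_of_angle(self):
        # separable model: mean energy equal in inner and outer cone
        n = 400_000
        k, theta = sample_bremsstrahlung(np.full(n, 8.8), rng())
        inner = k[theta < 0.05]
        outer = k[theta >= 0.05]
        se = np.sqrt(k.var() / inner.size + k.var() / outer.size)
        assert abs(inner.mean() - outer.mean()) < 3.5 * se


# ---------------------------------------------------------------------- #
# range cut
# ---------------------------------------------------------------------- #
class TestRangeCut:
    def test_zero_cut_degenerates_to_table_minimum(self):
        assert range_cut_to_energy(WATER, 0.0) == WATER.csda_e[0]

    def test_monotone_in_cut(self):
        assert range_cut_to_energy(WATER, 2.0) >= range_cut_to_energy(
            WATER, 1.0)

    def test_one_mm_water_matches_linear_scan_oracle(self):
        # independent oracle: linear scan of the embedded CSDA table
        expected = None
        for e, r in zip(WATER.csda_e, WATER.csda_v):
            if r / WATER.density * 10.0 >= 1.0:
                expected = e
                break
        assert range_cut_to_energy(WATER, 1.0) == expected

    def test_cut_beyond_table_raises(self):
        with pytest.raises(RangeCutError):
            range_cut_to_energy(WATER, 1e6)


def test_exponential_attenuation_limit():
    """Scatter-disabled pencil beam transmits as exp(-mu z): the fitted
    attenuation slope matches the embedded coefficient."""
    from linacmc.particles import ParticleBatch
    from linacmc.scoring import ScoringSpec
    from linacmc.transport import RunConfig, run_surface_batch

    n = 300_000
    b = ParticleBatch.photons(
        energy=np.full(n, 2.0), x=np.zeros(n), y=np.zeros(n),
        z=np.full(n, 100.0), ux=np.zeros(n), uy=np.zeros(n),
        uz=np.ones(n), weight=np.ones(n))
    spec = ScoringSpec(voxel_mm=5.0, x_range=(-3, 3), y_range=(-3, 3),
                       depth_range=(0, 30), cyl_radius_cm=1.0)
    res = run_surface_batch(b, RunConfig(n_histories=n, seed=2,
                                         disable_scatter=True), spec)
    pdd = res.cyl.pdd()
    slope = -np.polyfit(pdd.positions / 10.0, np.log(pdd.values), 1)[0]
    mu = attenuation_coefficient(WATER, 2.0)
    assert slope == pytest.approx(mu, rel=0.02)
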