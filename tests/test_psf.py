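"""Phase-space format, round trips, corruption handling, recycling."""
import numpy as np
import pytest

from linacmc.particles import ParticleBatch
from linacmc.psf import (MAGIC, RECORD_DTYPE, PhaseSpace, PSFFormatError,
                         export_csv, read_psf, recycle, write_psf)


def toy_phase_space(n=500, seed=3, plane_z=29.0) -> PhaseSpace:
    g = np.random.default_rng(seed)
    rec = np.zeros(n, dtype=RECORD_DTYPE)
    rec["kind"] = g.integers(0, 2, n)
    rec["energy"] = g.uniform(0.1, 7.0, n).astype(np.float32)
    rec["x_mm"] = g.normal(0, 20, n).astype(np.float32)
    rec["y_mm"] = g.normal(0, 20, n).astype(np.float32)
    u = g.normal(0, 0.05, n)
    v = g.normal(0, 0.05, n)
    w = np.sqrt(1 - u**2 - v**2)
    rec["u"], rec["v"], rec["w"] = u, v, w
    rec["weight"] = 1.0
    return PhaseSpace(plane_z, n * 10, rec, b"h" * 32)


class TestRoundTrip:
    def test_write_read_reproduces_records_exactly(self, tmp_path):
        ps = toy_phase_space()
        path = tmp_path / "a.bpsf"
        write_psf(path, ps)
        ps2 = read_psf(path)
        assert ps2.plane_z == ps.plane_z
        assert ps2.n_original_histories == ps.n_original_histories
        assert ps2.config_hash == ps.config_hash
        assert ps.records.tobytes() == ps2.records.tobytes()

    def test_hand_built_three_record_file_parses(self, tmp_path):
        """Byte-by-byte fixture following the documented layout."""
        import zlib

        records = np.zeros(3, dtype=RECORD_DTYPE)
        records["kind"] = [0, 1, 2]
        records["energy"] = [1.5, 0.7, 2.25]
        records["x_mm"] = [1.0, -2.0, 3.5]
        records["y_mm"] = [0.0, 4.0, -1.0]
        records["u"] = [0.0, 0.1, 0.0]
        records["v"] = [0.0, 0.0, 0.2]
        records["w"] = [1.0, 0.99498743710662, 0.9797958971132712]
        records["weight"] = [1.0, 0.5, 2.0]
        header = bytearray()
        header += MAGIC
        header += np.uint16(1).tobytes()
        header += np.float64(29.0).tobytes()
        header += np.uint64(42).tobytes()
        header += np.uint64(3).tobytes()
        header += b"\x00" * 32
        header += np.uint32(zlib.crc32(bytes(header))).tobytes()
        path = tmp_path / "hand.bpsf"
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            records.tofile(fh)
        ps = read_psf(path)
        assert len(ps) == 3
        assert ps.n_original_histories == 42
        assert ps.records["energy"].tolist() == pytest.approx(
            [1.5, 0.7, 2.25])
        assert ps.records["kind"].tolist() == [0, 1, 2]

    def test_csv_export_lists_all_records(self, tmp_path):
        ps = toy_phase_space(n=7)
        p = tmp_path / "x.csv"
        export_csv(ps, p)
        lines = [ln for ln in p.read_text().splitlines()
                 if ln and not ln.startswith("#")]
        assert len(lines) == 1 + 7  # header + records


class TestCorruption:
    def test_count_mismatch_raises_with_offset(self, tmp_path):
        ps = toy_phase_space()
        path = tmp_path / "a.bpsf"
        write_psf(path, ps)
        data = path.read_bytes()
        path.write_bytes(data[:-RECORD_DTYPE.itemsize])  # drop one record
        with pytest.raises(PSFFormatError, match="count mismatch"):
            read_psf(path)

    def test_bad_magic_raises(self, tmp_path):
        path = tmp_path / "a.bpsf"
        write_psf(path, toy_phase_space())
        data = bytearray(path.read_bytes())
        data[0] ^= 0xFF
        path.write_bytes(bytes(data))
        with pytest.raises(PSFFormatError, match="magic"):
            read_psf(path)

    def test_corrupt_header_fails_checksum(self, tmp_path):
        path = tmp_path / "a.bpsf"
        write_psf(path, toy_phase_space())
        data = bytearray(path.read_bytes())
        data[20] ^= 0x01  # flip a bit inside the header payload
        path.write_bytes(bytes(data))
        with pytest.raises(PSFFormatError, match="checksum"):
            read_psf(path)

    def test_truncated_header_raises(self, tmp_path):
        path = tmp_path / "a.bpsf"
        path.write_bytes(b"BPSF0001\x00")
        with pytest.raises(PSFFormatError, match="truncated"):
            read_psf(path)

    def test_upward_records_rejected(self):
        rec = np.zeros(1, dtype=RECORD_DTYPE)
        rec["energy"] = 1.0
        rec["w"] = -0.5
        with pytest.raises(PSFFormatError):
            PhaseSpace(29.0, 10, rec)


class TestRecycling:
    def test_equivalent_history_arithmetic(self):
        ps = toy_phase_space(n=300)
        g = np.random.default_rng(0)
        total = sum(len(b) for b in recycle(ps, 5, g))
        assert total == 5 * len(ps)
        # the headline bookkeeping: 1.5e9 originals x 5 = 7.5e9 equivalent
        assert 1_500_000_000 * 5 == 7_500_000_000

    def test_factor_one_is_plain_replay(self):
        ps = toy_phase_space(n=200)
        g = np.random.default_rng(0)
        batches = list(recycle(ps, 1, g))
        merged = ParticleBatch.concatenate(batches)
        np.testing.assert_allclose(merged.x * 10.0, ps.records["x_mm"],
                                   rtol=1e-6)
        np.testing.assert_allclose(merged.energy, ps.records["energy"],
                                   rtol=1e-7)

    def test_rotation_preserves_radius_and_energy(self):
        ps = toy_phase_space(n=400)
        g = np.random.default_rng(1)
        batches = list(recycle(ps, 3, g))
        r0 = np.hypot(ps.records["x_mm"], ps.records["y_mm"]) / 10.0
        for b in batches:
            np.testing.assert_allclose(np.hypot(b.x, b.y), r0, rtol=1e-5)
            np.testing.assert_allclose(b.energy, ps.records["energy"],
                                       rtol=1e-7)

    def test_plane_below_jaws_rejected(self):
        ps = toy_phase_space(plane_z=35.0)
        with pytest.raises(ValueError, match="above the jaws"):
            list(recycle(ps, 2, np.random.default_rng(0)))

    def test_spectrum_invariant_under_recycling(self):
        from linacmc.spectra import bin_fluence

        ps = toy_phase_space(n=4000)
        g = np.random.default_rng(2)
        base = bin_fluence(ps.to_batch(), None, 1)
        rec = ParticleBatch.concatenate(list(recycle(ps, 4, g)))
        rec_hist = bin_fluence(rec, None, 4)
        np.testing.assert_allclose(rec_hist.weights, base.weights,
                                   rtol=1e-9, atol=1e-12)


class TestRecyclingUncertainty:
    def test_recycled_runs_sit_between_plain_and_fresh(self, fff_preset):
        """Recycling factor 5 improves the dose uncertainty relative to a
        single pass, but cannot beat five times as many fresh histories
        (latent variance of the reused particles)."""
        from linacmc.scoring import ScoringSpec
        from linacmc.transport import (RunConfig, run_from_phase_space,
                                       run_simulation)

        head, source = fff_preset
        spec = ScoringSpec(voxel_mm=5.0, x_range=(-4, 4), y_range=(-4, 4),
                           depth_range=(0, 30), cyl_radius_cm=1.5)
        n = 100_000
        base = run_simulation(head, source,
                              RunConfig(n_histories=n, seed=17,
                                        photons_per_electron=4,
                                        psf_capture=True), spec)
        ps = base.phase_space

        def med_unc(result):
            unc = result.cyl.pdd().uncertainty_pct
            return float(np.median(unc[unc > 0]))

        plain = run_from_phase_space(ps, head,
                                     RunConfig(n_histories=n, seed=23),
                                     spec, recycle_factor=1)
        recycled = run_from_phase_space(ps, head,
                                        RunConfig(n_histories=n, seed=23),
                                        spec, recycle_factor=5)
        fresh = run_simulation(head, source,
                               RunConfig(n_histories=5 * n, seed=29,
                                         photons_per_electron=4), spec)
        assert med_unc(recycled) < med_unc(plain)
        assert med_unc(recycled) > 0.8 * med_unc(fresh)
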