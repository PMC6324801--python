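"""Shared fixtures.

The expensive Monte-Carlo campaigns (contamination pairs, depth-dose runs,
the tuning self-consistency harness, the off-axis spectrum scan) are
session-scoped so that the acceptance checks and the related unit tests
share one computation each.
"""
import numpy as np
import pytest

from linacmc import head as head_mod
from linacmc.contamination import contamination_fraction
from linacmc.transport import RunConfig, run_simulation


@pytest.fixture(scope="session")
def fff_preset():
    return head_mod.load_preset("fff7mv")


@pytest.fixture(scope="session")
def flat_preset():
    return head_mod.load_preset("flat6mv")


@pytest.fixture(scope="session")
def flat_head_with_filter(flat_preset):
    head, source = flat_preset
    return head.ensure_filter(), source


@pytest.fixture(scope="session")
def contamination_reports(fff_preset, flat_preset):
    """Paired full/electron-kill surface-dose campaigns, both modes and
    field sizes 10 and 20 cm (shared seed: common random numbers across
    modes and fields)."""
    out = {}
    for (name, preset), field, n in (
        (("fff", fff_preset), 10.0, 3_000_000),
        (("fff", fff_preset), 20.0, 3_000_000),
        (("flat", flat_preset), 10.0, 1_500_000),
        (("flat", flat_preset), 20.0, 1_500_000),
    ):
        head, source = preset
        head = head.with_field(field)
        run = RunConfig(n_histories=n, seed=21, photons_per_electron=8)
        out[(name, field)] = contamination_fraction(head, source, run)
    return out


@pytest.fixture(scope="session")
def pdd_runs(fff_preset, flat_preset):
    """CAX depth-dose runs (cylindrical tally) for both modes and fields."""
    from linacmc.tuning import _spec_for

    out = {}
    for (name, preset), field in ((("fff", fff_preset), 10.0),
                                  (("fff", fff_preset), 20.0),
                                  (("flat", flat_preset), 10.0),
                                  (("flat", flat_preset), 20.0)):
        head, source = preset
        head = head.with_field(field)
        run = RunConfig(n_histories=4_000_000, seed=31,
                        photons_per_electron=8)
        out[(name, field)] = run_simulation(head, source, run,
                                            _spec_for(head, profile=False))
    return out


@pytest.fixture(scope="session")
def tuning_reference(fff_preset):
    """Simulator-generated reference curves for the self-consistency
    harness (unseen seed relative to the tuning runs)."""
    from linacmc.synthetic import simulator_as_reference

    head, source = fff_preset
    run = RunConfig(n_histories=12_000_000, seed=555,
                    photons_per_electron=8)
    curves = simulator_as_reference(head, source, run)
    return {k: v for k, v in curves.items() if k != "result"}


@pytest.fixture(scope="session")
def tuning_result(fff_preset, tuning_reference):
    """Reduced-grid source recovery against the simulator reference."""
    from linacmc.tuning import TuningGrid, tune_source

    head, _ = fff_preset
    grid = TuningGrid(np.array([7.0, 7.45, 7.9, 8.35, 8.8]),
                      np.array([0.3, 0.6]), np.array([1.0, 2.0]))
    return tune_source(head, grid, tuning_reference,
                       histories_per_point=200_000,
                       final_histories=12_000_000, seed=7)


@pytest.fixture(scope="session")
def offaxis_scan(fff_preset):
    """Off-axis photon-spectrum scan, FFF 20 x 20 cm^2 field."""
    from linacmc.spectra import offaxis_spectrum_scan

    head, source = fff_preset
    return offaxis_spectrum_scan(head.with_field(20.0), source,
                                 n_histories=12_000_000, seed=11,
                                 photons_per_electron=10)
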