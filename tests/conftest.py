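import numpy as np
import pytest

from skiptic.simulate import SimulationConfig, simulate_study
from skiptic.splicing import build_psi_table, diff_splicing, extract_splice_events


SMALL = dict(
    n_genes=160,
    n_skiptic=8,
    n_cryptic=8,
    n_shared_alt=5,
    n_null_cassette=80,
    n_retained_intron=5,
    n_alt5=5,
    n_alt3=5,
    n_alt_first=5,
    n_alt_last=5,
    n_mutually_exclusive=5,
)


@pytest.fixture(scope="session")
def small_gof_sim():
    """A small GOF-regime synthetic study shared across unit tests."""
    return simulate_study(SimulationConfig(seed=11, regime="GOF", **SMALL))


@pytest.fixture(scope="session")
def small_gof_results(small_gof_sim):
    sim = small_gof_sim
    events = extract_splice_events(sim.models, sim.junctions)
    table = build_psi_table(events, sim.junctions, sim.sheet, intron_body=sim.intron_body)
    results = diff_splicing(table, sim.sheet)
    return events, table, results


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
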