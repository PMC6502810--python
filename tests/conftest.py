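"""Shared fixtures: one default simulation, run once per session.

The heavier synthetic datasets (2000 transcripts, 3 replicates per role)
are session-scoped so recovery tests across modules reuse them instead
of regenerating.
"""

import pytest

from ribostate.polysome import classify_shifts, normalize_fractions
from ribostate.ripseq import call_binders, rip_enrichment
from ribostate.simulate import (
    SimulationConfig,
    simulate_de,
    simulate_eclip,
    simulate_polysome,
    simulate_ripseq,
)

SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def rip_sim(default_config):
    return simulate_ripseq(default_config)


@pytest.fixture(scope="session")
def rip_results(rip_sim):
    results, factors = rip_enrichment(rip_sim.counts, rip_sim.transcripts)
    return results, factors


@pytest.fixture(scope="session")
def binders(rip_results):
    results, _ = rip_results
    return call_binders(results, cutoff=4.0)


@pytest.fixture(scope="session")
def eclip_peaks(default_config, rip_sim):
    return simulate_eclip(default_config, rip_sim.transcripts, rip_sim.bound)


@pytest.fixture(scope="session")
def poly_sim(default_config, rip_sim):
    return simulate_polysome(default_config, rip_sim.bound)


@pytest.fixture(scope="session")
def fraction_profiles(default_config, poly_sim):
    scheme = default_config.scheme
    wt = normalize_fractions(poly_sim.wt_counts, scheme, genotype="WT")
    ko = normalize_fractions(poly_sim.ko_counts, scheme, genotype="KO")
    return wt, ko


@pytest.fixture(scope="session")
def shift_calls(default_config, fraction_profiles):
    wt, ko = fraction_profiles
    return classify_shifts(wt, ko, default_config.scheme)


@pytest.fixture(scope="session")
def de_sim(default_config):
    return simulate_de(default_config)
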