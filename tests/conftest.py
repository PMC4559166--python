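import numpy as np
import pytest

import evotrace as et


@pytest.fixture(scope="session")
def small_genome():
    """100 kb reference shared by read-simulation and calling tests."""
    return et.generate_reference(100_000, gc_fraction=0.5, n_genes=10, seed=7)


@pytest.fixture(scope="session")
def strain_f_like_sample(small_genome):
    """A sample carrying one event of each strain-F class, rescaled tight."""
    g = small_genome
    events = [
        et.PlantedEvent("small_deletion", 15_000, 88),
        et.PlantedEvent("large_insertion", 45_000, 1199, "IS5"),
        et.PlantedEvent("snv", 70_000, 0,
                        "T" if g.sequence[70_000] != "T" else "A"),
    ]
    return et.plant_events(g, events)


@pytest.fixture(scope="session")
def null_pairs(small_genome):
    """Mate pairs from an event-free genome."""
    sample = et.plant_events(small_genome, [])
    cfg = et.ReadSimConfig(insert_mean=1200, insert_sd=100, read_length=50,
                           pair_coverage=50, seed=11)
    return et.simulate_mate_pairs(sample, cfg)
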