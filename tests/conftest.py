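import numpy as np
import pandas as pd
import pytest

import cfgi
from cfgi import simulate as sim
from cfgi import pipeline

TOY_READS = 500_000


@pytest.fixture(scope="session")
def toy_bins() -> pd.DataFrame:
    """Six 40-Mb chromosomes at 1 Mb (240 bins) with a synthetic GC track."""
    return sim.synthetic_gc(cfgi.build_bins(sim.toy_chromosomes(6, 40_000_000)), seed=1)


@pytest.fixture(scope="session")
def toy_controls(toy_bins):
    return sim.simulate_controls(toy_bins, n_controls=38,
                                 reads_per_sample=TOY_READS, seed=2)


@pytest.fixture(scope="session")
def toy_panel(toy_bins, toy_controls):
    return pipeline.control_panel(toy_controls, toy_bins)


@pytest.fixture(scope="session")
def hg19_bins() -> pd.DataFrame:
    return cfgi.build_bins(cfgi.load_hg19_autosomes())


def toy_tumor(bins, segments, tumor_fraction, seed):
    return sim.simulate_tumor(bins, segments, tumor_fraction,
                              reads_per_sample=TOY_READS, seed=seed)
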