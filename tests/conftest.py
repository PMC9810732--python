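"""Shared fixtures: small synthetic datasets reused across test modules."""

import pytest

from riboscreen import SimConfig, make_screen_dataset, run_screen


#: scaled-down study design for fast property tests
SMALL_CONFIG = SimConfig(
    n_coding=80,
    n_linc=40,
    n_differential=4,
    length_range=(300, 900),
    library_size_rpf=30_000,
    library_size_rna=30_000,
)


@pytest.fixture(scope="session")
def small_dataset():
    return make_screen_dataset(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_dataset):
    ds = small_dataset
    return run_screen(ds.transcripts, ds.rpf_alignments, ds.manifest, ds.rna_alignments)
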