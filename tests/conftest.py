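import numpy as np
import pytest

from nucleoamp import (
    AmpliconDef,
    FragmentRecord,
    SimulationConfig,
    generate_amplicon_panel,
    generate_nucleosome_landscape,
    sample_fragments,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def landscape():
    """Small deterministic nucleosome landscape shared across tests."""
    return generate_nucleosome_landscape(
        100_000, mean_spacing=190, spacing_jitter_sd=20.0, seed=11
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_fragments=5_000, seed=11, n_samples=4)


@pytest.fixture(scope="session")
def fragments(landscape, small_config):
    return sample_fragments(landscape, small_config)


@pytest.fixture(scope="session")
def panel(landscape):
    return generate_amplicon_panel(landscape, 25, seed=11)


def random_fragments(rng, n, contig="c", lo=0, hi=5000, max_len=300, sample_id="pooled"):
    """Helper: n random fragments within [lo, hi)."""
    starts = rng.integers(lo, hi - max_len, n)
    lengths = rng.integers(1, max_len, n)
    return [
        FragmentRecord(contig, int(s), int(s + l), sample_id)
        for s, l in zip(starts, lengths)
    ]


def make_amplicon(start, end, name="amp", contig="c", gc=0.5, fwd=20, rev=20):
    return AmpliconDef(contig, start, end, name, fwd, rev, gc)
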