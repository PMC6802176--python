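import numpy as np
import pytest

from lakephage.abundance import build_abundance_matrix
from lakephage.discovery import select_phage_candidates
from lakephage.synth import (
    CommunitySpec,
    TimeSeriesSpec,
    generate_community,
    generate_reads,
)

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Random substitutions; returns (mutated sequence, #changed positions)."""
    arr = np.array(list(seq))
    sites = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in sites:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr), len(sites)


@pytest.fixture(scope="session")
def community():
    """The default synthetic community (20 phages in 4 replicate groups plus
    singletons, 5 hosts, planted evidence on every founder)."""
    return generate_community(CommunitySpec(seed=7))


@pytest.fixture(scope="session")
def discovered(community):
    return select_phage_candidates(community.contigs)


@pytest.fixture(scope="session")
def time_series_samples(community):
    return generate_reads(community, TimeSeriesSpec(seed=7))


@pytest.fixture(scope="session")
def abundance_result(discovered, time_series_samples):
    return build_abundance_matrix(
        [g.sequence for g in discovered], time_series_samples
    )
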