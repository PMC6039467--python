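import math

import pytest

from tfreloc.genomic_io import GenomicInterval, Peak
from tfreloc.synthetic_data import (
    ScenarioConfig,
    build_genome,
    simulate_expression,
    simulate_tracks,
)


def small_scenario_config(seed: int = 11, **overrides) -> ScenarioConfig:
    """A desk-scale scenario used across tests: same structure as the
    default, ~10x smaller."""
    kwargs = dict(
        genome_length=1_500_000,
        n_chromosomes=2,
        n_genes=40,
        n_sites=200,
        n_background_genes=150,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scenario():
    return build_genome(small_scenario_config())


@pytest.fixture(scope="session")
def small_tracks(small_scenario):
    return simulate_tracks(small_scenario)


@pytest.fixture(scope="session")
def small_expression(small_scenario):
    return simulate_expression(small_scenario)


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=100_000,
                 min_len=20, max_len=600, with_summits=False):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(min_len, max_len))
        summit = int(rng.integers(0, length)) if with_summits else None
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + length),
                 name=f"p{i}", score=float(rng.random()), summit=summit)
        )
    return peaks


# --- independent PWM scoring used as the scanning oracle -------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_pwm_score(kmer: str, pwm) -> float:
    """Pure-python log-odds score of one window on the + strand."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(
        math.log2(pwm.matrix[i][idx[b]] / pwm.background[idx[b]])
        for i, b in enumerate(kmer)
    )


def brute_scan_threshold(pwm, fraction: float) -> float:
    idx_all = range(4)
    smin = sum(min(math.log2(pwm.matrix[i][b] / pwm.background[b])
                   for b in idx_all) for i in range(len(pwm)))
    smax = sum(max(math.log2(pwm.matrix[i][b] / pwm.background[b])
                   for b in idx_all) for i in range(len(pwm)))
    return smin + fraction * (smax - smin)
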