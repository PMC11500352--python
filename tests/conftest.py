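import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diffedit import CountTable, SampleSet

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(sites, samples1, samples2):
    """CountTable from oracle-style site records."""
    return CountTable.from_site_records(
        sites, SampleSet("set1", tuple(samples1)), SampleSet("set2", tuple(samples2))
    )


def random_case(rng, dyadic=True):
    """A random small analysis instance in oracle site-record form.

    With ``dyadic=True`` coverages are powers of two, so every editing
    ratio and every window sum is an exact binary fraction and any
    summation order yields bitwise-identical floats; with ``dyadic=False``
    coverages are arbitrary and results carry ordinary rounding.
    """
    window_size = int(rng.integers(3, 8))
    n_regions = int(rng.integers(1, 3))
    regions = []
    cursor = int(rng.integers(0, 50))
    for _ in range(n_regions):
        length = int(rng.integers(1, 4)) * window_size - int(rng.integers(0, window_size - 1))
        regions.append(("t1", cursor, cursor + length))
        cursor += length + int(rng.integers(5, 20))
    samples1 = [f"a{i}" for i in range(int(rng.integers(1, 5)))]
    samples2 = [f"b{i}" for i in range(int(rng.integers(1, 5)))]
    samples = samples1 + samples2

    if dyadic:
        coverage_pool = np.array([0, 4, 8, 16, 32])
        min_coverage = 8
    else:
        coverage_pool = np.arange(0, 40)
        min_coverage = 10
    sites = []
    for chrom, start, end in regions:
        for pos in range(start, end):
            if rng.random() < 0.1:  # an uncovered/absent position
                continue
            ref = "ACGT"[rng.integers(0, 4)]
            quads = {}
            for sample in samples:
                cov = int(rng.choice(coverage_pool))
                probs = rng.dirichlet(np.full(4, 0.5))
                quads[sample] = tuple(int(v) for v in rng.multinomial(cov, probs))
            sites.append((chrom, pos, ref, quads))
    cfg_kwargs = dict(
        window_size=window_size,
        min_coverage=min_coverage,
        snp_filter_enabled=bool(rng.random() < 0.5),
        snp_freq_threshold=0.80,
        min_sites_per_window=int(rng.integers(1, 3)),
    )
    return sites, samples1, samples2, regions, cfg_kwargs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
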