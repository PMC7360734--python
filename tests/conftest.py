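import numpy as np
import pytest

from ervreg.genome import GenomeLayout, Interval, RepeatAnnotation, RepeatElement
from ervreg.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeLayout(
        {"chr1": 10_000, "chr2": 8_000},
        [Interval("chr1", 2_000, 2_500), Interval("chr2", 0, 1_000)],
    )


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset shared by read-only tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for pipeline smoke tests."""
    return SyntheticConfig(
        seed=7, n_aml_samples=6, n_diff_samples=3, n_cell_lines=2,
        n_genes=60,
    )


def random_intervals(rng, n, chroms, max_len=200, min_len=1):
    """Uniform random intervals over the given {chrom: length} map."""
    names = list(chroms)
    out = []
    for _ in range(n):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, chroms[chrom] - length + 1))
        out.append(Interval(chrom, start, start + length))
    return out


def random_annotation(rng, n, chroms, family="FAM", max_len=200):
    ivs = random_intervals(rng, n, chroms, max_len)
    return RepeatAnnotation(
        [RepeatElement(iv.chrom, iv.start, iv.end, family, f"{family}_{i:04d}")
         for i, iv in enumerate(ivs)]
    )


def brute_force_counts(query, elements):
    """All-pairs O(n*m) overlap counting oracle."""
    ivs = [e.as_interval() for e in elements]
    n_query_hit = sum(1 for q in query if any(q.overlaps(e) for e in ivs))
    n_elements_hit = sum(1 for e in ivs if any(q.overlaps(e) for q in query))
    return n_query_hit, n_elements_hit
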