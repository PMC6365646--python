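import numpy as np
import pandas as pd
import pytest

from fitcaller import synthdata
from fitcaller.bcio import CountTable


@pytest.fixture(scope="session")
def small_genome():
    return synthdata.generate_genome(1, 100, 900, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_genome):
    pool, baseline = synthdata.generate_pool(small_genome, 2000, seed=12)
    return pool, baseline


@pytest.fixture(scope="session")
def default_genome():
    """The 1000-gene genome used by coverage/recovery sanity checks."""
    return synthdata.generate_genome(1, 1000, 900, 0.5, seed=21)


@pytest.fixture(scope="session")
def default_pool(default_genome):
    pool, baseline = synthdata.generate_pool(default_genome, 8000, seed=22)
    return pool, baseline


def make_count_table(counts: dict, samples: list[dict]) -> CountTable:
    """Hand-built count table; ``counts`` maps sample id -> list of ints."""
    barcodes = [f"{'ACGT'[i % 4] * 20}"[:20] for i in range(len(next(iter(counts.values()))))]
    # distinct deterministic barcodes
    barcodes = []
    n = len(next(iter(counts.values())))
    for i in range(n):
        digits = []
        x = i
        for _ in range(20):
            digits.append("ACGT"[x % 4])
            x //= 4
        barcodes.append("".join(digits))
    df = pd.DataFrame(counts, index=barcodes)
    return CountTable(counts=df, samples=pd.DataFrame(samples))


@pytest.fixture
def two_sample_table():
    """One experiment plus one Time0, equal totals of 1000."""
    t0 = [8, 16, 100, 876]
    after = [8, 4, 112, 876]
    return make_count_table(
        {"T0": t0, "expA": after},
        [
            {"sample": "T0", "condition": "Time0", "t0set": "T0A", "is_time0": True},
            {"sample": "expA", "condition": "glucose", "t0set": "T0A", "is_time0": False},
        ],
    )
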