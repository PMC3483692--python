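"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from tagdge.refdb import ReferenceTagDB
from tagdge.simulate import SimulationConfig, simulate_dataset

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def binom_interval(n: int, p: float, conf: float = 0.99) -> tuple[float, float]:
    """Central exact-binomial interval for an observed fraction."""
    from scipy.stats import binom

    alpha = (1 - conf) / 2
    return binom.ppf(alpha, n, p) / n, binom.ppf(1 - alpha, n, p) / n


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene, 20k-tag-per-library synthetic dataset with 30%
    off-reference contamination; shared across read-only tests."""
    config = SimulationConfig(
        n_genes=300, library_depth=20_000, offref_fraction=0.3, seed=11
    )
    records, truth, libraries, db = simulate_dataset(config)
    return config, records, truth, libraries, db


@pytest.fixture()
def toy_db() -> ReferenceTagDB:
    """Four hand-built genes: three taggable, one without any CATG."""
    a_tail = "A" * 17
    c_tail = "C" * 17
    records = [
        ("gA", "GG" + "CATG" + a_tail + "GG"),
        ("gB", "TT" + "CATG" + c_tail),
        ("gC", "CATG" + "ACGT" * 5 + "A" + "TTTT"),
        ("gNone", "AAAATTTTGGGGAAAATTTT"),
    ]
    return ReferenceTagDB.from_records(records)
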