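"""Shared fixtures: small genotype matrices and detection tables."""

import numpy as np
import pandas as pd
import pytest

from fjordflow.genotypes import GenotypeMatrix


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Ten individuals (two populations), six sites, no missing data."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    return GenotypeMatrix(
        calls=calls,
        chrom=np.array(["LG01"] * 6, dtype=object),
        pos=np.array([100, 2_000, 15_000, 30_000, 31_000, 60_000]),
        samples=[f"S{i}" for i in range(10)],
        populations=["A"] * 5 + ["B"] * 5,
    )


def make_matrix(calls, pos=None, pops=None, chrom="LG01", dp=None, gq=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if pops is None:
        pops = ["A"] * n
    return GenotypeMatrix(
        calls=calls,
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.asarray(pos),
        samples=[f"S{i}" for i in range(n)],
        populations=list(pops),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


@pytest.fixture
def detections_two_receivers() -> pd.DataFrame:
    """One fish, one 30-min bin: 3 detections at receiver A, 1 at B."""
    t = pd.Timestamp("2012-06-01 10:00", tz="UTC")
    return pd.DataFrame(
        {
            "fish_id": ["F1"] * 4,
            "timestamp": [t, t + pd.Timedelta(minutes=5), t + pd.Timedelta(minutes=10),
                          t + pd.Timedelta(minutes=15)],
            "receiver_id": ["A", "A", "A", "B"],
            "lon": [8.90, 8.90, 8.90, 8.94],
            "lat": [58.60, 58.60, 58.60, 58.64],
            "depth_m": [10.0, 12.0, 14.0, 20.0],
        }
    )
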