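import numpy as np
import pandas as pd
import pytest

from clipmap.io import CrosslinkTrack
from clipmap.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-gene synthetic dataset shared across fast tests."""
    return simulate_dataset(SyntheticConfig(n_genes=60, seed=1))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-condition synthetic dataset (seed 1)."""
    return simulate_dataset(SyntheticConfig(seed=1))


def random_instance(rng, chrom_len=1000, n_reps=4):
    """A random toy binding-site problem on one short chromosome.

    Returns (sites DataFrame, replicate tracks, merged track) plus the raw
    per-position count dicts for the brute-force oracle.
    """
    chrom_lengths = {"toy": chrom_len}
    reps = []
    for r in range(n_reps):
        track = CrosslinkTrack(chrom_lengths, label=f"rep{r + 1}")
        for strand in "+-":
            # sparse background plus a few hot clusters
            counts = rng.poisson(0.05, size=chrom_len)
            for _ in range(rng.integers(2, 6)):
                start = rng.integers(0, chrom_len - 30)
                counts[start:start + rng.integers(5, 25)] += rng.poisson(
                    2.0, size=None)
            track.data[("toy", strand)] = counts.astype(np.int64)
        reps.append(track)
    merged = CrosslinkTrack.merge(reps)
    rows = []
    for strand in "+-":
        counts = merged.counts("toy", strand)
        nonzero = np.flatnonzero(counts)
        if len(nonzero) == 0:
            continue
        take = rng.choice(nonzero, size=min(len(nonzero), rng.integers(5, 40)),
                          replace=False)
        for pos in np.sort(take):
            rows.append({"chrom": "toy", "pos": int(pos), "strand": strand,
                         "score": float(counts[pos]) + float(rng.random())})
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score"])
    return sites, reps, merged
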