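import numpy as np
import pandas as pd
import pytest

from tepop.panel import HaplotypePanel
from tepop.presence import PresenceMatrix


@pytest.fixture
def small_panel() -> HaplotypePanel:
    """Six haplotypes, nine sites; core site 4 splits 3 ancestral / 3 derived."""
    haps = np.array(
        [
            [0, 0, 1, 0, 0, 0, 0, 1, 0],
            [0, 0, 1, 0, 0, 0, 0, 1, 0],
            [0, 1, 0, 1, 0, 0, 1, 0, 1],
            [1, 0, 0, 0, 1, 1, 0, 0, 0],
            [1, 0, 0, 0, 1, 1, 0, 1, 0],
            [0, 1, 0, 1, 1, 1, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(haps, np.arange(9) * 1000 + 100, chrom="2L")


def random_panel(rng: np.random.Generator, n_max: int = 16, m_max: int = 60
                 ) -> HaplotypePanel:
    """A random small polymorphic panel for oracle-equivalence checks."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        m = int(rng.integers(5, m_max + 1))
        haps = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        freqs = haps.mean(axis=0)
        keep = (freqs > 0) & (freqs < 1)
        if keep.sum() >= 5:
            haps = haps[:, keep]
            pos = np.sort(rng.choice(100_000, size=haps.shape[1], replace=False))
            return HaplotypePanel(haps, pos, chrom="2L")


@pytest.fixture
def presence_8() -> PresenceMatrix:
    """Eight strains, 12 loci spanning the frequency classes."""
    rng = np.random.default_rng(42)
    strains = [f"S{i:03d}" for i in range(1, 9)]
    data = {}
    for j, f in enumerate([0.1, 0.1, 0.3, 0.3, 0.5, 0.5, 0.7, 0.7, 0.9, 1.0, 1.0, 1.0]):
        data[f"2L_{1000 * (j + 1)}_{1000 * (j + 1)}_pogo"] = rng.random(8) < f
    df = pd.DataFrame(data, index=strains)
    # guarantee at least one locus present everywhere and one rare
    df.iloc[:, -1] = True
    df.iloc[:, 0] = [True] + [False] * 7
    return PresenceMatrix(df)
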