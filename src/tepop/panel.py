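"""Phased haplotype panel: the in-memory container for selection scans."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypePanel:
    """Phased biallelic SNP haplotypes over one chromosome.

    Attributes
    ----------
    haplotypes
        ``(n_haplotypes, n_sites)`` int8 matrix; 0 = ancestral, 1 = derived.
    positions
        Physical positions in bp, strictly increasing.
    chrom
        Chromosome name.
    genetic_positions
        Optional cM positions, same length as ``positions``.
    hap_strains
        Strain id of each haplotype row (one or two rows per strain).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str = "chr"
    genetic_positions: np.ndarray | None = None
    hap_strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match number of sites")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("a panel needs at least two haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genetic_positions is not None:
            self.genetic_positions = np.asarray(self.genetic_positions, dtype=float)
            if self.genetic_positions.shape != self.positions.shape:
                raise ValueError("genetic positions length must match positions")
        if not self.hap_strains:
            self.hap_strains = [f"hap{i}" for i in range(self.haplotypes.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def derived_frequency(self, site: int) -> float:
        """Derived-allele frequency at a site index."""
        return float(self.haplotypes[:, site].mean())

    def derived_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def site_index(self, position: int) -> int:
        """Index of the site at (or nearest to) a physical position."""
        i = int(np.searchsorted(self.positions, position))
        if i >= self.n_sites:
            return self.n_sites - 1
        if i > 0 and position - self.positions[i - 1] <= self.positions[i] - position:
            return i - 1
        return i

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            self.haplotypes.copy(),
            self.positions.copy(),
            self.chrom,
            None if self.genetic_positions is None else self.genetic_positions.copy(),
            list(self.hap_strains),
        )
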