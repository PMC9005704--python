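"""Population-frequency classification, rarefaction and geographic sets.

Insertions are classified by the fraction of genomes carrying them: rare
(present in <10% of genomes), common (>=10% and <=95%) and fixed (>95%).
Rarefaction recomputes the class counts over random genome subsets of
increasing size to ask how many genomes are needed to capture the common
variation.  Boundary comparisons are done on integer counts (e.g. <10% of k
genomes means 10*present < k) so floating-point rounding can never flip a
class at the printed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from tepop.presence import PresenceMatrix

CLASSES = ("rare", "common", "fixed")


@dataclass(frozen=True)
class FrequencyThresholds:
    rare_below: float = 0.10
    fixed_above: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.rare_below < self.fixed_above < 1:
            raise ValueError("need 0 < rare_below < fixed_above < 1")


DEFAULT_THRESHOLDS = FrequencyThresholds()


def classify_frequency(f: float,
                       thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS) -> str:
    """Class of a single frequency: rare (< rare_below), fixed (> fixed_above),
    common otherwise."""
    if not 0 <= f <= 1:
        raise ValueError(f"frequency {f} outside [0, 1]")
    if f < thresholds.rare_below:
        return "rare"
    if f > thresholds.fixed_above:
        return "fixed"
    return "common"


def _classify_counts(present: np.ndarray, k: int,
                     thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS
                     ) -> dict[str, int]:
    """Exact-rational class counts for loci with ``present`` carriers out of
    ``k`` sampled genomes; loci absent from every sampled genome are not
    counted (they are unobservable in that subsample)."""
    present = present[present > 0]
    # thresholds as exact rationals; f < rare_below <=> present*den < num*k
    from fractions import Fraction

    rb = Fraction(thresholds.rare_below).limit_denominator(10**6)
    fa = Fraction(thresholds.fixed_above).limit_denominator(10**6)
    rare = int(np.sum(present * rb.denominator < rb.numerator * k))
    fixed = int(np.sum(present * fa.denominator > fa.numerator * k))
    return {"rare": rare, "fixed": fixed,
            "common": int(len(present) - rare - fixed)}


def classify_matrix(matrix: PresenceMatrix,
                    thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS
                    ) -> pd.Series:
    """Per-locus class over the full cohort."""
    counts = matrix.counts().values
    k = matrix.n_strains
    from fractions import Fraction

    rb = Fraction(thresholds.rare_below).limit_denominator(10**6)
    fa = Fraction(thresholds.fixed_above).limit_denominator(10**6)
    out = np.where(counts * rb.denominator < rb.numerator * k, "rare",
                   np.where(counts * fa.denominator > fa.numerator * k,
                            "fixed", "common"))
    return pd.Series(out, index=matrix.data.columns, name="class")


def rarefy(matrix: PresenceMatrix, k_min: int = 5, k_max: int | None = None,
           replicates: int = 30, seed: int = 0,
           thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Rarefaction curve: mean +- SD class counts over random genome subsets.

    For each k in [k_min, k_max], draws ``replicates`` subsets of strains
    without replacement, recomputes each locus's frequency among the k chosen
    strains and classifies it; loci absent from all k strains are excluded.
    At k equal to the cohort size every replicate is the full cohort, so the
    SD is zero by construction.
    """
    n = matrix.n_strains
    k_max = n if k_max is None else k_max
    if k_min > k_max:
        raise ValueError("k_min > k_max")
    if k_min < 2 or k_max > n:
        raise ValueError("need 2 <= k_min <= k_max <= cohort size")
    rng = np.random.default_rng(seed)
    data = matrix.data.values
    rows = []
    for k in range(k_min, k_max + 1):
        tallies = {c: [] for c in CLASSES}
        for _ in range(replicates):
            idx = rng.choice(n, size=k, replace=False)
            present = data[idx].sum(axis=0)
            counts = _classify_counts(present, k, thresholds)
            for c in CLASSES:
                tallies[c].append(counts[c])
        for c in CLASSES:
            v = np.array(tallies[c], dtype=float)
            rows.append({"k": k, "class": c, "mean": v.mean(),
                         "sd": v.std(ddof=1) if len(v) > 1 else 0.0})
    return pd.DataFrame(rows)


def rarefy_exhaustive(matrix: PresenceMatrix, k: int,
                      thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS
                      ) -> dict[str, float]:
    """Exact expected class counts over all C(n, k) subsets (small n only)."""
    data = matrix.data.values
    n = matrix.n_strains
    totals = {c: 0 for c in CLASSES}
    n_subsets = 0
    for combo in combinations(range(n), k):
        present = data[list(combo)].sum(axis=0)
        counts = _classify_counts(present, k, thresholds)
        for c in CLASSES:
            totals[c] += counts[c]
        n_subsets += 1
    return {c: totals[c] / n_subsets for c in CLASSES}


def common_set_intersections(matrix: PresenceMatrix,
                             ks: tuple[int, ...] = (10, 20, 30, 40, None),
                             seed: int = 0,
                             thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS
                             ) -> pd.DataFrame:
    """Intersection lattice of common-TE sets from one random subset per k.

    ``None`` in ``ks`` stands for the full cohort.  Returns one row per
    observed membership pattern (UpSet-style): boolean column per k plus a
    ``count`` column.
    """
    n = matrix.n_strains
    rng = np.random.default_rng(seed)
    sets: dict[int, set[str]] = {}
    for k in ks:
        kk = n if k is None else k
        if kk > n:
            raise ValueError(f"k={kk} exceeds cohort size {n}")
        idx = rng.choice(n, size=kk, replace=False)
        sub = matrix.subset_strains([matrix.strains[i] for i in sorted(idx)])
        cls = classify_matrix(sub, thresholds)
        sets[kk] = set(cls[cls == "common"].index)
    all_loci = set().union(*sets.values())
    patterns: dict[tuple[bool, ...], int] = {}
    order = sorted(sets)
    for locus in all_loci:
        pat = tuple(locus in sets[k] for k in order)
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = [dict(zip([f"k{k}" for k in order], pat), count=c)
            for pat, c in sorted(patterns.items())]
    return pd.DataFrame(rows)


def continental_sets(matrix: PresenceMatrix,
                     thresholds: FrequencyThresholds = DEFAULT_THRESHOLDS,
                     min_strains: int = 2) -> dict:
    """Per-continent frequency classes and region-specific common insertions.

    Frequencies are computed within each region's strains.  The summary lists
    insertions common in exactly one region and, among those, the ones absent
    (frequency zero) from each other region — candidates for local adaptation.
    """
    if matrix.metadata is None or "continent" not in matrix.metadata.columns:
        raise ValueError("presence matrix lacks continent metadata")
    regions = {}
    for region, grp in matrix.metadata.groupby("continent"):
        strains = [s for s in matrix.strains if s in set(grp.index)]
        if len(strains) < min_strains:
            import warnings

            warnings.warn(f"region {region!r} has <{min_strains} strains; excluded")
            continue
        sub = matrix.subset_strains(strains)
        regions[region] = {
            "classes": classify_matrix(sub, thresholds),
            "frequencies": sub.frequencies(),
        }
    region_names = sorted(regions)
    common_sets = {r: set(d["classes"][d["classes"] == "common"].index)
                   for r, d in regions.items()}
    specific = {}
    for r in region_names:
        others = [o for o in region_names if o != r]
        only_here = common_sets[r] - set().union(*(common_sets[o] for o in others)) \
            if others else common_sets[r]
        absent_elsewhere = {
            o: sorted(l for l in only_here
                      if regions[o]["frequencies"].get(l, 0) == 0)
            for o in others
        }
        specific[r] = {"common_only_here": sorted(only_here),
                       "absent_in": absent_elsewhere}
    return {"regions": regions, "region_specific": specific}
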