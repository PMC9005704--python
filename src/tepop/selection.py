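"""Extended-haplotype-homozygosity statistics: EHH, iHS, nSL and iHH12.

The statistics detect incomplete selective sweeps from the decay of haplotype
homozygosity around a core SNP.  EHH at distance x is the probability that two
randomly drawn haplotypes carrying the core allele are identical at every site
from the core out to x:

    EHH(x) = sum_h C(c_h, 2) / C(n_a, 2)

where c_h are the sizes of identical-haplotype classes among the n_a carriers.
iHS is ln(iHH_A / iHH_D), the log-ratio of the EHH integrals for ancestral vs
derived carriers; nSL is the same log-ratio with distance counted in number of
segregating sites; iHH12 integrates EHH computed over all haplotypes with the
two largest haplotype classes pooled, which keeps power under soft sweeps.

Standardization is done in derived-allele-frequency bins within each
chromosome, and significance is called against the empirical distribution of
standardized scores at putatively neutral SNPs (short-intron sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tepop.panel import HaplotypePanel

logger = logging.getLogger(__name__)

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAF_FLOOR = 0.05


class SiteUndefined(ValueError):
    """The requested statistic is undefined at this site (monomorphic core,
    fewer than two carriers, or a zero integral)."""


# ---------------------------------------------------------------------------
# EHH curves
# ---------------------------------------------------------------------------


@dataclass
class EHHSide:
    """One side of an EHH curve, ordered outward from the core.

    ``site_idx[0]`` is the core itself (EHH = 1 at distance 0).
    """

    site_idx: np.ndarray
    ehh: np.ndarray
    truncation: str  # "cutoff" | "chromosome-end"


@dataclass
class EHHCurve:
    core_idx: int
    allele_class: str  # "ancestral" | "derived" | "top2"
    left: EHHSide
    right: EHHSide
    panel: HaplotypePanel = field(repr=False)

    def distances(self, side: EHHSide, scale: str = "physical") -> np.ndarray:
        """Unsigned distances from the core for a side, in bp, cM or sites."""
        if scale == "sites":
            return np.abs(side.site_idx - self.core_idx).astype(float)
        if scale == "genetic":
            if self.panel.genetic_positions is None:
                raise ValueError("panel has no genetic positions")
            ref = self.panel.genetic_positions
        else:
            ref = self.panel.positions
        return np.abs(ref[side.site_idx] - ref[self.core_idx]).astype(float)


def _homozygosity(counts: np.ndarray, n: int, pool_top2: bool) -> float:
    if pool_top2 and len(counts) >= 2:
        counts = np.sort(counts)[::-1].astype(np.int64).copy()
        counts[0] += counts[1]
        counts = np.delete(counts, 1)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _extend(haps: np.ndarray, carriers: np.ndarray, core: int, step: int,
            cutoff: float, pool_top2: bool) -> EHHSide:
    """Walk outward from the core refining haplotype classes site by site.

    Stops after the first site whose EHH drops below ``cutoff`` (that point is
    included, matching the integration truncation rule) or at the chromosome
    end.  Classes only refine: once two haplotypes differ they never rejoin.
    """
    n = len(carriers)
    m = haps.shape[1]
    groups = np.zeros(n, dtype=np.int64)
    idx = [core]
    vals = [1.0]
    truncation = "chromosome-end"
    j = core + step
    while 0 <= j < m:
        alleles = haps[carriers, j].astype(np.int64)
        _, groups = np.unique(groups * 2 + alleles, return_inverse=True)
        counts = np.bincount(groups)
        e = _homozygosity(counts, n, pool_top2)
        idx.append(j)
        vals.append(e)
        if e < cutoff:
            truncation = "cutoff"
            break
        j += step
    return EHHSide(np.array(idx), np.array(vals), truncation)


def compute_ehh(panel: HaplotypePanel, core_idx: int, allele_class: str,
                cutoff: float = 0.0) -> EHHCurve:
    """EHH decay curve around a core site for one allele class.

    ``allele_class``: "ancestral" (allele 0 carriers), "derived" (allele 1)
    or "top2" (all haplotypes, two largest classes pooled — the EHH12 curve).
    ``cutoff`` truncates the walk after the first sub-cutoff point; 0 walks
    until homozygosity reaches zero or the chromosome end.
    """
    haps = panel.haplotypes
    col = haps[:, core_idx]
    if col.min() == col.max():
        raise SiteUndefined(f"core site {core_idx} is monomorphic")
    pool = False
    if allele_class == "ancestral":
        carriers = np.flatnonzero(col == 0)
    elif allele_class == "derived":
        carriers = np.flatnonzero(col == 1)
    elif allele_class == "top2":
        carriers = np.arange(haps.shape[0])
        pool = True
    else:
        raise ValueError(f"unknown allele class {allele_class!r}")
    if len(carriers) < 2:
        raise SiteUndefined(
            f"allele class {allele_class!r} has {len(carriers)} carrier(s) at site {core_idx}"
        )
    # stop once EHH is exactly 0: all further points contribute nothing
    eff_cutoff = max(cutoff, np.finfo(float).tiny)
    left = _extend(haps, carriers, core_idx, -1, eff_cutoff, pool)
    right = _extend(haps, carriers, core_idx, +1, eff_cutoff, pool)
    return EHHCurve(core_idx, allele_class, left, right, panel)


# ---------------------------------------------------------------------------
# Integration and per-site statistics
# ---------------------------------------------------------------------------


@dataclass
class IhhValue:
    value: float
    truncated: bool  # hit a chromosome end before reaching the EHH cutoff


def _integrate_side(distances: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    total = 0.0
    for i in range(1, len(ehh)):
        total += (ehh[i - 1] + ehh[i]) / 2.0 * (distances[i] - distances[i - 1])
        if ehh[i] < cutoff:
            break
    return total


def integrate_ihh(curve: EHHCurve, cutoff: float = DEFAULT_EHH_CUTOFF,
                  distance_scale: str = "physical") -> IhhValue:
    """Trapezoidal EHH integral, each side truncated at (and including) the
    first point below ``cutoff``, then summed over sides."""
    total = 0.0
    truncated = False
    for side in (curve.left, curve.right):
        d = curve.distances(side, distance_scale)
        total += _integrate_side(d, side.ehh, cutoff)
        if side.truncation == "chromosome-end" and (len(side.ehh) == 0 or side.ehh[-1] >= cutoff):
            truncated = True
    return IhhValue(total, truncated)


@dataclass
class SiteStat:
    value: float
    truncated: bool = False


def compute_ihs(panel: HaplotypePanel, core_idx: int,
                cutoff: float = DEFAULT_EHH_CUTOFF,
                distance_scale: str = "physical",
                maf_floor: float = DEFAULT_MAF_FLOOR) -> SiteStat:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived)."""
    daf = panel.derived_frequency(core_idx)
    if min(daf, 1 - daf) < maf_floor:
        raise SiteUndefined(f"minor allele frequency below {maf_floor} at site {core_idx}")
    a = compute_ehh(panel, core_idx, "ancestral", cutoff)
    d = compute_ehh(panel, core_idx, "derived", cutoff)
    ia = integrate_ihh(a, cutoff, distance_scale)
    id_ = integrate_ihh(d, cutoff, distance_scale)
    if ia.value == 0 or id_.value == 0:
        raise SiteUndefined(f"zero iHH at site {core_idx}")
    return SiteStat(float(np.log(ia.value / id_.value)), ia.truncated or id_.truncated)


def compute_nsl(panel: HaplotypePanel, core_idx: int,
                maf_floor: float = DEFAULT_MAF_FLOOR) -> SiteStat:
    """Unstandardized nSL = ln(SL_A / SL_D).

    SL for an allele class is the mean over carrier pairs of the length, in
    number of sites and counting the core, of the maximal interval around the
    core over which the pair is identical.  Equivalently
    SL = 1 + sum_k EHH_left(k) + sum_k EHH_right(k), summing until EHH reaches
    zero or the chromosome end (sites beyond the panel do not contribute).
    """
    daf = panel.derived_frequency(core_idx)
    if min(daf, 1 - daf) < maf_floor:
        raise SiteUndefined(f"minor allele frequency below {maf_floor} at site {core_idx}")

    def sl(allele_class: str) -> tuple[float, bool]:
        curve = compute_ehh(panel, core_idx, allele_class, cutoff=0.0)
        total = 1.0
        truncated = False
        for side in (curve.left, curve.right):
            total += float(side.ehh[1:].sum())
            if side.truncation == "chromosome-end" and side.ehh[-1] > 0:
                truncated = True
        return total, truncated

    sa, ta = sl("ancestral")
    sd, td = sl("derived")
    if sa == 0 or sd == 0:
        raise SiteUndefined(f"zero SL at site {core_idx}")
    return SiteStat(float(np.log(sa / sd)), ta or td)


def compute_ihh12(panel: HaplotypePanel, core_idx: int,
                  cutoff: float = DEFAULT_EHH_CUTOFF,
                  distance_scale: str = "physical") -> SiteStat:
    """Unstandardized iHH12: EHH integral over all haplotypes with the two
    largest haplotype classes pooled at every distance."""
    if panel.n_haplotypes < 4:
        raise SiteUndefined("iHH12 needs at least 4 haplotypes")
    curve = compute_ehh(panel, core_idx, "top2", cutoff)
    v = integrate_ihh(curve, cutoff, distance_scale)
    return SiteStat(v.value, v.truncated)


# ---------------------------------------------------------------------------
# Panel scan, normalization, neutral calibration
# ---------------------------------------------------------------------------


def scan_panel(panel: HaplotypePanel, cutoff: float = DEFAULT_EHH_CUTOFF,
               distance_scale: str | None = None,
               maf_floor: float = DEFAULT_MAF_FLOOR,
               drop_truncated: bool = True) -> pd.DataFrame:
    """Compute unstandardized iHS, nSL and iHH12 at every eligible site.

    Returns a DataFrame indexed by site with columns ``chrom``, ``pos``,
    ``daf``, ``ihs``, ``nsl``, ``ihh12`` (NaN where undefined or, when
    ``drop_truncated``, where the EHH walk hit a chromosome end before the
    cutoff).  ``distance_scale`` defaults to genetic when the panel carries
    genetic positions, physical otherwise.
    """
    if distance_scale is None:
        distance_scale = "genetic" if panel.genetic_positions is not None else "physical"
    rows = []
    for j in range(panel.n_sites):
        daf = panel.derived_frequency(j)
        rec = {"site": j, "chrom": panel.chrom, "pos": int(panel.positions[j]),
               "daf": daf, "ihs": np.nan, "nsl": np.nan, "ihh12": np.nan}
        for name, fn in (
            ("ihs", lambda: compute_ihs(panel, j, cutoff, distance_scale, maf_floor)),
            ("nsl", lambda: compute_nsl(panel, j, maf_floor)),
            ("ihh12", lambda: compute_ihh12(panel, j, cutoff, distance_scale)),
        ):
            try:
                st = fn()
            except SiteUndefined:
                continue
            if drop_truncated and st.truncated:
                continue
            rec[name] = st.value
        rows.append(rec)
    return pd.DataFrame(rows).set_index("site")


def normalize_scores(scores: pd.DataFrame, n_bins: int = 10,
                     statistics: tuple[str, ...] = ("ihs", "nsl", "ihh12")) -> pd.DataFrame:
    """Standardize each statistic in equal-width derived-frequency bins within
    each chromosome: z = (u - mean_bin) / sd_bin, sample sd (n-1).

    Adds ``bin`` plus ``<stat>_std`` columns; sites in bins with fewer than
    two finite values or zero sd stay NaN (unstandardizable).
    """
    out = scores.copy()
    out["bin"] = np.clip((out["daf"] * n_bins).astype(int), 0, n_bins - 1)
    for stat in statistics:
        out[f"{stat}_std"] = np.nan
        for (_, _), grp in out.groupby(["chrom", "bin"]):
            vals = grp[stat].dropna()
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if sd == 0:
                continue
            out.loc[vals.index, f"{stat}_std"] = (vals - vals.mean()) / sd
    return out


def neutral_sites(panel: HaplotypePanel, introns,
                  max_intron_len: int = 65, offset_min: int = 8,
                  offset_max: int = 30) -> np.ndarray:
    """Site indices of SNPs in the putatively neutral short-intron class.

    A site qualifies if it falls at offset 8-30 (1-based from the intron's 5'
    end on the transcribed strand) of an intron of length <= 65 bp.
    ``introns`` is an iterable of (chrom, start, end, strand), 0-based
    half-open.
    """
    keep = set()
    pos = panel.positions
    for chrom, start, end, strand in introns:
        if chrom != panel.chrom or end - start > max_intron_len:
            continue
        if strand == "+":
            lo, hi = start + offset_min - 1, start + offset_max - 1
        else:
            lo, hi = end - offset_max, end - offset_min
        lo, hi = max(lo, start), min(hi, end - 1)
        i0 = int(np.searchsorted(pos, lo, side="left"))
        i1 = int(np.searchsorted(pos, hi, side="right"))
        keep.update(range(i0, i1))
    return np.array(sorted(keep), dtype=int)


def call_significant(scores: pd.DataFrame, neutral_idx: np.ndarray,
                     percentile: float = 95.0,
                     statistics: tuple[str, ...] = ("ihs", "nsl", "ihh12"),
                     min_neutral: int = 20) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag sites whose standardized score exceeds the neutral-class threshold.

    Per statistic the threshold is the ``percentile``-th percentile (linear
    interpolation) of the neutral sites' standardized values; for iHS and nSL
    the comparison is on |z| (sweeps push either tail), for iHH12 on z.  Sites
    strictly greater than the threshold are flagged.
    """
    out = scores.copy()
    thresholds: dict[str, float] = {}
    for stat in statistics:
        col = f"{stat}_std"
        mag = out[col].abs() if stat in ("ihs", "nsl") else out[col]
        neut = mag.loc[mag.index.intersection(pd.Index(neutral_idx))].dropna()
        if len(neut) < min_neutral:
            raise ValueError(
                f"only {len(neut)} neutral sites with standardized {stat}; "
                f"need >= {min_neutral} — enlarge the panel or supply a threshold"
            )
        thr = float(np.percentile(neut.values, percentile))
        thresholds[stat] = thr
        out[f"{stat}_sig"] = (mag > thr).fillna(False)
    logger.info("neutral thresholds: %s", thresholds)
    return out, thresholds
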