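"""Candidate adaptive TE insertions: sweep-SNP pairing, carrier co-occurrence
rules, candidate filters, gene context and family enrichment.

A TE becomes a candidate when (i) it survives the frequency (10-95%),
recombination (>0) and family-exclusion (old, neutrally fixed families)
filters, (ii) a SNP with a significant haplotype statistic lies within 1 kb,
and (iii) the strains carrying the TE co-occur with the strains carrying the
swept allele under the tally rules below — the operational stand-in for
linkage disequilibrium between the insertion and the sweeping haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tepop.io import GeneModel, RecombinationMap
from tepop.orthology import OrthologGroup
from tepop.presence import PresenceMatrix

logger = logging.getLogger(__name__)

DEFAULT_PAIR_WINDOW = 1000
DEFAULT_EXCLUDED_FAMILIES = frozenset({"INE-1", "LARD"})


# ---------------------------------------------------------------------------
# SNP-TE pairing
# ---------------------------------------------------------------------------


@dataclass
class TESnpPair:
    group_id: str
    snp_pos: int
    distance: int
    statistic: str
    n_te: int = 0        # strains carrying the TE
    n_both: int = 0      # strains carrying TE and swept allele
    n_te_only: int = 0   # strains carrying TE but not the swept allele

    def __post_init__(self) -> None:
        if self.n_both + self.n_te_only != self.n_te:
            raise ValueError("carrier tallies inconsistent: n_both + n_te_only != n_te")


def pair_te_snp(groups: list[OrthologGroup], snps: pd.DataFrame,
                window: int = DEFAULT_PAIR_WINDOW) -> list[TESnpPair]:
    """Pair each significant SNP with every TE strictly closer than ``window``.

    ``snps`` needs columns ``chrom``, ``pos`` and ``statistic``.  Distance is
    the minimum gap between the SNP position and the TE interval (0 inside).
    """
    pairs = []
    for _, snp in snps.iterrows():
        for g in groups:
            if g.chrom != snp["chrom"]:
                continue
            pos = int(snp["pos"])
            if pos < g.start:
                d = g.start - pos
            elif pos >= max(g.end, g.start + 1):
                d = pos - max(g.end - 1, g.start)
            else:
                d = 0
            if d < window:
                pairs.append(TESnpPair(g.group_id, pos, d, str(snp["statistic"])))
    return pairs


def tally_pair(pair: TESnpPair, presence: PresenceMatrix,
               swept_carriers: set[str]) -> TESnpPair:
    """Fill a pair's carrier tallies from the presence matrix and the set of
    strains carrying the swept allele (any haplotype of the strain)."""
    col = presence.data[pair.group_id]
    te_strains = set(col.index[col])
    pair.n_te = len(te_strains)
    pair.n_both = len(te_strains & swept_carriers)
    pair.n_te_only = pair.n_te - pair.n_both
    return pair


def cooccurrence_test(pair: TESnpPair) -> tuple[bool, str]:
    """Carrier co-occurrence rule for a SNP-TE pair.

    Pass requires: for TEs present in 5-6 strains, at least 4 strains carrying
    both the swept allele and the TE; for TEs in >=7 strains, a strict
    majority carrying both; and in all cases the TE absent from every strain
    lacking the swept allele.  TEs in fewer than 5 strains fail (below the
    rule's domain).
    """
    if pair.n_te < 0 or pair.n_both < 0 or pair.n_te_only < 0:
        raise ValueError("negative carrier tallies")
    if pair.n_te_only > 0:
        return False, f"TE present in {pair.n_te_only} strain(s) without the swept allele"
    if pair.n_te < 5:
        return False, f"TE present in only {pair.n_te} strains (<5)"
    if pair.n_te <= 6:
        if pair.n_both >= 4:
            return True, ""
        return False, f"n_both={pair.n_both} < 4 for n_TE={pair.n_te}"
    if pair.n_both * 2 > pair.n_te:
        return True, ""
    return False, f"n_both={pair.n_both} not a majority of n_TE={pair.n_te}"


# ---------------------------------------------------------------------------
# Candidate filters
# ---------------------------------------------------------------------------


@dataclass
class FilterAudit:
    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_retained + sum(self.removed.values())


def candidate_filter(groups: list[OrthologGroup], rec_map: RecombinationMap,
                     freq_min: float = 0.10, freq_max: float = 0.95,
                     excluded_families: frozenset = DEFAULT_EXCLUDED_FAMILIES
                     ) -> tuple[list[OrthologGroup], FilterAudit]:
    """Candidate pool: frequency in [freq_min, freq_max], recombination rate
    above zero at the representative midpoint, family not excluded.

    Filters apply in order frequency -> recombination -> family; each removed
    group is attributed to the first filter that rejects it.
    """
    audit = FilterAudit(n_input=len(groups),
                        removed={"frequency": 0, "recombination": 0, "family": 0,
                                 "unmapped_position": 0})
    kept = []
    for g in groups:
        f = g.frequency
        n, k = len(g.members), len(g.strains)
        # exact count comparisons at the printed percent thresholds
        if n * 10 < k or n * 20 > 19 * k:
            audit.removed["frequency"] += 1
            continue
        mid = (g.start + g.end) // 2
        try:
            rate = rec_map.rate_at(g.chrom, mid)
        except (KeyError, ValueError):
            logger.warning("group %s outside recombination map; excluded", g.group_id)
            audit.removed["unmapped_position"] += 1
            continue
        if rate <= 0:
            audit.removed["recombination"] += 1
            continue
        if g.family in excluded_families:
            audit.removed["family"] += 1
            continue
        kept.append(g)
    audit.n_retained = len(kept)
    audit.check()
    logger.info("candidate filter: %d -> %d (removed %s)",
                audit.n_input, audit.n_retained, audit.removed)
    return kept, audit


def screen_candidates(groups: list[OrthologGroup], snps: pd.DataFrame,
                      presence: PresenceMatrix,
                      swept_carriers_by_snp: dict[int, set[str]],
                      rec_map: RecombinationMap,
                      window: int = DEFAULT_PAIR_WINDOW,
                      excluded_families: frozenset = DEFAULT_EXCLUDED_FAMILIES
                      ) -> pd.DataFrame:
    """Full candidate screen: filter -> pair -> co-occurrence.

    ``swept_carriers_by_snp`` maps SNP position to the strain set carrying the
    swept allele there.  Returns one row per passing (TE, SNP) pair.
    """
    pool, _ = candidate_filter(groups, rec_map,
                               excluded_families=excluded_families)
    pairs = pair_te_snp(pool, snps, window)
    rows = []
    for p in pairs:
        carriers = swept_carriers_by_snp.get(p.snp_pos, set())
        tally_pair(p, presence, carriers)
        ok, reason = cooccurrence_test(p)
        if ok:
            rows.append({"group_id": p.group_id, "snp_pos": p.snp_pos,
                         "distance": p.distance, "statistic": p.statistic,
                         "n_te": p.n_te, "n_both": p.n_both})
    return pd.DataFrame(rows, columns=["group_id", "snp_pos", "distance",
                                       "statistic", "n_te", "n_both"])


# ---------------------------------------------------------------------------
# Gene context
# ---------------------------------------------------------------------------

LOCATION_PRIORITY = ("five_prime_UTR", "three_prime_UTR", "CDS", "intron")
LOCATION_LABELS = {"five_prime_UTR": "5UTR", "three_prime_UTR": "3UTR",
                   "CDS": "CDS", "intron": "INTRON"}


def assign_gene_context(te_interval: tuple[str, int, int],
                        genes: list[GeneModel],
                        window: int = 1000) -> tuple[str, list[str]]:
    """Genomic location label of a TE relative to protein-coding genes.

    Labels resolve on the longest transcript: overlap with a feature gives
     5UTR/3UTR/CDS/INTRON; no overlap but within the 1 kb window upstream of
    the TSS gives PROMOTER; a nearest gene strictly closer than ``window``
    (downstream side) is reported with label Intergenic-proximal collapsed to
    Intergenic; otherwise Intergenic with no gene.  All genes at distance 0,
    or tied at the minimal distance, are reported.
    """
    chrom, start, end = te_interval
    mid = (start + end) // 2
    overlapping: list[tuple[str, str]] = []
    promoter: list[str] = []
    nearest: list[tuple[int, str]] = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if start < g.end and end > g.start:
            label = "INTRON"
            tr = g.longest_transcript
            for kind in LOCATION_PRIORITY:
                if any(start < fe and end > fs
                       for fs, fe in tr.features.get(kind, [])):
                    label = LOCATION_LABELS[kind]
                    break
            overlapping.append((g.gene_id, label))
            continue
        if g.strand == "+":
            in_promoter = g.start - window <= mid < g.start
        else:
            in_promoter = g.end <= mid < g.end + window
        d = g.start - end if end <= g.start else start - g.end
        if in_promoter:
            promoter.append(g.gene_id)
        elif 0 <= d < window:
            nearest.append((d, g.gene_id))
    if overlapping:
        label = overlapping[0][1]
        return label, [gid for gid, _ in overlapping]
    if promoter:
        return "PROMOTER", promoter
    if nearest:
        dmin = min(d for d, _ in nearest)
        return "Intergenic", [gid for d, gid in nearest if d == dmin]
    return "Intergenic", []


# ---------------------------------------------------------------------------
# Family enrichment and candidate-list merging
# ---------------------------------------------------------------------------


def enrichment_test(focal: list[str], background: list[str],
                    continuity_correction: bool = False) -> pd.DataFrame:
    """Per-group 2x2 chi-square enrichment of focal vs background membership.

    ``focal`` and ``background`` are group labels (family or superfamily) per
    insertion; the background must contain the focal set.  When an expected
    cell drops below 1 the test switches to Fisher's exact test (noted in the
    ``test`` column).  P-values are Benjamini-Hochberg adjusted across groups.
    """
    focal_s = pd.Series(focal)
    bg_s = pd.Series(background)
    rows = []
    for fam in sorted(bg_s.unique()):
        a = int((focal_s == fam).sum())
        b = len(focal_s) - a
        c = int((bg_s == fam).sum()) - a
        d = len(bg_s) - len(focal_s) - c
        table = np.array([[a, b], [c, d]])
        if table.sum() == 0 or min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            stat, p, test = np.nan, 1.0, "degenerate"
        else:
            expected = stats.contingency.expected_freq(table)
            if expected.min() < 1:
                _, p = stats.fisher_exact(table)
                stat, test = np.nan, "fisher"
            else:
                stat, p, _, _ = stats.chi2_contingency(
                    table, correction=continuity_correction)
                test = "chi2"
        rows.append({"group": fam, "n_focal": a, "n_background": a + c,
                     "statistic": stat, "p": p, "test": test})
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def merge_candidate_lists(*id_sets) -> list[str]:
    """Union of candidate-insertion id lists from multiple studies (shared
    insertions counted once)."""
    merged: set[str] = set()
    for ids in id_sets:
        merged.update(ids)
    return sorted(merged)
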