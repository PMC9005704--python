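"""Transfer of per-strain TE annotations onto a common reference.

Each TE copy is located on the reference through its two flanking sequences:
flanks are placed by exact k-mer seeding with ungapped extension (or by
externally supplied alignments), classified as mapping unequivocally,
multiply, partially or not at all, and the transfer is called reliable or
unreliable; a multiply-mapping flank can be rescued when its placement
nearest the other flank shares the same neighbouring gene on both genomes
(synteny anchoring).  Reliable transfers from all strains are then clustered
into orthologous insertion groups in a family-aware fashion.

The internal placement mode assumes genomes that share near-exact sequence
with the reference outside the insertions (the synthetic cohorts here, or
high-quality assemblies of close strains); real-data users may instead supply
flank-to-reference alignments produced by a long-read aligner.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from tepop.io import GeneModel, TEInsertionRecord
from tepop.presence import PresenceMatrix

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 1000
DEFAULT_POSITION_TOLERANCE = 100
DEFAULT_GAP_TOLERANCE = 50
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_COV = 0.8

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Flank extraction and placement
# ---------------------------------------------------------------------------


@dataclass
class Flank:
    side: str  # "left" | "right"
    chrom: str
    start: int
    end: int
    seq: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Placement:
    chrom: str
    start: int
    end: int
    identity: float  # percent
    coverage: float  # aligned fraction of the flank
    orientation: str  # "+" | "-"


@dataclass
class FlankPlacement:
    te: TEInsertionRecord
    left: Flank
    right: Flank
    left_hits: list[Placement] = field(default_factory=list)
    right_hits: list[Placement] = field(default_factory=list)
    left_class: str = "unmapped"   # unequivocal | multiple | partial | unmapped
    right_class: str = "unmapped"


def extract_flanks(te: TEInsertionRecord, genome: dict[str, str],
                   flank_bp: int = DEFAULT_FLANK_BP) -> tuple[Flank, Flank]:
    """Left and right flanking sequences in strain coordinates, truncated at
    chromosome ends (a zero-length flank leads to one-sided placement)."""
    seq = genome[te.chrom]
    ls = max(0, te.start - flank_bp)
    left = Flank("left", te.chrom, ls, te.start, seq[ls:te.start],
                 truncated=ls == 0 and te.start < flank_bp)
    re_ = min(len(seq), te.end + flank_bp)
    right = Flank("right", te.chrom, te.end, re_, seq[te.end:re_],
                  truncated=re_ == len(seq) and len(seq) - te.end < flank_bp)
    return left, right


class ReferenceIndex:
    """Exact k-mer index of a reference genome with ungapped extension."""

    def __init__(self, reference: dict[str, str], k: int = 31):
        self.reference = reference
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in reference.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((chrom, i))

    def _extend(self, query: str, chrom: str, ref_start: int) -> Placement | None:
        """Ungapped comparison of the whole query anchored at ``ref_start``."""
        ref = self.reference[chrom]
        end = ref_start + len(query)
        aligned = min(end, len(ref)) - ref_start
        if aligned <= 0:
            return None
        window = ref[ref_start:ref_start + aligned]
        matches = sum(a == b for a, b in zip(query[:aligned], window))
        identity = 100.0 * matches / aligned
        return Placement(chrom, ref_start, ref_start + aligned, identity,
                         aligned / len(query), "+")

    def place(self, query: str, min_identity: float = DEFAULT_MIN_IDENTITY
              ) -> list[Placement]:
        """All placements of ``query`` seeded by its first k-mer, both strands."""
        if len(query) < self.k:
            return []
        hits: list[Placement] = []
        seen: set[tuple[str, int, str]] = set()
        for oriented, orient in ((query, "+"), (revcomp(query), "-")):
            seed = oriented[: self.k]
            for chrom, pos in self._index.get(seed, []):
                key = (chrom, pos, orient)
                if key in seen:
                    continue
                seen.add(key)
                p = self._extend(oriented, chrom, pos)
                if p is not None and p.identity >= min_identity:
                    p.orientation = orient
                    hits.append(p)
        return hits


def place_flanks(flanks: tuple[Flank, Flank], ref_index: ReferenceIndex,
                 te: TEInsertionRecord,
                 min_identity: float = DEFAULT_MIN_IDENTITY,
                 min_cov: float = DEFAULT_MIN_COV) -> FlankPlacement:
    """Place both flanks on the reference and classify each mapping.

    Classes: ``unequivocal`` (exactly one full-coverage hit), ``multiple``,
    ``partial`` (best hit covers less than ``min_cov`` of the flank) or
    ``unmapped``.  Contradictory orientations between the two flanks demote
    both to ``multiple``.
    """
    left, right = flanks
    fp = FlankPlacement(te, left, right)

    def classify(flank: Flank) -> tuple[list[Placement], str]:
        if len(flank) == 0:
            return [], "unmapped"
        hits = ref_index.place(flank.seq, min_identity)
        full = [h for h in hits if h.coverage >= min_cov]
        if not hits:
            return [], "unmapped"
        if not full:
            return hits, "partial"
        if len(full) == 1:
            return full, "unequivocal"
        return full, "multiple"

    fp.left_hits, fp.left_class = classify(left)
    fp.right_hits, fp.right_class = classify(right)
    if (fp.left_class == "unequivocal" and fp.right_class == "unequivocal"
            and fp.left_hits[0].orientation != fp.right_hits[0].orientation):
        fp.left_class = fp.right_class = "multiple"
    return fp


# ---------------------------------------------------------------------------
# Gene-synteny anchors and transfer classification
# ---------------------------------------------------------------------------


class GeneAnchors:
    """Nearest-gene lookup on both the strain and the reference genome."""

    def __init__(self, strain_genes: dict[str, list[GeneModel]],
                 reference_genes: list[GeneModel]):
        self._strain = {s: self._prep(g) for s, g in strain_genes.items()}
        self._ref = self._prep(reference_genes)

    @staticmethod
    def _prep(genes: list[GeneModel]) -> dict[str, list[tuple[int, int, str]]]:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end, g.gene_id))
        for v in by_chrom.values():
            v.sort()
        return by_chrom

    @staticmethod
    def _nearest(table, chrom: str, pos: int) -> str | None:
        best, best_d = None, None
        for s, e, gid in table.get(chrom, []):
            d = 0 if s <= pos < e else min(abs(pos - s), abs(pos - (e - 1)))
            if best_d is None or d < best_d:
                best, best_d = gid, d
        return best

    def nearest_strain(self, strain: str, chrom: str, pos: int) -> str | None:
        return self._nearest(self._strain.get(strain, {}), chrom, pos)

    def nearest_reference(self, chrom: str, pos: int) -> str | None:
        return self._nearest(self._ref, chrom, pos)


@dataclass
class TransferredTE:
    te: TEInsertionRecord
    chrom: str | None
    ref_start: int | None
    ref_end: int | None
    reliability: str  # "reliable" | "unreliable"
    reason: str = ""
    transfer_note: str = "clean"  # clean | tandem | nested | one-sided

    @property
    def midpoint(self) -> float:
        return (self.ref_start + self.ref_end) / 2.0


def classify_transfer(placement: FlankPlacement,
                      gene_anchors: GeneAnchors | None = None,
                      gap_tolerance: int = DEFAULT_GAP_TOLERANCE) -> TransferredTE:
    """Decide whether a flank placement yields a reliable transfer.

    Reliable: both flanks unequivocal, on the same chromosome, concordant in
    orientation, with a reference gap between the placements no larger than
    ``gap_tolerance`` plus the TE's own length (the insertion may be present
    in the reference) and no smaller than ``-gap_tolerance`` (target-site
    duplications overlap slightly).  A single multiply-mapping flank is
    rescued when its placement nearest the other flank shares the strain-side
    flanking gene on the reference.  The projected interval is the gap between
    the placed flanks; zero length marks insertions absent in the reference.
    """
    te = placement.te

    def unreliable(reason: str) -> TransferredTE:
        return TransferredTE(te, None, None, None, "unreliable", reason)

    lc, rc = placement.left_class, placement.right_class
    lhit: Placement | None = placement.left_hits[0] if lc == "unequivocal" else None
    rhit: Placement | None = placement.right_hits[0] if rc == "unequivocal" else None
    note = "clean"

    if lc == "unmapped" and rc == "unmapped":
        return unreliable("both flanks unmapped")

    # synteny rescue of one multiply-mapping flank
    if lhit is None and lc == "multiple" and rhit is not None:
        lhit = _rescue(placement.left_hits, rhit, placement.left, te.strain_id,
                       gene_anchors)
        if lhit is None:
            return unreliable("left flank multiple, no synteny rescue")
    if rhit is None and rc == "multiple" and lhit is not None:
        rhit = _rescue(placement.right_hits, lhit, placement.right, te.strain_id,
                       gene_anchors)
        if rhit is None:
            return unreliable("right flank multiple, no synteny rescue")

    # one-sided placement when the other flank is absent (contig edge)
    if lhit is not None and len(placement.right) == 0:
        return TransferredTE(te, lhit.chrom, lhit.end, lhit.end, "reliable",
                             transfer_note="one-sided")
    if rhit is not None and len(placement.left) == 0:
        return TransferredTE(te, rhit.chrom, rhit.start, rhit.start, "reliable",
                             transfer_note="one-sided")

    if lhit is None or rhit is None:
        return unreliable(f"flank classes {lc}/{rc}")
    if lhit.chrom != rhit.chrom:
        return unreliable("flanks on different chromosomes")
    if lhit.orientation != rhit.orientation:
        return unreliable("discordant flank orientations")

    if lhit.orientation == "+":
        gap = rhit.start - lhit.end
        start, end = lhit.end, rhit.start
    else:
        gap = lhit.start - rhit.end
        start, end = rhit.end, lhit.start
    if gap > gap_tolerance + te.length:
        return unreliable(f"reference gap {gap} exceeds tolerance")
    if gap < -gap_tolerance:
        return unreliable(f"flank placements overlap by {-gap} bp")
    if gap < 0:
        start = end = (start + end) // 2
    return TransferredTE(te, lhit.chrom, start, max(end, start), "reliable",
                         transfer_note=note)


def _rescue(hits: list[Placement], other: Placement, flank: Flank,
            strain: str, anchors: GeneAnchors | None) -> Placement | None:
    same = [h for h in hits if h.chrom == other.chrom
            and h.orientation == other.orientation]
    if not same:
        return None
    cand = min(same, key=lambda h: abs((h.start + h.end) / 2
                                       - (other.start + other.end) / 2))
    if anchors is None:
        return None
    g_strain = anchors.nearest_strain(strain, flank.chrom,
                                      (flank.start + flank.end) // 2)
    g_ref = anchors.nearest_reference(cand.chrom, (cand.start + cand.end) // 2)
    if g_strain is not None and g_strain == g_ref:
        return cand
    return None


def transfer_strain(records: list[TEInsertionRecord], genome: dict[str, str],
                    ref_index: ReferenceIndex,
                    flank_bp: int = DEFAULT_FLANK_BP,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_cov: float = DEFAULT_MIN_COV,
                    gene_anchors: GeneAnchors | None = None,
                    gap_tolerance: int = DEFAULT_GAP_TOLERANCE
                    ) -> list[TransferredTE]:
    """Transfer every TE of one strain; nothing is dropped silently — each
    record comes back either reliable or unreliable with a reason."""
    out = []
    for te in records:
        flanks = extract_flanks(te, genome, flank_bp)
        placement = place_flanks(flanks, ref_index, te, min_identity, min_cov)
        out.append(classify_transfer(placement, gene_anchors, gap_tolerance))
    n_rel = sum(t.reliability == "reliable" for t in out)
    logger.info("strain %s: %d/%d transfers reliable",
                records[0].strain_id if records else "?", n_rel, len(out))
    return out


# ---------------------------------------------------------------------------
# Ortholog clustering
# ---------------------------------------------------------------------------


@dataclass
class OrthologGroup:
    group_id: str
    chrom: str
    start: int
    end: int
    family: str
    members: dict[str, TransferredTE]
    strains: list[str]

    @property
    def presence(self) -> pd.Series:
        return pd.Series([s in self.members for s in self.strains],
                         index=self.strains, name=self.group_id)

    @property
    def frequency(self) -> float:
        return len(self.members) / len(self.strains)

    @property
    def member_lengths(self) -> list[int]:
        return [t.te.length for t in self.members.values()]


def cluster_orthologs(transferred: list[TransferredTE], strains: list[str],
                      position_tolerance: int = DEFAULT_POSITION_TOLERANCE
                      ) -> tuple[list[OrthologGroup], list[TransferredTE]]:
    """Single-linkage clustering of reliable transfers into ortholog groups.

    Transfers of the same family on the same chromosome whose representative
    midpoints chain within ``position_tolerance`` bp form one group.  A second
    same-strain member in a group is flagged tandem and set aside (the member
    nearest the group median is kept).  Returns (groups, tandem-flagged).
    The result does not depend on the input order.
    """
    reliable = [t for t in transferred if t.reliability == "reliable"]
    tandem: list[TransferredTE] = []
    groups: list[OrthologGroup] = []
    keyed: dict[tuple[str, str], list[TransferredTE]] = {}
    for t in reliable:
        keyed.setdefault((t.chrom, t.te.family), []).append(t)
    for (chrom, family), items in sorted(keyed.items()):
        items.sort(key=lambda t: (t.midpoint, t.te.strain_id, t.te.start))
        chains: list[list[TransferredTE]] = [[items[0]]]
        for t in items[1:]:
            if t.midpoint - chains[-1][-1].midpoint <= position_tolerance:
                chains[-1].append(t)
            else:
                chains.append([t])
        for chain in chains:
            med = statistics.median(t.midpoint for t in chain)
            members: dict[str, TransferredTE] = {}
            for t in sorted(chain, key=lambda t: (abs(t.midpoint - med),
                                                  t.te.start)):
                sid = t.te.strain_id
                if sid in members:
                    t.transfer_note = "tandem"
                    tandem.append(t)
                else:
                    members[sid] = t
            rep = min(members.values(), key=lambda t: (abs(t.midpoint - med),
                                                       t.ref_start))
            gid = f"{chrom}_{rep.ref_start}_{rep.ref_end}_{family}"
            groups.append(OrthologGroup(gid, chrom, rep.ref_start, rep.ref_end,
                                        family, members, list(strains)))
    groups.sort(key=lambda g: (g.chrom, g.start, g.family))
    return groups, tandem


def groups_to_presence(groups: list[OrthologGroup], strains: list[str],
                       metadata: pd.DataFrame | None = None) -> PresenceMatrix:
    data = pd.DataFrame(
        {g.group_id: [s in g.members for s in strains] for g in groups},
        index=pd.Index(strains, name="strain"),
    )
    return PresenceMatrix(data, metadata)


# ---------------------------------------------------------------------------
# Filters and annotation comparison
# ---------------------------------------------------------------------------


def filter_groups_by_length(groups: list[OrthologGroup], min_len: int = 120
                            ) -> list[OrthologGroup]:
    """Keep groups in which strictly more than half the member copies are
    longer than ``min_len`` bp (a guard against fragmented annotations)."""
    kept = [g for g in groups
            if sum(l > min_len for l in g.member_lengths) * 2 > len(g.member_lengths)]
    logger.info("length filter (> %d bp majority): %d/%d groups kept",
                min_len, len(kept), len(groups))
    return kept


def postfilter_annotation(records: list[TEInsertionRecord],
                          min_copy_len: int = 100,
                          satellite_intervals=None,
                          max_sat_overlap: float = 0.8
                          ) -> list[TEInsertionRecord]:
    """Post-annotation filters: drop copies shorter than ``min_copy_len`` and
    copies with more than ``max_sat_overlap`` of their length under satellite
    annotations."""
    trees: dict[str, IntervalTree] = {}
    if satellite_intervals:
        for chrom, s, e in satellite_intervals:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    out = []
    for r in records:
        if r.length < min_copy_len:
            continue
        if trees:
            cov = _coverage(trees.get(r.chrom), r.start, r.end)
            if cov / r.length > max_sat_overlap:
                continue
        out.append(r)
    return out


def _coverage(tree: IntervalTree | None, start: int, end: int) -> int:
    if tree is None:
        return 0
    ivs = sorted((max(iv.begin, start), min(iv.end, end))
                 for iv in tree.overlap(start, end))
    total, cursor = 0, start
    for s, e in ivs:
        s = max(s, cursor)
        if e > s:
            total += e - s
            cursor = e
    return total


def compare_annotations(set_a: list[TEInsertionRecord],
                        set_b: list[TEInsertionRecord],
                        reciprocal_cov: float = 0.95) -> dict:
    """Family-aware reciprocal-coverage matching between two annotation sets.

    A pair matches when each copy covers at least ``reciprocal_cov`` of the
    other's length and the families agree.  Returns matched/unique counts per
    set plus per-family tallies.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for j, r in enumerate(set_b):
        trees.setdefault((r.chrom, r.family), IntervalTree()).addi(r.start, r.end, j)
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    for i, a in enumerate(set_a):
        tree = trees.get((a.chrom, a.family))
        if tree is None:
            continue
        for iv in tree.overlap(a.start, a.end):
            ov = min(a.end, iv.end) - max(a.start, iv.begin)
            if (ov >= reciprocal_cov * a.length
                    and ov >= reciprocal_cov * (iv.end - iv.begin)):
                matched_a.add(i)
                matched_b.add(iv.data)
    fam_counts = (
        pd.Series([set_a[i].family for i in matched_a]).value_counts().to_dict()
        if matched_a else {}
    )
    return {
        "n_a": len(set_a), "n_b": len(set_b),
        "matched_a": len(matched_a), "matched_b": len(matched_b),
        "unique_a": len(set_a) - len(matched_a),
        "unique_b": len(set_b) - len(matched_b),
        "matched_families": fam_counts,
    }
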