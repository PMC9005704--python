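"""Flank placement, transfer classification, clustering and filters."""

import numpy as np
import pytest

from tepop.io import GeneModel, TEInsertionRecord, Transcript
from tepop.orthology import (
    Flank,
    FlankPlacement,
    GeneAnchors,
    OrthologGroup,
    Placement,
    ReferenceIndex,
    TransferredTE,
    classify_transfer,
    cluster_orthologs,
    compare_annotations,
    extract_flanks,
    filter_groups_by_length,
    place_flanks,
    postfilter_annotation,
    revcomp,
    transfer_strain,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFlanks:
    def test_interior_flanks_have_requested_length(self):
        rng = np.random.default_rng(0)
        genome = {"2L": _random_seq(rng, 10_000)}
        te = TEInsertionRecord("s1", "2L", 4000, 4500, "pogo")
        left, right = extract_flanks(te, genome, flank_bp=1000)
        assert (left.start, left.end) == (3000, 4000)
        assert (right.start, right.end) == (4500, 5500)
        assert left.seq == genome["2L"][3000:4000]
        assert right.seq == genome["2L"][4500:5500]
        assert not left.truncated and not right.truncated

    def test_chromosome_start_truncates_left_flank(self):
        rng = np.random.default_rng(1)
        genome = {"2L": _random_seq(rng, 5000)}
        te = TEInsertionRecord("s1", "2L", 300, 700, "pogo")
        left, right = extract_flanks(te, genome, flank_bp=1000)
        assert (left.start, left.end, left.truncated) == (0, 300, True)
        assert len(left) == 300

    def test_te_at_position_zero_gives_zero_length_left_flank(self):
        rng = np.random.default_rng(2)
        genome = {"2L": _random_seq(rng, 5000)}
        te = TEInsertionRecord("s1", "2L", 0, 400, "pogo")
        left, _ = extract_flanks(te, genome)
        assert len(left) == 0 and left.truncated


class TestPlacement:
    def test_exact_unique_placement(self):
        rng = np.random.default_rng(3)
        ref = {"2L": _random_seq(rng, 8000)}
        idx = ReferenceIndex(ref)
        (hit,) = idx.place(ref["2L"][2000:3000])
        assert (hit.chrom, hit.start, hit.end) == ("2L", 2000, 3000)
        assert hit.identity == 100.0 and hit.coverage == 1.0
        assert hit.orientation == "+"

    def test_reverse_complement_placed_on_minus_strand(self):
        rng = np.random.default_rng(4)
        ref = {"2L": _random_seq(rng, 8000)}
        idx = ReferenceIndex(ref)
        (hit,) = idx.place(revcomp(ref["2L"][2000:3000]))
        assert (hit.start, hit.end, hit.orientation) == (2000, 3000, "-")

    def test_duplicated_segment_yields_multiple(self):
        rng = np.random.default_rng(5)
        block = _random_seq(rng, 1000)
        ref = {"2L": block + _random_seq(rng, 2000) + block}
        idx = ReferenceIndex(ref)
        hits = idx.place(block)
        assert len(hits) == 2
        te = TEInsertionRecord("s1", "2L", 0, 100, "pogo")
        fp = place_flanks(
            (Flank("left", "2L", 0, 1000, block),
             Flank("right", "2L", 0, 1000, _random_seq(rng, 1000))),
            idx, te)
        assert fp.left_class == "multiple"
        assert fp.right_class == "unmapped"

    def test_partial_when_coverage_below_threshold(self):
        rng = np.random.default_rng(6)
        ref = {"2L": _random_seq(rng, 5000)}
        idx = ReferenceIndex(ref)
        # query runs off the chromosome end: 500 of 1000 bp alignable
        query = ref["2L"][-500:] + _random_seq(rng, 500)
        hits = idx.place(query)
        assert hits and max(h.coverage for h in hits) == pytest.approx(0.5)
        te = TEInsertionRecord("s1", "2L", 0, 100, "pogo")
        fp = place_flanks((Flank("l", "2L", 0, 1000, query),
                           Flank("r", "2L", 0, 0, "")), idx, te)
        assert fp.left_class == "partial"


def _fp(te, lclass, rclass, lhits, rhits):
    fp = FlankPlacement(te, Flank("left", te.chrom, 0, 0, "x" * 10),
                        Flank("right", te.chrom, 0, 0, "x" * 10))
    fp.left_class, fp.right_class = lclass, rclass
    fp.left_hits, fp.right_hits = lhits, rhits
    return fp


class TestClassifyTransfer:
    def test_reliable_small_gap(self):
        te = TEInsertionRecord("s1", "2L", 5000, 5400, "pogo")
        fp = _fp(te, "unequivocal", "unequivocal",
                 [Placement("2L", 1000, 2000, 100.0, 1.0, "+")],
                 [Placement("2L", 2004, 3004, 100.0, 1.0, "+")])
        t = classify_transfer(fp)
        assert t.reliability == "reliable"
        assert (t.ref_start, t.ref_end) == (2000, 2004)

    def test_gap_just_over_tolerance_plus_length_unreliable(self):
        te = TEInsertionRecord("s1", "2L", 5000, 5400, "pogo")  # length 400
        fp = _fp(te, "unequivocal", "unequivocal",
                 [Placement("2L", 1000, 2000, 100.0, 1.0, "+")],
                 [Placement("2L", 2451, 3451, 100.0, 1.0, "+")])
        assert classify_transfer(fp, gap_tolerance=50).reliability == "unreliable"
        fp.right_hits = [Placement("2L", 2450, 3450, 100.0, 1.0, "+")]
        assert classify_transfer(fp, gap_tolerance=50).reliability == "reliable"

    def test_different_chromosomes_unreliable(self):
        te = TEInsertionRecord("s1", "2L", 5000, 5400, "pogo")
        fp = _fp(te, "unequivocal", "unequivocal",
                 [Placement("2L", 1000, 2000, 100.0, 1.0, "+")],
                 [Placement("3R", 2000, 3000, 100.0, 1.0, "+")])
        t = classify_transfer(fp)
        assert t.reliability == "unreliable"
        assert "chromosome" in t.reason

    def test_small_negative_gap_collapses_to_point(self):
        te = TEInsertionRecord("s1", "2L", 5000, 5400, "pogo")
        fp = _fp(te, "unequivocal", "unequivocal",
                 [Placement("2L", 1000, 2000, 100.0, 1.0, "+")],
                 [Placement("2L", 1990, 2990, 100.0, 1.0, "+")])
        t = classify_transfer(fp)
        assert t.reliability == "reliable"
        assert t.ref_start == t.ref_end

    def test_zero_length_flank_one_sided(self):
        te = TEInsertionRecord("s1", "2L", 0, 400, "pogo")
        fp = FlankPlacement(te, Flank("left", "2L", 0, 0, ""),
                            Flank("right", "2L", 400, 1400, "x" * 1000))
        fp.left_class = "unmapped"
        fp.right_class = "unequivocal"
        fp.right_hits = [Placement("2L", 400, 1400, 100.0, 1.0, "+")]
        t = classify_transfer(fp)
        assert t.reliability == "reliable" and t.transfer_note == "one-sided"
        assert t.ref_start == t.ref_end == 400


class TestSyntenyRescue:
    def _setup(self):
        # left flank maps twice; the copy near the right flank shares gene gA
        te = TEInsertionRecord("s1", "2L", 5000, 5400, "pogo")
        lhits = [Placement("2L", 1000, 2000, 100.0, 1.0, "+"),
                 Placement("2L", 50_000, 51_000, 100.0, 1.0, "+")]
        rhit = Placement("2L", 2004, 3004, 100.0, 1.0, "+")
        fp = _fp(te, "multiple", "unequivocal", lhits, [rhit])
        fp.left = Flank("left", "2L", 4000, 5000, "x" * 1000)
        fp.right = Flank("right", "2L", 5400, 6400, "y" * 1000)
        return fp

    def _gene(self, gid, chrom, start, end):
        return GeneModel(gid, chrom, "+", start, end,
                         [Transcript(f"{gid}.t1", {"exon": [(start, end)]})])

    def test_rescued_with_shared_anchor(self):
        fp = self._setup()
        anchors = GeneAnchors(
            {"s1": [self._gene("gA", "2L", 3000, 4500)]},
            [self._gene("gA", "2L", 500, 1800)])
        t = classify_transfer(fp, anchors)
        assert t.reliability == "reliable"
        assert (t.ref_start, t.ref_end) == (2000, 2004)

    def test_not_rescued_when_anchors_disagree(self):
        fp = self._setup()
        anchors = GeneAnchors(
            {"s1": [self._gene("gA", "2L", 3000, 4500)]},
            [self._gene("gB", "2L", 500, 1800)])
        t = classify_transfer(fp, anchors)
        assert t.reliability == "unreliable"
        assert "rescue" in t.reason

    def test_not_rescued_without_anchors(self):
        t = classify_transfer(self._setup(), None)
        assert t.reliability == "unreliable"


def _tt(strain, chrom, start, end, family, start_strain=None):
    te = TEInsertionRecord(strain, chrom,
                           start_strain if start_strain is not None else start,
                           (start_strain if start_strain is not None else start)
                           + max(end - start, 1) + 200,
                           family)
    return TransferredTE(te, chrom, start, end, "reliable")


class TestClustering:
    STRAINS = ["s1", "s2", "s3"]

    def test_same_position_same_family_one_group(self):
        items = [_tt("s1", "2L", 1000, 1004, "pogo"),
                 _tt("s2", "2L", 1050, 1054, "pogo")]
        groups, tandem = cluster_orthologs(items, self.STRAINS)
        assert len(groups) == 1 and not tandem
        assert list(groups[0].presence) == [True, True, False]

    def test_same_position_different_family_two_groups(self):
        items = [_tt("s1", "2L", 1000, 1004, "pogo"),
                 _tt("s2", "2L", 1000, 1004, "Doc")]
        groups, _ = cluster_orthologs(items, self.STRAINS)
        assert len(groups) == 2

    def test_250bp_apart_two_groups(self):
        items = [_tt("s1", "2L", 1000, 1004, "pogo"),
                 _tt("s2", "2L", 1250, 1254, "pogo")]
        groups, _ = cluster_orthologs(items, self.STRAINS)
        assert len(groups) == 2

    def test_tolerance_boundary_inclusive(self):
        a = [_tt("s1", "2L", 1000, 1000, "pogo"),
             _tt("s2", "2L", 1100, 1100, "pogo")]
        groups, _ = cluster_orthologs(a, self.STRAINS, position_tolerance=100)
        assert len(groups) == 1
        b = [_tt("s1", "2L", 1000, 1000, "pogo"),
             _tt("s2", "2L", 1101, 1101, "pogo")]
        groups, _ = cluster_orthologs(b, self.STRAINS, position_tolerance=100)
        assert len(groups) == 2

    def test_second_same_strain_member_flagged_tandem(self):
        items = [_tt("s1", "2L", 1000, 1004, "pogo"),
                 _tt("s1", "2L", 1060, 1064, "pogo", start_strain=9000),
                 _tt("s2", "2L", 1002, 1006, "pogo")]
        groups, tandem = cluster_orthologs(items, self.STRAINS)
        assert len(groups) == 1 and len(tandem) == 1
        assert tandem[0].transfer_note == "tandem"
        # the kept s1 member is the one nearest the group median
        assert groups[0].members["s1"].ref_start == 1000

    def test_order_independence(self):
        rng = np.random.default_rng(8)
        items = []
        for i, s in enumerate(self.STRAINS):
            for pos in (1000 + 10 * i, 5000 + 7 * i, 9000):
                items.append(_tt(s, "2L", pos, pos + 4, "pogo",
                                 start_strain=pos + 100 * i))
        ref_ids = None
        for _ in range(5):
            perm = list(items)
            rng.shuffle(perm)
            groups, _ = cluster_orthologs(perm, self.STRAINS)
            ids = [(g.group_id, tuple(sorted(g.members))) for g in groups]
            if ref_ids is None:
                ref_ids = ids
            assert ids == ref_ids

    def test_unreliable_never_clustered(self):
        bad = TransferredTE(TEInsertionRecord("s1", "2L", 0, 10, "pogo"),
                            None, None, None, "unreliable", "x")
        groups, tandem = cluster_orthologs([bad], self.STRAINS)
        assert groups == [] and tandem == []


def _group(lengths, family="pogo"):
    members = {}
    for i, L in enumerate(lengths):
        te = TEInsertionRecord(f"s{i}", "2L", 1000, 1000 + L, family)
        members[f"s{i}"] = TransferredTE(te, "2L", 1000, 1004, "reliable")
    return OrthologGroup("2L_1000_1004_" + family, "2L", 1000, 1004, family,
                         members, [f"s{i}" for i in range(len(lengths))])


class TestLengthFilter:
    def test_majority_long_kept(self):
        g = _group([150, 130, 140, 90, 80])  # 3/5 > 120
        assert filter_groups_by_length([g]) == [g]

    def test_minority_long_removed(self):
        g = _group([90, 80, 150])
        assert filter_groups_by_length([g]) == []

    def test_exactly_half_removed(self):
        g = _group([150, 130, 90, 80])  # 2/4: not a strict majority
        assert filter_groups_by_length([g]) == []

    def test_boundary_length_not_counted(self):
        g = _group([120, 120, 121])  # only one member strictly > 120
        assert filter_groups_by_length([g]) == []


class TestPostfilter:
    def test_short_copy_dropped_at_boundary(self):
        recs = [TEInsertionRecord("s", "2L", 0, 99, "pogo"),
                TEInsertionRecord("s", "2L", 200, 300, "pogo")]
        out = postfilter_annotation(recs)
        assert [r.length for r in out] == [100]

    def test_satellite_overlap(self):
        recs = [TEInsertionRecord("s", "2L", 0, 200, "pogo")]
        # 85% covered -> dropped; 75% covered -> kept
        assert postfilter_annotation(recs, satellite_intervals=[("2L", 0, 170)]) == []
        assert postfilter_annotation(
            recs, satellite_intervals=[("2L", 0, 150)]) == recs

    def test_split_satellite_coverage_is_summed(self):
        recs = [TEInsertionRecord("s", "2L", 0, 200, "pogo")]
        ivs = [("2L", 0, 90), ("2L", 100, 190)]
        assert postfilter_annotation(recs, satellite_intervals=ivs) == []


class TestCompareAnnotations:
    def test_exact_match(self):
        a = [TEInsertionRecord("a", "2L", 100, 600, "pogo")]
        b = [TEInsertionRecord("b", "2L", 100, 600, "pogo")]
        res = compare_annotations(a, b)
        assert res["matched_a"] == res["matched_b"] == 1
        assert res["matched_families"] == {"pogo": 1}

    def test_family_mismatch_not_matched(self):
        a = [TEInsertionRecord("a", "2L", 100, 600, "pogo")]
        b = [TEInsertionRecord("b", "2L", 100, 600, "Doc")]
        res = compare_annotations(a, b)
        assert res["matched_a"] == 0 and res["unique_b"] == 1

    def test_reciprocal_coverage_boundary(self):
        a = [TEInsertionRecord("a", "2L", 0, 1000, "pogo")]
        # 94% overlap fails, 95% passes
        res94 = compare_annotations(a, [TEInsertionRecord("b", "2L", 0, 940, "pogo")])
        res95 = compare_annotations(a, [TEInsertionRecord("b", "2L", 0, 950, "pogo")])
        assert res94["matched_a"] == 0  # 940/1000 = 0.94 < 0.95
        assert res95["matched_a"] == 1  # 950/1000 = 0.95, inclusive


class TestEndToEnd:
    def test_round_trip_against_simulated_truth(self):
        from tepop.synthetic import CohortConfig, simulate_cohort

        cfg = CohortConfig(n_strains=8, n_te_loci=12, chrom_length=300_000, seed=77)
        cohort = simulate_cohort(cfg)
        idx = ReferenceIndex(cohort.reference)
        strains = list(cohort.metadata.index)
        transferred = []
        for s in strains:
            transferred += transfer_strain(cohort.annotations[s],
                                           cohort.strain_genomes[s], idx)
        groups, tandem = cluster_orthologs(transferred, strains)
        assert not tandem
        truth_pm = cohort.truth.presence_matrix()
        observable = [l for l in cohort.truth.loci if any(l.presence.values())]
        assert len(groups) == len(observable)
        for g in groups:
            truth_col = truth_pm.data[g.group_id]
            assert (g.presence.reindex(truth_col.index) == truth_col).all()
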