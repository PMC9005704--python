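"""Unit and property tests for the EHH-family statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_panel
from oracles import brute_ihh12, brute_ihs, brute_nsl
from tepop import selection
from tepop.panel import HaplotypePanel
from tepop.selection import (
    EHHCurve,
    SiteUndefined,
    call_significant,
    compute_ehh,
    compute_ihh12,
    compute_ihs,
    compute_nsl,
    integrate_ihh,
    neutral_sites,
    normalize_scores,
    scan_panel,
)


def make_panel(rows, positions=None):
    haps = np.array(rows, dtype=np.int8)
    if positions is None:
        positions = np.arange(haps.shape[1]) * 1000
    return HaplotypePanel(haps, positions, chrom="2L")


class TestEHH:
    def test_identical_carriers_keep_ehh_at_one(self):
        # 4 identical derived carriers plus 2 distinct ancestral haplotypes
        panel = make_panel([
            [1, 1, 1, 0, 1],
            [1, 1, 1, 0, 1],
            [1, 1, 1, 0, 1],
            [1, 1, 1, 0, 1],
            [0, 0, 0, 0, 0],
            [0, 1, 0, 0, 1],
        ])
        curve = compute_ehh(panel, 2, "derived")
        assert np.all(curve.left.ehh == 1.0)
        assert np.all(curve.right.ehh == 1.0)

    def test_three_carrier_hand_example(self):
        # carriers' flanking alleles right of core: (0,0), (0,0), (0,1)
        panel = make_panel([
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 1],
            [0, 1, 1],  # ancestral pair so the core is polymorphic
            [0, 1, 0],
        ])
        curve = compute_ehh(panel, 0, "derived")
        assert curve.right.ehh[1] == 1.0          # first flank site: all same
        assert curve.right.ehh[2] == pytest.approx(1 / 3)  # C(2,2)/C(3,2)

    def test_monotone_and_bounded(self, small_panel):
        for allele in ("ancestral", "derived", "top2"):
            curve = compute_ehh(small_panel, 4, allele)
            for side in (curve.left, curve.right):
                assert side.ehh[0] == 1.0
                assert np.all(np.diff(side.ehh) <= 1e-12)
                assert np.all((side.ehh >= 0) & (side.ehh <= 1))

    def test_monomorphic_core_and_single_carrier_rejected(self):
        panel = make_panel([[0, 0, 1], [0, 1, 0], [0, 1, 1]])
        with pytest.raises(SiteUndefined):
            compute_ehh(panel, 0, "derived")
        panel2 = make_panel([[1, 0, 1], [0, 1, 0], [0, 1, 1]])
        with pytest.raises(SiteUndefined):
            compute_ehh(panel2, 0, "derived")


class TestIntegration:
    def _curve(self, positions, ehh, core_pos=0):
        pos = np.array([core_pos] + list(positions))
        panel = HaplotypePanel(np.zeros((2, len(pos)), dtype=np.int8) +
                               np.array([[0] * len(pos), [1] * len(pos)], dtype=np.int8),
                               pos, chrom="2L")
        side = selection.EHHSide(np.arange(len(pos)), np.array([1.0] + list(ehh)),
                                 "cutoff")
        empty = selection.EHHSide(np.array([0]), np.array([1.0]), "cutoff")
        return EHHCurve(0, "derived", empty, side, panel)

    def test_rectangle(self):
        curve = self._curve([10_000], [1.0])
        v = integrate_ihh(curve, cutoff=0.05)
        assert v.value == pytest.approx(10_000)

    def test_hand_trapezoid_with_truncation(self):
        # points (0,1), (1000,0.5), (2000,0.04): 750 + 270 = 1020
        curve = self._curve([1000, 2000], [0.5, 0.04])
        v = integrate_ihh(curve, cutoff=0.05)
        assert v.value == pytest.approx(1020.0)

    def test_cutoff_zero_integrates_everything(self):
        curve = self._curve([1000, 2000, 3000], [0.5, 0.04, 0.0])
        v = integrate_ihh(curve, cutoff=0.0)
        assert v.value == pytest.approx(750 + 270 + 20)


class TestStatistics:
    def test_ihs_zero_under_allele_symmetry(self):
        # panel invariant under swapping allele labels at the core
        panel = make_panel([
            [1, 1, 0, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 0],
            [0, 0, 1, 1],
        ])
        st = compute_ihs(panel, 1, maf_floor=0.0)
        assert st.value == pytest.approx(0.0, abs=1e-12)

    def test_allele_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            panel = random_panel(rng, n_max=12, m_max=30)
            core = panel.n_sites // 2
            col = panel.haplotypes[:, core]
            if col.sum() < 2 or (1 - col).sum() < 2:
                continue
            flipped = panel.copy()
            flipped.haplotypes[:, core] = 1 - flipped.haplotypes[:, core]
            a = compute_ihs(panel, core, maf_floor=0.0)
            b = compute_ihs(flipped, core, maf_floor=0.0)
            assert a.value == pytest.approx(-b.value)
            an = compute_nsl(panel, core, maf_floor=0.0)
            bn = compute_nsl(flipped, core, maf_floor=0.0)
            assert an.value == pytest.approx(-bn.value)

    def test_nsl_pair_length_convention(self):
        # two derived carriers identical over 7 sites left and 4 right of the
        # core: SL_D = 7 + 4 + 1 = 12
        m = 15
        core = 7
        a = np.zeros(m, dtype=np.int8)
        b = np.zeros(m, dtype=np.int8)
        a[core] = b[core] = 1
        # all 7 left sites identical; right identity broken at the 5th site
        b[core + 5] = 1
        anc1 = np.zeros(m, dtype=np.int8)
        anc2 = np.zeros(m, dtype=np.int8)
        anc2[1] = 1
        panel = make_panel([a, b, anc1, anc2])
        curve = compute_ehh(panel, core, "derived", cutoff=0.0)
        sl_d = 1 + curve.left.ehh[1:].sum() + curve.right.ehh[1:].sum()
        assert sl_d == pytest.approx(12.0)

    def test_ihh12_pooled_class_formula(self):
        # extended alleles over sites 1-2: (0,0) x2, (1,0) x2, (0,1) x1 ->
        # class sizes {2,2,1}; pooled EHH12 = [C(4,2) + 0] / C(5,2) = 6/10
        panel = make_panel([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ])
        curve = compute_ehh(panel, 0, "top2", cutoff=0.0)
        assert curve.right.ehh[2] == pytest.approx(6 / 10)

    def test_ihh12_pooling_dominates_plain_ehh(self, small_panel):
        c12 = compute_ehh(small_panel, 4, "top2", cutoff=0.0)
        n = small_panel.n_haplotypes
        # plain EHH over all haplotypes: reuse class machinery with a fake
        # all-carrier derived class by brute force
        from oracles import brute_ehh_curve

        idx, vals = brute_ehh_curve(small_panel.haplotypes, np.arange(n), 4, 1, 0.0)
        for i in range(min(len(vals), len(c12.right.ehh))):
            assert c12.right.ehh[i] >= vals[i] - 1e-12


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 30:
            panel = random_panel(rng)
            core = int(rng.integers(1, panel.n_sites - 1))
            col = panel.haplotypes[:, core]
            if col.sum() < 2 or (1 - col).sum() < 2:
                continue
            haps, pos = panel.haplotypes, panel.positions
            assert compute_ihs(panel, core, maf_floor=0.0).value == pytest.approx(
                brute_ihs(haps, pos, core))
            assert compute_nsl(panel, core, maf_floor=0.0).value == pytest.approx(
                brute_nsl(haps, core))
            assert compute_ihh12(panel, core).value == pytest.approx(
                brute_ihh12(haps, pos, core))
            checked += 1


class TestNormalization:
    def test_closed_form_bin(self):
        df = pd.DataFrame({
            "chrom": "2L", "pos": [1, 2, 3], "daf": [0.25, 0.26, 0.27],
            "ihs": [-1.0, 0.0, 1.0], "nsl": np.nan, "ihh12": np.nan,
        })
        out = normalize_scores(df, statistics=("ihs",))
        # sample sd of {-1,0,1} is 1, so values are unchanged
        assert list(out["ihs_std"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_bin_index(self):
        df = pd.DataFrame({"chrom": "2L", "pos": [1], "daf": [0.349],
                           "ihs": [0.0], "nsl": [0.0], "ihh12": [0.0]})
        out = normalize_scores(df)
        assert out["bin"].iloc[0] == 3

    def test_per_bin_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "chrom": "2L", "pos": np.arange(200),
            "daf": rng.uniform(0.05, 0.95, 200),
            "ihs": rng.normal(size=200), "nsl": rng.normal(size=200),
            "ihh12": rng.normal(size=200),
        })
        out = normalize_scores(df)
        for _, grp in out.groupby("bin"):
            vals = grp["ihs_std"].dropna()
            if len(vals) >= 2:
                assert vals.mean() == pytest.approx(0.0, abs=1e-10)
                assert vals.std(ddof=1) == pytest.approx(1.0)


class TestNeutralSites:
    @pytest.mark.parametrize(
        "intron_len,offset,expected",
        [(65, 8, True),    # boundary: longest allowed intron, first offset
         (66, 10, False),  # intron one bp too long
         (65, 30, True),   # last allowed offset
         (65, 31, False),  # one past the window
         (64, 7, False)],  # before the window
    )
    def test_offset_and_length_boundaries(self, intron_len, offset, expected):
        start = 1000
        snp_pos = start + offset - 1  # 1-based offset from 5' end, + strand
        panel = HaplotypePanel(
            np.array([[0, 1], [1, 0]], dtype=np.int8),
            np.array([snp_pos, 90_000]), chrom="2L")
        idx = neutral_sites(panel, [("2L", start, start + intron_len, "+")])
        assert (0 in idx) is expected

    def test_minus_strand_offsets_from_three_prime_end(self):
        # intron [1000,1060) on -: 5' end is position 1059; offset 8 => 1052
        panel = HaplotypePanel(np.array([[0, 1], [1, 0]], dtype=np.int8),
                               np.array([1052, 90_000]), chrom="2L")
        idx = neutral_sites(panel, [("2L", 1000, 1060, "-")])
        assert 0 in idx


class TestSignificance:
    def _scores(self, values):
        n = len(values)
        return pd.DataFrame({
            "chrom": "2L", "pos": np.arange(n), "daf": 0.5,
            "ihs_std": np.nan, "nsl_std": np.nan, "ihh12_std": values,
        })

    def test_percentile_linear_interpolation(self):
        df = self._scores(np.arange(1, 101, dtype=float))
        out, thr = call_significant(df, np.arange(100), percentile=95,
                                    statistics=("ihh12",))
        assert thr["ihh12"] == pytest.approx(95.05)

    def test_site_exactly_at_threshold_not_flagged(self):
        # neutral values 1..100 give threshold 95.05; a non-neutral site at
        # exactly 95.05 stays unflagged (strict >), one just above is flagged
        vals = np.concatenate([np.arange(1, 101, dtype=float), [95.05, 95.06]])
        df = self._scores(vals)
        out, thr = call_significant(df, np.arange(100), percentile=95,
                                    statistics=("ihh12",))
        assert thr["ihh12"] == pytest.approx(95.05)
        assert not out["ihh12_sig"].iloc[100]
        assert out["ihh12_sig"].iloc[101]

    def test_no_flags_when_nothing_exceeds(self):
        df = self._scores(np.ones(50))
        out, _ = call_significant(df, np.arange(50), percentile=95,
                                  statistics=("ihh12",))
        assert not out["ihh12_sig"].any()

    def test_too_few_neutral_sites_is_an_error(self):
        df = self._scores(np.arange(30, dtype=float))
        with pytest.raises(ValueError, match="neutral"):
            call_significant(df, np.arange(5), statistics=("ihh12",))


def test_scan_panel_shape_and_maf_floor(small_panel):
    out = scan_panel(small_panel, maf_floor=0.4, drop_truncated=False)
    assert set(out.columns) >= {"chrom", "pos", "daf", "ihs", "nsl", "ihh12"}
    low_maf = out[np.minimum(out["daf"], 1 - out["daf"]) < 0.4]
    assert low_maf["ihs"].isna().all()
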