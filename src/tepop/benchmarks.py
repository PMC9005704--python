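"""End-to-end evaluation routines on synthetic data with known truth.

Each function runs one self-contained benchmark of the pipeline — sweep
candidate recovery, annotation-transfer round-trip, rarefaction against an
exhaustive oracle, eQTL null calibration and planted-effect recovery — and
returns plain dictionaries of summary numbers.  They are used by the test
suite and by the reproduction script; all are deterministic given a seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tepop import frequency, selection
from tepop.candidates import screen_candidates
from tepop.eqtl import permutation_pass
from tepop.io import RecombinationMap, TEInsertionRecord, intron_intervals
from tepop.orthology import (
    OrthologGroup,
    ReferenceIndex,
    TransferredTE,
    cluster_orthologs,
    transfer_strain,
)
from tepop.presence import PresenceMatrix
from tepop.synthetic import (
    CohortConfig,
    SweepConfig,
    plant_sweep,
    short_intron_genes,
    simulate_cohort,
    simulate_haplotypes,
    strain_names,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sweep -> candidate-TE recovery
# ---------------------------------------------------------------------------


def _group_from_carriers(chrom: str, start: int, family: str,
                         carriers: list[str], strains: list[str],
                         te_len: int = 500) -> OrthologGroup:
    members = {}
    for s in carriers:
        te = TEInsertionRecord(s, chrom, start, start + te_len, family)
        members[s] = TransferredTE(te, chrom, start, start + 4, "reliable")
    return OrthologGroup(f"{chrom}_{start}_{start + 4}_{family}", chrom,
                         start, start + 4, family, members, list(strains))


def sweep_candidate_replicate(seed: int, n_haplotypes: int = 40,
                              n_sites: int = 500,
                              carrier_fraction: float = 0.6,
                              n_unlinked: int = 10,
                              region_length: int = 1_000_000) -> dict:
    """One haploid cohort with a planted sweep and a TE on the swept
    haplotype, plus unlinked common TEs; run the scan and candidate screen.

    Returns whether the linked TE was flagged and how many of the unlinked
    common TEs were (the false flags).
    """
    rng = np.random.default_rng(seed)
    panel = simulate_haplotypes(n_haplotypes=n_haplotypes, n_sites=n_sites,
                                region_length=region_length, seed=seed)
    core_pos = int(panel.positions[panel.n_sites // 2])
    swept, truth = plant_sweep(panel, SweepConfig(
        core_position=core_pos, carrier_fraction=carrier_fraction,
        decay_scale=50_000, seed=seed + 1_000_000))
    strains = strain_names(n_haplotypes)

    # selection scan with neutral short-intron calibration
    scores = selection.scan_panel(swept)
    scores = selection.normalize_scores(scores)
    introns = intron_intervals(short_intron_genes(swept))
    neutral = selection.neutral_sites(swept, introns)
    flagged, _ = selection.call_significant(scores, neutral)
    sig = flagged[flagged[["ihs_sig", "nsl_sig", "ihh12_sig"]].any(axis=1)]

    # swept-allele carriers per significant SNP: the allele on the long
    # haplotypes (sign of the standardized score; negative iHS/nSL = derived)
    carriers_by_snp: dict[int, set[str]] = {}
    for site_idx, row in sig.iterrows():
        z = row["nsl_std"] if np.isfinite(row["nsl_std"]) else row["ihs_std"]
        if np.isfinite(z):
            derived_swept = z < 0
        else:
            derived_swept = row["daf"] >= 0.5
        col = swept.haplotypes[:, site_idx]
        hap_idx = np.flatnonzero(col == (1 if derived_swept else 0))
        carriers_by_snp[int(row["pos"])] = {strains[h] for h in hap_idx}

    snps = pd.DataFrame({"chrom": swept.chrom, "pos": sig["pos"].astype(int),
                         "statistic": "scan"})

    # linked TE: carried exactly by the swept haplotypes, 200 bp from the core
    linked_carriers = [strains[h] for h in truth.carriers]
    linked = _group_from_carriers(swept.chrom, core_pos + 200, "pogo",
                                  linked_carriers, strains)
    groups = [linked]
    positions = {core_pos + 200}
    for u in range(n_unlinked):
        while True:
            start = int(rng.integers(2000, region_length - 2000))
            if all(abs(start - p) > 1200 for p in positions):
                positions.add(start)
                break
        size = int(rng.integers(max(4, n_haplotypes // 10),
                                int(0.9 * n_haplotypes)))
        carr = list(rng.choice(strains, size=size, replace=False))
        groups.append(_group_from_carriers(swept.chrom, start, "Doc",
                                           carr, strains))

    pm = PresenceMatrix(pd.DataFrame(
        {g.group_id: [s in g.members for s in strains] for g in groups},
        index=strains))
    rec_map = RecombinationMap(pd.DataFrame(
        {"chrom": [swept.chrom], "start": [0], "end": [region_length],
         "rate": [2.0]}))

    res = screen_candidates(groups, snps, pm, carriers_by_snp, rec_map)
    hits = set(res["group_id"]) if len(res) else set()
    unlinked_common = [g for g in groups[1:]
                      if 0.10 * len(strains) <= len(g.members)
                      <= 0.95 * len(strains)]
    n_false = sum(g.group_id in hits for g in unlinked_common)
    return {"linked_flagged": linked.group_id in hits,
            "n_unlinked_common": len(unlinked_common),
            "n_false_flags": n_false,
            "n_significant_snps": int(len(sig))}


def sweep_recovery(n_replicates: int = 30, seed: int = 0, **kwargs) -> dict:
    """Power and false-flag rate of the candidate screen over replicates."""
    n_hit, n_false, n_unlinked = 0, 0, 0
    for i in range(n_replicates):
        rep = sweep_candidate_replicate(seed + i, **kwargs)
        n_hit += rep["linked_flagged"]
        n_false += rep["n_false_flags"]
        n_unlinked += rep["n_unlinked_common"]
    return {"n_replicates": n_replicates, "n_linked_flagged": n_hit,
            "power": n_hit / n_replicates,
            "n_unlinked_common": n_unlinked, "n_false_flags": n_false,
            "false_flag_rate": n_false / n_unlinked if n_unlinked else 0.0}


# ---------------------------------------------------------------------------
# Orthology round-trip
# ---------------------------------------------------------------------------


def orthology_roundtrip(n_seeds: int = 30, seed0: int = 0,
                        n_strains: int = 8, n_te_loci: int = 12,
                        chrom_length: int = 300_000) -> dict:
    """Simulate cohorts, transfer every strain's annotation back onto the
    reference, cluster, and compare against the planted truth.

    A planted locus counts as recovered when an ortholog group exists at its
    position/family with a presence vector equal to the truth.  Loci that no
    sampled strain carries are unobservable and excluded from the
    denominator.
    """
    n_loci = n_recovered = 0
    for i in range(n_seeds):
        cohort = simulate_cohort(CohortConfig(
            n_strains=n_strains, n_te_loci=n_te_loci,
            chrom_length=chrom_length, seed=seed0 + i))
        strains = list(cohort.metadata.index)
        index = ReferenceIndex(cohort.reference)
        transferred = []
        for s in strains:
            transferred += transfer_strain(cohort.annotations[s],
                                           cohort.strain_genomes[s], index)
        groups, _ = cluster_orthologs(transferred, strains)
        by_id = {g.group_id: g for g in groups}
        truth_pm = cohort.truth.presence_matrix()
        for locus in cohort.truth.loci:
            if not any(locus.presence.values()):
                continue
            n_loci += 1
            g = by_id.get(locus.locus_id)
            if g is None:
                continue
            truth_col = truth_pm.data[locus.locus_id]
            if (g.presence.reindex(truth_col.index) == truth_col).all():
                n_recovered += 1
    return {"n_seeds": n_seeds, "n_observable_loci": n_loci,
            "n_recovered": n_recovered,
            "recovery_rate": n_recovered / n_loci if n_loci else 0.0}


# ---------------------------------------------------------------------------
# Rarefaction vs exhaustive oracle
# ---------------------------------------------------------------------------


def rarefaction_check(presence: PresenceMatrix, k: int = 5,
                      replicates: int = 4000, seed: int = 0) -> dict:
    """Monte-Carlo rarefaction vs the exact all-subsets average at one k,
    plus the SD-zero check at k = cohort size."""
    exact = frequency.rarefy_exhaustive(presence, k=k)
    mc = frequency.rarefy(presence, k_min=k, k_max=k, replicates=replicates,
                          seed=seed)
    full = frequency.rarefy(presence, k_min=presence.n_strains,
                            replicates=10, seed=seed)
    out = {"k": k, "replicates": replicates}
    for c in frequency.CLASSES:
        row = mc[mc["class"] == c].iloc[0]
        out[f"exact_{c}"] = exact[c]
        out[f"mc_mean_{c}"] = float(row["mean"])
        out[f"mc_sd_{c}"] = float(row["sd"])
    out["full_cohort_max_sd"] = float(full["sd"].max())
    return out


# ---------------------------------------------------------------------------
# eQTL calibration
# ---------------------------------------------------------------------------


def eqtl_null_calibration(n_genes: int = 500, n_strains: int = 20,
                          n_tes_per_gene: int = 3, n_perm: int = 200,
                          seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of genes with beta-adjusted p below alpha under a global
    null (expression independent of every cis TE)."""
    rng = np.random.default_rng(seed)
    strains = strain_names(n_strains)
    n_sig = 0
    for g in range(n_genes):
        while True:
            geno = (rng.random((n_strains, n_tes_per_gene))
                    < rng.uniform(0.2, 0.8, size=n_tes_per_gene)).astype(int)
            if (np.ptp(geno, axis=0) > 0).any():
                break
        cis = pd.DataFrame(geno, index=strains,
                           columns=[f"te{j}" for j in range(n_tes_per_gene)])
        y = rng.normal(size=n_strains)
        res = permutation_pass(f"g{g}", y, cis, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
        n_sig += res.adjusted_p < alpha
    return {"n_genes": n_genes, "n_perm": n_perm, "alpha": alpha,
            "n_significant": n_sig, "fraction_significant": n_sig / n_genes}


def eqtl_effect_recovery(n_replicates: int = 30, n_strains: int = 20,
                         effect_sd: float = 2.0, te_frequency: float = 0.5,
                         n_perm: int = 1000, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """Recovery of a planted effect of ``effect_sd`` noise standard
    deviations carried by a TE at the given frequency."""
    rng = np.random.default_rng(seed)
    strains = strain_names(n_strains)
    n_carriers = round(n_strains * te_frequency)
    n_hit = 0
    for i in range(n_replicates):
        carrier = np.zeros(n_strains, dtype=bool)
        carrier[rng.choice(n_strains, size=n_carriers, replace=False)] = True
        decoys = rng.random((n_strains, 2)) < 0.5
        cis = pd.DataFrame(np.column_stack([carrier, decoys]), index=strains,
                           columns=["causal", "d0", "d1"]).astype(bool)
        y = effect_sd * carrier + rng.normal(size=n_strains)
        res = permutation_pass(f"rep{i}", y, cis, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
        n_hit += (res.adjusted_p < alpha) and ("causal" in ([res.te_id]
                                                            + res.ties))
    return {"n_replicates": n_replicates, "n_recovered": n_hit,
            "recovery_rate": n_hit / n_replicates}
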