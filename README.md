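# tepop

Population genomics of transposable-element (TE) insertion polymorphisms:
building a cross-strain presence/absence matrix of TE insertions from
per-genome annotations, classifying insertion frequencies, scanning phased
haplotypes for selective sweeps, screening for putatively adaptive
insertions, and mapping cis-eQTLs of TE presence on gene expression. The
package also ships a synthetic-data generator with known ground truth, so
every stage can be validated end to end without any external data.

## The scientific problem

TE insertions segregate in natural populations as large structural
polymorphisms. Given high-quality genome assemblies of tens of strains, the
questions this package addresses are:

1. **Which insertions are the same insertion?** Per-strain TE annotations
   live in per-strain coordinates. Each copy is projected onto a common
   reference through its two flanking sequences and clustered with copies
   from other strains into *ortholog groups* — the rows of a strains ×
   insertions presence/absence matrix.
2. **How do insertion frequencies distribute?** Insertions are classified as
   rare (<10% of genomes), common (≥10% and ≤95%) or fixed (>95%), with
   rarefaction over genome subsets to ask how many genomes capture the
   common variation.
3. **Are any insertions under positive selection?** Haplotype-based sweep
   statistics are computed at every SNP and calibrated against a putatively
   neutral class (positions 8–30 bp of introns ≤65 bp). Insertions near
   significant SNPs whose carriers co-occur with the swept haplotype become
   adaptive candidates, after frequency, recombination and family filters.
4. **Do insertions affect nearby gene expression?** A permutation-based
   cis-eQTL scan associates TE presence with expression of genes within
   1 kb, using a beta approximation to the permutation null for per-gene
   multiple-testing correction and presence-matrix principal components as
   population-structure covariates.

## Core statistics

For a core SNP, the extended haplotype homozygosity at distance *x* among
the carriers of one allele is

> EHH(x) = Σ_h C(c_h, 2) / C(n_a, 2),

the probability that two random carrier haplotypes are identical over the
interval from the core to *x* (the sum runs over identity classes *h* with
multiplicities *c_h* among the *n_a* carriers). From it:

- **iHS** = ln(iHH_A / iHH_D), where iHH is the trapezoid-integrated EHH of
  the ancestral (A) or derived (D) allele, truncated where EHH falls below
  0.05;
- **nSL** — the same log-ratio with distance measured in number of
  segregating sites (equivalently SL = 1 + Σ EHH over site steps), robust to
  recombination-rate variation;
- **iHH12** — integrated EHH over *all* haplotypes with the two largest
  haplotype classes pooled, sensitive to soft sweeps.

Raw scores are standardized within derived-allele-frequency bins (10
equal-width bins per chromosome) and flagged when they exceed the 95th
percentile of the neutral short-intron class (|z| for iHS/nSL, z for iHH12).

## Worked example

```python
from tepop.synthetic import (CohortConfig, SweepConfig, plant_sweep,
                             short_intron_genes, simulate_cohort,
                             simulate_haplotypes)
from tepop.orthology import (ReferenceIndex, cluster_orthologs,
                             groups_to_presence, transfer_strain)
from tepop.frequency import classify_matrix, rarefy
from tepop.io import intron_intervals
from tepop import selection

# 1. simulate a 12-strain cohort with 20 TE insertion loci
cohort = simulate_cohort(CohortConfig(n_strains=12, n_te_loci=20,
                                      chrom_length=400_000, seed=7))
strains = list(cohort.metadata.index)

# 2. transfer each strain's annotation onto the reference and cluster
index = ReferenceIndex(cohort.reference)
transferred = []
for s in strains:
    transferred += transfer_strain(cohort.annotations[s],
                                   cohort.strain_genomes[s], index)
groups, tandem = cluster_orthologs(transferred, strains)
presence = groups_to_presence(groups, strains)
print(f"{len(groups)} ortholog groups from "
      f"{sum(len(a) for a in cohort.annotations.values())} per-strain copies")

# 3. population frequency classes and a rarefaction curve
classes = classify_matrix(presence)
print(classes.value_counts().to_dict())
curve = rarefy(presence, k_min=4, replicates=30, seed=0)
common = curve[curve["class"] == "common"]
print(common.to_string(index=False, float_format=lambda x: f"{x:.2f}"))

# 4. selection scan on a phased panel with a planted sweep
panel = simulate_haplotypes(n_haplotypes=40, n_sites=500,
                            region_length=1_000_000, seed=1)
core_pos = int(panel.positions[250])
swept, truth = plant_sweep(panel, SweepConfig(core_position=core_pos,
                                              carrier_fraction=0.6,
                                              decay_scale=50_000, seed=2))
scores = selection.normalize_scores(selection.scan_panel(swept))
neutral = selection.neutral_sites(
    swept, intron_intervals(short_intron_genes(swept)))
flagged, thresholds = selection.call_significant(scores, neutral)
core = flagged[flagged["pos"] == core_pos].iloc[0]
print({k: round(v, 2) for k, v in thresholds.items()})
print(f"core site z: nSL={core['nsl_std']:.2f} (flagged={core['nsl_sig']}), "
      f"iHH12={core['ihh12_std']:.2f} (flagged={core['ihh12_sig']})")
```

Output (log lines omitted):

```
12 ortholog groups from 77 per-strain copies
{'common': 9, 'fixed': 2, 'rare': 1}
 k  class  mean   sd
 4 common  7.47 1.01
 5 common  8.20 1.16
 6 common  8.73 0.69
 7 common  9.33 0.71
 8 common  9.37 0.56
 9 common  9.60 0.50
10 common  9.73 0.45
11 common  8.73 0.45
12 common  9.00 0.00
{'ihs': 2.8, 'nsl': 2.78, 'ihh12': 1.85}
core site z: nSL=-3.23 (flagged=True), iHH12=3.26 (flagged=True)
```

All 77 per-strain copies collapse to 12 ortholog groups whose presence
vectors match the planted truth; the planted 60%-frequency sweep pushes the
core SNP far past the neutral thresholds on both the hard-sweep (nSL, the
negative sign meaning long derived-allele haplotypes) and soft-sweep (iHH12)
statistics.

The same pipeline is available on the command line:

```sh
tepop simulate --out cohort/ --seed 7 --n-strains 12 --n-te-loci 20
tepop transfer --cohort cohort/ --out cohort/result
tepop classify --presence cohort/result.presence.tsv --out classes.tsv
tepop rarefy   --presence cohort/result.presence.tsv --out rarefaction.tsv
tepop scan     --vcf panel.vcf --gff genes.gff3 --out scores.tsv
tepop eqtl     --expression expr.tsv --presence cohort/result.presence.tsv \
               --gff genes.gff3 --groups cohort/result.groups.tsv --out eqtl.tsv
```

## Reproduction

`scripts/acceptance.py` runs every synthetic benchmark end to end and
writes the headline quantities as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

At seed 1 this reports (≈90 s on one CPU): sweep-candidate power 1.0 over
30 replicates with 0/300 unlinked common TEs falsely flagged; orthology
round-trip recovery 253/253 observable planted loci over 30 cohorts;
rarefaction Monte-Carlo means within 0.012 of the exhaustive all-subsets
oracle at N=8, k=5 (SD exactly 0 at k=N); eQTL null fraction of
beta-adjusted p<0.05 of 0.078 over 500 genes (binomial 95% CI of the 5%
target is [0.031, 0.069]; the beta approximation's true rate measured at
5000 genes is ≈0.052); planted 2-noise-sd effects recovered in 28/30
replicates; merged candidate count 84+5+18 → 107.

The test suite mirrors these checks: `tests/test_acceptance.py` holds one
test per end-to-end check (oracle equivalence of the haplotype
statistics against brute-force pair counting, sweep recovery, orthology
round-trip, rarefaction, eQTL calibration, boundary fidelity of the printed
thresholds, and candidate-list bookkeeping), and the remaining test modules
cover each library module directly.

See `docs/methods.md` for the methods, parameter defaults and design
decisions.
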