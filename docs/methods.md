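# Methods

This note records what each stage of `tepop` computes, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## 1. Data model

- **Haplotype panel** (`tepop.panel.HaplotypePanel`): an n_haplotypes ×
  n_sites int8 matrix of phased biallelic SNPs, 0 = ancestral, 1 = derived,
  with strictly increasing 0-based physical positions and optional genetic
  positions (cM). Phased VCF input accepts haploid genotypes (one haplotype
  per sample) or phased diploids (two); unphased diploid records are an
  error, not a silent coercion, because every downstream statistic is
  haplotype-based. Sites with any missing genotype and sites that are not
  biallelic SNPs are dropped at parse time.
- **Presence matrix** (`tepop.presence.PresenceMatrix`): a boolean strains ×
  insertion-loci DataFrame with optional strain metadata. This is the
  interchange object between orthology, frequency, candidate and eQTL
  stages.
- **Intervals** are 0-based, half-open everywhere (BED convention); GFF3
  input/output converts at the boundary. Recombination maps are windowed
  rates in cM/Mb; genetic position is the exact piecewise-linear integral of
  the window rates.

## 2. Ortholog-group construction

Each per-strain TE copy is located on the reference through its two flanking
sequences (default `flank_bp=1000`, long enough to be effectively unique in
a fly-sized genome yet short enough to rarely span neighbouring
insertions). Flanks are placed by exact 31-mer seeding with ungapped
extension over the whole flank (default `min_identity=90`,
`min_cov=0.8`); this internal placement mode assumes assemblies that are
near-identical to the reference outside the insertions, which holds for the
synthetic cohorts and for high-quality assemblies of close strains. For
real data with higher divergence, placements from a long-read aligner can
be supplied instead — the classification logic is unchanged.

Each flank is classed `unequivocal` (exactly one ≥80%-coverage hit),
`multiple`, `partial` or `unmapped`. A transfer is **reliable** when both
flanks are unequivocal, concordant in chromosome and orientation, and the
reference gap between them is within `gap_tolerance=50` bp of either 0 (the
insertion is absent in the reference) or the TE length (present in the
reference); small negative gaps (target-site duplication overlap) collapse
to the midpoint. One multiply-mapping flank can be rescued when its
placement nearest the other flank has the same nearest gene on both
genomes (synteny anchoring); a zero-length flank at a contig edge yields a
one-sided placement. Everything else is returned as unreliable with an
explicit reason — no record is dropped silently.

Reliable transfers are clustered per (chromosome, family) by single-linkage
chaining of projected midpoints within `position_tolerance=100` bp — larger
than target-site-duplication jitter, smaller than typical inter-insertion
distances. A second same-strain member in a group is flagged tandem and set
aside. Groups in which copies >120 bp are not a strict majority are removed
as fragmented annotations; a post-filter drops copies <100 bp and copies
with >80% of their length under satellite annotation. Annotation sets are
compared family-aware with reciprocal ≥95% coverage.

## 3. Frequency classes and rarefaction

Classes: rare f < 0.10, common 0.10 ≤ f ≤ 0.95, fixed f > 0.95. Boundary
comparisons are done on integer counts through exact rationals (present ×
10 < k ⇔ rare), so floating-point rounding can never flip a class at the
printed thresholds — e.g. 5 of 47 genomes (10.6%) is common and 4 of 47
(8.5%) is rare, exactly.

Rarefaction draws `replicates=30` random strain subsets per size k
(default from k=5 up to the cohort size) and re-classifies each locus
within the subset; loci absent from every sampled strain are excluded as
unobservable. At k = N every replicate is the full cohort, so the SD is 0
by construction. An exhaustive all-subsets oracle
(`rarefy_exhaustive`) exists for small cohorts and anchors the tests.

## 4. Selection scan

EHH for an allele class is computed by iterative refinement of haplotype
identity classes outward from the core (O(n·m) per curve rather than
O(n²·m) pair counting; the brute-force pair-counting implementation lives in
the test suite as an independent oracle). The walk stops at the first point
with EHH below `cutoff=0.05` (that point is included) or at the chromosome
end, in which case the site is marked truncated and excluded from scans by
default (`drop_truncated=True`) — integrals cut by a chromosome end are
biased low.

- iHS = ln(iHH_A/iHH_D), trapezoid integration on physical (or genetic,
  when available) distance.
- nSL uses distance in number of sites; SL_c = 1 + Σ EHH_c over site steps
  on both sides, an exact identity with the mean pairwise maximal shared
  interval length (counting the core).
- iHH12 integrates the all-haplotypes EHH with the two largest classes
  pooled at every distance.

Sites with minor allele frequency below `maf_floor=0.05` are skipped
(undefined or wildly variable log-ratios). Scores are standardized within
10 equal-width derived-allele-frequency bins per chromosome using the
sample SD (ddof=1); bins with fewer than two finite values stay NaN.

Significance is calibrated on a putatively neutral class: SNPs at 1-based
offsets 8–30 from the 5′ end (on the transcribed strand) of introns ≤65 bp.
The threshold per statistic is the 95th percentile (linear interpolation)
of the neutral |z| (iHS, nSL — sweeps push either tail) or z (iHH12);
sites strictly above it are flagged. At least 20 neutral sites are
required, otherwise the call errors rather than returning an arbitrary
threshold.

## 5. Candidate adaptive insertions

A candidate must (i) pass the pool filters — frequency within [0.10, 0.95]
(fixed and rare insertions carry no sweep information), recombination rate
> 0 at the insertion midpoint (haplotype statistics are uninterpretable in
non-recombining regions), family not in the excluded set (families known to
be old and neutrally fixed; default {INE-1, LARD}) — applied in that order
with a conservation audit; (ii) lie strictly within 1000 bp of a flagged
SNP; and (iii) satisfy the carrier co-occurrence rule: the TE absent from
every strain lacking the swept allele, at least 4 co-carriers when the TE
is in 5–6 strains, a strict majority when in ≥7, and automatic failure
below 5 strains (too few carriers to distinguish linkage from chance).

Gene context resolves on the longest transcript with priority
5′UTR > 3′UTR > CDS > intron; PROMOTER is the 1 kb window upstream of the
TSS (strand-aware, by TE midpoint); otherwise the nearest gene strictly
within 1 kb is reported (ties all reported) under the label Intergenic.
Family enrichment uses a 2×2 chi-square without continuity correction,
switching to Fisher's exact test when an expected cell is below 1, with
Benjamini–Hochberg correction across families. Candidate lists from
multiple sources merge as a set union (shared insertions counted once).

## 6. cis-eQTL mapping

Genes are paired with TE groups intersecting the gene span widened by 1 kb.
The nominal pass residualizes expression and genotype on the covariates
(default: the first two principal components of the centered presence
matrix) and converts the Pearson correlation with the exact t transform,
df = n − 2 − #covariates. The permutation pass permutes residualized
expression across strains (default `n_perm=100 000`; a minimum of 100 is
enforced), records the best nominal p over the gene's cis TEs per
permutation, fits a Beta(a, b) to the permutation minima by maximum
likelihood (Nelder–Mead on the exact log-likelihood, method-of-moments
start and fallback), and reports the Beta CDF at the observed best p as the
gene-level adjusted p, alongside the empirical permutation p
(1 + #{p_perm ≤ p_obs})/(n_perm + 1). TEs tied at the best p are all
reported. Significant calls require adjusted p < 0.05 and positive
recombination at the TE. Measured on a global null at 200 permutations the
adjusted p is calibrated to ≈0.052 rejection at the 5% level (see
`tepop.benchmarks.eqtl_null_calibration`).

## 7. Synthetic-data generator

Two generators with full ground truth:

- **Cohorts** (`simulate_cohort`): a random reference sequence, TE loci
  spaced ≥2×flank apart (even spacing with jitter), per-locus target
  frequencies drawn from a configurable mixture (default 40% at 0.05, 30%
  at 0.3, 20% at 0.7, 10% fixed — a rare-heavy spectrum typical of active
  TE families), Bernoulli presence per strain, and per-strain genomes that
  are the reference with consensus sequences physically inserted; BED
  annotations cover the insertions exactly. This emulates the coordinate
  bookkeeping of assembly-based TE annotation, not TE biology: there are no
  SNPs between strains, no nested or truncated copies (flank uniqueness can
  be broken deliberately via `flank_uniqueness=False`), and no reference
  bias.
- **Haplotypes** (`simulate_haplotypes`): founder-mosaic panels — a small
  number of founder haplotypes, geometric recombination breakpoints
  (p = 1 − exp(−rate·gap)), Poisson private mutations. This produces
  realistic LD decay for testing the scan but is not a coalescent
  simulation: no demography, no mutation-rate heterogeneity.
  `plant_sweep` copies a donor haplotype onto a chosen carrier fraction
  over geometrically decaying tracts (mean `decay_scale=50 kb`), setting
  the core column exactly — an idealized incomplete hard sweep.
- **Expression** (`simulate_expression`): gene baseline + effect × presence
  + Gaussian noise, for eQTL calibration.

## 8. Numerical decisions

- EHH uses exact rational pair counts within float arithmetic; oracle
  agreement is exact to 1e-12 relative.
- A cutoff of exactly 0 is replaced internally by a tiny positive value so
  that a walk always stops once EHH reaches 0 (it cannot recover).
- Threshold percentiles use linear interpolation (numpy default), and
  flagging is strictly greater-than, so a site exactly at the threshold is
  not flagged.
- Frequency-class boundaries use exact integer arithmetic (§3).
- Beta fitting clips permutation minima to (1e-300, 1−1e-16) to keep the
  log-likelihood finite.
- All stochastic routines take explicit seeds; per-gene permutation seeds
  derive from a `SeedSequence` so results are independent of gene order.

## 9. Limitations

- The internal flank placer assumes near-exact flank sequence identity with
  the reference; divergent populations need external alignments.
- The co-occurrence rule is a strain-level stand-in for haplotype linkage;
  with phased data a direct LD test would be stronger.
- The neutral short-intron class needs enough short introns in the region
  scanned; panels without gene annotations cannot be calibrated.
- The beta-adjusted eQTL p is approximate at very small permutation counts
  (mildly anti-conservative, ≈+0.2–0.4% absolute at 200 permutations).
- The synthetic generators validate software correctness, not biological
  realism; parameter recovery on them does not imply power on real data.
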