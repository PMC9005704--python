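"""Seeded synthetic cohorts: genomes with planted TE insertions, phased
haplotype panels with an optional planted sweep, expression with additive TE
effects, and short-intron gene models — each with a truth table.

The generator emulates the input side of a multi-strain TE polymorphism
study: a reference genome, per-strain assemblies derived from it by inserting
family-consensus TE sequences at loci segregating at chosen population
frequencies, phased SNP haplotypes with background linkage disequilibrium,
and a normalized expression matrix.  It does not model demography, forward
selection-drift dynamics or sequencing error; the haplotype background is a
founder-mosaic scheme (each haplotype is a mosaic of founder haplotypes with
geometric breakpoints plus private mutations), which yields distance-decaying
LD sufficient for EHH statistics without a coalescent dependency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tepop.io import GeneModel, TEInsertionRecord, Transcript
from tepop.panel import HaplotypePanel
from tepop.presence import PresenceMatrix

CHROM_NAMES = ("2L", "2R", "3L", "3R", "X")
BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    The defaults mirror a desk-scale version of a 47-strain cohort: 20
    strains, one chromosome arm, 30 TE loci with a frequency mixture spanning
    the rare/common/fixed classes.
    """

    n_strains: int = 20
    n_chromosomes: int = 1
    chrom_length: int = 300_000
    n_te_loci: int = 30
    frequency_mixture: tuple[tuple[float, float], ...] = (
        (0.05, 0.4), (0.3, 0.3), (0.7, 0.2), (1.0, 0.1),
    )
    te_families: tuple[tuple[str, int], ...] = (
        ("pogo", 2100), ("Doc", 4700), ("roo", 9100), ("FB4", 4100),
    )
    flank_uniqueness: bool = True
    flank_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 5:
            raise ValueError("need at least 5 strains")
        w = sum(w for _, w in self.frequency_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"frequency mixture weights sum to {w}, expected 1")
        if any(not 0 <= f <= 1 for f, _ in self.frequency_mixture):
            raise ValueError("target frequencies must lie in [0, 1]")
        max_len = max(l for _, l in self.te_families)
        if self.chrom_length < 10 * max_len:
            raise ValueError("chrom_length must be >= 10x the longest consensus")


@dataclass
class SweepConfig:
    """A planted incomplete sweep: a donor haplotype copied onto a carrier
    set over geometric-length tracts around the core."""

    core_position: int
    carrier_fraction: float = 0.6
    linked_te_locus: str | None = None
    decay_scale: float = 50_000.0  # expected identity-tract length, bp
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must be in (0, 1)")


@dataclass
class LocusTruth:
    locus_id: str
    chrom: str
    ref_pos: int  # insertion point in reference coordinates (zero-length)
    family: str
    target_freq: float
    presence: dict[str, bool]

    @property
    def realized_freq(self) -> float:
        return sum(self.presence.values()) / len(self.presence)


@dataclass
class SweepTruth:
    core_site: int
    core_position: int
    carriers: list[int]  # haplotype indices
    carrier_strains: list[str]


@dataclass
class GeneEffectTruth:
    gene_id: str
    locus_id: str | None
    effect: float
    baseline: float
    noise_sd: float


@dataclass
class TruthTable:
    loci: list[LocusTruth] = field(default_factory=list)
    sweep: SweepTruth | None = None
    gene_effects: list[GeneEffectTruth] = field(default_factory=list)

    def locus(self, locus_id: str) -> LocusTruth:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def presence_matrix(self, metadata: pd.DataFrame | None = None) -> PresenceMatrix:
        strains = list(self.loci[0].presence)
        data = pd.DataFrame(
            {l.locus_id: [l.presence[s] for s in strains] for l in self.loci},
            index=strains,
        )
        return PresenceMatrix(data, metadata)

    def loci_tsv(self, path) -> None:
        rows = [
            {"locus_id": l.locus_id, "chrom": l.chrom, "ref_pos": l.ref_pos,
             "family": l.family, "target_freq": l.target_freq,
             "realized_freq": l.realized_freq,
             "carriers": ",".join(s for s, p in l.presence.items() if p)}
            for l in self.loci
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    reference: dict[str, str]
    strain_genomes: dict[str, dict[str, str]]
    annotations: dict[str, list[TEInsertionRecord]]
    metadata: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def strain_names(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


def default_metadata(strains: list[str]) -> pd.DataFrame:
    """Round-robin assignment across two synthetic continents."""
    continents = ["Europe", "North America"]
    return pd.DataFrame(
        {
            "population": [f"POP{i % 4 + 1}" for i in range(len(strains))],
            "continent": [continents[i % 2] for i in range(len(strains))],
            "climate": ["temperate" if i % 2 == 0 else "continental"
                        for i in range(len(strains))],
        },
        index=pd.Index(strains, name="strain_id"),
    )


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Build a reference, per-strain genomes and TE annotations with truth.

    Each strain genome equals the reference with the family consensus inserted
    at the strain's planted loci; annotation intervals (strain coordinates)
    exactly cover the inserted sequences.  Loci are spaced at least twice the
    flank length apart so flanks never overlap a neighbouring insertion.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [CHROM_NAMES[i % len(CHROM_NAMES)] if config.n_chromosomes <= len(CHROM_NAMES)
              else f"chr{i + 1}" for i in range(config.n_chromosomes)]
    reference = {c: _random_seq(rng, config.chrom_length) for c in chroms}
    consensus = {fam: _random_seq(rng, ln) for fam, ln in config.te_families}

    if not config.flank_uniqueness:
        # duplicate a segment so some flanks become multi-mapping
        c0 = chroms[0]
        seg = reference[c0][5000:6000]
        ref = reference[c0]
        mid = len(ref) // 2
        reference[c0] = ref[:mid] + seg + ref[mid + len(seg):]

    strains = strain_names(config.n_strains)
    fams = list(consensus)
    margin = config.flank_bp + max(len(s) for s in consensus.values())
    n_per = [config.n_te_loci // len(chroms)] * len(chroms)
    for i in range(config.n_te_loci % len(chroms)):
        n_per[i] += 1

    targets = np.array([f for f, _ in config.frequency_mixture])
    weights = np.array([w for _, w in config.frequency_mixture])

    loci: list[LocusTruth] = []
    for c, n_loci in zip(chroms, n_per):
        if n_loci == 0:
            continue
        usable = config.chrom_length - 2 * margin
        spacing = usable / n_loci
        if spacing < 2 * config.flank_bp:
            raise ValueError(
                f"cannot place {n_loci} loci on {c}: minimum spacing "
                f"{2 * config.flank_bp} bp exceeds available {spacing:.0f} bp"
            )
        jitter = rng.uniform(0, spacing - 2 * config.flank_bp, size=n_loci)
        positions = (margin + np.arange(n_loci) * spacing + jitter).astype(int)
        for pos in positions:
            fam = fams[int(rng.integers(len(fams)))]
            target = float(targets[int(rng.choice(len(targets), p=weights))])
            present = rng.random(config.n_strains) < target
            loci.append(
                LocusTruth(
                    locus_id=f"{c}_{pos}_{pos}_{fam}", chrom=c, ref_pos=int(pos),
                    family=fam, target_freq=target,
                    presence=dict(zip(strains, map(bool, present))),
                )
            )

    strain_genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[TEInsertionRecord]] = {}
    for s in strains:
        genomes: dict[str, str] = {}
        anns: list[TEInsertionRecord] = []
        for c in chroms:
            mine = sorted(
                (l for l in loci if l.chrom == c and l.presence[s]),
                key=lambda l: l.ref_pos,
            )
            pieces = []
            cursor = 0
            shift = 0
            for l in mine:
                pieces.append(reference[c][cursor:l.ref_pos])
                seq = consensus[l.family]
                start = l.ref_pos + shift
                anns.append(TEInsertionRecord(s, c, start, start + len(seq),
                                              l.family, strand="+",
                                              identity_to_consensus=100.0))
                pieces.append(seq)
                shift += len(seq)
                cursor = l.ref_pos
            pieces.append(reference[c][cursor:])
            genomes[c] = "".join(pieces)
        strain_genomes[s] = genomes
        annotations[s] = anns

    truth = TruthTable(loci=loci)
    return SimulatedCohort(config, reference, strain_genomes, annotations,
                           default_metadata(strains), truth)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write a cohort as FASTA/BED/TSV files plus a JSON manifest."""
    import json
    from pathlib import Path

    from tepop.io import write_fasta, write_te_bed

    out = Path(outdir)
    (out / "strains").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    write_fasta(cohort.reference, out / "reference.fa")
    for s, genome in cohort.strain_genomes.items():
        write_fasta(genome, out / "strains" / f"{s}.fa")
        write_te_bed(cohort.annotations[s], out / "annotations" / f"{s}.bed")
    meta = cohort.metadata.reset_index()
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    cohort.truth.loci_tsv(out / "truth_loci.tsv")
    manifest = {
        "reference": "reference.fa",
        "strains": {s: {"genome": f"strains/{s}.fa",
                        "annotation": f"annotations/{s}.bed"}
                    for s in cohort.strain_genomes},
        "metadata": "metadata.tsv",
        "truth": "truth_loci.tsv",
        "seed": cohort.config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Haplotype panels
# ---------------------------------------------------------------------------


def simulate_haplotypes(n_haplotypes: int = 40, n_sites: int = 500,
                        region_length: int = 1_000_000,
                        mutation_density: float = 2e-6,
                        n_founders: int = 8,
                        recomb_rate: float = 5e-5,
                        seed: int = 0, chrom: str = "2L",
                        strains: list[str] | None = None) -> HaplotypePanel:
    """Founder-mosaic haplotype panel with distance-decaying LD.

    Each haplotype follows one of ``n_founders`` founder haplotypes, switching
    to a random founder between adjacent sites with probability
    ``1 - exp(-recomb_rate * gap)``; private mutations are then sprinkled at
    rate ``mutation_density`` per bp per haplotype.  Allele 0 is ancestral.
    Monomorphic sites are dropped; fewer than two surviving sites is an error.
    """
    if n_founders > n_haplotypes:
        raise ValueError("n_founders must be <= n_haplotypes")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(region_length, size=n_sites, replace=False))

    # founder alleles: at each site a random nonempty proper founder subset
    # carries the derived allele (sites monomorphic among founders only arise
    # with a single founder)
    founders = np.zeros((n_founders, n_sites), dtype=np.int8)
    for j in range(n_sites):
        if n_founders >= 2:
            k = int(rng.integers(1, n_founders))
            idx = rng.choice(n_founders, size=k, replace=False)
            founders[idx, j] = 1

    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-recomb_rate * gaps)
    haps = np.zeros((n_haplotypes, n_sites), dtype=np.int8)
    for i in range(n_haplotypes):
        f = int(rng.integers(n_founders))
        haps[i, 0] = founders[f, 0]
        switches = rng.random(n_sites - 1) < p_switch
        for j in range(1, n_sites):
            if switches[j - 1]:
                f = int(rng.integers(n_founders))
            haps[i, j] = founders[f, j]

    n_private = rng.poisson(mutation_density * region_length, size=n_haplotypes)
    for i, k in enumerate(n_private):
        if k:
            sites = rng.integers(0, n_sites, size=int(k))
            haps[i, sites] = 1 - haps[i, sites]

    freqs = haps.mean(axis=0)
    poly = (freqs > 0) & (freqs < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites survived sampling")
    haps = haps[:, poly]
    positions = positions[poly]
    hap_strains = strains if strains is not None else [
        f"S{i + 1:03d}" for i in range(n_haplotypes)
    ]
    return HaplotypePanel(haps, positions, chrom, None, hap_strains)


def plant_sweep(panel: HaplotypePanel, sweep: SweepConfig
                ) -> tuple[HaplotypePanel, SweepTruth]:
    """Copy a donor haplotype onto a carrier set around the sweep core.

    Per-carrier tract half-lengths are geometric with mean ``decay_scale`` bp
    (infinite decay copies the whole region).  Afterwards the core site's
    derived allele is carried by exactly the carrier set.
    """
    if not (panel.positions[0] <= sweep.core_position <= panel.positions[-1]):
        raise ValueError("core position outside panel span")
    rng = np.random.default_rng(sweep.seed)
    n = panel.n_haplotypes
    n_carriers = round(sweep.carrier_fraction * n)
    if n_carriers < 2:
        raise ValueError("sweep needs at least 2 carriers (EHH undefined for one)")
    carriers = np.sort(rng.choice(n, size=n_carriers, replace=False))
    core_site = panel.site_index(sweep.core_position)
    core_pos = int(panel.positions[core_site])

    out = panel.copy()
    donor = panel.haplotypes[carriers[0]].copy()
    for h in carriers:
        if math.isinf(sweep.decay_scale):
            lo, hi = 0, panel.n_sites
        else:
            left = int(rng.geometric(1.0 / sweep.decay_scale))
            right = int(rng.geometric(1.0 / sweep.decay_scale))
            lo = int(np.searchsorted(panel.positions, core_pos - left, side="left"))
            hi = int(np.searchsorted(panel.positions, core_pos + right, side="right"))
        out.haplotypes[h, lo:hi] = donor[lo:hi]
    out.haplotypes[:, core_site] = 0
    out.haplotypes[carriers, core_site] = 1
    carrier_strains = sorted({panel.hap_strains[h] for h in carriers})
    return out, SweepTruth(core_site, core_pos, [int(h) for h in carriers],
                           carrier_strains)


# ---------------------------------------------------------------------------
# Gene models with short introns (neutral-site hosts)
# ---------------------------------------------------------------------------


def short_intron_genes(panel: HaplotypePanel, every: int = 5,
                       intron_len: int = 60, offset: int = 16) -> list[GeneModel]:
    """Synthetic gene models whose short introns host every ``every``-th SNP.

    Each selected SNP sits at 1-based offset ``offset`` of a ``intron_len``-bp
    intron (both within the neutral 8-30 bp / <=65 bp window), giving the scan
    a neutral calibration class.
    """
    genes = []
    for gi, j in enumerate(range(0, panel.n_sites, every)):
        p = int(panel.positions[j])
        istart = p - (offset - 1)
        iend = istart + intron_len
        if istart < 0:
            continue
        tr = Transcript(
            f"G{gi:04d}.t1",
            {
                "exon": [(istart - 100, istart), (iend, iend + 100)],
                "intron": [(istart, iend)],
            },
        )
        genes.append(GeneModel(f"G{gi:04d}", panel.chrom, "+",
                               istart - 100, iend + 100, [tr]))
    return genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(presence: PresenceMatrix, gene_ids: list[str],
                        effects: dict[str, tuple[str, float]],
                        baseline_sd: float = 1.0, seed: int = 0,
                        baseline_mean: float = 8.0,
                        baseline_spread: float = 1.0
                        ) -> tuple[pd.DataFrame, list[GeneEffectTruth]]:
    """Expression = baseline(gene) + effect x presence(locus) + Gaussian noise.

    ``effects`` maps gene id -> (locus id, effect size in expression units);
    genes not listed have no TE effect.  Returns a genes x strains matrix on
    the (already normalized) expression scale plus the per-gene truth.
    """
    for gene, (locus, _) in effects.items():
        if locus not in presence.data.columns:
            raise KeyError(f"effect for gene {gene} names unknown locus {locus}")
    rng = np.random.default_rng(seed)
    strains = presence.strains
    mat = np.empty((len(gene_ids), len(strains)))
    truth: list[GeneEffectTruth] = []
    for i, gene in enumerate(gene_ids):
        baseline = float(rng.normal(baseline_mean, baseline_spread))
        noise = rng.normal(0.0, baseline_sd, size=len(strains))
        row = baseline + noise
        locus_id, effect = None, 0.0
        if gene in effects:
            locus_id, effect = effects[gene]
            row = row + effect * presence.data[locus_id].values.astype(float)
        mat[i] = row
        truth.append(GeneEffectTruth(gene, locus_id, effect, baseline, baseline_sd))
    expr = pd.DataFrame(mat, index=gene_ids, columns=strains)
    return expr, truth
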