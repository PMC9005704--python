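"""Readers and writers for the interchange formats used across the pipeline.

Coordinate convention: every interval held in memory is 0-based half-open.
VCF positions are converted from 1-based on read and back on write.  BED is
0-based half-open already; GFF3 is 1-based closed and converted at the
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from tepop.panel import HaplotypePanel

logger = logging.getLogger(__name__)

#: TE classification orders recognised by the annotation hierarchy.
TE_ORDERS = ("Helitron", "LARD", "LINE", "LTR", "TIR", "other")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# TE annotation records (BED6)
# ---------------------------------------------------------------------------


@dataclass
class TEInsertionRecord:
    """One annotated TE copy in one strain genome (0-based half-open)."""

    strain_id: str
    chrom: str
    start: int
    end: int
    family: str
    superfamily: str = ""
    order: str = "other"
    strand: str = "."
    identity_to_consensus: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} <= start {self.start}")
        if self.identity_to_consensus is not None and not (
            0.0 <= self.identity_to_consensus <= 100.0
        ):
            raise ValueError("identity must be in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_te_bed(path, strain_id: str | None = None,
                family_table: pd.DataFrame | None = None) -> list[TEInsertionRecord]:
    """Read TE annotations from a BED3-BED6 file.

    The name column (4th) carries the family; score (5th) the percent identity
    to the family consensus.  ``family_table``, if given, maps family ->
    superfamily/order (columns ``family``, ``superfamily``, ``order``).
    """
    path = Path(path)
    sid = strain_id if strain_id is not None else path.stem
    lookup = {}
    if family_table is not None:
        for _, row in family_table.iterrows():
            lookup[row["family"]] = (row.get("superfamily", ""), row.get("order", "other"))
    records: list[TEInsertionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            family = parts[3] if len(parts) > 3 and parts[3] else "unknown"
            identity = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    identity = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score field {parts[4]!r}") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            superfamily, order = lookup.get(family, ("", "other"))
            records.append(
                TEInsertionRecord(sid, chrom, start, end, family, superfamily,
                                  order, strand, identity)
            )
    logger.info("read %d TE records from %s", len(records), path)
    return records


def write_te_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.identity_to_consensus is None else f"{r.identity_to_consensus:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t{score}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("exon", "intron", "CDS", "five_prime_UTR", "three_prime_UTR")


@dataclass
class Transcript:
    transcript_id: str
    #: feature kind -> list of (start, end) 0-based half-open intervals
    features: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        exons = self.features.get("exon", [])
        if exons:
            return sum(e - s for s, e in exons)
        return sum(e - s for ivs in self.features.values() for s, e in ivs)

    def span(self) -> tuple[int, int]:
        ivs = [iv for ivs in self.features.values() for iv in ivs]
        return min(s for s, _ in ivs), max(e for _, e in ivs)


@dataclass
class GeneModel:
    """Protein-coding gene with its transcripts; location labels use the
    longest transcript only."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first
        transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def longest_transcript(self) -> Transcript:
        return max(self.transcripts, key=lambda t: (t.length, t.transcript_id))


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene models from a GFF3 file (gene/mRNA/exon/CDS/UTR/intron).

    Introns are derived from exon gaps when not annotated explicitly.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end,
        )
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            tr = Transcript(t.id)
            for child in db.children(t):
                if child.featuretype in FEATURE_KINDS:
                    tr.features.setdefault(child.featuretype, []).append(
                        (child.start - 1, child.end)
                    )
            for kind in tr.features:
                tr.features[kind].sort()
            if "intron" not in tr.features and len(tr.features.get("exon", [])) > 1:
                exons = tr.features["exon"]
                tr.features["intron"] = [
                    (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
                ]
            gene.transcripts.append(tr)
        genes.append(gene)
    return genes


def write_gff3_genes(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\ttepop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                s, e = t.span()
                fh.write(
                    f"{g.chrom}\ttepop\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for kind, ivs in sorted(t.features.items()):
                    for i, (fs, fe) in enumerate(ivs):
                        fh.write(
                            f"{g.chrom}\ttepop\t{kind}\t{fs + 1}\t{fe}\t.\t{g.strand}\t.\t"
                            f"ID={t.transcript_id}.{kind}.{i};Parent={t.transcript_id}\n"
                        )


def intron_intervals(genes) -> list[tuple[str, int, int, str]]:
    """All introns of the longest transcripts as (chrom, start, end, strand)."""
    out = []
    for g in genes:
        for s, e in g.longest_transcript.features.get("intron", []):
            out.append((g.chrom, s, e, g.strand))
    return out


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------


class RecombinationMap:
    """Piecewise-constant recombination rates (cM/Mb) over physical windows."""

    def __init__(self, windows: pd.DataFrame):
        """``windows``: columns chrom, start, end (bp, 0-based half-open),
        rate (cM/Mb); non-overlapping and sorted within each chromosome."""
        req = {"chrom", "start", "end", "rate"}
        if not req <= set(windows.columns):
            raise ValueError(f"recombination map needs columns {sorted(req)}")
        if (windows["rate"] < 0).any():
            raise ValueError("negative recombination rate")
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, grp in windows.groupby("chrom", sort=False):
            grp = grp.sort_values("start").reset_index(drop=True)
            if (grp["end"].values[:-1] > grp["start"].values[1:]).any():
                raise ValueError(f"overlapping windows on {chrom}")
            # cumulative cM at each window start
            lengths_mb = (grp["end"] - grp["start"]) / 1e6
            cum = np.concatenate([[0.0], np.cumsum(grp["rate"].values * lengths_mb.values)])
            grp["cum_cM"] = cum[:-1]
            self._by_chrom[chrom] = grp

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        pd.concat(
            [g[["chrom", "start", "end", "rate"]] for g in self._by_chrom.values()]
        ).to_csv(path, sep="\t", index=False)

    def _window(self, chrom: str, pos: int) -> pd.Series:
        if chrom not in self._by_chrom:
            raise KeyError(f"no recombination map for chromosome {chrom!r}")
        grp = self._by_chrom[chrom]
        i = int(np.searchsorted(grp["start"].values, pos, side="right")) - 1
        if i < 0 or pos >= grp["end"].iloc[i]:
            raise ValueError(f"position {chrom}:{pos} outside mapped span")
        return grp.iloc[i]

    def genetic_position(self, chrom: str, pos: int) -> float:
        """Cumulative genetic position in cM at a physical position."""
        w = self._window(chrom, pos)
        return float(w["cum_cM"] + w["rate"] * (pos - w["start"]) / 1e6)

    def rate_at(self, chrom: str, pos: int) -> float:
        """Local rate (cM/Mb) of the window containing ``pos``."""
        return float(self._window(chrom, pos)["rate"])


def genetic_position(rec_map: RecombinationMap, chrom: str, pos: int) -> float:
    return rec_map.genetic_position(chrom, pos)


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(path, haploid: bool | None = None,
                    rec_map: RecombinationMap | None = None) -> dict[str, HaplotypePanel]:
    """Read phased biallelic SNPs into one :class:`HaplotypePanel` per chromosome.

    Only biallelic SNP records are kept; any record with a missing genotype in
    any sample is dropped (the cohort filter used throughout: no missing data
    in any genome).  REF maps to allele 0, treated as ancestral by default.
    ``haploid`` forces the genotype interpretation; if ``None`` it is inferred
    from the first record.  Unphased diploid genotypes raise :class:`ParseError`.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    per_chrom: dict[str, dict[str, list]] = {}
    n_dropped_missing = 0
    n_dropped_nonbiallelic = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_dropped_nonbiallelic += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_dropped_nonbiallelic += 1
            continue
        row_alleles: list[int] = []
        row_strains: list[str] = []
        missing = False
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or any(a is None for a in gt):
                missing = True
                break
            if haploid is None:
                haploid = len(gt) == 1
            if len(gt) > 1 and not call.phased:
                raise ParseError(
                    f"{path}: unphased diploid genotype for sample {s} at "
                    f"{rec.chrom}:{rec.pos}"
                )
            if haploid:
                row_alleles.append(int(gt[0]))
                row_strains.append(s)
            else:
                row_alleles.extend(int(a) for a in gt)
                row_strains.extend([s] * len(gt))
        if missing:
            n_dropped_missing += 1
            continue
        d = per_chrom.setdefault(rec.chrom, {"pos": [], "gts": [], "strains": row_strains})
        d["pos"].append(rec.pos - 1)  # to 0-based
        d["gts"].append(row_alleles)
    logger.info(
        "VCF %s: dropped %d non-biallelic-SNP and %d missing-data records",
        path, n_dropped_nonbiallelic, n_dropped_missing,
    )
    panels = {}
    for chrom, d in per_chrom.items():
        haps = np.array(d["gts"], dtype=np.int8).T
        pos = np.array(d["pos"], dtype=np.int64)
        gpos = None
        if rec_map is not None:
            gpos = np.array([rec_map.genetic_position(chrom, int(p)) for p in pos])
        panels[chrom] = HaplotypePanel(haps, pos, chrom, gpos, d["strains"])
    return panels


def write_phased_vcf(panels: dict[str, HaplotypePanel], path, haploid: bool = True) -> None:
    """Write panels as a minimal phased VCF (haploid GT per strain by default;
    for diploid output consecutive haplotype pairs of one strain are joined
    with '|')."""
    first = next(iter(panels.values()))
    if haploid:
        samples = first.hap_strains
    else:
        samples = list(dict.fromkeys(first.hap_strains))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, panel in panels.items():
            fh.write(f"##contig=<ID={chrom},length={int(panel.positions[-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, panel in panels.items():
            for j in range(panel.n_sites):
                col = panel.haplotypes[:, j]
                if haploid:
                    gts = "\t".join(str(int(a)) for a in col)
                else:
                    gts = "\t".join(
                        f"{int(col[i])}|{int(col[i + 1])}" for i in range(0, len(col), 2)
                    )
                fh.write(f"{chrom}\t{int(panel.positions[j]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# FASTA, metadata, expression
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_strain_metadata(path) -> pd.DataFrame:
    """TSV with columns strain_id, population, continent, climate."""
    df = pd.read_csv(path, sep="\t")
    if df["strain_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate strain ids")
    return df.set_index("strain_id")


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x strains matrix of normalized expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing expression values")
    return df
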