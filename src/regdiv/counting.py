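"""Allele-specific read counting over breed-informative SNPs.

Reads are assigned to a parental allele from the bases they show at
heterozygous sites: among the sites whose base matches either parental
allele, the read goes to the majority allele when its fraction exceeds
``prop_cut`` (default 0.9 — with typical SNP densities this demands that
all sites on a read agree). Assigned reads are aggregated to gene level:
a read covering at least one informative SNP inside a gene's exon set
increments that gene's allele count once, no matter how many exons or
SNPs it spans.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import HetSnp

logger = logging.getLogger(__name__)

ALLELE1 = "allele1"
ALLELE2 = "allele2"
UNASSIGNED = "unassigned"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class AlignedReadEvidence:
    """Bases one read shows at informative-SNP positions on one chromosome."""

    read_id: str
    chrom: str
    sites: tuple[tuple[int, str], ...]  # (1-based pos, observed base)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValueError(f"read {self.read_id}: positions must strictly increase")
        if any(base.upper() not in "ACGTN" for _, base in self.sites):
            raise ValueError(f"read {self.read_id}: bases must be in A,C,G,T,N")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene; coordinates 1-based inclusive.

    ``cds_exons`` (optional) carry the coding intervals used by the
    conservation stage; empty for non-coding models.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    tss: int
    cds_exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon {start}-{end} inverted")
        ordered = sorted(self.exons)
        if list(self.exons) != ordered:
            raise ValueError(f"{self.gene_id}: exons must be sorted")
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass
class AlleleCountTable:
    """Per-gene, per-sample allele counts plus per-sample library sizes.

    ``counts`` has columns gene_id, sample, count_allele1, count_allele2.
    For hybrid samples the two columns are the two parental alleles; for
    purebred samples strain identity plays the role of the allele, so the
    same container carries both arms of the design.
    """

    counts: pd.DataFrame
    library_sizes: dict[str, float] = field(default_factory=dict)

    COLUMNS = ("gene_id", "sample", "count_allele1", "count_allele2")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.counts[["count_allele1", "count_allele2"]] < 0).any().any():
            raise ValueError("allele counts must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return sorted(self.counts["sample"].unique())

    def pooled(self) -> pd.DataFrame:
        """Sum counts over samples: gene_id -> (count_allele1, count_allele2)."""
        return (
            self.counts.groupby("gene_id")[["count_allele1", "count_allele2"]]
            .sum()
            .sort_index()
        )

    def gene_totals(self) -> pd.Series:
        pooled = self.pooled()
        return pooled["count_allele1"] + pooled["count_allele2"]

    @classmethod
    def concat(cls, tables: Sequence["AlleleCountTable"]) -> "AlleleCountTable":
        sizes: dict[str, float] = {}
        for t in tables:
            sizes.update(t.library_sizes)
        return cls(pd.concat([t.counts for t in tables], ignore_index=True), sizes)

    def to_tsv(self, counts_path: str, libsizes_path: str | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        if libsizes_path is not None:
            pd.Series(self.library_sizes, name="library_size").rename_axis(
                "sample"
            ).to_csv(libsizes_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, counts_path: str, libsizes_path: str | None = None
    ) -> "AlleleCountTable":
        counts = pd.read_csv(counts_path, sep="\t")
        sizes: dict[str, float] = {}
        if libsizes_path is not None:
            ser = pd.read_csv(libsizes_path, sep="\t", index_col=0)["library_size"]
            sizes = {str(k): float(v) for k, v in ser.items()}
        return cls(counts, sizes)


@dataclass
class AssignmentSummary:
    """Read-level accounting; the four outcomes partition the input reads."""

    n_allele1: int = 0
    n_allele2: int = 0
    n_unassigned: int = 0
    n_uninformative: int = 0
    n_skipped_chrom: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_allele1 + self.n_allele2 + self.n_unassigned + self.n_uninformative
        )


def assign_read_allele(
    read: AlignedReadEvidence,
    snps: Mapping[tuple[str, int], tuple[str, str]],
    prop_cut: float = 0.9,
) -> str:
    """Assign one read to a parental allele from its SNP-site bases.

    ``snps`` maps (chrom, pos) to the (parent1, parent2) bases. Bases that
    match neither parental allele (sequencing error) are dropped from the
    denominator. Among matching sites with majority fraction f, the read is
    assigned iff f > prop_cut; otherwise it is ``unassigned``. Reads with no
    matching site are ``uninformative``.
    """
    n1 = n2 = 0
    for pos, base in read.sites:
        alleles = snps.get((read.chrom, pos))
        if alleles is None:
            continue
        base = base.upper()
        if base == alleles[0]:
            n1 += 1
        elif base == alleles[1]:
            n2 += 1
    n = n1 + n2
    if n == 0:
        return UNINFORMATIVE
    f = max(n1, n2) / n
    if f > prop_cut:
        return ALLELE1 if n1 > n2 else ALLELE2
    return UNASSIGNED


def build_snp_lookup(snps: Iterable[HetSnp]) -> dict[tuple[str, int], tuple[str, str]]:
    return {(s.chrom, s.pos): (s.allele_p1, s.allele_p2) for s in snps}


def build_snp_gene_index(
    snps: Iterable[HetSnp], gene_models: Iterable[GeneModel]
) -> dict[tuple[str, int], tuple[str, ...]]:
    """Map each informative SNP inside an exon to the gene(s) containing it."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[tuple[str, int], tuple[str, ...]] = {}
    n_multi = 0
    for s in snps:
        genes = tuple(
            g.gene_id for g in by_chrom.get(s.chrom, ()) if g.contains(s.pos)
        )
        if genes:
            index[(s.chrom, s.pos)] = genes
            if len(genes) > 1:
                n_multi += 1
    if n_multi:
        logger.info("%d SNPs fall in overlapping genes", n_multi)
    return index


def count_gene_alleles(
    reads: Iterable[AlignedReadEvidence],
    gene_models: Sequence[GeneModel],
    snps: Sequence[HetSnp],
    prop_cut: float = 0.9,
    sample: str = "sample",
    library_size: float | None = None,
) -> tuple[AlleleCountTable, AssignmentSummary]:
    """Count reads per gene and parental allele for one sample.

    Each assigned read increments each overlapping gene's cell for its
    allele exactly once regardless of how many exons or SNPs it spans.
    Reads on chromosomes absent from the SNP list are uninformative; the
    summary partitions every input read into one of the four outcomes.
    """
    snp_lookup = build_snp_lookup(snps)
    snp_genes = build_snp_gene_index(snps, gene_models)
    known_chroms = {g.chrom for g in gene_models}

    cells: dict[tuple[str, str], int] = {}
    summary = AssignmentSummary()
    n_reads = 0
    for read in reads:
        n_reads += 1
        if read.chrom not in known_chroms:
            summary.n_skipped_chrom += 1
        outcome = assign_read_allele(read, snp_lookup, prop_cut)
        if outcome == ALLELE1:
            summary.n_allele1 += 1
        elif outcome == ALLELE2:
            summary.n_allele2 += 1
        elif outcome == UNASSIGNED:
            summary.n_unassigned += 1
            continue
        else:
            summary.n_uninformative += 1
            continue
        genes: set[str] = set()
        for pos, _ in read.sites:
            genes.update(snp_genes.get((read.chrom, pos), ()))
        for gene_id in genes:
            cells[(gene_id, outcome)] = cells.get((gene_id, outcome), 0) + 1

    rows = []
    for g in gene_models:
        rows.append(
            {
                "gene_id": g.gene_id,
                "sample": sample,
                "count_allele1": cells.get((g.gene_id, ALLELE1), 0),
                "count_allele2": cells.get((g.gene_id, ALLELE2), 0),
            }
        )
    table = AlleleCountTable(
        pd.DataFrame(rows, columns=list(AlleleCountTable.COLUMNS)),
        {sample: float(library_size if library_size is not None else n_reads)},
    )
    return table, summary


def filter_expressed(
    purebred_totals: Mapping[str, int],
    hybrid_totals: Mapping[str, int],
    min_total: int = 6,
    max_total: int = 1000,
) -> set[str]:
    """Keep genes whose pooled totals in both arms lie in [min_total, max_total].

    Totals are sums over the replicates of each arm (purebred offspring and
    hybrid offspring) within one sex-by-tissue group; bounds are inclusive.
    Genes missing from either arm are dropped.
    """
    kept: set[str] = set()
    n_missing = 0
    for gene in set(purebred_totals) | set(hybrid_totals):
        if gene not in purebred_totals or gene not in hybrid_totals:
            n_missing += 1
            continue
        p, h = purebred_totals[gene], hybrid_totals[gene]
        if min_total <= p <= max_total and min_total <= h <= max_total:
            kept.add(gene)
    if n_missing:
        logger.info("dropped %d genes missing from one design arm", n_missing)
    return kept


def normalize_library(library_sizes: Mapping[str, float]) -> dict[str, float]:
    """Per-sample scale factors: library size over the geometric mean size."""
    sizes = {k: float(v) for k, v in library_sizes.items()}
    if any(v <= 0 for v in sizes.values()):
        raise ValueError("library sizes must be positive")
    log_mean = float(np.mean([math.log(v) for v in sizes.values()]))
    geo_mean = math.exp(log_mean)
    return {k: v / geo_mean for k, v in sizes.items()}


def null_proportion(n_a: float, n_b: float) -> float:
    """Expected fraction of reads from library a under no expression difference.

    Exact tests need integer counts, so mapped-library-size normalization
    enters the binomial null as p0 = N_a / (N_a + N_b) instead of rescaling
    the counts.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be positive")
    return n_a / (n_a + n_b)


@dataclass
class PseudoHybridReport:
    """Per-gene ratio comparison between a concatenated pseudo-hybrid and
    separately counted purebred samples, with their Pearson correlation."""

    per_gene: pd.DataFrame  # gene_id, ratio_pseudo, ratio_separate, totals
    pearson_r: float  # NaN when undefined
    n_genes: int


def pseudo_hybrid_validation(
    reads_a: Sequence[AlignedReadEvidence],
    reads_b: Sequence[AlignedReadEvidence],
    snps: Sequence[HetSnp],
    gene_models: Sequence[GeneModel],
    prop_cut: float = 0.9,
    min_total: int = 6,
    max_total: int = 1000,
) -> PseudoHybridReport:
    """Validate allele assignment by concatenating two purebred samples.

    Sample A must come from the strain carrying allele 1 at informative
    sites and sample B from the other strain. Concatenating their reads
    fabricates a "hybrid" whose true allelic ratio per gene is the ratio of
    the two samples' informative read counts; a faithful counter therefore
    shows a strong correlation between log2(allele1/allele2) in the
    pseudo-hybrid and log2(sampleA/sampleB) from separate counting.
    """
    from scipy import stats

    pseudo_reads = list(reads_a) + list(reads_b)
    pseudo_table, _ = count_gene_alleles(
        pseudo_reads, gene_models, snps, prop_cut, sample="pseudo_hybrid"
    )
    table_a, _ = count_gene_alleles(reads_a, gene_models, snps, prop_cut, sample="a")
    table_b, _ = count_gene_alleles(reads_b, gene_models, snps, prop_cut, sample="b")

    pooled = pseudo_table.pooled()
    count_a = table_a.gene_totals()
    count_b = table_b.gene_totals()

    rows = []
    for gene_id, row in pooled.iterrows():
        h1, h2 = int(row["count_allele1"]), int(row["count_allele2"])
        ca, cb = int(count_a.get(gene_id, 0)), int(count_b.get(gene_id, 0))
        total_pseudo = h1 + h2
        total_sep = ca + cb
        if not (min_total <= total_pseudo <= max_total):
            continue
        if not (min_total <= total_sep <= max_total):
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "ratio_pseudo": math.log2((h1 + 0.5) / (h2 + 0.5)),
                "ratio_separate": math.log2((ca + 0.5) / (cb + 0.5)),
                "pseudo_total": total_pseudo,
                "separate_total": total_sep,
            }
        )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "ratio_pseudo",
            "ratio_separate",
            "pseudo_total",
            "separate_total",
        ],
    )
    r = float("nan")
    if len(per_gene) < 10:
        logger.warning(
            "only %d comparable genes; correlation undefined", len(per_gene)
        )
    elif per_gene["ratio_pseudo"].nunique() > 1 and per_gene[
        "ratio_separate"
    ].nunique() > 1:
        r = float(
            stats.pearsonr(per_gene["ratio_pseudo"], per_gene["ratio_separate"])[0]
        )
    else:
        logger.warning("constant ratios; correlation undefined")
    return PseudoHybridReport(per_gene=per_gene, pearson_r=r, n_genes=len(per_gene))


# ---------------------------------------------------------------------------
# I/O: simplified read table, SAM, gene-model TSV
# ---------------------------------------------------------------------------


def write_read_table(reads: Sequence[AlignedReadEvidence], path: str,
                     gene_ids: Mapping[str, str] | None = None) -> None:
    """Write reads as the simplified TSV: read_id, chrom, gene_id,
    snp_positions (comma-separated), observed_bases."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tgene_id\tsnp_positions\tobserved_bases\n")
        for r in reads:
            positions = ",".join(str(p) for p, _ in r.sites)
            bases = "".join(b for _, b in r.sites)
            gene = gene_ids.get(r.read_id, ".") if gene_ids else "."
            fh.write(f"{r.read_id}\t{r.chrom}\t{gene}\t{positions}\t{bases}\n")


def read_read_table(path: str) -> list[AlignedReadEvidence]:
    reads: list[AlignedReadEvidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            positions = parts[idx["snp_positions"]]
            bases = parts[idx["observed_bases"]]
            sites = tuple(
                (int(p), b) for p, b in zip(positions.split(","), bases) if p
            )
            reads.append(
                AlignedReadEvidence(parts[idx["read_id"]], parts[idx["chrom"]], sites)
            )
    return reads


def read_evidence_from_sam(
    path: str, snp_positions: Iterable[tuple[str, int]]
) -> list[AlignedReadEvidence]:
    """Extract per-read bases at informative positions from a SAM/BAM file."""
    import pysam

    wanted = set(snp_positions)
    reads: list[AlignedReadEvidence] = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            chrom = aln.reference_name
            sites = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if (chrom, rpos + 1) in wanted:
                    sites.append((rpos + 1, aln.query_sequence[qpos]))
            sites.sort()
            reads.append(AlignedReadEvidence(aln.query_name, chrom, tuple(sites)))
    return reads


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as TSV with interval lists encoded start-end,start-end."""

    def fmt(intervals: tuple[tuple[int, int], ...]) -> str:
        return ",".join(f"{s}-{e}" for s, e in intervals) or "."

    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texons\tcds_exons\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{fmt(g.exons)}\t{fmt(g.cds_exons)}\n"
            )


def read_gene_models(path: str) -> list[GeneModel]:
    def parse(text: str) -> tuple[tuple[int, int], ...]:
        if text == ".":
            return ()
        return tuple(
            (int(s), int(e)) for s, e in (part.split("-") for part in text.split(","))
        )

    genes: list[GeneModel] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene_id, chrom, strand, tss, exons, cds = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(gene_id, chrom, strand, parse(exons), int(tss), parse(cds))
            )
    return genes
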