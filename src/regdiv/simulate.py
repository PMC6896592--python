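"""Synthetic F1-cross data with known regulatory truth.

The generator emulates the study design downstream stages expect: two
inbred parental lines differing at homozygous SNPs, purebred offspring
of each line and F1 hybrids (three replicates per group), RNA-seq read
counts generated under known cis (c) and trans (t) log2 effects, SNP-
bearing reads for phasing, and planted coding/upstream variants with
known synonymous / non-synonymous status.

Generative model (effects on the log2 scale, split symmetrically):

* purebred strain 1 expectation  = s_i * base * 2**((c + t) / 2)
* purebred strain 2 expectation  = s_i * base * 2**(-(c + t) / 2)
* hybrid total around s_i * base, allele 1 drawn binomially with
  proportion 2**c / (1 + 2**c)

so the purebred log2 ratio equals c + t in expectation and the hybrid
allelic log2 ratio equals c. Counts are negative binomial with variance
mu + dispersion * mu**2 (Poisson at dispersion 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import CATEGORIES
from .counting import AlignedReadEvidence, AlleleCountTable, GeneModel
from .variants import GenotypeCall, HetSnp

#: Default category mix, shaped like a typical tissue group of the design it
#: emulates: most genes conserved or ambiguous, trans divergence more common
#: than cis, and a visible compensatory class.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "conserved": 0.55,
    "ambiguous": 0.10,
    "cis": 0.07,
    "trans": 0.13,
    "cis+trans(same)": 0.03,
    "cis+trans(opposite)": 0.03,
    "cisxtrans": 0.03,
    "compensatory": 0.06,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; identical config (incl. seed) gives
    byte-identical output.

    ``effect_distribution`` is ``"normal"`` (half-normal magnitude with the
    given scale, floored at 0.1 log2 units so category invariants hold) or
    ``"fixed"`` (every effect magnitude equals the scale exactly).
    """

    n_genes: int = 200
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    cis_effect_scale: float = 1.0
    trans_effect_scale: float = 1.0
    effect_distribution: str = "normal"
    base_expression_mean: float = 100.0
    dispersion: float = 0.05
    replicates_per_group: int = 3
    library_sizes: Mapping[str, float] | None = None
    snps_per_gene: int = 3
    read_length: int = 100
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if any(v < 0 for v in self.category_mix.values()) or abs(total - 1) > 1e-9:
            raise ValueError(
                f"category_mix must be nonnegative and sum to 1 (got {total})"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be positive")
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be at least 1")
        if self.read_length < 1:
            raise ValueError("read_length must be at least 1")
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("genotype_error_rate must lie in [0,1]")
        if self.base_expression_mean <= 0:
            raise ValueError("base_expression_mean must be positive")
        if self.effect_distribution not in ("normal", "fixed"):
            raise ValueError("effect_distribution must be 'normal' or 'fixed'")


@dataclass(frozen=True)
class TruthRecord:
    """The planted regulatory state of one gene: category and log2 effects."""

    gene_id: str
    true_category: str
    c: float
    t: float

    def __post_init__(self) -> None:
        if self.true_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")


MIN_EFFECT = 0.1  # log2 floor keeping nonzero-effect categories nonzero


def _magnitude(rng: np.random.Generator, scale: float, distribution: str) -> float:
    if distribution == "fixed":
        return float(scale)
    m = abs(rng.normal(0.0, scale))
    return max(m, MIN_EFFECT)


def generate_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Draw per-gene categories from the mix and effects respecting them.

    Category constraints: conserved has c = t = 0; cis has t = 0; trans has
    c = 0; compensatory has t = -c; the cis+trans subtypes place t so the
    purebred ratio c + t keeps / flips the sign of c as their definition
    requires; ambiguous genes get small sub-threshold effects of both kinds.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    draws = rng.choice(len(cats), size=config.n_genes, p=probs)
    width = len(str(config.n_genes))
    records: list[TruthRecord] = []
    for i, k in enumerate(draws):
        cat = cats[k]
        gene_id = f"gene{i + 1:0{width}d}"
        dist = config.effect_distribution
        c = t = 0.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if cat == "cis":
            c = sign * _magnitude(rng, config.cis_effect_scale, dist)
        elif cat == "trans":
            t = sign * _magnitude(rng, config.trans_effect_scale, dist)
        elif cat == "compensatory":
            c = sign * _magnitude(rng, config.cis_effect_scale, dist)
            t = -c
        elif cat == "cis+trans(same)":
            c = sign * _magnitude(rng, config.cis_effect_scale, dist)
            t = sign * _magnitude(rng, config.trans_effect_scale, dist)
        elif cat == "cis+trans(opposite)":
            # t opposes c but is smaller, so |c + t| < |c| with the same sign
            c = sign * _magnitude(rng, config.cis_effect_scale, dist)
            t = -sign * float(rng.uniform(0.25, 0.75)) * abs(c)
        elif cat == "cisxtrans":
            # t opposes and exceeds c, flipping the sign of c + t
            c = sign * _magnitude(rng, config.cis_effect_scale, dist)
            t = -sign * (abs(c) + _magnitude(rng, config.trans_effect_scale, dist))
        elif cat == "ambiguous":
            c = sign * 0.25 * MIN_EFFECT
            t = (1.0 if rng.random() < 0.5 else -1.0) * 0.25 * MIN_EFFECT
        records.append(TruthRecord(gene_id, cat, c, t))
    return records


def hybrid_allele1_proportion(c: float) -> float:
    """Expected allele-1 share of hybrid reads under cis effect c."""
    r = 2.0 ** c
    return r / (1.0 + r)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with var = mean + dispersion * mean**2 (gamma-Poisson
    mixture); exact Poisson at dispersion 0."""
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


@dataclass
class SimulatedCounts:
    """Count tables for both design arms plus sample metadata.

    In the purebred table, strain identity plays the role of the allele:
    strain-1 samples have their reads in count_allele1 and vice versa.
    """

    purebred: AlleleCountTable
    hybrid: AlleleCountTable
    strain_of_sample: dict[str, int]
    truth: list[TruthRecord]


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    r = config.replicates_per_group
    pure1 = [f"pure_s1_r{i + 1}" for i in range(r)]
    pure2 = [f"pure_s2_r{i + 1}" for i in range(r)]
    hybrid = [f"hyb_r{i + 1}" for i in range(r)]
    return pure1, pure2, hybrid


def _library_sizes(config: SimulationConfig, samples: Sequence[str]) -> dict[str, float]:
    if config.library_sizes is None:
        return {s: 1.0e6 for s in samples}
    sizes = dict(config.library_sizes)
    missing = [s for s in samples if s not in sizes]
    if missing:
        raise ValueError(f"library_sizes missing samples: {missing}")
    return {s: float(sizes[s]) for s in samples}


def simulate_counts(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> SimulatedCounts:
    """Draw purebred and hybrid allele count tables under the planted truth.

    Expectations scale with each sample's library size relative to the
    geometric mean library. The hybrid total is drawn first and split
    binomially between alleles, matching the counting-statistics view of
    allele-specific expression.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    pure1, pure2, hyb = _sample_names(config)
    samples = pure1 + pure2 + hyb
    sizes = _library_sizes(config, samples)
    log_mean = float(np.mean([math.log(v) for v in sizes.values()]))
    geo = math.exp(log_mean)
    scale = {s: sizes[s] / geo for s in samples}

    base = config.base_expression_mean
    disp = config.dispersion
    pure_rows, hyb_rows = [], []
    for rec in truth:
        half = (rec.c + rec.t) / 2.0
        mu1, mu2 = base * 2.0 ** half, base * 2.0 ** (-half)
        p1 = hybrid_allele1_proportion(rec.c)
        for s in pure1:
            pure_rows.append(
                (rec.gene_id, s, _nb_draw(rng, scale[s] * mu1, disp), 0)
            )
        for s in pure2:
            pure_rows.append(
                (rec.gene_id, s, 0, _nb_draw(rng, scale[s] * mu2, disp))
            )
        for s in hyb:
            total = _nb_draw(rng, scale[s] * base, disp)
            h1 = int(rng.binomial(total, p1)) if total > 0 else 0
            hyb_rows.append((rec.gene_id, s, h1, total - h1))

    columns = list(AlleleCountTable.COLUMNS)
    purebred = AlleleCountTable(
        pd.DataFrame(pure_rows, columns=columns),
        {s: sizes[s] for s in pure1 + pure2},
    )
    hybrid = AlleleCountTable(
        pd.DataFrame(hyb_rows, columns=columns), {s: sizes[s] for s in hyb}
    )
    strain = {**{s: 1 for s in pure1}, **{s: 2 for s in pure2}, **{s: 0 for s in hyb}}
    return SimulatedCounts(purebred, hybrid, strain, list(truth))


def simulate_reciprocal_counts(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> dict[str, SimulatedCounts]:
    """Duplicate the design with swapped parents (no parent-of-origin effect):
    the second cross sees the same genes with both effects negated and the
    allele columns exchanged."""
    cross_a = simulate_counts(truth, config)
    flipped = [
        replace(r, c=-r.c, t=-r.t) for r in truth
    ]
    cross_b = simulate_counts(flipped, replace(config, seed=config.seed + 1))
    return {"cross_a": cross_a, "cross_b": cross_b}


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_OTHER = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass(frozen=True)
class ReadRecord:
    """One simulated read with its genomic placement and SNP-site bases."""

    read_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str
    true_allele: int  # 1 or 2
    sites: tuple[tuple[int, str], ...]

    def evidence(self) -> AlignedReadEvidence:
        return AlignedReadEvidence(self.read_id, self.chrom, self.sites)


@dataclass
class ReadSimulation:
    reads: list[ReadRecord]
    snps: list[HetSnp]
    genes: list[GeneModel]
    reference: dict[str, str]
    truth: list[TruthRecord]

    def evidence(self) -> list[AlignedReadEvidence]:
        return [r.evidence() for r in self.reads]


def _gene_layout(
    truth: Sequence[TruthRecord], config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], list[HetSnp]]:
    """Lay genes along one autosome: two exons each, SNPs spread over exons."""
    exon_len = max(2 * config.read_length, 2 * config.snps_per_gene)
    intron_len = 100
    spacing = 500
    span = 2 * exon_len + intron_len + spacing
    length = 1000 + span * len(truth)
    chrom = "chr1"
    seq = rng.choice(_BASES, size=length)
    genes: list[GeneModel] = []
    snps: list[HetSnp] = []
    for i, rec in enumerate(truth):
        g_start = 1000 + i * span + 1
        exon1 = (g_start, g_start + exon_len - 1)
        exon2 = (exon1[1] + intron_len + 1, exon1[1] + intron_len + exon_len)
        exonic = list(range(exon1[0], exon1[1] + 1)) + list(
            range(exon2[0], exon2[1] + 1)
        )
        picks = sorted(
            rng.choice(len(exonic), size=config.snps_per_gene, replace=False)
        )
        for j in picks:
            pos = exonic[j]
            a1 = str(seq[pos - 1])
            a2 = _OTHER[a1]
            snps.append(HetSnp(chrom, pos, a1, a2))
        genes.append(
            GeneModel(rec.gene_id, chrom, "+", (exon1, exon2), tss=exon1[0])
        )
    return {chrom: "".join(seq)}, genes, snps


def simulate_reads(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    kind: str = "hybrid",
    mean_reads: float | None = None,
) -> ReadSimulation:
    """Generate SNP-bearing reads for one sample.

    ``kind`` selects the sample: ``"hybrid"`` draws each read's parental
    allele with proportion 2**c / (1 + 2**c); ``"purebred1"`` /
    ``"purebred2"`` emit reads from a single strain with expression scaled
    by 2**(+-(c + t) / 2). Bases at SNP sites report the read's allele,
    flipped to the other parental base with ``genotype_error_rate``. Each
    read stays within one exon and covers at least one SNP.
    """
    if kind not in ("hybrid", "purebred1", "purebred2"):
        raise ValueError(f"unknown sample kind {kind!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, 2, {"hybrid": 0, "purebred1": 1, "purebred2": 2}[kind]]
        ).generate_state(1)[0]
    )
    reference, genes, snps = _gene_layout(truth, config, np.random.default_rng(
        np.random.SeedSequence([config.seed, 3]).generate_state(1)[0]
    ))
    chrom = genes[0].chrom
    snp_by_gene: dict[str, list[HetSnp]] = {g.gene_id: [] for g in genes}
    gene_by_id = {g.gene_id: g for g in genes}
    for s in snps:
        for g in genes:
            if g.contains(s.pos):
                snp_by_gene[g.gene_id].append(s)
                break
    base = config.base_expression_mean if mean_reads is None else mean_reads
    rl = config.read_length
    err = config.genotype_error_rate
    reads: list[ReadRecord] = []
    n_read = 0
    for rec in truth:
        gene = gene_by_id[rec.gene_id]
        gene_snps = snp_by_gene[rec.gene_id]
        if kind == "hybrid":
            mean = base
        elif kind == "purebred1":
            mean = base * 2.0 ** ((rec.c + rec.t) / 2.0)
        else:
            mean = base * 2.0 ** (-(rec.c + rec.t) / 2.0)
        n = int(rng.poisson(mean))
        p1 = hybrid_allele1_proportion(rec.c)
        for _ in range(n):
            n_read += 1
            if kind == "hybrid":
                allele = 1 if rng.random() < p1 else 2
            else:
                allele = 1 if kind == "purebred1" else 2
            anchor = gene_snps[int(rng.integers(len(gene_snps)))]
            exon = next(s_e for s_e in gene.exons if s_e[0] <= anchor.pos <= s_e[1])
            lo = max(exon[0], anchor.pos - rl + 1)
            hi = min(anchor.pos, max(exon[0], exon[1] - rl + 1))
            start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            end = min(exon[1], start + rl - 1)
            sites = []
            for s in gene_snps:
                if start <= s.pos <= end:
                    true_base = s.allele_p1 if allele == 1 else s.allele_p2
                    if err > 0 and rng.random() < err:
                        true_base = (
                            s.allele_p2 if allele == 1 else s.allele_p1
                        )
                    sites.append((s.pos, true_base))
            reads.append(
                ReadRecord(
                    read_id=f"{kind}_read{n_read:07d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    gene_id=rec.gene_id,
                    true_allele=allele,
                    sites=tuple(sites),
                )
            )
    return ReadSimulation(reads, snps, genes, reference, list(truth))


def write_sam(sim: ReadSimulation, path: str) -> None:
    """Write the simulated reads as a valid single-end SAM file."""
    import pysam

    chroms = sorted(sim.reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(sim.reference[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in sim.reads:
            ref = sim.reference[r.chrom]
            seq = list(ref[r.start - 1 : r.end])
            for pos, base in r.sites:
                seq[pos - r.start] = base
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = "".join(seq)
            a.flag = 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            out.write(a)


def parental_calls_from_snps(
    snps: Sequence[HetSnp], seed: int = 0
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Express an informative-SNP list as the two parental genotype call sets
    that would have produced it (parent 1 homozygous reference, parent 2
    homozygous alternate, depths comfortably above the selection cutoff)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]).generate_state(1)[0])
    calls_p1, calls_p2 = [], []
    for s in sorted(snps):
        d1, d2 = int(rng.integers(15, 40)), int(rng.integers(15, 40))
        calls_p1.append(
            GenotypeCall(s.chrom, s.pos, s.allele_p1, s.allele_p2, "hom-ref", d1, 0)
        )
        calls_p2.append(
            GenotypeCall(s.chrom, s.pos, s.allele_p1, s.allele_p2, "hom-alt", 0, d2)
        )
    return calls_p1, calls_p2


# ---------------------------------------------------------------------------
# Parental variant simulation (conservation stage inputs)
# ---------------------------------------------------------------------------


@dataclass
class ParentalVariantSim:
    """Reference, parental call sets and coding models with exact planted
    truth counts of synonymous / non-synonymous / upstream variants."""

    reference: dict[str, str]
    calls_p1: list[GenotypeCall]
    calls_p2: list[GenotypeCall]
    genes: list[GeneModel]
    truth: pd.DataFrame  # gene_id, n_syn, n_nonsyn, n_upstream


_CODON_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _CODON_STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def simulate_parental_variants(
    config: SimulationConfig,
    n_codons: int = 20,
    upstream_window: int = 1000,
) -> ParentalVariantSim:
    """Plant coding and upstream SNVs between two homozygous parents.

    Each gene gets a single-exon CDS (ATG ... TAA) on an alternating
    strand, 0-3 synonymous, 0-3 missense and 0-5 upstream variants; the
    planted class of every coding variant is verified by direct codon
    translation at planting time, so the recorded truth is exact. Parent 1
    carries the reference base everywhere; parent 2 the alternate.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 4]).generate_state(1)[0]
    )
    cds_len = 3 * n_codons
    margin = upstream_window + 500
    span = 2 * margin + cds_len
    chrom = "chr1"
    length = 1000 + span * config.n_genes
    seq = list(rng.choice(_BASES, size=length))

    genes: list[GeneModel] = []
    truth_rows = []
    calls: list[tuple[int, str, str]] = []  # (pos, ref, alt)
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"cgene{i + 1:0{width}d}"
        strand = "+" if i % 2 == 0 else "-"
        block = 1000 + i * span
        cds_start = block + margin + 1
        cds_end = cds_start + cds_len - 1
        cds_seq = _random_cds(rng, n_codons)
        planted = cds_seq if strand == "+" else _revcomp(cds_seq)
        seq[cds_start - 1 : cds_end] = list(planted)
        tss = cds_start if strand == "+" else cds_end
        gene = GeneModel(
            gene_id, chrom, strand, ((cds_start, cds_end),), tss,
            cds_exons=((cds_start, cds_end),),
        )
        genes.append(gene)

        # coding order -> genomic position
        if strand == "+":
            pos_of = lambda k: cds_start + k
        else:
            pos_of = lambda k: cds_end - k

        n_syn_target = int(rng.integers(0, 4))
        n_mis_target = int(rng.integers(0, 4))
        used: set[int] = set()
        n_syn = n_mis = 0
        attempts = 0
        while (n_syn < n_syn_target or n_mis < n_mis_target) and attempts < 500:
            attempts += 1
            # keep start and stop codons intact so classes stay syn/missense
            k = int(rng.integers(3, cds_len - 3))
            if k in used:
                continue
            codon_i, off = divmod(k, 3)
            codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
            alt_c = str(rng.choice([b for b in "ACGT" if b != codon[off]]))
            alt_codon = codon[:off] + alt_c + codon[off + 1 :]
            if alt_codon in _CODON_STOPS:
                continue
            synonymous = _translate(codon) == _translate(alt_codon)
            if synonymous and n_syn >= n_syn_target:
                continue
            if not synonymous and n_mis >= n_mis_target:
                continue
            used.add(k)
            pos = pos_of(k)
            ref_base = seq[pos - 1]
            alt_base = alt_c if strand == "+" else _revcomp(alt_c)
            calls.append((pos, ref_base, alt_base))
            if synonymous:
                n_syn += 1
            else:
                n_mis += 1

        n_up_target = int(rng.integers(0, 6))
        if strand == "+":
            window = range(tss - upstream_window, tss)
        else:
            window = range(tss + 1, tss + upstream_window + 1)
        up_positions = rng.choice(
            np.array(list(window)), size=n_up_target, replace=False
        )
        for pos in sorted(int(p) for p in up_positions):
            ref_base = seq[pos - 1]
            alt_base = _OTHER[ref_base]
            calls.append((pos, ref_base, alt_base))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "n_syn": n_syn,
                "n_nonsyn": n_mis,
                "n_upstream": n_up_target,
            }
        )

    calls.sort()
    calls_p1, calls_p2 = [], []
    for pos, ref_base, alt_base in calls:
        d1 = int(rng.integers(15, 40))
        d2 = int(rng.integers(15, 40))
        calls_p1.append(
            GenotypeCall(chrom, pos, ref_base, alt_base, "hom-ref", d1, 0)
        )
        calls_p2.append(
            GenotypeCall(chrom, pos, ref_base, alt_base, "hom-alt", 0, d2)
        )
    return ParentalVariantSim(
        reference={chrom: "".join(seq)},
        calls_p1=calls_p1,
        calls_p2=calls_p2,
        genes=genes,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Text-format writers
# ---------------------------------------------------------------------------


def write_fasta(reference: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(
    calls: Sequence[GenotypeCall],
    path: str,
    sample_name: str,
    contigs: Mapping[str, int],
) -> None:
    """Write single-sample genotype calls as an uncompressed VCF (pysam)."""
    import pysam

    header = pysam.VariantHeader()
    for name, ln in contigs.items():
        header.contigs.add(name, length=ln)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.add_sample(sample_name)
    gt_of = {"hom-ref": (0, 0), "het": (0, 1), "hom-alt": (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos,
                alleles=(call.ref_allele, call.alt_allele),
            )
            rec.samples[sample_name]["GT"] = gt_of[call.zygosity]
            rec.samples[sample_name]["AD"] = (call.ref_depth, call.alt_depth)
            out.write(rec)


def write_truth(truth: Sequence[TruthRecord], path: str) -> None:
    pd.DataFrame(
        [
            {"gene_id": r.gene_id, "true_category": r.true_category, "c": r.c, "t": r.t}
            for r in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(row.gene_id, row.true_category, float(row.c), float(row.t))
        for row in df.itertuples()
    ]
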