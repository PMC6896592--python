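"""Breed-informative SNP selection and parental-genome substitution.

In an F1 design between two inbred lines, a site is informative for
allele-specific read assignment when both parents are homozygous for
different bases: every hybrid offspring is then heterozygous there, and
the observed base on an RNA-seq read identifies the parental origin of
the transcript. This module builds that SNP list from two parental
genotype call sets and produces "substituted" parental genome sequences
in which well-supported alternate alleles replace the reference base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Sex chromosomes excluded from the autosomal analysis.
DEFAULT_EXCLUDED_CHROMS = frozenset({"Z", "W"})


@dataclass(frozen=True)
class GenotypeCall:
    """A single-sample SNV genotype call at one site.

    ``zygosity`` is one of ``"hom-ref"``, ``"het"``, ``"hom-alt"``.
    ``ref_depth``/``alt_depth`` are the read depths supporting each allele
    (the VCF AD field).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: str
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be nonnegative")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele.upper() in _BASES
            and self.alt_allele.upper() in _BASES
        )

    @property
    def called_allele(self) -> str | None:
        """The homozygous allele, or None for heterozygous calls."""
        if self.zygosity == "hom-ref":
            return self.ref_allele.upper()
        if self.zygosity == "hom-alt":
            return self.alt_allele.upper()
        return None

    @property
    def called_depth(self) -> int:
        """Depth supporting the homozygous allele (0 for het calls)."""
        if self.zygosity == "hom-ref":
            return self.ref_depth
        if self.zygosity == "hom-alt":
            return self.alt_depth
        return 0


@dataclass(frozen=True, order=True)
class HetSnp:
    """A breed-informative site: parent 1 and parent 2 carry different bases."""

    chrom: str
    pos: int  # 1-based
    allele_p1: str
    allele_p2: str

    def __post_init__(self) -> None:
        if self.allele_p1 == self.allele_p2:
            raise ValueError(
                f"informative site {self.chrom}:{self.pos} requires distinct alleles"
            )


def _check_sorted(calls: Sequence[GenotypeCall], label: str) -> None:
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError(f"{label} call set is not sorted by (chrom, pos)")


def select_informative_snps(
    calls_p1: Sequence[GenotypeCall],
    calls_p2: Sequence[GenotypeCall],
    min_depth: int = 10,
) -> list[HetSnp]:
    """Select sites homozygous for different alleles in the two parents.

    A site is emitted iff both parents carry a homozygous SNV call there,
    the two called alleles differ, and each parent's supporting depth for
    its called allele is strictly greater than ``min_depth``. Sites present
    in only one call set are treated as uncalled and skipped; non-SNV
    records are skipped with a logged count.

    Both inputs must be sorted by (chrom, pos); the output is sorted.
    """
    _check_sorted(calls_p1, "parent 1")
    _check_sorted(calls_p2, "parent 2")

    n_non_snv = 0
    by_site_p2: dict[tuple[str, int], GenotypeCall] = {}
    for call in calls_p2:
        if not call.is_snv:
            n_non_snv += 1
            continue
        by_site_p2[(call.chrom, call.pos)] = call

    out: list[HetSnp] = []
    for c1 in calls_p1:
        if not c1.is_snv:
            n_non_snv += 1
            continue
        c2 = by_site_p2.get((c1.chrom, c1.pos))
        if c2 is None:
            continue
        a1, a2 = c1.called_allele, c2.called_allele
        if a1 is None or a2 is None or a1 == a2:
            continue
        if c1.called_depth > min_depth and c2.called_depth > min_depth:
            out.append(HetSnp(c1.chrom, c1.pos, a1, a2))
    if n_non_snv:
        logger.info("skipped %d non-SNV records", n_non_snv)
    out.sort()
    return out


def substitute_reference(sequence: str, calls: Iterable[GenotypeCall]) -> str:
    """Replace reference bases by alternate alleles with majority read support.

    At each SNV call the base becomes the alternate allele iff
    ``alt_depth > ref_depth`` (a tie keeps the reference). Output length
    always equals input length. ``calls`` must all lie within the sequence;
    chromosome names are not checked here — pass the calls for one sequence.
    """
    seq = list(sequence)
    for call in calls:
        if not call.is_snv:
            continue
        if call.pos > len(seq):
            raise ValueError(
                f"call at {call.chrom}:{call.pos} beyond sequence end ({len(seq)} bp)"
            )
        if call.alt_depth > call.ref_depth:
            seq[call.pos - 1] = call.alt_allele.upper()
    return "".join(seq)


def _chrom_matches(chrom: str, excluded: frozenset[str] | set[str]) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return chrom in excluded or name in excluded


def exclude_sex_chromosomes(records, excluded_names=DEFAULT_EXCLUDED_CHROMS):
    """Drop records on the given chromosomes (default Z and W), keeping order.

    ``records`` is any iterable of objects with a ``chrom`` attribute.
    Names are matched with or without a ``chr`` prefix.
    """
    excluded = frozenset(excluded_names)
    return [r for r in records if not _chrom_matches(r.chrom, excluded)]


# ---------------------------------------------------------------------------
# VCF / TSV I/O
# ---------------------------------------------------------------------------


def read_genotype_calls(vcf_path: str, sample: str | int = 0) -> list[GenotypeCall]:
    """Load single-sample genotype calls from a VCF using pysam.

    Multi-allelic and non-SNV records are kept as calls but flagged non-SNV
    downstream (``select_informative_snps`` skips and counts them). The AD
    field supplies the allele depths; records without AD get depth 0.
    """
    import pysam

    calls: list[GenotypeCall] = []
    with pysam.VariantFile(vcf_path) as vcf:
        sample_name = (
            list(vcf.header.samples)[sample] if isinstance(sample, int) else sample
        )
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            sm = rec.samples[sample_name]
            gt = sm.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if all(a == 0 for a in gt):
                zyg = "hom-ref"
            elif all(a == 1 for a in gt):
                zyg = "hom-alt"
            else:
                zyg = "het"
            ad = sm.get("AD")
            ref_depth, alt_depth = (int(ad[0]), int(ad[1])) if ad else (0, 0)
            calls.append(
                GenotypeCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    zygosity=zyg,
                    ref_depth=ref_depth,
                    alt_depth=alt_depth,
                )
            )
    return calls


def write_het_snps(snps: Sequence[HetSnp], path: str) -> None:
    """Write the informative-SNP list as a sorted 4-column TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele_p1\tallele_p2\n")
        for s in sorted(snps):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.allele_p1}\t{s.allele_p2}\n")


def read_het_snps(path: str) -> list[HetSnp]:
    snps: list[HetSnp] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: expected a header line starting with 'chrom'")
        for line in fh:
            chrom, pos, a1, a2 = line.rstrip("\n").split("\t")
            snps.append(HetSnp(chrom, int(pos), a1, a2))
    return snps
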