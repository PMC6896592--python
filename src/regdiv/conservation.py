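"""Sequence-conservation scoring of classified genes.

Two complementary measures compare selective constraint between the
cis- and trans-regulated gene groups:

* pN/pS — the ratio of non-synonymous to synonymous SNP counts within a
  gene's coding sequence (raw count ratio, no site normalization); lower
  values indicate stronger purifying selection on the protein.
* upstream variant density — the number of SNPs within 1 kb upstream of
  the transcription start site, where proximal cis-regulatory elements
  concentrate.

Variant effects are annotated by strand-aware codon substitution against
the standard genetic code; non-synonymous covers missense plus the
start/stop gain/loss classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .counting import GeneModel

logger = logging.getLogger(__name__)

EFFECT_CLASSES = (
    "missense",
    "start_lost",
    "start_gained",
    "stop_lost",
    "stop_gained",
    "synonymous",
    "non_coding",
)

NON_SYNONYMOUS = frozenset(
    {"missense", "start_lost", "start_gained", "stop_lost", "stop_gained"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantEffect:
    variant: Variant
    effect_class: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class GeneConservation:
    """Per-gene counts of coding and upstream variants; pn_ps is None when
    no synonymous variant exists (excluded from group means)."""

    gene_id: str
    n_nonsyn: int
    n_syn: int
    upstream_variants: int

    @property
    def pn_ps(self) -> float | None:
        if self.n_syn == 0:
            return None
        return self.n_nonsyn / self.n_syn


def _cds_map(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in coding (5'->3') order."""
    positions: list[int] = []
    for start, end in gene.cds_exons:
        positions.extend(range(start, end + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


def _read_base(reference: str, pos: int) -> str:
    return reference[pos - 1].upper()


def annotate_variant(
    variant: Variant, gene: GeneModel, reference: str
) -> VariantEffect:
    """Classify an SNV's effect on one gene's coding sequence.

    The reference string is the sequence of the variant's chromosome.
    Positions outside the CDS are non_coding. Within the CDS the reference
    codon and the substituted codon are compared in coding orientation:
    changes at the initiator codon are start_lost / start_gained, stop
    codon changes are stop_lost / stop_gained (these take precedence over
    missense), identical amino acids are synonymous, the rest missense.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValueError("only SNVs can be annotated")
    cds_positions = _cds_map(gene)
    if len(cds_positions) % 3 != 0:
        raise ValueError(
            f"{gene.gene_id}: CDS length {len(cds_positions)} not divisible by 3"
        )
    try:
        cds_index = cds_positions.index(variant.pos)
    except ValueError:
        return VariantEffect(variant, "non_coding", gene.gene_id)

    codon_index = cds_index // 3
    offset = cds_index % 3
    codon_genomic = cds_positions[codon_index * 3 : codon_index * 3 + 3]
    ref_codon = "".join(_read_base(reference, p) for p in codon_genomic)
    alt_base = variant.alt.upper()
    if gene.strand == "-":
        ref_codon = ref_codon.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    expected_ref = variant.ref.upper()
    if gene.strand == "-":
        expected_ref = expected_ref.translate(_COMPLEMENT)
    if ref_codon[offset] != expected_ref:
        logger.warning(
            "variant %s:%d ref %s disagrees with reference base %s",
            variant.chrom, variant.pos, variant.ref, ref_codon[offset],
        )
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]

    if codon_index == 0:
        if ref_codon == "ATG" and alt_codon != "ATG":
            return VariantEffect(variant, "start_lost", gene.gene_id)
        if ref_codon != "ATG" and alt_codon == "ATG":
            return VariantEffect(variant, "start_gained", gene.gene_id)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == "*" and alt_aa != "*":
        return VariantEffect(variant, "stop_lost", gene.gene_id)
    if alt_aa == "*" and ref_aa != "*":
        return VariantEffect(variant, "stop_gained", gene.gene_id)
    if ref_aa == alt_aa:
        return VariantEffect(variant, "synonymous", gene.gene_id)
    return VariantEffect(variant, "missense", gene.gene_id)


def count_upstream_variants(
    gene: GeneModel, variants: Iterable[Variant], window: int = 1000
) -> int:
    """Count variants within ``window`` bases upstream of the TSS.

    Plus strand: positions [tss - window, tss - 1]; minus strand:
    [tss + 1, tss + window]; both bounds inclusive, the TSS excluded.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if gene.strand == "+":
        lo, hi = gene.tss - window, gene.tss - 1
    else:
        lo, hi = gene.tss + 1, gene.tss + window
    return sum(
        1 for v in variants if v.chrom == gene.chrom and lo <= v.pos <= hi
    )


def compute_pn_ps(
    gene_id: str,
    effects: Sequence[VariantEffect],
    upstream_variants: int = 0,
) -> GeneConservation:
    """Aggregate annotated variants of one gene into conservation counts."""
    n_nonsyn = sum(1 for e in effects if e.effect_class in NON_SYNONYMOUS)
    n_syn = sum(1 for e in effects if e.effect_class == "synonymous")
    return GeneConservation(gene_id, n_nonsyn, n_syn, upstream_variants)


def annotate_gene(
    gene: GeneModel,
    variants: Sequence[Variant],
    reference: str,
    window: int = 1000,
) -> GeneConservation:
    """Annotate all of a gene's chromosome variants and count both measures."""
    effects = []
    for v in variants:
        if v.chrom != gene.chrom:
            continue
        effects.append(annotate_variant(v, gene, reference))
    upstream = count_upstream_variants(gene, variants, window)
    return compute_pn_ps(gene.gene_id, effects, upstream)


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    method: str


def compare_conservation(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "mann_whitney",
) -> GroupComparison:
    """Two-sided comparison of a conservation measure between two gene groups.

    ``mann_whitney`` is the rank test used for upstream variant counts;
    ``welch_t`` the unequal-variance t-test used for pN/pS means. Groups
    need at least two finite values each.
    """
    from scipy import stats

    a = np.asarray([v for v in values_a if v is not None and math.isfinite(v)])
    b = np.asarray([v for v in values_b if v is not None and math.isfinite(v)])
    if a.size < 2 or b.size < 2:
        logger.warning("insufficient group sizes (%d, %d)", a.size, b.size)
        return GroupComparison(
            float("nan"), float("nan"),
            float(a.mean()) if a.size else float("nan"),
            float(b.mean()) if b.size else float("nan"),
            int(a.size), int(b.size), method,
        )
    if method == "mann_whitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "welch_t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        float(stat), float(p), float(a.mean()), float(b.mean()),
        int(a.size), int(b.size), method,
    )


def conservation_table(
    genes: Sequence[GeneModel],
    variants: Sequence[Variant],
    reference: Mapping[str, str],
    window: int = 1000,
):
    """Per-gene conservation rows for a cohort of coding genes."""
    import pandas as pd

    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    rows = []
    for g in genes:
        if not g.cds_exons:
            continue
        chrom_seq = reference[g.chrom]
        cons = annotate_gene(g, by_chrom.get(g.chrom, []), chrom_seq, window)
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_nonsyn": cons.n_nonsyn,
                "n_syn": cons.n_syn,
                "pn_ps": cons.pn_ps if cons.pn_ps is not None else float("nan"),
                "upstream_variants": cons.upstream_variants,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_nonsyn", "n_syn", "pn_ps", "upstream_variants"]
    )
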