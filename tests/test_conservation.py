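"""Codon-effect annotation against a brute-force genetic-code oracle,
pN/pS aggregation, upstream windows and group comparisons."""

import numpy as np
import pytest

from regdiv.conservation import (
    GeneConservation,
    Variant,
    annotate_variant,
    compare_conservation,
    compute_pn_ps,
    count_upstream_variants,
)
from regdiv.counting import GeneModel

# The standard genetic code, written out as the independent oracle.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def expected_class(ref_codon: str, alt_codon: str) -> str:
    """Oracle for a substitution in an internal (non-initiator) codon."""
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


def gene_with_middle_codon(codon: str, strand: str):
    """A 3-codon CDS (ATG, codon, TAA) at positions 101..109 of a chromosome.

    Returns (gene, reference) with the CDS written on the requested strand.
    """
    cds = "ATG" + codon + "TAA"
    planted = cds if strand == "+" else revcomp(cds)
    reference = "A" * 100 + planted + "C" * 100
    tss = 101 if strand == "+" else 109
    gene = GeneModel(
        "g", "chr1", strand, ((101, 109),), tss, cds_exons=((101, 109),)
    )
    return gene, reference


def all_middle_codon_cases():
    cases = []
    for codon in CODON_TABLE:
        for offset in range(3):
            for alt in "ACGT":
                if alt == codon[offset]:
                    continue
                for strand in "+-":
                    cases.append((codon, offset, alt, strand))
    return cases


class TestCodonOracle:
    def test_all_single_base_substitutions_both_strands(self):
        cases = all_middle_codon_cases()
        assert len(cases) == 64 * 9 * 2
        for codon, offset, alt, strand in cases:
            gene, reference = gene_with_middle_codon(codon, strand)
            alt_codon = codon[:offset] + alt + codon[offset + 1 :]
            # map coding offset within the middle codon to a genomic position
            cds_index = 3 + offset
            pos = 101 + cds_index if strand == "+" else 109 - cds_index
            ref_base = reference[pos - 1]
            alt_base = alt if strand == "+" else alt.translate(COMPLEMENT)
            eff = annotate_variant(
                Variant("chr1", pos, ref_base, alt_base), gene, reference
            )
            assert eff.effect_class == expected_class(codon, alt_codon), (
                codon, offset, alt, strand,
            )

    @pytest.mark.parametrize("strand", "+-")
    def test_initiator_codon_changes(self, strand):
        gene, reference = gene_with_middle_codon("GGG", strand)
        # destroy the ATG: coding position 1 (offset 1 in codon 0), T->C
        pos = 101 + 1 if strand == "+" else 109 - 1
        ref_base = reference[pos - 1]
        alt_base = "C" if strand == "+" else "G"
        eff = annotate_variant(
            Variant("chr1", pos, ref_base, alt_base), gene, reference
        )
        assert eff.effect_class == "start_lost"

    def test_start_gained_at_annotated_start(self):
        # CDS starts ACG (not ATG); C->T at coding position 1 creates ATG
        cds = "ACG" + "GGG" + "TAA"
        reference = "A" * 100 + cds + "C" * 100
        gene = GeneModel(
            "g", "chr1", "+", ((101, 109),), 101, cds_exons=((101, 109),)
        )
        eff = annotate_variant(Variant("chr1", 102, "C", "T"), gene, reference)
        assert eff.effect_class == "start_gained"

    def test_outside_cds_is_non_coding(self):
        gene, reference = gene_with_middle_codon("GGG", "+")
        eff = annotate_variant(Variant("chr1", 50, "A", "G"), gene, reference)
        assert eff.effect_class == "non_coding"

    def test_cds_length_not_multiple_of_three_rejected(self):
        gene = GeneModel(
            "g", "chr1", "+", ((101, 108),), 101, cds_exons=((101, 108),)
        )
        with pytest.raises(ValueError, match="divisible by 3"):
            annotate_variant(Variant("chr1", 103, "A", "G"), gene, "A" * 200)


class TestPnPs:
    def test_ratio_arithmetic(self):
        effs = [_effect("missense", 0), _effect("stop_gained", 1),
                _effect("start_lost", 2), _effect("stop_lost", 3),
                _effect("synonymous", 4), _effect("synonymous", 5)]
        cons = compute_pn_ps("g", effs)
        assert cons.n_nonsyn == 4 and cons.n_syn == 2
        assert cons.pn_ps == pytest.approx(2.0)

    def test_zero_nonsynonymous(self):
        effs = [_effect("synonymous", i) for i in range(3)]
        assert compute_pn_ps("g", effs).pn_ps == 0.0

    def test_no_synonymous_is_undefined(self):
        effs = [_effect("missense", 0), _effect("missense", 1)]
        assert compute_pn_ps("g", effs).pn_ps is None

    def test_non_coding_ignored(self):
        effs = [_effect("non_coding", 0), _effect("synonymous", 1)]
        cons = compute_pn_ps("g", effs)
        assert cons.n_nonsyn == 0 and cons.n_syn == 1


def _effect(effect_class, i):
    from regdiv.conservation import VariantEffect

    return VariantEffect(Variant("chr1", 100 + i, "A", "G"), effect_class, "g")


class TestUpstreamWindow:
    def plus_gene(self, tss=10000):
        return GeneModel("g", "chr1", "+", ((tss, tss + 99),), tss)

    def minus_gene(self, tss=10000):
        return GeneModel("g", "chr1", "-", ((tss - 99, tss),), tss)

    def variants(self, positions):
        return [Variant("chr1", p, "A", "G") for p in positions]

    def test_plus_strand_window(self):
        g = self.plus_gene()
        assert count_upstream_variants(g, self.variants([9500, 9990, 10050])) == 2
        # boundaries: tss-1000 and tss-1 inside, tss itself excluded
        assert count_upstream_variants(g, self.variants([9000, 9999, 10000])) == 2
        assert count_upstream_variants(g, self.variants([8999])) == 0

    def test_minus_strand_window_reflects(self):
        g = self.minus_gene()
        assert count_upstream_variants(g, self.variants([10500])) == 1
        assert count_upstream_variants(g, self.variants([10001, 11000, 11001])) == 2
        assert count_upstream_variants(g, self.variants([10000, 9999])) == 0

    def test_no_variants(self):
        assert count_upstream_variants(self.plus_gene(), []) == 0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            count_upstream_variants(self.plus_gene(), [], window=0)


class TestGroupComparison:
    def test_identical_groups(self):
        cmp = compare_conservation([1, 2, 3], [1, 2, 3], "mann_whitney")
        assert cmp.pvalue == pytest.approx(1.0)

    def test_separated_groups_minimal_exact_p(self):
        cmp = compare_conservation([1, 2, 3], [101, 102, 103], "mann_whitney")
        assert cmp.statistic == 0.0
        assert cmp.pvalue == pytest.approx(0.1)
        assert cmp.mean_a == pytest.approx(2.0)
        assert cmp.mean_b == pytest.approx(102.0)

    def test_welch_t_runs_two_sided(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 50), rng.normal(1.5, 2, 50)
        cmp = compare_conservation(a, b, "welch_t")
        assert cmp.pvalue < 0.01

    def test_insufficient_group_warns_not_raises(self):
        cmp = compare_conservation([1.0], [1.0, 2.0], "mann_whitney")
        assert np.isnan(cmp.pvalue)

    def test_none_values_excluded(self):
        cmp = compare_conservation([1.0, None, 2.0], [3.0, 4.0], "mann_whitney")
        assert cmp.n_a == 2


class TestStrandReflection:
    def test_reverse_complementing_reference_preserves_classes(self):
        rng = np.random.default_rng(8)
        from regdiv.simulate import SimulationConfig, simulate_parental_variants
        from regdiv.conservation import conservation_table

        sim = simulate_parental_variants(SimulationConfig(n_genes=6, seed=13))
        chrom = "chr1"
        seq = sim.reference[chrom]
        L = len(seq)
        flipped_seq = revcomp(seq)
        flipped_genes = [
            GeneModel(
                g.gene_id, chrom,
                "-" if g.strand == "+" else "+",
                tuple(sorted((L - e + 1, L - s + 1) for s, e in g.exons)),
                L - g.tss + 1,
                tuple(sorted((L - e + 1, L - s + 1) for s, e in g.cds_exons)),
            )
            for g in sim.genes
        ]
        variants = [
            Variant(chrom, c.pos, c.ref_allele, c.alt_allele) for c in sim.calls_p1
        ]
        flipped_variants = [
            Variant(
                chrom, L - v.pos + 1,
                v.ref.translate(COMPLEMENT), v.alt.translate(COMPLEMENT),
            )
            for v in variants
        ]
        orig = conservation_table(sim.genes, variants, {chrom: seq})
        flip = conservation_table(
            flipped_genes, flipped_variants, {chrom: flipped_seq}
        )
        merged = orig.merge(flip, on="gene_id", suffixes=("_o", "_f"))
        assert (merged["n_syn_o"] == merged["n_syn_f"]).all()
        assert (merged["n_nonsyn_o"] == merged["n_nonsyn_f"]).all()
        assert (merged["upstream_variants_o"] == merged["upstream_variants_f"]).all()
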