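"""The synthetic-data generator: truth invariants, generative means,
read-level phasing evidence, and format round-trips."""

import numpy as np
import pandas as pd
import pytest

from regdiv.classify import CATEGORIES
from regdiv.counting import count_gene_alleles, read_evidence_from_sam
from regdiv.simulate import (
    SimulationConfig,
    TruthRecord,
    generate_truth,
    hybrid_allele1_proportion,
    simulate_counts,
    simulate_parental_variants,
    simulate_reads,
    write_sam,
)


class TestConfigValidation:
    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(category_mix={"cis": 0.5, "trans": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(category_mix={"cis": 1.2, "trans": -0.2})
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig(category_mix={"sideways": 1.0})

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=-0.1)

    def test_short_reads_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            SimulationConfig(read_length=0)


class TestGenerateTruth:
    def test_pure_conserved_mix(self):
        cfg = SimulationConfig(
            n_genes=50, category_mix={"conserved": 1.0}, seed=1
        )
        truth = generate_truth(cfg)
        assert all(r.c == 0 and r.t == 0 for r in truth)

    def test_fixed_magnitude_compensatory(self):
        cfg = SimulationConfig(
            n_genes=100, category_mix={"compensatory": 1.0},
            cis_effect_scale=1.0, effect_distribution="fixed", seed=2,
        )
        truth = generate_truth(cfg)
        assert all((r.c, r.t) in ((1.0, -1.0), (-1.0, 1.0)) for r in truth)

    def test_uniform_mix_counts_within_multinomial_bounds(self):
        cfg = SimulationConfig(
            n_genes=1000, category_mix={c: 1 / 8 for c in CATEGORIES}, seed=3
        )
        truth = generate_truth(cfg)
        counts = pd.Series([r.true_category for r in truth]).value_counts()
        assert set(counts.index) == set(CATEGORIES)
        assert counts.between(80, 170).all()

    def test_category_constraints_hold(self):
        cfg = SimulationConfig(n_genes=2000, seed=4)
        for r in generate_truth(cfg):
            if r.true_category == "conserved":
                assert r.c == 0 and r.t == 0
            elif r.true_category == "cis":
                assert r.c != 0 and r.t == 0
            elif r.true_category == "trans":
                assert r.c == 0 and r.t != 0
            elif r.true_category == "compensatory":
                assert r.c == -r.t != 0
            elif r.true_category == "cis+trans(same)":
                assert r.c * r.t > 0
            elif r.true_category == "cis+trans(opposite)":
                assert r.c * r.t < 0 and abs(r.t) < abs(r.c)
            elif r.true_category == "cisxtrans":
                assert r.c * r.t < 0 and abs(r.t) > abs(r.c)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=200, seed=11)
        assert generate_truth(cfg) == generate_truth(cfg)


class TestSimulateCounts:
    def test_hybrid_proportion_formula(self):
        assert hybrid_allele1_proportion(0.0) == 0.5
        assert hybrid_allele1_proportion(1.0) == pytest.approx(2 / 3)

    def test_purebred_ratio_recovers_cis_plus_trans(self):
        # c=0, t=2 => strain1/strain2 mean ratio = 2**2 = 4, Poisson noise
        n = 10000
        truth = [TruthRecord(f"g{i}", "trans", 0.0, 2.0) for i in range(n)]
        cfg = SimulationConfig(
            n_genes=n, base_expression_mean=1000.0, dispersion=0.0,
            replicates_per_group=1, seed=5,
        )
        sc = simulate_counts(truth, cfg)
        pooled = sc.purebred.pooled()
        ratio = pooled["count_allele1"].mean() / pooled["count_allele2"].mean()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_hybrid_split_recovers_cis(self):
        n = 2000
        truth = [TruthRecord(f"g{i}", "cis", 1.0, 0.0) for i in range(n)]
        cfg = SimulationConfig(
            n_genes=n, base_expression_mean=500.0, dispersion=0.0, seed=6
        )
        sc = simulate_counts(truth, cfg)
        pooled = sc.hybrid.pooled()
        prop = pooled["count_allele1"].sum() / pooled.to_numpy().sum()
        assert prop == pytest.approx(2 / 3, abs=0.01)

    def test_per_gene_proportion_within_binomial_error(self):
        # dispersion 0: nearly all genes within 3 SE of 2**c/(1+2**c)
        rng = np.random.default_rng(12)
        n = 300
        truth = [
            TruthRecord(f"g{i}", "cis", float(rng.uniform(-2, 2)) or 0.5, 0.0)
            for i in range(n)
        ]
        cfg = SimulationConfig(
            n_genes=n, base_expression_mean=3500.0, dispersion=0.0,
            replicates_per_group=3, seed=13,
        )
        sc = simulate_counts(truth, cfg)
        pooled = sc.hybrid.pooled()
        ok = 0
        for r in truth:
            h1 = pooled.loc[r.gene_id, "count_allele1"]
            total = h1 + pooled.loc[r.gene_id, "count_allele2"]
            p = hybrid_allele1_proportion(r.c)
            se = np.sqrt(p * (1 - p) / total)
            ok += abs(h1 / total - p) <= 3 * se
        assert ok / n >= 0.99

    def test_library_size_scales_expectations(self):
        truth = [TruthRecord(f"g{i}", "conserved", 0.0, 0.0) for i in range(400)]
        sizes = {
            "pure_s1_r1": 4e6, "pure_s2_r1": 1e6, "hyb_r1": 2e6,
        }
        cfg = SimulationConfig(
            n_genes=400, base_expression_mean=200.0, dispersion=0.0,
            replicates_per_group=1, library_sizes=sizes, seed=7,
        )
        sc = simulate_counts(truth, cfg)
        pooled = sc.purebred.pooled()
        # libraries differ 4:1 so equal-expression genes show a 4:1 count ratio
        ratio = pooled["count_allele1"].sum() / pooled["count_allele2"].sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts([], SimulationConfig())

    def test_deterministic_under_seed(self, small_truth, small_config):
        a = simulate_counts(small_truth, small_config)
        b = simulate_counts(small_truth, small_config)
        assert a.purebred.counts.equals(b.purebred.counts)
        assert a.hybrid.counts.equals(b.hybrid.counts)


class TestSimulateReads:
    def test_error_free_reads_unambiguous(self, hybrid_read_sim):
        from regdiv.counting import assign_read_allele, build_snp_lookup

        lookup = build_snp_lookup(hybrid_read_sim.snps)
        for r in hybrid_read_sim.reads[:500]:
            outcome = assign_read_allele(r.evidence(), lookup)
            assert outcome == f"allele{r.true_allele}"

    def test_high_error_rate_produces_mixed_vectors(self, small_truth):
        cfg = SimulationConfig(
            n_genes=len(small_truth), genotype_error_rate=0.5,
            snps_per_gene=3, seed=21, base_expression_mean=50.0,
        )
        sim = simulate_reads(small_truth, cfg, kind="hybrid")
        lookup = {(s.chrom, s.pos): (s.allele_p1, s.allele_p2) for s in sim.snps}
        mixed = 0
        multi = 0
        for r in sim.reads:
            if len(r.sites) < 2:
                continue
            multi += 1
            matches = {
                0 if b == lookup[(r.chrom, p)][0] else 1 for p, b in r.sites
            }
            mixed += len(matches) == 2
        assert multi > 0 and mixed > 0

    def test_allelic_ratio_recovered_from_reads(self):
        # one strongly expressed cis gene: assigned ratio ~ 2:1 within 99% CI
        truth = [TruthRecord("g1", "cis", 1.0, 0.0)]
        cfg = SimulationConfig(
            n_genes=1, base_expression_mean=10000.0, seed=22,
            genotype_error_rate=0.0,
        )
        sim = simulate_reads(truth, cfg, kind="hybrid")
        n1 = sum(1 for r in sim.reads if r.true_allele == 1)
        n = len(sim.reads)
        p = n1 / n
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p - 2 / 3) <= 2.58 * se

    def test_reads_cover_at_least_one_snp(self, hybrid_read_sim):
        assert all(len(r.sites) >= 1 for r in hybrid_read_sim.reads)

    def test_deterministic_under_seed(self, small_truth, small_config):
        a = simulate_reads(small_truth, small_config, kind="hybrid")
        b = simulate_reads(small_truth, small_config, kind="hybrid")
        assert a.reads == b.reads
        assert a.snps == b.snps
        assert a.reference == b.reference

    def test_sam_round_trip_counts_identically(
        self, hybrid_read_sim, tmp_path
    ):
        sam_path = str(tmp_path / "reads.sam")
        write_sam(hybrid_read_sim, sam_path)
        sam_reads = read_evidence_from_sam(
            sam_path, [(s.chrom, s.pos) for s in hybrid_read_sim.snps]
        )
        t_mem, s_mem = count_gene_alleles(
            hybrid_read_sim.evidence(), hybrid_read_sim.genes, hybrid_read_sim.snps
        )
        t_sam, s_sam = count_gene_alleles(
            sam_reads, hybrid_read_sim.genes, hybrid_read_sim.snps
        )
        assert t_mem.counts.equals(t_sam.counts)
        assert s_mem.total == s_sam.total


class TestSimulateParentalVariants:
    def test_truth_counts_recovered_by_annotation(self):
        from regdiv.conservation import Variant, conservation_table

        sim = simulate_parental_variants(SimulationConfig(n_genes=25, seed=30))
        variants = [
            Variant(c.chrom, c.pos, c.ref_allele, c.alt_allele)
            for c in sim.calls_p1
        ]
        table = conservation_table(sim.genes, variants, sim.reference)
        merged = table.merge(sim.truth, on="gene_id", suffixes=("_got", "_true"))
        assert (merged["n_syn_got"] == merged["n_syn_true"]).all()
        assert (merged["n_nonsyn_got"] == merged["n_nonsyn_true"]).all()
        assert (merged["upstream_variants"] == merged["n_upstream"]).all()

    def test_minus_strand_upstream_lies_beyond_tss(self):
        sim = simulate_parental_variants(SimulationConfig(n_genes=12, seed=31))
        coding = {
            (s, e) for g in sim.genes for s, e in g.cds_exons
        }
        for g in sim.genes:
            if g.strand != "-":
                continue
            ups = [
                c.pos for c in sim.calls_p1
                if g.tss < c.pos <= g.tss + 1000
            ]
            # all planted non-coding variants of this gene sit above the TSS
            gene_vars = [
                c.pos for c in sim.calls_p1
                if abs(c.pos - g.tss) <= 1000
                and not any(s <= c.pos <= e for s, e in coding)
            ]
            assert sorted(ups) == sorted(gene_vars)

    def test_planted_pn_ps_by_construction(self):
        sim = simulate_parental_variants(SimulationConfig(n_genes=40, seed=32))
        row = sim.truth[(sim.truth.n_nonsyn == 2) & (sim.truth.n_syn == 1)]
        if not row.empty:
            assert (row.n_nonsyn / row.n_syn == 2.0).all()
        assert (sim.truth.n_syn >= 0).all()

    def test_parent_calls_are_opposite_homozygotes(self):
        sim = simulate_parental_variants(SimulationConfig(n_genes=10, seed=33))
        assert all(c.zygosity == "hom-ref" for c in sim.calls_p1)
        assert all(c.zygosity == "hom-alt" for c in sim.calls_p2)
        assert [(c.chrom, c.pos) for c in sim.calls_p1] == [
            (c.chrom, c.pos) for c in sim.calls_p2
        ]
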