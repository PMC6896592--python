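"""End-to-end orchestration: SNP selection -> counting -> filtering ->
classification -> conservation, one tissue-by-sex-by-cross group at a time,
with manifests recording thresholds and input checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    CATEGORIES,
    GeneCountSummary,
    classify_table,
    summarize_gene_counts,
)
from .conservation import Variant, compare_conservation, conservation_table
from .counting import (
    AlleleCountTable,
    count_gene_alleles,
    filter_expressed,
    read_evidence_from_sam,
    read_gene_models,
    read_read_table,
    null_proportion,
)
from .variants import (
    exclude_sex_chromosomes,
    read_genotype_calls,
    read_het_snps,
    select_informative_snps,
    write_het_snps,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and sample layout for one analysis group.

    ``samples`` maps sample name to its read file (simplified TSV or SAM,
    chosen by extension); ``sample_arms`` maps each sample to one of
    ``purebred1`` / ``purebred2`` / ``hybrid``.
    """

    vcf_p1: str
    vcf_p2: str
    samples: dict[str, str]
    sample_arms: dict[str, str]
    genes_path: str
    out_dir: str
    fasta_path: str | None = None
    library_sizes: dict[str, float] | None = None
    group: str = "group1"
    min_depth: int = 10
    prop_cut: float = 0.9
    min_total: int = 6
    max_total: int = 1000
    alpha: float = 0.05
    upstream_window: int = 1000
    exclude_chroms: tuple[str, ...] = ("Z", "W")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.prop_cut <= 1.0:
            raise ValueError("prop_cut must lie in (0,1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        if self.min_total > self.max_total:
            raise ValueError("min_total must not exceed max_total")
        if self.upstream_window <= 0:
            raise ValueError("upstream_window must be positive")
        bad_arm = {
            s: a for s, a in self.sample_arms.items()
            if a not in ("purebred1", "purebred2", "hybrid")
        }
        if bad_arm:
            raise ValueError(f"unknown design arms: {bad_arm}")
        for path in [self.vcf_p1, self.vcf_p2, self.genes_path, *self.samples.values()]:
            if not os.path.exists(path):
                raise FileNotFoundError(path)


@dataclass
class ResultBundle:
    per_gene: pd.DataFrame
    summary: pd.DataFrame
    conservation: pd.DataFrame | None
    conservation_tests: dict | None
    n_snps: int
    n_filtered_genes: int
    out_dir: str
    group: str
    manifest: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reads(path: str):
    if path.endswith((".sam", ".bam")):
        raise ValueError(
            "SAM inputs need the SNP list first; run_pipeline handles this"
        )
    return read_read_table(path)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute all stages for one group and write every intermediate.

    Identical config and inputs produce identical outputs: every stage is
    deterministic (the seed is recorded in the manifest for the synthetic
    generator upstream, not consumed here).
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    # Stage 1: informative-SNP selection
    calls_p1 = read_genotype_calls(config.vcf_p1)
    calls_p2 = read_genotype_calls(config.vcf_p2)
    snps = select_informative_snps(calls_p1, calls_p2, config.min_depth)
    snps = exclude_sex_chromosomes(snps, set(config.exclude_chroms))
    het_path = os.path.join(config.out_dir, f"{config.group}.het_snps.tsv")
    write_het_snps(snps, het_path)

    # Stage 2: gene models
    genes = exclude_sex_chromosomes(
        read_gene_models(config.genes_path), set(config.exclude_chroms)
    )

    # Stage 3: per-sample allele counting
    snp_positions = [(s.chrom, s.pos) for s in snps]
    pure_tables: list[AlleleCountTable] = []
    hyb_tables: list[AlleleCountTable] = []
    arm_of: dict[str, str] = {}
    for sample, path in sorted(config.samples.items()):
        if path.endswith((".sam", ".bam")):
            reads = read_evidence_from_sam(path, snp_positions)
        else:
            reads = read_read_table(path)
        lib = (config.library_sizes or {}).get(sample)
        table, summary = count_gene_alleles(
            reads, genes, snps, config.prop_cut, sample=sample, library_size=lib
        )
        logger.info(
            "%s: %d reads -> allele1 %d, allele2 %d, unassigned %d, uninformative %d",
            sample, summary.total, summary.n_allele1, summary.n_allele2,
            summary.n_unassigned, summary.n_uninformative,
        )
        arm = config.sample_arms[sample]
        arm_of[sample] = arm
        (hyb_tables if arm == "hybrid" else pure_tables).append(table)
    if not pure_tables or not hyb_tables:
        raise ValueError("need at least one purebred and one hybrid sample")
    purebred = AlleleCountTable.concat(pure_tables)
    hybrid = AlleleCountTable.concat(hyb_tables)
    counts_path = os.path.join(config.out_dir, f"{config.group}.counts.tsv")
    AlleleCountTable.concat([purebred, hybrid]).to_tsv(
        counts_path, os.path.join(config.out_dir, f"{config.group}.libsizes.tsv")
    )

    # Stage 4: expression filter on pooled arm totals
    pure_totals = purebred.gene_totals()
    hyb_totals = hybrid.gene_totals()
    kept = filter_expressed(
        pure_totals.to_dict(), hyb_totals.to_dict(),
        config.min_total, config.max_total,
    )
    kept_genes = sorted(kept)

    # Stage 5: classification
    n1 = sum(
        purebred.library_sizes[s] for s, a in arm_of.items() if a == "purebred1"
    )
    n2 = sum(
        purebred.library_sizes[s] for s, a in arm_of.items() if a == "purebred2"
    )
    p0_P = null_proportion(n1, n2) if n1 > 0 and n2 > 0 else 0.5
    geo = (n1 * n2) ** 0.5
    norm_P = (n1 / geo, n2 / geo) if geo > 0 else (1.0, 1.0)
    summaries = summarize_gene_counts(
        purebred.pooled(), hybrid.pooled(), kept_genes, p0_P=p0_P, norm_P=norm_P
    )
    per_gene, summary = classify_table(summaries, config.alpha)
    per_gene.to_csv(
        os.path.join(config.out_dir, f"{config.group}.categories.tsv"),
        sep="\t", index=False,
    )
    summary.to_csv(
        os.path.join(config.out_dir, f"{config.group}.category_summary.tsv"),
        sep="\t", index=False,
    )

    # Stage 6: conservation (needs a reference sequence)
    cons_df = None
    cons_tests = None
    if config.fasta_path is not None:
        import pyfaidx

        fa = pyfaidx.Fasta(config.fasta_path)
        reference = {name: str(fa[name][:]) for name in fa.keys()}
        variants = [
            Variant(s.chrom, s.pos, s.allele_p1, s.allele_p2) for s in snps
        ]
        cons_df = conservation_table(
            genes, variants, reference, config.upstream_window
        )
        cons_df.to_csv(
            os.path.join(config.out_dir, f"{config.group}.conservation.tsv"),
            sep="\t", index=False,
        )
        cat_of = dict(zip(per_gene["gene_id"], per_gene["category"]))
        cis_ids = {g for g, c in cat_of.items() if c == "cis"}
        trans_ids = {g for g, c in cat_of.items() if c == "trans"}
        cis_rows = cons_df[cons_df["gene_id"].isin(cis_ids)]
        trans_rows = cons_df[cons_df["gene_id"].isin(trans_ids)]
        cons_tests = {}
        up = compare_conservation(
            cis_rows["upstream_variants"], trans_rows["upstream_variants"],
            method="mann_whitney",
        )
        pn = compare_conservation(
            cis_rows["pn_ps"].dropna(), trans_rows["pn_ps"].dropna(),
            method="welch_t",
        )
        cons_tests = {
            "upstream_variants": vars(up),
            "pn_ps": vars(pn),
        }
        with open(
            os.path.join(config.out_dir, f"{config.group}.conservation_tests.json"),
            "w",
        ) as fh:
            json.dump(cons_tests, fh, indent=2, default=float)

    manifest = {
        "tool": "regdiv",
        "version": __version__,
        "group": config.group,
        "seed": config.seed,
        "thresholds": {
            "min_depth": config.min_depth,
            "prop_cut": config.prop_cut,
            "min_total": config.min_total,
            "max_total": config.max_total,
            "alpha": config.alpha,
            "upstream_window": config.upstream_window,
            "exclude_chroms": list(config.exclude_chroms),
        },
        "inputs": {
            os.path.basename(p): _sha256(p)
            for p in [config.vcf_p1, config.vcf_p2, config.genes_path,
                      *config.samples.values()]
        },
        "n_informative_snps": len(snps),
        "n_filtered_genes": len(kept_genes),
    }
    with open(
        os.path.join(config.out_dir, f"{config.group}.manifest.json"), "w"
    ) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ResultBundle(
        per_gene=per_gene,
        summary=summary,
        conservation=cons_df,
        conservation_tests=cons_tests,
        n_snps=len(snps),
        n_filtered_genes=len(kept_genes),
        out_dir=config.out_dir,
        group=config.group,
        manifest=manifest,
    )


def summarize_intersections(
    calls_by_group: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Cross-group consistency: how often each category label recurs.

    ``calls_by_group`` maps group name -> {gene_id: category}. Intersections
    are computed on the genes present in every group (mismatched universes
    are reduced to the common set, with the sizes logged). Returns one row
    per (category, k) with the number of common-set genes carrying that
    label in exactly k groups, plus ``in_all_groups`` / ``one_group_only``
    convenience columns on the k rows they correspond to.
    """
    groups = list(calls_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    universes = [set(calls_by_group[g]) for g in groups]
    common = set.intersection(*universes)
    if any(len(u) != len(common) for u in universes):
        logger.info(
            "gene universes differ (sizes %s); using %d common genes",
            [len(u) for u in universes], len(common),
        )
    n_groups = len(groups)
    rows = []
    for cat in CATEGORIES:
        tally: dict[int, int] = {k: 0 for k in range(1, n_groups + 1)}
        for gene in common:
            k = sum(1 for g in groups if calls_by_group[g][gene] == cat)
            if k > 0:
                tally[k] += 1
        for k in range(1, n_groups + 1):
            rows.append(
                {
                    "category": cat,
                    "k_groups": k,
                    "n_genes": tally[k],
                    "in_all_groups": tally[k] if k == n_groups else None,
                    "one_group_only": tally[k] if k == 1 else None,
                }
            )
    return pd.DataFrame(rows)


def export_report(
    bundles: Sequence[ResultBundle], out_prefix: str
) -> tuple[str, str]:
    """Write the per-group category table in both TSV and JSON renderings.

    The two renderings agree field for field; missing sections (e.g. a
    group without conservation inputs) are marked explicitly.
    """
    rows = []
    payload: dict = {"groups": {}}
    for b in bundles:
        total = int(b.summary["count"].sum())
        group_obj: dict = {"n_genes": total, "categories": {}, "manifest": b.manifest}
        for _, r in b.summary.iterrows():
            prop = float(r["proportion"]) if total else float("nan")
            rows.append(
                {
                    "group": b.group,
                    "category": r["category"],
                    "count": int(r["count"]),
                    "proportion": prop,
                }
            )
            group_obj["categories"][r["category"]] = {
                "count": int(r["count"]),
                "proportion": prop,
            }
        group_obj["conservation_tests"] = (
            b.conservation_tests if b.conservation_tests is not None else "missing"
        )
        payload["groups"][b.group] = group_obj
    tsv_path = out_prefix + ".report.tsv"
    json_path = out_prefix + ".report.json"
    pd.DataFrame(rows, columns=["group", "category", "count", "proportion"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    return tsv_path, json_path
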