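# regdiv

Cis/trans regulatory-divergence analysis from allele-specific expression in
F1 crosses of inbred lines.

## The problem

When two diverged lines are crossed, both alleles of every autosomal gene
in the F1 hybrid sit in the same nucleus and see the same trans-acting
factors. A **cis**-regulatory difference between the parental haplotypes
therefore shows up as allelic imbalance inside the hybrid, while a
**trans**-acting difference changes expression between the purebred lines
but leaves the hybrid's alleles balanced. Contrasting the two measurements
separates — gene by gene — the mode of regulatory divergence between the
parental lines. `regdiv` is for researchers running this design with
RNA-seq of purebred and hybrid offspring plus genome sequencing of the
parents, including the common case where no strain-specific reference
genome exists.

## What it computes

Writing c and t for the cis and trans log2 effects, the purebred log2
expression ratio estimates c + t and the hybrid allelic log2 ratio
estimates c. Per gene, on replicate-pooled counts:

* **P test** — binomial, purebred strain 1 vs strain 2 counts against the
  library-size null p0 = N1/(N1+N2);
* **H test** — binomial, hybrid allele 1 vs allele 2 counts against 0.5;
* **T test** — Fisher's exact test on [[P1, P2], [H1, H2]], detecting a
  difference between the two ratios, the signature of trans divergence.

Each family is corrected to Storey q-values (significant at q < 0.05), and
the significance pattern plus ratio signs/magnitudes place every gene in
one of eight categories: cis, trans, cis+trans(same), cis+trans(opposite),
cisxtrans, compensatory, conserved, ambiguous.

Around this core the package provides: breed-informative SNP selection
from parental VCFs (opposite homozygotes, depth > 10), reference-base
substitution for building parental genomes, prop.cut read-to-allele
assignment and exon-set-level gene counting (SAM or a simplified read
table), the 6–1000 pooled expression filter, a pseudo-hybrid concatenation
validation, pN/pS and 1-kb-upstream variant-density conservation scoring
with Mann-Whitney/Welch group comparisons, and a synthetic-data generator
with known regulatory truth that makes every stage testable without
external data.

## Worked example

Simulate a 500-gene study (Poisson counting noise, pooled depth ~900 per
arm) and classify it:

```python
from regdiv import SimulationConfig, generate_truth, classify_table
from regdiv.simulate import simulate_counts
from regdiv.classify import summarize_gene_counts

cfg = SimulationConfig(n_genes=500, base_expression_mean=300.0,
                       dispersion=0.0, seed=7)
truth = generate_truth(cfg)
sim = simulate_counts(truth, cfg)
summaries = summarize_gene_counts(sim.purebred.pooled(), sim.hybrid.pooled())
per_gene, summary = classify_table(summaries, alpha=0.05)
print(summary.to_string(index=False))
```

```
           category  count  proportion
                cis     31       0.062
              trans     56       0.112
    cis+trans(same)     11       0.022
cis+trans(opposite)      6       0.012
          cisxtrans     12       0.024
       compensatory     23       0.046
          conserved    329       0.658
          ambiguous     32       0.064
```

The mix mirrors the generator's default truth composition: most genes
conserved, trans divergence more common than cis, and a visible
compensatory class (allelic imbalance in the hybrid that cancels between
the purebreds). Comparing `per_gene` against the planted truth, 75.8% of
genes receive exactly their true label at this depth; most disagreements
are conserved/ambiguous boundary cases and small-effect genes below the
power of a ~900-read contrast.

The same analysis runs from the shell on files:

```bash
regdiv simulate --n-genes 200 --seed 1 -o study/
regdiv select-snps --p1 study/expr_parent1.vcf --p2 study/expr_parent2.vcf -o het.tsv
regdiv count --reads study/hybrid.reads.sam --snps het.tsv \
             --genes study/genes.tsv --sample hyb -o hyb.counts.tsv
regdiv classify --purebred-counts pure.counts.tsv \
                --hybrid-counts hyb.counts.tsv -o categories.tsv
regdiv conserve --vcf study/parent1.vcf --genes study/coding_genes.tsv \
                --fasta study/coding_reference.fa -o conservation.tsv
```

See `docs/methods.md` for the model, assumptions, defaults, and known
limitations (notably the sensitivity of the pooled exact tests to
biological overdispersion).

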