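# Methods

## The problem

In an F1 hybrid between two inbred lines, both alleles of a gene share one
nucleus and therefore one trans-acting environment. A cis-regulatory
difference between the parental haplotypes shows up as allelic imbalance in
the hybrid; a trans-acting difference changes expression between the
purebred lines but leaves the hybrid alleles balanced. Comparing the two
contrasts separates the modes of regulatory divergence. `regdiv` implements
that comparison end to end for designs with purebred and reciprocal-hybrid
offspring of two inbred lines genotyped at parental homozygous SNPs.

## Model and tests

Let c and t denote the cis and trans log2 effects on strain 1 relative to
strain 2. The expected purebred log2 expression ratio is c + t; the expected
hybrid allelic log2 ratio is c. Three pooled-count exact tests are run per
gene within one tissue-by-sex-by-cross group:

* **P** (purebred divergence): binomial test of pooled strain-1 vs strain-2
  purebred counts against the library-size null p0 = N1 / (N1 + N2).
* **H** (allelic imbalance): binomial test of pooled hybrid allele-1 vs
  allele-2 counts against 0.5 (both alleles share each hybrid library).
* **T** (trans divergence): Fisher's exact test on the 2x2 table
  [[P1, P2], [H1, H2]] — a ratio difference between the two contrasts is the
  signature of trans action. Raw pooled counts are used: the shared
  library-size effect largely cancels in the ratio comparison, an
  approximation noted in the log.

Both exact tests use the two-sided "minlike" convention (sum of outcome
probabilities no larger than the observed outcome's). p-values from each
test family are corrected separately to q-values by the Storey procedure:
pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95, extrapolated with
a cubic smoother and clipped to (0, 1]; for families under 100 tests the
smoother is unstable and pi0 = 1 is used, which reduces to
Benjamini-Hochberg. A contrast is significant at q < 0.05.

The eight-way decision table (sig = significant):

| category              | rule                                                         |
|-----------------------|--------------------------------------------------------------|
| cis                   | sig P and H, not T                                           |
| trans                 | sig P and T, not H                                           |
| cis+trans(same)       | all sig; ratios same sign; purebred ratio larger in magnitude |
| cis+trans(opposite)   | all sig; ratios same sign; hybrid ratio larger in magnitude  |
| cisxtrans             | all sig; ratios opposite sign                                |
| compensatory          | sig H and T, not P                                           |
| conserved             | none significant                                             |
| ambiguous             | every other pattern                                          |

Ratios are log2 of normalized pooled counts with a 0.5 pseudocount, so they
are finite for every filtered gene; a zero ratio or an exact magnitude tie
(measure-zero after pseudocounting) routes to ambiguous. The
cis+trans(opposite) rule is implemented exactly as stated for this analysis
family — same sign with the hybrid difference larger — rather than the
alternative trans-sign formulation used elsewhere in the literature; with
effects drawn accordingly (t opposing but smaller than c) the two agree.

## Read counting

A read is evidence for a parental allele through the bases it shows at
informative SNPs (sites where the two parents are homozygous for different
bases, each with more than 10 supporting reads — strict inequality). Bases
matching neither parental allele are treated as sequencing error and
dropped from the denominator; among matching sites with majority fraction
f, the read is assigned when f > prop.cut (default 0.9, so in practice all
sites on a read must agree). An assigned read increments each overlapping
gene once, however many exons or SNPs it spans; reads overlapping several
genes' exon sets count once for each (overlaps are logged; arbitrating
them would discard information for no clear gain). Purebred samples flow
through the same code path, with strain identity playing the role of the
allele. Genes are kept when the pooled totals of both design arms lie in
[6, 1000], bounds inclusive. Z and W genes are excluded throughout;
only autosomal loci are analyzed.

Mapped-library-size normalization enters the binomial tests through the
null proportion rather than by rescaling counts, because exact tests need
integers; the per-sample scale factor (library size over the geometric
mean) is exposed for the log2 ratios.

## Conservation scoring

Variant effects are computed by strand-aware codon substitution under the
standard genetic code. Non-synonymous covers missense, start_lost,
start_gained, stop_lost and stop_gained; synonymous is an identical amino
acid. "start gained" is ill-defined for SNVs in general and is implemented
narrowly as an ATG created at the annotated initiator codon. pN/pS is the
raw count ratio n_nonsyn / n_syn, undefined (and excluded from group means)
when n_syn = 0 — a pseudocount would bias the cis-vs-trans group
comparison. Upstream variant density counts SNPs in the 1-kb window
upstream of the TSS ([tss-1000, tss-1] on the plus strand, mirrored on the
minus strand; both bounds inclusive, TSS excluded). Groups are compared
with the two-sided Mann-Whitney U test (upstream counts) and Welch's t
(pN/pS means; the unequal-variance form is the safer default when the
variant is unstated).

## The synthetic-data generator

The generator emulates the study design, not any particular dataset: two
inbred parents differing at homozygous SNVs; three purebred replicates per
strain and three hybrids; counts with expectation

* purebred strain 1: s_i * base * 2^((c+t)/2), strain 2 mirrored,
* hybrid: total around s_i * base, allele 1 binomial with
  proportion 2^c / (1 + 2^c),

where s_i is the sample's library scale factor. Count noise is negative
binomial with variance mu + dispersion * mu^2 (gamma-Poisson mixture),
exactly Poisson at dispersion 0 — the standard bulk RNA-seq noise family;
the upstream study reports replicates but no noise model. Defaults: 200
genes, base mean 100 reads/gene/sample, dispersion 0.05, read length 100 bp
(the platform's paired-end read length), 3 SNPs per gene, equal library
sizes. The default category mix is shaped like a typical tissue group of
such a cross — mostly conserved/ambiguous, trans more common than cis, a
visible compensatory class. Per-gene read depths are chosen for test power;
the real depth distribution of any given experiment is not emulated.

Truth effects respect the category definitions exactly (conserved c=t=0;
cis t=0; trans c=0; compensatory t=-c; the cis+trans subtypes place t so
the purebred ratio keeps or flips the sign of c as required). "Ambiguous"
is unconstrained by the definitions, so those genes receive small
sub-threshold effects of both kinds (0.025 log2 units). Effect magnitudes
are half-normal at the configured scale, floored at 0.1 log2 units so
nonzero-effect categories stay nonzero; a "fixed" mode uses the scale as
the exact magnitude. Read simulation places each gene as two exons on one
autosome, plants the SNPs inside exons, anchors every read on a SNP within
one exon, and flips SNP bases to the other parental allele with the
configured genotype error rate. Reads are emitted both as an in-memory /
TSV table and as valid SAM; both routes count identically.

Planted coding variants are chosen by trying random CDS positions and
alternate bases and verifying the resulting codon change by direct
translation at planting time, so the recorded synonymous / non-synonymous
/ upstream truth counts are exact by construction. What the generator does
not simulate: mapping bias, base-quality scores, parent-of-origin or
imprinting effects, sex-chromosome dosage. Passing tests therefore
demonstrate correctness of the counting and testing machinery under the
stated model, not robustness to alignment artifacts in real data.

## Verification problem sizes and numerical choices

The validation suite and `scripts/acceptance.py` use these problem sizes,
chosen so each check has clear statistical resolution: 1,000 random tables
(counts up to 200) for the exact-test enumeration oracles; all 1,152
single-base codon substitutions on both strands for the annotation oracle;
5,000 all-conserved genes at depth 100 for null error control; 500 genes
per category at |effects| = 2 and pooled depth 600 for parameter recovery;
200 genes for the pseudo-hybrid concatenation check; 10,000 uniform
p-values with 5,000 replicates for q-value calibration.

Null error control and parameter recovery are evaluated at dispersion 0.
The pooled exact tests model counting noise only; that is the regime in
which their calibration claims hold. This is also a real limitation: under
biological overdispersion (dispersion 0.05) the T test's null is violated,
cis recovery falls to roughly 65% and compensatory truth leaks into the
cisxtrans and cis+trans(opposite) labels. Users analyzing designs with
strong replicate-level variability should treat the cis+trans subcategories
with caution; a replicate-aware dispersion model is out of scope here, as
it is in the analysis family this package implements.

Other numerical notes: q-value computation sorts with a stable mergesort so
tied p-values get deterministic ranks; the binomial and Fisher
implementations delegate to scipy.stats (`binomtest`, `fisher_exact`),
whose two-sided conventions were verified against full enumeration to
better than 1e-12; a Fisher table with a zero margin carries no ratio
information and returns p = 1; an empty contrast (n = 0) yields an
undefined test and routes the gene to ambiguous. All coordinates are
1-based inclusive (SAM/VCF convention). Every random draw flows from a
single integer seed through named `SeedSequence` streams, so outputs are
byte-identical across runs and platforms.
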