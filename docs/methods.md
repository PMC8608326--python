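# Methods

## The problem

F1 hybrids of inbred crop parents often outperform both parents
(heterosis). Testing every candidate cross in the field is the
bottleneck of hybrid breeding: a pool of 50 cytoplasmic-male-sterile
(CMS) female lines and 8 restorer males already implies 400 crosses
grown across environments. `pgsihet` implements a genomic-selection
route around the field test: predict high-parent and mid-parent
heterosis (HPH, MPH) of a cross directly from the paired parental
genome sequences, so that a new (female, male) combination can be
scored in silico.

The central modeling idea is dimension reduction through a *parental
genetic similarity index* (PGSI): instead of feeding millions of SNPs
to the model, the genome is cut into fixed windows (1 Mb, 500 kb,
100 kb) and each window is summarized as a similarity score of the two
parental haplotypes. Window similarity is the biologically meaningful
quantity under dominance/over-dominance models of heterosis — a
dissimilar window generates heterozygosity in the F1 — and reduces the
feature count from millions to hundreds or thousands.

## PGSI

For a cross and a window, every SNP where both parents have a resolved
(homozygous, non-missing) call is marked:

* **2** — both parents carry the same nucleotide;
* **1** — exactly one parent matches the reference, the other differs;
* **0** — the parents differ from the reference and from each other.

The window PGSI is `sum(marks) / (2 * n_loci)`, which maps marks onto
[0, 1] with identical parents at 1. An alternative "literal" statistic,
two times the accumulated marks divided by the locus count, ranges over
[0, 4]; the normalized form (the unique scaling under which marks behave
as shared-allele counts) is the default and the literal form is retained
behind `literal=True` for auditability. The two differ only by the
constant factor 4, so correlations and LASSO selections are unaffected
by the choice.

Two boundary rules are worth stating. First, identical parental
nucleotides score 2 regardless of the reference: for strictly biallelic
SNPs, "both parents differ from the reference" can only mean they also
differ from each other at multiallelic sites, so the identity rule
takes precedence. Second, windows with no informative locus for a cross
default to PGSI 1.0 with a per-cell flag (no observed divergence among
the panel's called SNPs), with a `missing` policy available; model
layers impute missing cells with the training column mean.

Parents are assumed inbred throughout. A heterozygous parental call is
set missing at that site (logged), with a strict mode that raises
instead. Hybrid (F1) genotypes are never sequenced; they are inferred
by combining one resolved allele from each parent, which is exact for
inbred parents.

## Phenotype integration and heterosis

Multi-environment replicate data are integrated in two steps: replicate
observations are collapsed to genotype x environment means, and those
means are fit with the mixed model `y = Zg + Eu + e`, genotype effects
`g` fixed, environment effects `u ~ N(0, sigma_u^2 I)` random, residual
`e ~ N(0, sigma_e^2 I)`. The variance ratio is estimated by REML with a
profiled likelihood (bounded scalar search on the log ratio; the
genotype one-hot design and the block compound-symmetric covariance are
handled in closed form, so no large matrices are built). The fixed
genotype estimates are the BLUEs, already on the trait scale. For a
single environment the model degenerates to genotype means; the same
happens for any balanced layout, which is the expected behavior of a
genotype-fixed model.

Heterosis is computed from BLUEs as fractions, `HPH = (F1 - HP)/HP`
with `HP = max(P1, P2)` and `MPH = (F1 - MP)/MP` with
`MP = (P1+P2)/2`, exported as percentages (x100, 2 decimals).
"High parent" always means the numerically larger parental BLUE;
traits where smaller values are agronomically better are not
special-cased. Non-positive denominators yield missing values with a
warning; this can only occur for traits whose scale admits zero.
Top-fraction summaries (e.g. the mean heterosis of the best decile)
rank hybrids descending and keep `ceil(fraction * n)` of them, which
guarantees a non-empty selection.

## Prediction engines

Both engines share the marker model `y = X beta + sum_k Z_k gamma_k +
eps`. Additive marker codes are 1 / 0 / -1 for minor-allele homozygote
/ heterozygote / major-allele homozygote, with the minor allele
determined in the coded population and a 50/50 tie assigning "minor" to
the alternate allele (deterministic and independent of sample order).
Dominance codes are a per-marker mean-centered heterozygosity
indicator; the dominance kinship is built from them exactly like the
additive one.

**GBLUP.** `gamma_k ~ N(0, phi^2/m)` gives `var(y) = K phi^2 + I
sigma^2` with `K = (1/m) Z Z'` (no extra centering or scaling beyond
the coding). Single-kinship REML profiles the likelihood over
`lambda = phi^2/sigma^2` after one eigendecomposition of K, searching
`log10 lambda` in [-6, 6] to 1e-8; the additive+dominance model
maximizes over both log ratios by Nelder-Mead (max 500 iterations).
Fixed effects default to an intercept. Predictions for test
individuals use the test x train kinship blocks:
`g_test = sum_K lambda_K K_test,train V0^-1 (y - X beta)`. On any
common marker set this is algebraically identical to ridge regression
on marker effects with penalty `m/lambda`, which the tests verify to
1e-8.

**LASSO with OLS re-estimation.** Features are PGSI windows (one model
per window width) or a uniform 0.05% subsample of the additive SNP
codes. Columns are standardized internally; the L1 path (100 penalties)
is fit with coordinate descent and the penalty chosen by seeded inner
10-fold cross-validation minimizing squared error. The variables
selected at the optimum are then re-estimated by ordinary least squares
(normal equations with a 1e-8 ridge for numerical stability; if the
selection approaches the training size, the largest-|coefficient| half
is kept and the cap is logged). Predictions use only the re-estimated
coefficients. An empty selection degenerates to an intercept-only model
(flagged, not an error).

The 0.05% marker subsample applies to both the SNP-feature LASSO and
to the GBLUP kinships by default (a `use_all_markers_for_gblup` flag
restores full-marker kinships), and is drawn once per model run from
the outer seed rather than per fold, mirroring a single up-front
marker thinning.

## h-QTLs

Every window retained by a window-level LASSO heterosis model is an
h-QTL; the top 10% and bottom 10% of re-estimated coefficients (counts
`ceil(0.1 k)` each) are high-impact. Because features are similarity
values, the conventional effect label is inverted relative to the
coefficient sign: a *positive* effect (more divergence, more heterosis)
corresponds to a negative PGSI coefficient. Both the raw coefficient
and the label are always exported. Boundary ties are broken by larger
|coefficient|, then earlier genomic position. Names follow
`Chr.<chrom>-<NN>`, numbering windows from the chromosome top,
zero-padded to at least two digits (padding grows past 99 records).
Records on unplaced contigs are kept in tables but flagged unmappable.
Per-chromosome influence is the sum of |r| over the window-PGSI x
heterosis correlations, with A/C subgenome aggregates keyed by the
chromosome-name prefix. Gene lookup intersects gene spans from a GFF3
with the half-open window intervals.

Only selected (nonzero-coefficient) variables are reported as h-QTLs:
the alternative reading — every candidate window — would make the
h-QTL count equal the window count and is inconsistent with reported
counts far below the window totals.

## Cross-validation

Predictability is the Pearson correlation between observed and
predicted heterosis under replicated 10-fold cross-validation: per
replicate a fresh random partition is drawn, each fold is predicted
from a model trained on the rest (so every hybrid is predicted exactly
once per replicate), and one correlation is computed over the pooled
out-of-fold predictions. The reported predictability is the mean over
replicates (100 by default). The LASSO penalty-selection CV is nested
inside each training fold; all fold and inner seeds derive
deterministically from (seed, replicate, fold). Heterosis is computed
once from BLUEs before CV — folds split hybrids, never phenotype
records. External validation trains on the full training population
and correlates predictions with observations on hybrids whose IDs are
disjoint from training (parents may overlap, as a CMS pool reused
across populations does), optionally grouped by male parent.

Note a property of pooled-correlation CV visible in the tests: under
the null (labels permuted), predictions that are nearly constant
within folds anti-correlate with the held-out fold means, biasing the
pooled r slightly negative (order -1/sqrt(fold size) in the extreme of
fold-constant predictions). The permutation check therefore bounds the
null mean in a band around zero rather than expecting exactly zero.

## The synthetic generator

The generator emulates the targeted study design so every stage is
testable without the (unreleased) real sequencing data: 50 homozygous
female lines x 8 homozygous males (defaults), full-factorial F1s,
optional held-out males for an external test population, 3 environments
x 3 replicates, 6 traits with field-realistic scales (plant height
180 +/- 12 cm, grain yield 3000 +/- 350, etc.).

Genomes default to 4 chromosomes (A01, A02, C01, C02) x 5 Mb at 1 SNP
per kb — small enough that the full pipeline runs in minutes while
retaining two subgenome prefixes; a 19-chromosome "napus-shape"
preset exists for naming/subgenome logic. Reference-allele frequencies
are Beta(0.5, 0.5) truncated to [0.05, 0.95]; each parent is a
homozygous mosaic of a 16-founder haplotype pool in 100 kb segments.
The segment length sets the block-LD scale and defaults to 100 kb
because the semi-winter rapeseed populations this design mirrors decay
in LD within 100 kb.

Traits follow `hybrid = mu + GCA_f + GCA_m + sum_w beta_w PGSI_w`, with
planted window effects of both signs (10 negative = dissimilarity-
favoring, 10 positive by default), scaled so the PGSI term explains a
configured fraction (default 50%) of the hybrid genetic variance;
parent values are `mu + 2 GCA_p - delta` with inbreeding depression
delta = 0.5 genetic SD, which yields visibly positive mean MPH.
Replicate noise is calibrated so entry-mean (BLUE-level) heritability
hits its target (default 0.7). Everything derives from one seed.

What the generator does *not* emulate: coalescent-accurate LD and
recombination maps, selection history, epistasis (the trait model is
linear in PGSI plus GCA), genotype x environment interaction, and
phenotyping pathologies (outliers, spatial field trends). Passing
tests therefore demonstrate that the machinery recovers window-level
similarity effects under its own generative assumptions — not that
real rapeseed heterosis is this predictable.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the default
shape (20k SNPs, 400 training hybrids, 200 windows at 100 kb), with
10 seeds for the recovery and model-ordering checks and 3 CV
replicates in the acceptance script; these sizes keep a complete run
in minutes while leaving the statistical conclusions stable across
seeds. Other numerics: kinships are symmetrized and checked PSD to
1e-6 relative tolerance; missing marker codes are mean-imputed per
marker only when building kinships; missing PGSI cells are imputed
with training column means at the model layer; REML uses bounded
searches as above; multiallelic sites are reduced to reference + the
most frequent alternate (other alternates become missing), since both
the coding and the marking rules are binary and frequency-major
decomposition loses the least data.

## Known limitations

* The BLUE model treats genotype effects as fixed with a single random
  environment term; no genotype x environment interaction or spatial
  adjustment.
* The PGSI empty-window default (similarity 1.0) is an assumption —
  absence of called SNPs is weak evidence of identity when coverage is
  uneven; use the `missing` policy when that matters.
* GBLUP's default marker subsample (0.05%) follows the modeled
  protocol; for small synthetic genomes it leaves very few markers and
  correspondingly weak kinships. Use `use_all_markers_for_gblup` for a
  fair GBLUP baseline on small data.
* h-QTL windows are fixed-width and ignore local LD and gene density
  by design.
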