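# Methods

## Model and assumptions

A gene's intragenic SNP haplotypes are treated as the levels of one
multi-allelic polymorphism ("gene alleles", labelled `GeneName*k` in order
of decreasing frequency). The joint unit of inference is the *gene-SNP
haplotype*: a gene allele concatenated with a haplotype over selected
flanking tag SNPs. Three assumptions carry all of the probability
calculus:

1. **Hardy-Weinberg equilibrium.** A diploid subject's two gene-SNP
   haplotypes are independent draws from the population frequency table,
   so the likelihood of any unphased observation is a sum of frequency
   products over the set Ω of ordered haplotype pairs consistent with it.
2. **Biallelic autosomal SNPs.** Genotypes are coded 0/1/2 copies of the
   alternate allele, with −1 for missing. Multi-allelic sites, sex
   chromosomes and structural variants are out of scope.
3. **A single panmictic frequency table.** Training cohorts of mixed
   ancestry are pooled into one table; no per-population stratification of
   frequencies is attempted.

Missing genotypes are marginalized, not dropped: a missing locus
contributes all four ordered allele pairs to Ω (so an observation with
*s* heterozygous and *u* missing loci has 2^s · 4^u ordered decompositions).
Cohort-level missingness is instead handled by the upstream filters (below).

## Phasing (EM)

Haplotype frequencies are estimated by EM on the HWE multinomial
likelihood. The E-step distributes each subject's posterior mass over its
compatible ordered pairs; the M-step renormalizes expected counts.
Identical genotype rows are deduplicated and weighted. Two regimes:

* **Full enumeration** for genes with at most `enumeration_limit` SNPs
  (default 8): EM over all 2^L haplotypes from a uniform start. In this
  regime the estimate is a bona fide stationary point of the full
  likelihood, and the test suite checks it against an independent
  loop-based EM.
* **Progressive locus insertion** beyond that: EM converges on the first
  two loci; each retained haplotype is then extended by both alleles of
  the next locus, EM re-runs (again from a uniform start over the extended
  pool, keeping the procedure deterministic), and haplotypes below the
  pruning threshold (default 1e-5) are discarded. This trades the global
  guarantee for tractability on genes with dozens of SNPs; recovery is
  validated on synthetic cohorts instead.

Convergence: stop when the largest frequency change falls below 1e-9 or
the log-likelihood gain below 1e-12, capped at 5000 iterations. These are
deliberately tight — a looser stop (e.g. 1e-7/1e-9) can leave the
log-likelihood ~1e-6 short of the optimum on small cohorts, which is the
same order as the agreement the oracle tests demand. Frequencies at or
below 1e-10 are treated as zero when enumerating pairs.

Diplotype calls require the maximum-posterior unordered pair to *exceed*
0.95 (strict); otherwise the subject's phase is missing. Ties anywhere
(argmax calls, allele labelling) break lexicographically on the
allele-code string, for reproducibility. Following the two-phase protocol,
frequencies may be estimated on the full cohort and calls then made on
training and validation subsets separately with the same fitted table.

## Cohort filters and polymorphism metric

Applied in this order: (1) per gene, flag subjects with ≥1 missing SNP in
the gene; exclude genes with more than 50% flagged or with ≤1 SNP;
(2) exclude subjects flagged in more than 60% of the kept genes;
(3) after phasing, keep genes with under 10% missing diplotypes in both
the training and validation sets. All three comparisons are strict, read
literally from their definitions. Whether step 2 precedes or follows gene
exclusion is underdetermined; gene filters run first, then sample
exclusion (counting only kept genes). Polymorphism is summarized as
Shannon entropy E = −Σ f log f (natural log throughout the package),
0 for a monomorphic gene, at most ln(n) for n alleles.

## Model building and tag-SNP selection

With gene diplotypes observed and SNP phase latent, the joint table
Pr(hG) is fitted by the same EM engine. Candidate sets are scored by

    Q = −Σ_i log f(h_i | g_i) + (m − k)

with f(h|g) computed by the Bayesian rule (SNP phase summed out in both
numerator and denominator), m the joint haplotypes retained above the
pruning threshold and k the gene alleles in the dictionary — so m − k is
the AIC count of parameters beyond the gene's own allele frequencies.

Selection is greedy forward-backward over a candidate window of SNPs
within a flanking distance of the gene (default 250 kb, the operating
point where the rescaled objective bottoms out for most genes in flank
scans; a `flank_scan` utility recomputes the (O − min)/(max − min)
rescaling across 0–500 kb in 50 kb steps). Intragenic candidates are
tried first (distance 0) but not forced in. Each forward step refits the
joint EM with one candidate added — warm-started by splitting each
retained haplotype's mass across the new SNP's alleles in proportion to
its cohort allele frequency — and accepts the best candidate only if it
improves Q by more than ε = 1e-6 (preventing float-noise cycling); each
backward step symmetrically tries dropping one selected SNP (warm-started
by marginalizing the table). Previously removed SNPs may re-enter, as in
standard stepwise procedures. The Q trace over accepted steps is strictly
decreasing by construction and asserted on every build. The SNP cap
defaults to 40. A candidate whose refit leaves any training subject with
zero posterior support is treated as Q = +∞ rather than an error during
search.

Train/validation splitting is stratified by population label: within each
population, ⌈n/2⌉ subjects go to training (the extra one on odd counts),
uniformly at random given the seed.

## Prediction and evaluation

For a new subject only the tag-SNP genotypes are observed. The posterior
over unordered gene-allele pairs sums joint-frequency products over all
ordered pairs compatible with the genotype; missing SNPs marginalize, and
an all-missing genotype reproduces the HWE prior on allele pairs. A call
is emitted iff the maximum posterior exceeds CT (strict) — at the default
CT = 0 any positive posterior yields a call; a genotype with zero support
is a no-call flagged as outside the model.

Accuracy is (1/2N) Σ n_i with n_i ∈ {0,1,2} the best per-allele match
count over the two phase orderings — invariant to allele order on either
side. No-call subjects are excluded from both the numerator and N (call
rate is reported separately per CT, which is also how paired
accuracy/call-rate reporting is usually read). Raising CT can only shrink
the called set, so call rate is non-increasing and the mean posterior of
called subjects non-decreasing in CT.

## Association and translation

Prediction uncertainty is carried into testing through expected dosages:
dosage(a) = Σ_pairs P(pair) · #a(pair), summing to 2 per subject. Hard
calls are the point-mass special case (both modes are exposed; dosage is
the default). Case status is regressed jointly on the dosages of all
common non-reference alleles (logistic regression, Wald inference),
"common" meaning frequency strictly above 0.01 in both cases and controls;
the reference — by default the most frequent allele — is omitted so each
coefficient is a log-odds contrast against it. Rare alleles are reported
with frequencies only. 95% CIs are exp(coef ± 1.96·SE). The Wald form is
used because the target output (Coef, SE, Z) is Wald-shaped; an
estimating-equation variant would differ only in higher-order terms.
Separation or non-convergence is flagged on the affected rows with
diagnostics rather than raised.

Coding alleles translate by substituting their alternate bases into the
spliced reference CDS (1-based inclusive exons; minus-strand CDS are
reverse-complemented), then applying the standard codon table with stops
kept as `*`. Variants outside the CDS are ignored with a warning; a
spliced length not divisible by 3 is an error. Alleles with identical
proteins collapse into amino-acid alleles labelled `GeneName*aa*k` by
control-frequency rank, with frequencies and dosages summed over members —
the device that turns several synonymous DNA-level contrasts into one
better-powered protein-level contrast.

## Synthetic data generator

The generator emulates the regime the method targets, not sequence-level
realism: a pool of `n_alleles` distinct intragenic haplotypes with
Dirichlet-distributed frequencies (concentration 0.5 by default, giving
the skewed spectra with rare alleles that stress rare-allele failure
modes; defaults of ~9 gene SNPs and ~9 alleles sit in the middle of the
2–42 SNP / 6–41 allele range typical of deeply sequenced exon panels),
flank haplotypes in tunable LD with the gene alleles via `tag_fidelity`
(the probability that a designated flank haplotype carries its allele;
the remaining mass spreads uniformly over all designated flank
haplotypes), HWE cohort sampling, and case-control sampling under a
per-allele logistic model (default 2000/3000, GWAS scale) whose intercept
is solved by root-finding so the population case fraction matches the
design, followed by rejection sampling to exact group sizes.

Where possible the designated flank haplotypes are chosen so all unordered
pairwise allele-code sums are distinct, making unphased flank genotypes
fully informative about allele pairs — the deterministic-encoding regime
in which exact recovery (accuracy 1.0, call rate 1.0 at CT = 0) is a
meaningful target. The exact-recovery fixtures additionally use equal
allele frequencies so that every allele is observed in a 200-subject
training set; with the skewed default spectrum, rare alleles can be absent
from training and recovery is then bounded by sampling, not by the method.

What the generator does *not* emulate: recombination and realistic LD
decay, coalescent genealogies, population structure, genotyping error.
Passing tests therefore demonstrate correctness of the estimation and
selection machinery under its own model assumptions, not field accuracy on
real panels.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately modest sizes
chosen to exercise every code path: oracle EM comparisons at ≤5 loci and
≤30 subjects (20 instances), posterior normalization at 1000 random
instances, end-to-end recovery at 8 alleles / 6 tag SNPs with 200/200
train/validation subjects, and association calibration at 100 replicates
of 2000/3000 case-control studies. Natural logarithms are used everywhere
(likelihoods, Q, entropy). Model JSON serializes frequencies as decimal
strings at full double precision; TSV outputs have fixed column order so
reruns are byte-identical.

## Known limitations

* Very polymorphic or long genes (dozens of SNPs, >40 alleles, entropy
  ≳ 2) phase poorly and overfit in selection; splitting the gene into
  LD-coherent segments is the practical remedy.
* Alleles distinguished only by SNPs absent from (and not in LD with) the
  genotyping panel are inherently unpredictable; they can only be merged
  or genotyped directly.
* Rare alleles unobserved in training cannot be predicted; accuracy on
  carriers is bounded by training-panel size.
* The association model takes dosages as fixed covariates; prediction
  uncertainty propagates through the dosage expectation but not into the
  standard errors.
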