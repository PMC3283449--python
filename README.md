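# diploseq — in silico gene sequencing from SNP genotypes

Direct sequencing of a candidate gene in every subject of a large cohort is
expensive; genome-wide SNP genotypes are cheap and ubiquitous. `diploseq`
bridges the two: given a training cohort that *has* been deeply sequenced in
a gene region, it learns how the gene's phased intragenic sequences — its
**gene alleles**, treated as one large multi-allelic polymorphism — travel
with the haplotypes of nearby tag SNPs, and then predicts a pair of phased
gene alleles (a **diplotype**) for any new subject from SNP genotypes alone.
Predicted coding alleles translate directly to amino-acid sequences, so a
SNP association can be re-expressed as a protein-level association.

It is intended for statistical geneticists moving from GWAS hits to
functional interpretation: phase a sequenced reference panel, build a
per-gene prediction model, apply it to a genotyped case-control cohort, and
run a multi-allelic association test on the predicted alleles.

## The model

For subject *i*, let *h<sub>i</sub>* = (ḣ<sub>i</sub>, ḧ<sub>i</sub>) be the
two gene alleles and *g<sub>i</sub>* the unphased genotypes of *q* flanking
SNPs. The concatenation of a gene allele with a flanking-SNP haplotype — a
*gene-SNP haplotype* *hG* — follows a multinomial distribution with
frequencies Pr(*hG*), estimated by maximizing

&nbsp;&nbsp;ℓ = Σ<sub>i</sub> log Σ<sub>Ω(h_i, g_i)</sub> f(ḣĠ) f(ḧG̈),

where Ω enumerates all ordered haplotype pairs consistent with the observed
genotypes, and the product form inside the sum is Hardy-Weinberg
equilibrium. Estimation is by EM (with progressive locus insertion for
genes with many SNPs). New subjects are predicted by the Bayesian rule
f(h | g) = f(h, g) / Σ<sub>H</sub> f(H, g), with a call emitted only when
the posterior exceeds a call threshold CT (default 0).

Tag SNPs are chosen by a forward-backward greedy search over candidates
within a flanking window (default ±250 kb), scored by the AIC-penalized
objective

&nbsp;&nbsp;Q = −Σ<sub>i</sub> log f(h<sub>i</sub> | g<sub>i</sub>) + (m − k),

where *m* is the number of retained gene-SNP haplotypes and *k* the number
of gene alleles. Gene polymorphism is summarized by the Shannon entropy
E = −Σ f<sub>i</sub> log f<sub>i</sub> of the allele frequencies. Downstream,
predicted diplotypes become per-allele expected dosages (summing to 2 per
subject) and enter a joint logistic regression against a reference allele,
yielding per-allele log-odds, OR, 95% CI, Wald Z and p-value; synonymous
alleles can be collapsed to amino-acid alleles to concentrate power.

## Worked example (command line)

A synthetic 6-allele gene whose flank haplotypes deterministically tag the
alleles, 300 subjects:

```sh
diploseq simulate --out-dir demo --seed 7 --gene-snps 4 --flank-snps 6 \
    --alleles 6 --alpha 8 --subjects 300 --gene-name DEMO
diploseq phase    --vcf demo/gene.vcf --gene-name DEMO --out demo/calls.tsv
diploseq build    --calls demo/truth.tsv --alleles demo/alleles.tsv \
    --vcf demo/flank.vcf --gene-bed demo/gene.bed --out demo/model.json
diploseq predict  --model demo/model.json --vcf demo/flank.vcf --ct 0 \
    --out demo/pred.tsv
diploseq evaluate --predictions demo/pred.tsv --truth demo/truth.tsv \
    --gene-name DEMO --out demo/eval.tsv
```

which logs:

```
INFO phased 300 subjects over 4 SNPs: 6 alleles, entropy 1.741, call rate 0.870
INFO gene DEMO: selected 4 SNP(s), Q=0.0000, 300 training subjects
INFO predicted 300 subjects, call rate 1.000 at CT=0
INFO gene DEMO: accuracy 1.0000, call rate 1.0000
```

Reading the numbers: the EM phaser found 6 gene alleles with entropy 1.741
(close to the 6-allele maximum ln 6 ≈ 1.79, i.e. a highly polymorphic
gene) and confidently phased 87% of subjects at the stringent 0.95
threshold. The tag-SNP search kept 4 SNPs and drove the objective Q to 0 —
every training subject's diplotype has posterior 1 under the model with no
excess parameters (m = k). Applied to the cohort's flanking genotypes, the
model calls every subject at CT = 0 and every predicted diplotype matches
the truth (accuracy 1.0), as expected when tagging is deterministic.
`demo/pred.tsv` holds the per-subject calls:

```
sample    allele1  allele2  posterior  called
sim00001  DEMO*2   DEMO*6   1          True
sim00002  DEMO*2   DEMO*5   1          True
```

`diploseq associate` then takes such predictions plus a phenotype table and
emits the per-allele association table (frequencies, Coef, SE, OR, 95% CI,
Z, p against the reference allele), and `diploseq translate` maps a model's
gene alleles to amino-acid sequences via a CDS model and reference FASTA.

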