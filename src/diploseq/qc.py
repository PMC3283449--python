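"""Cohort/gene data-cleaning filters and the entropy polymorphism metric.

Filtering rules (applied before any phasing or model building):

* per gene, subjects with at least one missing SNP genotype inside the gene
  are flagged; a gene is excluded when more than 50% of subjects are
  flagged, or when it has at most one SNP;
* subjects flagged in more than 60% of the kept genes are excluded from the
  cohort;
* after phasing, a gene is kept only when fewer than 10% of subjects have a
  missing diplotype call in both the training and the validation set.

All three fractions are compared strictly.  Gene polymorphism is summarized
by the Shannon entropy of the allele frequencies, E = -sum f_i ln f_i,
which is 0 for a monomorphic gene and at most ln(n) for n alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .core import MISSING, GenotypeMatrix


@dataclass
class GeneQcReport:
    """Outcome of the per-gene missingness filter."""

    gene: str
    n_samples_kept: int
    n_samples_filtered: int
    n_snps: int
    status: str  # kept | filtered | too_few_snps | unphased
    sample_filtered: np.ndarray = field(repr=False, default=None)


def filter_gene(
    G: Union[GenotypeMatrix, np.ndarray], gene: str = "GENE"
) -> GeneQcReport:
    """Flag subjects with any missing SNP in the gene; classify the gene.

    ``status`` is ``too_few_snps`` when the gene has <= 1 SNP, ``filtered``
    when the flagged fraction exceeds 50% (strict), else ``kept``.
    """
    codes = G.codes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    n, n_snps = codes.shape
    flagged = np.any(codes == MISSING, axis=1)
    n_filtered = int(flagged.sum())
    if n_snps <= 1:
        status = "too_few_snps"
    elif n > 0 and n_filtered / n > 0.5:
        status = "filtered"
    else:
        status = "kept"
    return GeneQcReport(
        gene=gene,
        n_samples_kept=n - n_filtered,
        n_samples_filtered=n_filtered,
        n_snps=n_snps,
        status=status,
        sample_filtered=flagged,
    )


def filter_samples_across_genes(reports: Sequence[GeneQcReport]) -> np.ndarray:
    """Boolean mask of samples excluded for being flagged in more than 60%
    (strict) of the kept genes.  Genes whose status is not ``kept`` do not
    count toward the denominator."""
    kept = [r for r in reports if r.status == "kept"]
    if not kept:
        raise ValueError("no kept genes")
    flags = np.stack([r.sample_filtered for r in kept], axis=1)
    frac = flags.mean(axis=1)
    return frac > 0.6


def phasing_qc(
    train_calls: Sequence[Optional[object]],
    val_calls: Sequence[Optional[object]],
) -> bool:
    """Pass iff the missing-diplotype fraction is below 10% (strict) in the
    training set *and* in the validation set."""
    if len(train_calls) == 0 or len(val_calls) == 0:
        raise ValueError("both call sets must be non-empty")
    miss_train = sum(c is None for c in train_calls) / len(train_calls)
    miss_val = sum(c is None for c in val_calls) / len(val_calls)
    return miss_train < 0.10 and miss_val < 0.10


def entropy(freqs: Sequence[float]) -> float:
    """Shannon entropy E = -sum f_i ln(f_i) of an allele-frequency vector.

    Zero frequencies contribute nothing; the input must be a probability
    vector (non-negative, summing to 1 within 1e-9).  E = 0 iff the gene is
    monomorphic; the maximum, attained at uniform frequencies, is ln(n).
    """
    f = np.asarray(list(freqs), dtype=float)
    if np.any(f < 0):
        raise ValueError("negative allele frequency")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {f.sum()!r}, expected 1")
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())
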