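"""Probabilistic core: domain types, compatible-pair enumeration and
Hardy-Weinberg diplotype posteriors.

The central abstraction is a :class:`FrequencyTable` holding population
frequencies of haplotypes (vectors of 0/1 allele codes over an ordered list
of biallelic SNP loci).  Under Hardy-Weinberg equilibrium (HWE) the two
haplotypes of a diploid subject are independent draws from this table, so
the likelihood of an unphased genotype is a sum of products of haplotype
frequencies over every ordered pair of haplotypes consistent with the
observed genotype codes.  Everything else in the package (EM phasing, tag
SNP selection, diplotype prediction) is built on these sums.

Genotype codes follow the usual convention: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, :data:`MISSING` (-1) = no call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

#: Genotype code for a missing (uncalled) genotype.
MISSING: int = -1

#: Frequencies at or below this value are treated as zero when enumerating
#: compatible haplotype pairs; bounds the work spent on numerical dust.
ZERO_FREQ_EPS: float = 1e-10

Haplotype = Tuple[int, ...]


class LocusMismatchError(ValueError):
    """Raised when a frequency table and a genotype span different loci."""


class InconsistentGenotypeError(ValueError):
    """Raised when a genotype has zero likelihood under a frequency table."""


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP locus.

    Parameters
    ----------
    id : str
        Marker identifier (typically an rsID).
    chrom : str
        Chromosome label.
    pos : int
        1-based position.
    ref, alt : str
        Reference and alternate alleles; must differ (biallelic only).
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref and alt alleles must differ")


@dataclass(frozen=True)
class GenotypeVector:
    """Unphased genotype codes of one subject over an ordered locus list."""

    loci: Tuple[SnpLocus, ...]
    codes: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.codes):
            raise ValueError(
                f"{len(self.codes)} codes for {len(self.loci)} loci"
            )
        for c in self.codes:
            if c not in (0, 1, 2, MISSING):
                raise ValueError(f"invalid genotype code {c}")


@dataclass(frozen=True)
class GeneAllele:
    """A distinct phased intragenic sequence, one level of a multi-allelic
    gene polymorphism.  ``label`` follows the ``GeneName*k`` convention where
    ``k`` is the frequency rank (1 = most frequent)."""

    label: str
    sequence: Haplotype = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class Diplotype:
    """The unordered pair of gene alleles carried by one subject.

    Equality and hashing ignore allele order and the posterior probability:
    ``Diplotype(a, b) == Diplotype(b, a)``.
    """

    allele1: GeneAllele
    allele2: GeneAllele
    posterior: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a, b = self.allele1, self.allele2
        if (b.label, b.sequence) < (a.label, a.sequence):
            object.__setattr__(self, "allele1", b)
            object.__setattr__(self, "allele2", a)
        if self.posterior is not None and not 0.0 <= self.posterior <= 1.0 + 1e-12:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")

    @property
    def labels(self) -> Tuple[str, str]:
        return (self.allele1.label, self.allele2.label)

    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2


@dataclass(frozen=True)
class GeneSnpHaplotype:
    """A gene allele concatenated with a haplotype over the selected
    flanking tag SNPs — the unit whose population frequency the joint
    prediction model estimates."""

    gene_allele: GeneAllele
    snp_haplotype: Haplotype


class FrequencyTable:
    """Map from haplotype (or gene-SNP haplotype) to population frequency.

    Entries must be non-negative and sum to one (within 1e-9).  Keys are
    either plain allele-code tuples (phasing tables) or
    :class:`GeneSnpHaplotype` instances (joint prediction models).
    """

    def __init__(
        self,
        entries: Mapping,
        loci: Optional[Sequence[SnpLocus]] = None,
    ) -> None:
        total = 0.0
        for key, f in entries.items():
            if f < -1e-12:
                raise ValueError(f"negative frequency {f} for {key!r}")
            total += f
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total!r}, expected 1")
        self.entries: Dict = dict(entries)
        self.loci: Optional[Tuple[SnpLocus, ...]] = (
            tuple(loci) if loci is not None else None
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def freq(self, key, default: float = 0.0) -> float:
        return self.entries.get(key, default)

    def n_loci(self) -> int:
        if self.loci is not None:
            return len(self.loci)
        key = next(iter(self.entries))
        hap = key.snp_haplotype if isinstance(key, GeneSnpHaplotype) else key
        return len(hap)

    def haplotype_arrays(self) -> Tuple[List, np.ndarray, np.ndarray]:
        """Return (keys, hap_matrix, freqs) with only frequencies above
        :data:`ZERO_FREQ_EPS`; ``hap_matrix`` stacks the SNP allele codes."""
        keys, rows, freqs = [], [], []
        for key, f in self.entries.items():
            if f <= ZERO_FREQ_EPS:
                continue
            hap = key.snp_haplotype if isinstance(key, GeneSnpHaplotype) else key
            keys.append(key)
            rows.append(hap)
            freqs.append(f)
        mat = (
            np.array(rows, dtype=np.int8)
            if rows
            else np.zeros((0, self.n_loci()), dtype=np.int8)
        )
        if mat.ndim == 1:  # zero-locus haplotypes
            mat = mat.reshape(len(keys), 0)
        return keys, mat, np.asarray(freqs, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FrequencyTable({len(self.entries)} haplotypes)"


# ---------------------------------------------------------------------------
# Compatible-pair enumeration and HWE likelihoods
# ---------------------------------------------------------------------------

_DECOMPOSITIONS = {
    0: ((0, 0),),
    1: ((0, 1), (1, 0)),
    2: ((1, 1),),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def enumerate_compatible_pairs(
    g: GenotypeVector,
) -> List[Tuple[Haplotype, Haplotype]]:
    """All ordered haplotype pairs consistent with an unphased genotype.

    At a non-missing locus the two haplotype alleles must sum to the
    genotype code; a missing locus is expanded over every allele pair (the
    subject is marginalized over, not dropped).  For ``s`` heterozygous and
    ``u`` missing loci there are ``2**s * 4**u`` ordered pairs.
    """
    if len(g.codes) == 0:
        raise ValueError("degenerate genotype vector: no loci")
    per_locus = [_DECOMPOSITIONS[c] for c in g.codes]
    pairs: List[Tuple[Haplotype, Haplotype]] = []
    for combo in itertools.product(*per_locus):
        h1 = tuple(a for a, _ in combo)
        h2 = tuple(b for _, b in combo)
        pairs.append((h1, h2))
    return pairs


def compatible_pair_mask(hap_matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Boolean (m, m) mask of ordered haplotype-row pairs whose allele sums
    match ``codes`` at every non-missing locus."""
    if hap_matrix.shape[1] == 0:
        m = hap_matrix.shape[0]
        return np.ones((m, m), dtype=bool)
    sums = hap_matrix[:, None, :] + hap_matrix[None, :, :]
    ok = (sums == codes[None, None, :]) | (codes[None, None, :] == MISSING)
    return ok.all(axis=2)


def _check_span(freqs: FrequencyTable, g: GenotypeVector) -> None:
    if freqs.n_loci() != len(g.codes):
        raise LocusMismatchError(
            f"table spans {freqs.n_loci()} loci, genotype has {len(g.codes)}"
        )
    if freqs.loci is not None and tuple(freqs.loci) != tuple(g.loci):
        raise LocusMismatchError("table and genotype loci differ")


def pair_likelihood(freqs: FrequencyTable, g: GenotypeVector) -> float:
    """HWE likelihood of an unphased genotype: the sum of
    ``freq(H1) * freq(H2)`` over all ordered compatible haplotype pairs."""
    _check_span(freqs, g)
    _, mat, f = freqs.haplotype_arrays()
    if len(f) == 0:
        return 0.0
    mask = compatible_pair_mask(mat, np.asarray(g.codes))
    return float(f @ (mask @ f))


def posterior_pairs(
    freqs: FrequencyTable, g: GenotypeVector
) -> Dict[Tuple[Haplotype, Haplotype], float]:
    """Posterior distribution over unordered haplotype pairs given an
    unphased genotype, by the Bayesian rule under HWE.

    Each unordered pair's mass is proportional to ``freq(H1) * freq(H2)``,
    doubled when the two haplotypes differ.  Raises
    :class:`InconsistentGenotypeError` when no compatible pair has positive
    frequency.
    """
    _check_span(freqs, g)
    keys, mat, f = freqs.haplotype_arrays()
    if len(f) == 0:
        raise InconsistentGenotypeError("genotype inconsistent with model")
    mask = compatible_pair_mask(mat, np.asarray(g.codes))
    weights = np.where(mask, f[:, None] * f[None, :], 0.0)
    total = float(weights.sum())
    if total <= 0.0:
        raise InconsistentGenotypeError("genotype inconsistent with model")
    out: Dict[Tuple[Haplotype, Haplotype], float] = {}
    ii, jj = np.nonzero(weights)
    for i, j, w in zip(ii, jj, weights[ii, jj]):
        a, b = keys[i], keys[j]
        key = (a, b) if a <= b else (b, a)
        out[key] = out.get(key, 0.0) + float(w)
    for key in out:
        out[key] /= total
    return out


@dataclass
class GenotypeMatrix:
    """Subjects x biallelic SNP loci, unphased genotype codes.

    ``codes`` is an (n_samples, n_loci) integer array over
    {0, 1, 2, MISSING}.
    """

    samples: List[str]
    loci: List[SnpLocus]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def genotype_vector(self, i: int) -> GenotypeVector:
        return GenotypeVector(tuple(self.loci), tuple(int(c) for c in self.codes[i]))

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[j] for j in idx],
            codes=self.codes[:, idx],
        )

    def subset_samples(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            codes=self.codes[idx, :],
        )
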