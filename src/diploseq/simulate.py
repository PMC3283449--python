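"""Synthetic gene-SNP haplotype pools, HWE cohorts and case-control
datasets with known truth.

The generator emulates the data regime the method targets: a gene whose
intragenic SNP haplotypes form a multi-allelic polymorphism with skewed
(Dirichlet) allele frequencies, flanking tag SNPs in tunable linkage
disequilibrium with the gene alleles, random-mating (HWE) diploid
subjects, and case-control sampling under per-allele logistic effects.

``tag_fidelity`` controls the LD between flank haplotypes and gene
alleles: each gene allele has a designated flank haplotype that carries it
with probability ``tag_fidelity``; the remaining mass is spread uniformly
over all designated flank haplotypes.  At fidelity 1 the map from flank
haplotype to gene allele is a function.  Where possible the designated
flank haplotypes are additionally chosen so that all unordered pairwise
allele-code sums are distinct, making unphased flank genotypes fully
informative about the pair of gene alleles — the deterministic-tagging
regime used for exact-recovery checks.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core import (
    Diplotype,
    FrequencyTable,
    GeneAllele,
    GeneSnpHaplotype,
    GenotypeMatrix,
    SnpLocus,
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults mirror the scale of deeply sequenced exon data: around nine
    intragenic SNPs and nine gene alleles per gene (gene SNP counts in real
    panels run from 2 to ~42 and allele counts from 6 to ~41), a skewed
    allele-frequency spectrum (Dirichlet concentration 0.5, producing rare
    alleles that stress the rare-allele failure modes), and GWAS-scale
    case/control sizes of 2000/3000.
    """

    n_gene_snps: int = 9
    n_flank_snps: int = 8
    n_alleles: int = 9
    dirichlet_alpha: float = 0.5
    allele_freqs: Optional[Sequence[float]] = None
    tag_fidelity: float = 1.0
    n_subjects: int = 500
    n_cases: int = 2000
    n_controls: int = 3000
    effect_map: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    gene_name: str = "GENE1"
    chrom: str = "1"
    gene_start: int = 1_000_001
    gene_end: int = 1_020_000
    flank_span: int = 250_000

    def __post_init__(self) -> None:
        for name in ("n_gene_snps", "n_flank_snps", "n_alleles", "n_subjects"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.tag_fidelity <= 1.0:
            raise ValueError("tag_fidelity must be in [0, 1]")


@dataclass
class SimulatedPool:
    """A gene-SNP haplotype pool plus the locus metadata needed to emit
    cohorts and VCFs.  ``table`` is the joint frequency table over
    :class:`~diploseq.core.GeneSnpHaplotype` keys."""

    table: FrequencyTable
    alleles: List[GeneAllele]
    gene_loci: List[SnpLocus]
    flank_loci: List[SnpLocus]
    gene_name: str
    interval: Tuple[str, int, int]


def _distinct_bit_rows(rng, n_rows: int, n_bits: int) -> np.ndarray:
    if n_rows > 2**n_bits:
        raise ValueError(
            f"cannot draw {n_rows} distinct haplotypes over {n_bits} SNPs"
        )
    if n_bits <= 20:
        ints = rng.choice(2**n_bits, size=n_rows, replace=False)
    else:
        seen: set = set()
        ints_list: List[int] = []
        while len(ints_list) < n_rows:
            v = int(rng.integers(0, 2**n_bits))
            if v not in seen:
                seen.add(v)
                ints_list.append(v)
        ints = np.array(ints_list)
    return np.array(
        [[(v >> b) & 1 for b in range(n_bits - 1, -1, -1)] for v in ints],
        dtype=np.int8,
    )


def _sum_distinct(rows: np.ndarray) -> bool:
    sums = set()
    n = len(rows)
    for i in range(n):
        for j in range(i, n):
            s = tuple((rows[i] + rows[j]).tolist())
            if s in sums:
                return False
            sums.add(s)
    return True


def _spaced_loci(
    prefix: str, chrom: str, lo: int, hi: int, n: int
) -> List[SnpLocus]:
    span = hi - lo
    positions = [lo + max(1, span // (n + 1)) * (i + 1) for i in range(n)]
    positions = [min(p, hi) for p in positions]
    # keep positions strictly increasing
    for i in range(1, n):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1
    return [
        SnpLocus(f"{prefix}{i + 1}", chrom, positions[i], "A", "G")
        for i in range(n)
    ]


def simulate_pool(cfg: SimulationConfig) -> SimulatedPool:
    """Draw a gene-SNP haplotype pool: ``n_alleles`` distinct intragenic
    haplotypes with Dirichlet(alpha) frequencies, each linked to a
    designated flank haplotype with probability ``tag_fidelity``.
    Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    gene_rows = _distinct_bit_rows(rng, cfg.n_alleles, cfg.n_gene_snps)

    if cfg.allele_freqs is not None:
        freqs = np.asarray(list(cfg.allele_freqs), dtype=float)
        if len(freqs) != cfg.n_alleles:
            raise ValueError("allele_freqs length must equal n_alleles")
        freqs = freqs / freqs.sum()
    else:
        freqs = rng.dirichlet(np.full(cfg.n_alleles, cfg.dirichlet_alpha))
    order = np.argsort(-freqs, kind="stable")
    freqs = freqs[order]
    gene_rows = gene_rows[order]
    alleles = [
        GeneAllele(f"{cfg.gene_name}*{i + 1}", tuple(int(x) for x in row))
        for i, row in enumerate(gene_rows)
    ]

    # designated flank haplotypes; prefer a set whose unordered pairwise
    # sums are all distinct so unphased genotypes identify allele pairs
    flank_rows = _distinct_bit_rows(rng, cfg.n_alleles, cfg.n_flank_snps)
    for _ in range(200):
        if _sum_distinct(flank_rows):
            break
        flank_rows = _distinct_bit_rows(rng, cfg.n_alleles, cfg.n_flank_snps)

    n = cfg.n_alleles
    tf = cfg.tag_fidelity
    entries: Dict[GeneSnpHaplotype, float] = {}
    for i, allele in enumerate(alleles):
        for j in range(n):
            mass = freqs[i] * ((tf if i == j else 0.0) + (1 - tf) / n)
            if mass <= 0.0:
                continue
            key = GeneSnpHaplotype(allele, tuple(int(x) for x in flank_rows[j]))
            entries[key] = entries.get(key, 0.0) + float(mass)

    gene_loci = _spaced_loci(
        f"{cfg.gene_name}_g", cfg.chrom, cfg.gene_start, cfg.gene_end,
        cfg.n_gene_snps,
    )
    half = cfg.n_flank_snps // 2
    upstream = _spaced_loci(
        f"{cfg.gene_name}_u", cfg.chrom,
        max(1, cfg.gene_start - cfg.flank_span), cfg.gene_start - 1, half,
    )
    downstream = _spaced_loci(
        f"{cfg.gene_name}_d", cfg.chrom,
        cfg.gene_end + 1, cfg.gene_end + cfg.flank_span,
        cfg.n_flank_snps - half,
    )
    flank_loci = upstream + downstream
    table = FrequencyTable(entries, loci=flank_loci)
    return SimulatedPool(
        table=table,
        alleles=alleles,
        gene_loci=gene_loci,
        flank_loci=flank_loci,
        gene_name=cfg.gene_name,
        interval=(cfg.chrom, cfg.gene_start, cfg.gene_end),
    )


@dataclass
class Cohort:
    """HWE cohort with retained truth."""

    samples: List[str]
    diplotypes: List[Diplotype]
    gene_genotypes: GenotypeMatrix
    flank_genotypes: GenotypeMatrix


def _pool_arrays(pool: SimulatedPool):
    keys = list(pool.table.entries)
    f = np.array([pool.table.entries[k] for k in keys])
    f = f / f.sum()
    allele_index = {a.label: i for i, a in enumerate(pool.alleles)}
    gidx = np.array([allele_index[k.gene_allele.label] for k in keys])
    gene_mat = np.array([k.gene_allele.sequence for k in keys], dtype=np.int8)
    flank_mat = np.array([k.snp_haplotype for k in keys], dtype=np.int8)
    return keys, f, gidx, gene_mat, flank_mat


def _draws_to_cohort(
    pool: SimulatedPool, draws: np.ndarray, prefix: str = "sim"
) -> Cohort:
    _, _, gidx, gene_mat, flank_mat = _pool_arrays(pool)
    n = len(draws)
    samples = [f"{prefix}{i + 1:05d}" for i in range(n)]
    diplotypes = [
        Diplotype(pool.alleles[gidx[a]], pool.alleles[gidx[b]])
        for a, b in draws
    ]
    gene_codes = gene_mat[draws[:, 0]] + gene_mat[draws[:, 1]]
    flank_codes = flank_mat[draws[:, 0]] + flank_mat[draws[:, 1]]
    return Cohort(
        samples=samples,
        diplotypes=diplotypes,
        gene_genotypes=GenotypeMatrix(samples, list(pool.gene_loci), gene_codes),
        flank_genotypes=GenotypeMatrix(samples, list(pool.flank_loci), flank_codes),
    )


def simulate_cohort(
    pool: SimulatedPool, n_subjects: int, seed: int
) -> Cohort:
    """Draw ``n_subjects`` diploid subjects as two independent haplotype
    draws from the pool (HWE); genotypes are the unphased allele sums and
    the true diplotypes are retained."""
    rng = np.random.default_rng(seed)
    _, f, *_ = _pool_arrays(pool)
    draws = rng.choice(len(f), p=f, size=(n_subjects, 2))
    return Cohort(
        **{
            k: v
            for k, v in _draws_to_cohort(pool, draws).__dict__.items()
        }
    )


@dataclass
class CaseControlCohort(Cohort):
    phenotypes: np.ndarray = None  # 1 = case, 0 = control


def simulate_case_control(
    pool: SimulatedPool,
    effect_map: Dict[str, float],
    n_cases: int,
    n_controls: int,
    seed: int,
) -> CaseControlCohort:
    """Sample a case-control study under a per-allele logistic model.

    A subject carrying allele dosages d has case probability
    ``sigmoid(beta0 + sum_a d_a * effect_map[a])``, with the intercept
    solved so the population case fraction matches
    ``n_cases / (n_cases + n_controls)``; subjects are then
    rejection-sampled to the exact group sizes.
    """
    labels = {a.label for a in pool.alleles}
    unknown = set(effect_map) - labels
    if unknown:
        raise ValueError(f"effect_map references unknown alleles: {unknown}")
    target = n_cases / (n_cases + n_controls)
    if not 0.0 < target < 1.0:
        raise ValueError("unreachable case fraction")

    _, f, gidx, _, _ = _pool_arrays(pool)
    beta = np.array(
        [effect_map.get(a.label, 0.0) for a in pool.alleles], dtype=float
    )
    # expected case fraction under HWE pair probabilities
    allele_p = np.bincount(gidx, weights=f, minlength=len(pool.alleles))
    pair_eta = beta[:, None] + beta[None, :]
    pair_p = allele_p[:, None] * allele_p[None, :]

    def _case_fraction(b0: float) -> float:
        return float(np.sum(pair_p * expit(b0 + pair_eta)))

    beta0 = brentq(lambda b: _case_fraction(b) - target, -50.0, 50.0)

    rng = np.random.default_rng(seed)
    case_rows: List[np.ndarray] = []
    ctrl_rows: List[np.ndarray] = []
    need_cases, need_ctrls = n_cases, n_controls
    while need_cases > 0 or need_ctrls > 0:
        batch = max(1024, 2 * (need_cases + need_ctrls))
        draws = rng.choice(len(f), p=f, size=(batch, 2))
        eta = beta0 + beta[gidx[draws[:, 0]]] + beta[gidx[draws[:, 1]]]
        is_case = rng.random(batch) < expit(eta)
        for row, c in zip(draws, is_case):
            if c and need_cases > 0:
                case_rows.append(row)
                need_cases -= 1
            elif not c and need_ctrls > 0:
                ctrl_rows.append(row)
                need_ctrls -= 1
            if need_cases == 0 and need_ctrls == 0:
                break
    draws = np.array(case_rows + ctrl_rows)
    phenotypes = np.concatenate(
        [np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    )
    base = _draws_to_cohort(pool, draws)
    return CaseControlCohort(phenotypes=phenotypes, **base.__dict__)
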