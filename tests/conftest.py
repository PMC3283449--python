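"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive: plain-Python loops over fully
enumerated haplotype spaces.  They exist to check the vectorized
implementations against an independent computation path, so they must not
reuse package internals beyond the basic domain types.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from diploseq.core import MISSING, SnpLocus


def make_loci(n: int, chrom: str = "1", start: int = 1) -> tuple:
    return tuple(
        SnpLocus(f"rs{i + 1}", chrom, start + i, "A", "G") for i in range(n)
    )


def naive_decompositions(code: int):
    """Ordered allele pairs consistent with one genotype code."""
    if code == 0:
        return [(0, 0)]
    if code == 1:
        return [(0, 1), (1, 0)]
    if code == 2:
        return [(1, 1)]
    if code == MISSING:
        return [(0, 0), (0, 1), (1, 0), (1, 1)]
    raise ValueError(code)


def naive_ordered_pairs(codes):
    """Brute-force enumeration of all ordered compatible haplotype pairs."""
    out = []
    for combo in itertools.product(*(naive_decompositions(c) for c in codes)):
        out.append(
            (tuple(a for a, _ in combo), tuple(b for _, b in combo))
        )
    return out


def naive_likelihood(freq_map, codes):
    """Brute-force HWE genotype likelihood over the full 2^L x 2^L space."""
    L = len(codes)
    total = 0.0
    for h1 in itertools.product((0, 1), repeat=L):
        for h2 in itertools.product((0, 1), repeat=L):
            if all(
                c == MISSING or a + b == c for a, b, c in zip(h1, h2, codes)
            ):
                total += freq_map.get(h1, 0.0) * freq_map.get(h2, 0.0)
    return total


def naive_em(genotypes, max_iter=5000, tol=1e-12):
    """Full-enumeration EM for haplotype frequencies, loops only.

    Starts uniform over all 2^L haplotypes; returns (freq_map, loglik).
    """
    genotypes = [tuple(int(c) for c in row) for row in np.asarray(genotypes)]
    L = len(genotypes[0])
    haps = list(itertools.product((0, 1), repeat=L))
    f = {h: 1.0 / len(haps) for h in haps}
    subj_pairs = [naive_ordered_pairs(codes) for codes in genotypes]
    loglik = -math.inf
    for _ in range(max_iter):
        counts = {h: 0.0 for h in haps}
        ll = 0.0
        for pairs in subj_pairs:
            lik = sum(f[h1] * f[h2] for h1, h2 in pairs)
            if lik <= 0:
                continue
            ll += math.log(lik)
            for h1, h2 in pairs:
                w = f[h1] * f[h2] / lik
                counts[h1] += w
                counts[h2] += w
        total = sum(counts.values())
        f = {h: c / total for h, c in counts.items()}
        if abs(ll - loglik) < tol:
            loglik = ll
            break
        loglik = ll
    # log-likelihood at the returned frequencies
    ll = 0.0
    for pairs in subj_pairs:
        lik = sum(f[h1] * f[h2] for h1, h2 in pairs)
        if lik > 0:
            ll += math.log(lik)
    return f, ll


def random_em_instance(rng, max_loci=5, max_subjects=30, missing_rate=0.05):
    """A random unphased cohort drawn from a random haplotype pool."""
    L = int(rng.integers(2, max_loci + 1))
    n = int(rng.integers(4, max_subjects + 1))
    n_haps = int(rng.integers(2, min(6, 2**L) + 1))
    hap_ints = rng.choice(2**L, size=n_haps, replace=False)
    haps = [
        tuple((v >> b) & 1 for b in range(L - 1, -1, -1)) for v in hap_ints
    ]
    freqs = rng.dirichlet(np.ones(n_haps))
    draws = rng.choice(n_haps, p=freqs, size=(n, 2))
    codes = np.array(
        [
            [haps[a][j] + haps[b][j] for j in range(L)]
            for a, b in draws
        ],
        dtype=np.int64,
    )
    mask = rng.random(codes.shape) < missing_rate
    codes[mask] = MISSING
    # keep at least one informative subject
    if np.all(codes == MISSING):
        codes[0] = [haps[0][j] * 2 for j in range(L)]
    return codes


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
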