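"""Apply a fitted prediction model to SNP genotypes of new subjects.

For a new subject only the flanking-SNP genotypes g are observed; the gene
diplotype h is latent.  The posterior over unordered gene-allele pairs
follows the Bayesian rule

    f(h | g) = f(h, g) / sum_H f(H, g),

where both numerator and denominator sum the products of joint gene-SNP
haplotype frequencies over every ordered pair consistent with g (missing
genotypes are marginalized).  A prediction is emitted only when the maximum
posterior exceeds the call threshold CT (strict); at CT = 0, the default,
any positive posterior yields a call.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import MISSING, Diplotype, GeneAllele, GenotypeMatrix, compatible_pair_mask
from .model import PredictionModel

logger = logging.getLogger(__name__)


def _posterior_gene_pairs(
    labels: List[str],
    gene_idx: np.ndarray,
    snp_mat: np.ndarray,
    freqs: np.ndarray,
    codes: np.ndarray,
) -> Optional[Dict[Tuple[int, int], float]]:
    """Posterior over unordered gene-allele index pairs, or None when the
    genotype is outside the model's support."""
    mask = compatible_pair_mask(snp_mat, codes)
    weights = np.where(mask, freqs[:, None] * freqs[None, :], 0.0)
    total = float(weights.sum())
    if total <= 0.0:
        return None
    out: Dict[Tuple[int, int], float] = {}
    ii, jj = np.nonzero(weights)
    for i, j, w in zip(ii, jj, weights[ii, jj]):
        a, b = int(gene_idx[i]), int(gene_idx[j])
        key = (a, b) if a <= b else (b, a)
        out[key] = out.get(key, 0.0) + float(w)
    for key in out:
        out[key] /= total
    return out


def predict_diplotype(
    model: PredictionModel,
    g: Union[Sequence[int], np.ndarray],
    ct: float = 0.0,
) -> Optional[Diplotype]:
    """Predict one subject's gene diplotype from genotype codes over the
    model's selected SNPs (MISSING codes are marginalized; an all-missing
    genotype yields the HWE prior).  Returns ``None`` (no call) when the
    maximum posterior does not exceed ``ct`` or the genotype lies outside
    the model's support.  Ties at the maximum are broken lexicographically
    by allele-label pair."""
    return predict_cohort(model, np.asarray(g, dtype=np.int64)[None, :], ct)[0]


def posterior_distribution(
    model: PredictionModel, g: Union[Sequence[int], np.ndarray]
) -> Optional[Dict[Tuple[str, str], float]]:
    """Full posterior over unordered gene-allele label pairs for one
    subject (None when outside support)."""
    labels, gene_idx, snp_mat, freqs = model.arrays()
    codes = np.asarray(g, dtype=np.int64)
    post = _posterior_gene_pairs(labels, gene_idx, snp_mat, freqs, codes)
    if post is None:
        return None
    return {(labels[a], labels[b]): p for (a, b), p in post.items()}


def predict_cohort(
    model: PredictionModel,
    G: Union[GenotypeMatrix, np.ndarray],
    ct: float = 0.0,
) -> List[Optional[Diplotype]]:
    """Vectorized :func:`predict_diplotype` over a genotype matrix whose
    columns follow ``model.selected_snps``."""
    codes = G.codes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    codes = np.asarray(codes, dtype=np.int64)
    labels, gene_idx, snp_mat, freqs = model.arrays()
    allele_objs = {
        lab: GeneAllele(lab, tuple(model.allele_dictionary[lab]))
        for lab in labels
    }
    calls: List[Optional[Diplotype]] = []
    cache: Dict[Tuple[int, ...], Optional[Diplotype]] = {}
    for row in codes:
        key = tuple(int(c) for c in row)
        if key in cache:
            calls.append(cache[key])
            continue
        post = _posterior_gene_pairs(labels, gene_idx, snp_mat, freqs, np.asarray(key))
        if post is None:
            logger.warning("genotype outside model support; no call")
            call: Optional[Diplotype] = None
        else:
            (a, b), p = min(
                post.items(),
                key=lambda kv: (-kv[1], (labels[kv[0][0]], labels[kv[0][1]])),
            )
            if p > ct:
                call = Diplotype(
                    allele_objs[labels[a]], allele_objs[labels[b]],
                    posterior=float(min(p, 1.0)),
                )
            else:
                call = None
        cache[key] = call
        calls.append(call)
    return calls


def accuracy(
    predicted: Sequence[Optional[Diplotype]],
    observed: Sequence[Optional[Diplotype]],
) -> float:
    """Diplotype prediction accuracy: (1/2N) sum_i n_i, where n_i in
    {0, 1, 2} is the best allele-matching count over the two phase
    orderings.  Subjects where either side is a no-call are excluded from
    both N and the sum; returns NaN when nothing is called."""
    if len(predicted) != len(observed):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs "
            f"{len(observed)} observed"
        )
    total = 0
    n = 0
    for p, o in zip(predicted, observed):
        if p is None or o is None:
            continue
        n += 1
        p1, p2 = p.labels
        o1, o2 = o.labels
        total += max(
            (p1 == o1) + (p2 == o2),
            (p1 == o2) + (p2 == o1),
        )
    if n == 0:
        return float("nan")
    return total / (2 * n)


def call_rate(calls: Sequence[Optional[Diplotype]]) -> float:
    """Fraction of subjects with a non-missing call."""
    if len(calls) == 0:
        raise ValueError("empty call list")
    return sum(c is not None for c in calls) / len(calls)
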