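"""Vectorized EM engine for haplotype-frequency estimation.

The engine is agnostic to what a "haplotype" is: callers provide, for every
(weighted, usually deduplicated) observation, the index pairs of haplotypes
whose ordered combination is consistent with that observation.  The E-step
then distributes each observation's posterior mass over its compatible
ordered pairs, and the M-step renormalizes the expected haplotype counts.
The observed-data log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class EmResult:
    freqs: np.ndarray
    loglik: float
    n_iter: int
    loglik_trace: List[float]


def build_pair_index(
    pair_lists: Sequence[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate per-observation (n_pairs, 2) ordered-pair index arrays
    into flat (i1, i2, obs_id) arrays for vectorized E-steps."""
    i1, i2, seg = [], [], []
    for obs_id, pairs in enumerate(pair_lists):
        if len(pairs) == 0:
            continue
        arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        i1.append(arr[:, 0])
        i2.append(arr[:, 1])
        seg.append(np.full(len(arr), obs_id, dtype=np.int64))
    if not i1:
        return (
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    return np.concatenate(i1), np.concatenate(i2), np.concatenate(seg)


def run_em(
    n_haplotypes: int,
    pair_lists: Sequence[np.ndarray],
    weights: Sequence[float],
    init: np.ndarray | None = None,
    tol_freq: float = 1e-9,
    tol_loglik: float = 1e-12,
    max_iter: int = 5000,
) -> EmResult:
    """Maximize the HWE multinomial likelihood by EM.

    Parameters
    ----------
    n_haplotypes : int
        Size of the haplotype pool being estimated.
    pair_lists : sequence of (n_pairs, 2) int arrays
        For each observation, the ordered compatible haplotype index pairs.
        Observations with an empty list contribute nothing (the caller is
        expected to have excluded or warned about them).
    weights : sequence of float
        Multiplicity of each observation (deduplicated genotype counts).
    init : array, optional
        Starting frequencies; uniform over the pool when omitted.
    tol_freq, tol_loglik, max_iter
        Convergence controls: stop when the largest absolute frequency
        change drops below ``tol_freq``, when the log-likelihood gain drops
        below ``tol_loglik``, or after ``max_iter`` iterations.
    """
    m = int(n_haplotypes)
    if m == 0:
        raise ValueError("empty haplotype pool")
    w = np.asarray(weights, dtype=float)
    i1, i2, seg = build_pair_index(pair_lists)
    active = np.zeros(len(w), dtype=bool)
    if len(seg):
        active[np.unique(seg)] = True
    total_w = float(w[active].sum())
    if total_w <= 0:
        raise ValueError("no observation is compatible with the haplotype pool")

    f = (
        np.full(m, 1.0 / m)
        if init is None
        else np.asarray(init, dtype=float) / float(np.sum(init))
    )
    n_obs = len(w)
    trace: List[float] = []
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        pw = f[i1] * f[i2]
        lik = np.bincount(seg, weights=pw, minlength=n_obs)
        # observations whose mass vanished under the current frequencies
        # drop out of this iteration's expectations
        ok = lik > 0.0
        loglik_new = float(np.sum(w[ok & active] * np.log(lik[ok & active])))
        denom = lik[seg]
        safe = denom > 0.0
        post = np.zeros_like(pw)
        post[safe] = pw[safe] / denom[safe] * w[seg[safe]]
        counts = np.bincount(i1, weights=post, minlength=m) + np.bincount(
            i2, weights=post, minlength=m
        )
        f_new = counts / counts.sum()
        trace.append(loglik_new)
        delta_f = float(np.max(np.abs(f_new - f)))
        delta_ll = loglik_new - loglik
        f, loglik = f_new, loglik_new
        if delta_f < tol_freq or (it > 1 and abs(delta_ll) < tol_loglik):
            break

    # final log-likelihood evaluated at the returned frequencies
    pw = f[i1] * f[i2]
    lik = np.bincount(seg, weights=pw, minlength=n_obs)
    ok = (lik > 0.0) & active
    loglik = float(np.sum(w[ok] * np.log(lik[ok])))
    return EmResult(freqs=f, loglik=loglik, n_iter=it, loglik_trace=trace)


def dedupe_rows(rows: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse duplicate observation rows; returns (unique_rows, weights,
    inverse) where ``inverse`` maps each original row to its unique index."""
    uniq, inverse, counts = np.unique(
        rows, axis=0, return_inverse=True, return_counts=True
    )
    return uniq, counts.astype(float), inverse
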