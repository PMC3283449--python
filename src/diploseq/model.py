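"""Prediction-model building: joint gene-SNP haplotype frequencies,
AIC-penalized objective, forward-backward tag-SNP selection and the
flanking-region scan.

A gene's prediction model is a frequency table over *gene-SNP haplotypes* —
a gene allele concatenated with a haplotype over selected flanking SNPs.
Given training subjects with called gene diplotypes h_i and unphased SNP
genotypes g_i, the table Pr(hG) is estimated by EM under HWE (the SNP phase
is latent; the gene diplotype is observed).  Candidate SNP sets are scored
by the AIC-penalized negative log posterior

    Q = -sum_i log f(h_i | g_i) + (m - k),

where f(h_i | g_i) follows the Bayesian rule with the SNP phase summed out,
m is the number of gene-SNP haplotypes retained with non-negligible
frequency and k the number of gene alleles (so m - k counts the parameters
added beyond the gene's own allele frequencies).  SNPs are selected
greedily: each forward step adds the candidate whose refit minimizes Q,
each backward step drops the selected SNP whose removal minimizes Q, and a
step is accepted only when it improves Q by more than a small tolerance, so
the Q trace over accepted steps is strictly decreasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._em import dedupe_rows, run_em
from .core import (
    MISSING,
    Diplotype,
    FrequencyTable,
    GeneAllele,
    GeneSnpHaplotype,
    GenotypeMatrix,
    SnpLocus,
    compatible_pair_mask,
)

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Controls for joint EM fitting and stepwise selection."""

    epsilon: float = 1e-6  # minimum Q improvement to accept a step
    max_snps: int = 40
    prune_threshold: float = 1e-5
    tol_freq: float = 1e-9
    tol_loglik: float = 1e-12
    max_iter: int = 5000
    flank_size: int = 250_000


@dataclass
class PredictionModel:
    """A gene's in-silico sequencing model.

    Holds the gene's interval, the selected tag SNP loci, the joint
    gene-SNP haplotype frequency table, and the dictionary mapping allele
    labels to their intragenic sequences.
    """

    gene_name: str
    selected_snps: Tuple[SnpLocus, ...]
    joint_freqs: FrequencyTable
    allele_dictionary: Dict[str, Tuple[int, ...]]
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    flank_size: Optional[int] = None
    training_meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.joint_freqs:
            if key.gene_allele.label not in self.allele_dictionary:
                raise ValueError(
                    f"joint haplotype references unknown allele "
                    f"{key.gene_allele.label}"
                )

    def allele_labels(self) -> List[str]:
        return list(self.allele_dictionary)

    def arrays(self) -> Tuple[List[str], np.ndarray, np.ndarray, np.ndarray]:
        """(labels, gene_idx, snp_matrix, freqs) views of the joint table."""
        labels = self.allele_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        gene_idx, rows, freqs = [], [], []
        for key, f in self.joint_freqs.items():
            gene_idx.append(index[key.gene_allele.label])
            rows.append(key.snp_haplotype)
            freqs.append(f)
        mat = np.array(rows, dtype=np.int8)
        if mat.ndim == 1:
            mat = mat.reshape(len(rows), 0)
        return labels, np.asarray(gene_idx), mat, np.asarray(freqs, dtype=float)


@dataclass
class FlankScanResult:
    """Objective values of one selection run per flanking-region size,
    rescaled to [0, 1] as (O - min) / (max - min)."""

    sizes: List[int]
    objectives: List[float]
    rescaled: List[float]


# ---------------------------------------------------------------------------
# Joint EM over gene-SNP haplotypes (gene diplotype observed, SNP phase latent)
# ---------------------------------------------------------------------------


@dataclass
class _JointFit:
    gene_idx: np.ndarray  # (m,)
    snp_mat: np.ndarray  # (m, q)
    freqs: np.ndarray  # (m,)
    loglik: float


def _gene_pair_mask(gene_idx: np.ndarray, a1: int, a2: int) -> np.ndarray:
    g1 = gene_idx[:, None]
    g2 = gene_idx[None, :]
    return ((g1 == a1) & (g2 == a2)) | ((g1 == a2) & (g2 == a1))


def _fit_joint(
    y_idx: np.ndarray,
    Gs: np.ndarray,
    n_alleles: int,
    cfg: BuildConfig,
    init: Optional[_JointFit] = None,
) -> _JointFit:
    """EM for Pr(hG) with observed gene diplotypes and unphased SNP codes."""
    n, q = Gs.shape
    y_sorted = np.sort(y_idx, axis=1)
    obs = np.column_stack([y_sorted, Gs]).astype(np.int64)
    rows, weights, _ = dedupe_rows(obs)

    if init is None:
        # independence start: allele prior x per-SNP allele frequencies
        counts = np.bincount(y_idx.ravel(), minlength=n_alleles).astype(float)
        prior = counts / counts.sum()
        import itertools

        if q == 0:
            snp_haps = np.zeros((1, 0), dtype=np.int8)
        else:
            snp_haps = np.array(
                list(itertools.product((0, 1), repeat=q)), dtype=np.int8
            )
        p_alt = np.array(
            [
                _alt_frequency(Gs[:, j])
                for j in range(q)
            ]
        )
        hap_p = np.ones(len(snp_haps))
        for j in range(q):
            hap_p *= np.where(snp_haps[:, j] == 1, p_alt[j], 1 - p_alt[j])
        gene_idx = np.repeat(np.arange(n_alleles), len(snp_haps))
        snp_mat = np.tile(snp_haps, (n_alleles, 1))
        f0 = np.repeat(prior, len(snp_haps)) * np.tile(hap_p, n_alleles)
        f0 = np.maximum(f0, 1e-12)
    else:
        gene_idx, snp_mat, f0 = init.gene_idx, init.snp_mat, init.freqs

    pair_lists = []
    for row in rows:
        a1, a2 = int(row[0]), int(row[1])
        mask = _gene_pair_mask(gene_idx, a1, a2)
        if q:
            mask = mask & compatible_pair_mask(snp_mat, row[2:])
        pair_lists.append(np.argwhere(mask))
    res = run_em(
        len(gene_idx),
        pair_lists,
        weights,
        init=f0,
        tol_freq=cfg.tol_freq,
        tol_loglik=cfg.tol_loglik,
        max_iter=cfg.max_iter,
    )
    keep = res.freqs >= cfg.prune_threshold
    if not np.any(keep):
        keep = res.freqs == res.freqs.max()
    freqs = res.freqs[keep]
    return _JointFit(
        gene_idx=gene_idx[keep],
        snp_mat=snp_mat[keep],
        freqs=freqs / freqs.sum(),
        loglik=res.loglik,
    )


def _alt_frequency(col: np.ndarray) -> float:
    ok = col != MISSING
    if not np.any(ok):
        return 0.5
    p = float(col[ok].mean()) / 2.0
    return min(max(p, 1e-6), 1 - 1e-6)


def _extend_fit(fit: _JointFit, new_col: np.ndarray) -> _JointFit:
    """Warm start after adding a SNP: split each retained joint haplotype's
    mass across the new SNP's two alleles in proportion to its cohort
    allele frequency."""
    p = _alt_frequency(new_col)
    m = len(fit.freqs)
    gene_idx = np.repeat(fit.gene_idx, 2)
    bit = np.tile([0, 1], m).astype(np.int8)
    snp_mat = np.column_stack([np.repeat(fit.snp_mat, 2, axis=0), bit])
    freqs = np.repeat(fit.freqs, 2) * np.tile([1 - p, p], m)
    return _JointFit(gene_idx, snp_mat, np.maximum(freqs, 1e-12), np.nan)


def _drop_fit(fit: _JointFit, pos: int) -> _JointFit:
    """Warm start after removing the SNP at column ``pos``: marginalize the
    table over that SNP."""
    snp_mat = np.delete(fit.snp_mat, pos, axis=1)
    agg: Dict[Tuple, float] = {}
    for a, row, f in zip(fit.gene_idx, snp_mat, fit.freqs):
        key = (int(a), tuple(int(x) for x in row))
        agg[key] = agg.get(key, 0.0) + float(f)
    gene_idx = np.array([k[0] for k in agg])
    mat = np.array([k[1] for k in agg], dtype=np.int8).reshape(len(agg), -1)
    freqs = np.array(list(agg.values()))
    return _JointFit(gene_idx, mat, freqs, np.nan)


def _q_value(
    fit: _JointFit,
    y_idx: np.ndarray,
    Gs: np.ndarray,
    n_alleles: int,
    strict: bool = False,
) -> float:
    """Q = -sum_i log f(h_i|g_i) + (m - k) for a fitted joint table."""
    q = Gs.shape[1]
    y_sorted = np.sort(y_idx, axis=1)
    obs = np.column_stack([y_sorted, Gs]).astype(np.int64)
    rows, weights, _ = dedupe_rows(obs)
    f = fit.freqs
    nll = 0.0
    for row, w in zip(rows, weights):
        a1, a2 = int(row[0]), int(row[1])
        snp_ok = (
            compatible_pair_mask(fit.snp_mat, row[2:])
            if q
            else np.ones((len(f), len(f)), dtype=bool)
        )
        den = float(f @ (snp_ok @ f))
        num_mask = snp_ok & _gene_pair_mask(fit.gene_idx, a1, a2)
        num = float(f @ (num_mask @ f))
        if num <= 0.0 or den <= 0.0:
            if strict:
                raise ValueError("model inconsistent with training subject")
            return math.inf
        nll -= w * (math.log(num) - math.log(den))
    m = int(np.sum(f > 0))
    return nll + (m - n_alleles)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _diplotypes_to_idx(
    diplotypes: Sequence[Diplotype], labels: Sequence[str]
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    out = np.empty((len(diplotypes), 2), dtype=np.int64)
    for i, d in enumerate(diplotypes):
        out[i, 0] = index[d.allele1.label]
        out[i, 1] = index[d.allele2.label]
    return out


def _fit_from_model(model: PredictionModel) -> Tuple[List[str], _JointFit]:
    labels, gene_idx, snp_mat, freqs = model.arrays()
    return labels, _JointFit(gene_idx, snp_mat, freqs, np.nan)


def objective_q(
    model: PredictionModel,
    diplotypes: Sequence[Diplotype],
    G: Union[GenotypeMatrix, np.ndarray],
) -> float:
    """Evaluate the AIC-penalized objective of a model on training subjects
    with called gene diplotypes and SNP genotypes over the model's selected
    SNPs.  Raises when any subject has zero posterior support."""
    labels, fit = _fit_from_model(model)
    codes = G.codes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    y_idx = _diplotypes_to_idx(diplotypes, labels)
    return _q_value(fit, y_idx, np.asarray(codes), len(labels), strict=True)


def candidate_window(
    gene_interval: Tuple[str, int, int],
    flank_size: int,
    catalog: Sequence[SnpLocus],
) -> List[SnpLocus]:
    """Candidate SNPs within ``flank_size`` bp of the gene, ordered by
    distance from the gene boundary (intragenic SNPs first, at distance 0),
    ties broken by position."""
    chrom, start, end = gene_interval
    out = []
    for locus in catalog:
        if locus.chrom != chrom:
            continue
        if start - flank_size <= locus.pos <= end + flank_size:
            if start <= locus.pos <= end:
                dist = 0
            else:
                dist = min(abs(locus.pos - start), abs(locus.pos - end))
            out.append((dist, locus.pos, locus))
    out.sort(key=lambda t: (t[0], t[1]))
    return [locus for _, _, locus in out]


def _build_model(
    gene_calls: Sequence[Diplotype],
    snp_data: GenotypeMatrix,
    candidates: Sequence[SnpLocus],
    cfg: BuildConfig,
    gene_name: str,
    interval: Optional[Tuple[str, int, int]] = None,
) -> PredictionModel:
    # allele dictionary ordered by label rank (GeneName*1, *2, ...)
    seen: Dict[str, Tuple[int, ...]] = {}
    for d in gene_calls:
        for a in (d.allele1, d.allele2):
            seen.setdefault(a.label, a.sequence)

    def _rank(label: str):
        tail = label.rsplit("*", 1)[-1]
        return (0, int(tail)) if tail.isdigit() else (1, tail)

    labels = sorted(seen, key=_rank)
    alleles = {lab: seen[lab] for lab in labels}
    y_idx = _diplotypes_to_idx(gene_calls, labels)
    k = len(labels)

    col_of = {locus: j for j, locus in enumerate(snp_data.loci)}
    try:
        cand_cols = [col_of[locus] for locus in candidates]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"candidate locus missing from genotype data: {exc}")

    codes = snp_data.codes
    empty = np.empty((len(gene_calls), 0), dtype=np.int64)
    fit = _fit_joint(y_idx, empty, k, cfg)
    q_cur = _q_value(fit, y_idx, empty, k)
    selected: List[int] = []  # candidate indices, in order of addition
    q_trace = [q_cur]

    def _gs(sel: List[int]) -> np.ndarray:
        return codes[:, [cand_cols[s] for s in sel]].astype(np.int64)

    while True:
        improved = False
        # forward: try adding each remaining candidate
        if len(selected) < cfg.max_snps:
            best = None
            for c in range(len(candidates)):
                if c in selected:
                    continue
                trial_sel = selected + [c]
                warm = _extend_fit(fit, codes[:, cand_cols[c]])
                trial_fit = _fit_joint(y_idx, _gs(trial_sel), k, cfg, init=warm)
                q_trial = _q_value(trial_fit, y_idx, _gs(trial_sel), k)
                if best is None or q_trial < best[0]:
                    best = (q_trial, c, trial_fit)
            if best is not None and best[0] < q_cur - cfg.epsilon:
                q_cur, c, fit = best
                selected.append(c)
                q_trace.append(q_cur)
                improved = True
        # backward: try dropping each selected SNP
        if len(selected) >= 1:
            best = None
            for pos in range(len(selected)):
                trial_sel = selected[:pos] + selected[pos + 1 :]
                warm = _drop_fit(fit, pos)
                trial_fit = _fit_joint(y_idx, _gs(trial_sel), k, cfg, init=warm)
                q_trial = _q_value(trial_fit, y_idx, _gs(trial_sel), k)
                if best is None or q_trial < best[0]:
                    best = (q_trial, pos, trial_fit)
            if best is not None and best[0] < q_cur - cfg.epsilon:
                q_cur, pos, fit = best
                del selected[pos]
                q_trace.append(q_cur)
                improved = True
        if not improved:
            break

    allele_objs = [GeneAllele(lab, alleles[lab]) for lab in labels]
    entries = {
        GeneSnpHaplotype(allele_objs[int(a)], tuple(int(x) for x in row)): float(f)
        for a, row, f in zip(fit.gene_idx, fit.snp_mat, fit.freqs)
    }
    chrom, start, end = interval if interval else (None, None, None)
    model = PredictionModel(
        gene_name=gene_name,
        selected_snps=tuple(candidates[s] for s in selected),
        joint_freqs=FrequencyTable(entries),
        allele_dictionary=alleles,
        chrom=chrom,
        start=start,
        end=end,
        flank_size=cfg.flank_size,
        training_meta={
            "n_training": len(gene_calls),
            "q": q_cur,
            "q_trace": q_trace,
            "n_alleles": k,
        },
    )
    return model


def forward_backward_select(
    gene_calls: Sequence[Diplotype],
    snp_data: GenotypeMatrix,
    candidates: Sequence[SnpLocus],
    cfg: Optional[BuildConfig] = None,
    gene_name: str = "GENE",
    interval: Optional[Tuple[str, int, int]] = None,
) -> PredictionModel:
    """Greedy forward-backward tag-SNP selection minimizing Q.

    With no candidates the returned model has zero SNPs (a prior-only
    predictor).  The Q trace over accepted steps (stored in
    ``training_meta['q_trace']``) is strictly decreasing by construction.
    """
    return _build_model(
        gene_calls, snp_data, list(candidates), cfg or BuildConfig(),
        gene_name, interval,
    )


def rescale_objectives(objectives: Sequence[float]) -> List[float]:
    """(O - min) / (max - min); a constant series maps to all zeros."""
    o = np.asarray(list(objectives), dtype=float)
    span = o.max() - o.min()
    if span == 0:
        return [0.0] * len(o)
    return list((o - o.min()) / span)


def flank_scan(
    gene_interval: Tuple[str, int, int],
    gene_calls: Sequence[Diplotype],
    snp_data: GenotypeMatrix,
    sizes: Optional[Sequence[int]] = None,
    cfg: Optional[BuildConfig] = None,
    gene_name: str = "GENE",
) -> FlankScanResult:
    """Run one tag-SNP selection per flanking-region size and record the
    objective, rescaled across sizes to [0, 1].  Default sizes span 0 to
    500 kb in 50 kb steps."""
    if sizes is None:
        sizes = list(range(0, 500_001, 50_000))
    sizes = list(sizes)
    cfg = cfg or BuildConfig()
    objectives = []
    for size in sizes:
        window = candidate_window(gene_interval, size, snp_data.loci)
        model = forward_backward_select(
            gene_calls, snp_data, window, cfg, gene_name, gene_interval
        )
        objectives.append(float(model.training_meta["q"]))
    return FlankScanResult(
        sizes=sizes,
        objectives=objectives,
        rescaled=rescale_objectives(objectives),
    )


def split_train_validation(
    populations: Sequence[str], seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Split sample indices half/half within each population label,
    uniformly at random given ``seed`` (odd counts put the extra sample in
    the training set).  Returns sorted (train_idx, validation_idx)."""
    pops = list(populations)
    rng = np.random.default_rng(seed)
    train: List[int] = []
    val: List[int] = []
    for pop in sorted(set(pops)):
        idx = np.array([i for i, p in enumerate(pops) if p == pop])
        perm = rng.permutation(len(idx))
        n_train = (len(idx) + 1) // 2
        train.extend(idx[perm[:n_train]])
        val.extend(idx[perm[n_train:]])
    return np.array(sorted(train)), np.array(sorted(val))


class GeneAllelePredictor(BaseEstimator):
    """Predict a pair of phased gene alleles from flanking-SNP genotypes
    (scikit-learn style).

    ``fit(X, y)`` takes unphased SNP genotype codes ``X`` of shape
    (n_subjects, n_candidate_snps) and called gene diplotypes ``y``
    (a sequence of :class:`~diploseq.core.Diplotype`), runs forward-backward
    tag-SNP selection minimizing the AIC-penalized objective Q, and stores
    the fitted :class:`PredictionModel`.  ``predict(X)`` returns per-subject
    diplotype calls at ``call_threshold`` (CT); ``score(X, y)`` is the
    diplotype prediction accuracy over called subjects.

    Attributes
    ----------
    model_ : PredictionModel
    selected_indices_ : list of int
        Column indices of the selected SNPs in the fit-time candidate order.
    q_ : float
        Final objective value.
    q_trace_ : list of float
        Objective after each accepted selection step (strictly decreasing).
    """

    def __init__(
        self,
        gene_name: str = "GENE",
        call_threshold: float = 0.0,
        flank_size: int = 250_000,
        epsilon: float = 1e-6,
        max_snps: int = 40,
        prune_threshold: float = 1e-5,
        max_iter: int = 5000,
    ) -> None:
        self.gene_name = gene_name
        self.call_threshold = call_threshold
        self.flank_size = flank_size
        self.epsilon = epsilon
        self.max_snps = max_snps
        self.prune_threshold = prune_threshold
        self.max_iter = max_iter

    def _config(self) -> BuildConfig:
        return BuildConfig(
            epsilon=self.epsilon,
            max_snps=self.max_snps,
            prune_threshold=self.prune_threshold,
            max_iter=self.max_iter,
            flank_size=self.flank_size,
        )

    def fit(self, X, y, loci: Optional[Sequence[SnpLocus]] = None):
        if isinstance(X, GenotypeMatrix):
            gm = X
        else:
            X = np.asarray(X)
            if loci is None:
                loci = [
                    SnpLocus(f"snp{j + 1}", "1", j + 1, "A", "G")
                    for j in range(X.shape[1])
                ]
            gm = GenotypeMatrix(
                samples=[f"s{i}" for i in range(X.shape[0])],
                loci=list(loci),
                codes=X,
            )
        self.n_features_in_ = gm.n_loci
        self.model_ = forward_backward_select(
            list(y), gm, gm.loci, self._config(), gene_name=self.gene_name
        )
        self.selected_indices_ = [
            gm.loci.index(locus) for locus in self.model_.selected_snps
        ]
        self.q_ = float(self.model_.training_meta["q"])
        self.q_trace_ = list(self.model_.training_meta["q_trace"])
        return self

    def predict(self, X) -> List[Optional[Diplotype]]:
        from .predict import predict_cohort

        if not hasattr(self, "model_"):
            raise RuntimeError("predictor is not fitted")
        codes = X.codes if isinstance(X, GenotypeMatrix) else np.asarray(X)
        if codes.shape[1] == self.n_features_in_:
            codes = codes[:, self.selected_indices_]
        elif codes.shape[1] != len(self.selected_indices_):
            raise ValueError(
                "X must cover the candidate loci seen in fit or exactly the "
                "selected SNPs"
            )
        return predict_cohort(self.model_, codes, ct=self.call_threshold)

    def score(self, X, y) -> float:
        from .predict import accuracy

        return accuracy(self.predict(X), list(y))
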