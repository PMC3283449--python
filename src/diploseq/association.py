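"""Multi-allelic case-control association on predicted gene alleles, and
translation of coding gene alleles into amino-acid alleles.

Predicted diplotypes (or full posterior distributions over allele pairs)
are converted to per-subject expected allele *dosages* — the posterior
expected copy count of each allele, summing to 2 per subject — and tested
jointly by logistic regression of case status on the dosages of all common
non-reference alleles.  Wald statistics give per-allele log-odds
coefficients, odds ratios with 95% confidence intervals and two-sided
p-values against the reference allele (by convention the most frequent).
Alleles whose frequency does not exceed a floor (default 0.01) in *both*
cases and controls are reported with frequencies only, untested.

Coding gene alleles can be translated to protein sequences through a CDS
model (exon coordinates + strand on a reference sequence); alleles whose
differences are all synonymous collapse to a single amino-acid allele,
concentrating frequency mass and typically increasing test power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Seq import Seq

from .core import Diplotype, GeneAllele, SnpLocus

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AssociationResult:
    """One allele's row of a multi-allelic association table."""

    allele: str
    freq_control: float
    freq_case: float
    tested: bool
    reference: bool = False
    coef: Optional[float] = None
    se: Optional[float] = None
    or_: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    z: Optional[float] = None
    p: Optional[float] = None
    converged: bool = True
    message: str = ""


def expected_dosages(
    posteriors: Sequence[
        Union[Diplotype, None, Mapping[Tuple[str, str], float]]
    ],
    alleles: Sequence[str],
) -> pd.DataFrame:
    """Per-subject posterior expected allele dosages.

    Each element of ``posteriors`` is either a hard :class:`Diplotype` call
    (a point mass), ``None`` (row of NaNs), or a mapping from unordered
    allele-label pairs to probabilities.  Dosages of each subject sum to 2.
    """
    data = np.zeros((len(posteriors), len(alleles)))
    col = {a: j for j, a in enumerate(alleles)}
    for i, entry in enumerate(posteriors):
        if entry is None:
            data[i, :] = np.nan
            continue
        if isinstance(entry, Diplotype):
            dist: Mapping[Tuple[str, str], float] = {entry.labels: 1.0}
        else:
            dist = entry
        for (a1, a2), p in dist.items():
            data[i, col[a1]] += p
            data[i, col[a2]] += p
    return pd.DataFrame(data, columns=list(alleles))


def allele_frequencies(
    dosages: pd.DataFrame, phenotype: Sequence[int]
) -> pd.DataFrame:
    """Per-group allele frequencies (mean dosage / 2) from a dosage table."""
    y = np.asarray(phenotype)
    out = pd.DataFrame(
        {
            "control": dosages[y == 0].mean(axis=0) / 2.0,
            "case": dosages[y == 1].mean(axis=0) / 2.0,
        }
    )
    return out


def multiallelic_test(
    dosages: pd.DataFrame,
    phenotype: Sequence[int],
    reference: Optional[str] = None,
    floor: float = 0.01,
) -> List[AssociationResult]:
    """Joint logistic regression of case status on allele dosages.

    All alleles with frequency strictly above ``floor`` in both cases and
    controls enter the model together, except the reference allele (by
    default the most frequent allele overall), which is omitted so each
    coefficient is a log-odds contrast against it.  Rare alleles are
    reported untested with their frequencies only.  Subjects with missing
    dosages (no-calls) are dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y[~np.isnan(y)])) - {0.0, 1.0}:
        raise ValueError("phenotype must be coded 0 (control) / 1 (case)")
    keep = ~(dosages.isna().any(axis=1).to_numpy() | np.isnan(y))
    d = dosages.loc[keep]
    y = y[keep]
    freqs = allele_frequencies(d, y)
    if reference is None:
        reference = (freqs["control"] + freqs["case"]).idxmax()
    if reference not in dosages.columns:
        raise ValueError(f"reference allele {reference!r} not in dosage table")

    common = [
        a
        for a in dosages.columns
        if freqs.loc[a, "control"] > floor and freqs.loc[a, "case"] > floor
    ]
    if reference not in common:
        raise ValueError(
            f"reference allele {reference!r} is below the frequency floor"
        )
    tested = [a for a in common if a != reference]

    results: Dict[str, AssociationResult] = {}
    results[reference] = AssociationResult(
        allele=reference,
        freq_control=float(freqs.loc[reference, "control"]),
        freq_case=float(freqs.loc[reference, "case"]),
        tested=True,
        reference=True,
        or_=1.0,
    )

    converged, message = True, ""
    params = bse = None
    if tested:
        X = sm.add_constant(d[tested].to_numpy())
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, bse = fit.params[1:], fit.bse[1:]
            if not converged:
                message = "logistic regression did not converge"
        except Exception as exc:  # separation, singular design, ...
            converged = False
            message = f"logistic regression failed: {exc}"
            logger.warning(message)

    for j, a in enumerate(tested):
        res = AssociationResult(
            allele=a,
            freq_control=float(freqs.loc[a, "control"]),
            freq_case=float(freqs.loc[a, "case"]),
            tested=True,
            converged=converged,
            message=message,
        )
        if params is not None:
            coef, se = float(params[j]), float(bse[j])
            res.coef = coef
            res.se = se
            res.or_ = math.exp(coef)
            res.ci = (math.exp(coef - Z_95 * se), math.exp(coef + Z_95 * se))
            res.z = coef / se if se > 0 else float("nan")
            res.p = 2 * (1 - _norm_cdf(abs(res.z)))
        results[a] = res

    for a in dosages.columns:
        if a in results:
            continue
        results[a] = AssociationResult(
            allele=a,
            freq_control=float(freqs.loc[a, "control"]),
            freq_case=float(freqs.loc[a, "case"]),
            tested=False,
        )

    # reference first, then tested by decreasing control frequency, then rare
    def _key(r: AssociationResult):
        return (not r.reference, not r.tested, -r.freq_control, r.allele)

    return sorted(results.values(), key=_key)


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def allele_ratio_or(
    freq_case_allele: float,
    freq_case_ref: float,
    freq_ctrl_allele: float,
    freq_ctrl_ref: float,
) -> float:
    """Odds ratio of an allele versus the reference computed directly from
    printed case/control allele frequencies:
    (f_case_allele / f_case_ref) / (f_ctrl_allele / f_ctrl_ref)."""
    if freq_case_ref <= 0 or freq_ctrl_ref <= 0:
        raise ValueError("reference allele frequency must be positive")
    if freq_case_allele <= 0 or freq_ctrl_allele <= 0:
        raise ValueError("allele frequencies must be positive")
    return (freq_case_allele / freq_case_ref) / (freq_ctrl_allele / freq_ctrl_ref)


# ---------------------------------------------------------------------------
# Translation of gene alleles to amino-acid alleles
# ---------------------------------------------------------------------------


@dataclass
class CdsModel:
    """Coding-sequence model: 1-based inclusive exon intervals on a
    chromosome, plus strand.  Exon lengths must sum to a multiple of 3."""

    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon end {e} before start {s}")

    def genomic_positions(self) -> List[int]:
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_allele(
    allele: GeneAllele,
    loci: Sequence[SnpLocus],
    cds: CdsModel,
    reference_sequence: str,
) -> str:
    """Translate a gene allele to its amino-acid sequence.

    The allele's alternate bases are substituted into the spliced reference
    CDS (reverse-complemented for minus-strand genes) and translated with
    the standard codon table; stop codons are retained as ``'*'``.
    Variants outside the CDS (UTR/intronic) are ignored with a warning; a
    CDS whose spliced length is not a multiple of 3 is an error.
    """
    if len(allele.sequence) != len(loci):
        raise ValueError("allele sequence length does not match locus list")
    genomic = cds.genomic_positions()
    if len(genomic) % 3 != 0:
        raise ValueError(
            f"frame violation: spliced CDS length {len(genomic)} is not a "
            "multiple of 3"
        )
    index_of = {p: i for i, p in enumerate(genomic)}
    bases = [reference_sequence[p - 1].upper() for p in genomic]
    for locus, code in zip(loci, allele.sequence):
        if code == 0:
            continue
        i = index_of.get(locus.pos)
        if i is None:
            logger.warning(
                "variant %s at %s:%d lies outside the CDS; ignored",
                locus.id, locus.chrom, locus.pos,
            )
            continue
        if bases[i] != locus.ref.upper():
            logger.warning(
                "reference base %s at %s:%d differs from locus ref %s",
                bases[i], locus.chrom, locus.pos, locus.ref,
            )
        bases[i] = locus.alt.upper()
    cds_seq = "".join(bases)
    if cds.strand == "-":
        cds_seq = "".join(_COMPLEMENT[b] for b in reversed(cds_seq))
    return str(Seq(cds_seq).translate())


@dataclass
class AminoAcidAllele:
    """A group of gene alleles sharing one protein sequence."""

    label: str
    protein: str
    members: Tuple[str, ...]
    frequencies: Dict[str, float] = field(default_factory=dict)


def collapse_synonymous(
    gene_name: str,
    allele_frequencies: Mapping[str, Mapping[str, float]],
    translations: Mapping[str, str],
) -> List[AminoAcidAllele]:
    """Group gene alleles with identical protein sequences into amino-acid
    alleles.

    ``allele_frequencies`` maps phenotype-group name (e.g. ``'control'``,
    ``'case'``) to per-allele frequencies; group frequencies are summed
    over members, preserving total mass.  Labels are assigned as
    ``GeneName*aa*k`` by decreasing frequency in the first group
    (control-frequency rank by convention).
    """
    groups = list(allele_frequencies)
    if not groups:
        raise ValueError("no phenotype groups supplied")
    by_protein: Dict[str, List[str]] = {}
    for label in translations:
        by_protein.setdefault(translations[label], []).append(label)
    rank_group = groups[0]
    records = []
    for protein, members in by_protein.items():
        freqs = {
            g: float(sum(allele_frequencies[g].get(m, 0.0) for m in members))
            for g in groups
        }
        records.append((freqs[rank_group], protein, tuple(sorted(members)), freqs))
    records.sort(key=lambda r: (-r[0], r[1]))
    return [
        AminoAcidAllele(
            label=f"{gene_name}*aa*{k}",
            protein=protein,
            members=members,
            frequencies=freqs,
        )
        for k, (_, protein, members, freqs) in enumerate(records, start=1)
    ]


def collapse_dosages(
    dosages: pd.DataFrame, aa_alleles: Sequence[AminoAcidAllele]
) -> pd.DataFrame:
    """Re-express a per-DNA-allele dosage table on amino-acid alleles by
    summing member columns (dosages still sum to 2 per subject)."""
    out = {}
    for aa in aa_alleles:
        cols = [m for m in aa.members if m in dosages.columns]
        out[aa.label] = dosages[cols].sum(axis=1) if cols else 0.0
    return pd.DataFrame(out, index=dosages.index)
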