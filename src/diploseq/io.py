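"""Readers and writers for the standard formats the pipeline touches:
VCF genotypes, BED gene intervals, TSV reports and the JSON model schema.

Model files are human-diffable JSON with a stamped schema version;
frequencies are serialized as decimal strings at full double precision so
a round trip is lossless.  All TSV outputs have a header row and stable
column order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    Diplotype,
    FrequencyTable,
    GeneAllele,
    GeneSnpHaplotype,
    GenotypeMatrix,
    SnpLocus,
)
from .model import PredictionModel

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> Tuple[str, Optional[int], Optional[int]]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-", 1)
    return chrom, int(start), int(end)


def read_vcf(path, region: Optional[str] = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    GT fields map to codes 0 (hom-ref), 1 (het; phase on input is
    ignored), 2 (hom-alt) and MISSING (./.).  Multi-allelic records are
    skipped with a warning.  ``region`` may be ``"chrom"`` or
    ``"chrom:start-end"`` (1-based inclusive).
    """
    path = str(path)
    with open(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise ValueError(f"{path}: line 1: missing ##fileformat VCF header")
    want = _parse_region(region) if region else None
    try:
        vcf = VCF(path, gts012=True)
        samples = list(vcf.samples)
        loci: List[SnpLocus] = []
        rows: List[np.ndarray] = []
        n_skipped = 0
        for idx, v in enumerate(vcf):
            if want is not None:
                chrom, start, end = want
                if v.CHROM != chrom:
                    continue
                if start is not None and not (start <= v.POS <= end):
                    continue
            if len(v.ALT) != 1:
                n_skipped += 1
                continue
            loci.append(
                SnpLocus(
                    id=v.ID or f"{v.CHROM}:{v.POS}",
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=v.ALT[0],
                )
            )
            codes = v.gt_types.astype(np.int8)  # 0,1,2 = genotypes; 3 = unknown
            codes[codes == 3] = MISSING
            rows.append(codes)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: malformed VCF: {exc}") from exc
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic record(s)", path, n_skipped)
    codes = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, loci=loci, codes=codes)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, gm: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 with GT only."""
    lines = ["##fileformat=VCFv4.2", "##source=diploseq"]
    for chrom in dict.fromkeys(l.chrom for l in gm.loci):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    order = sorted(range(gm.n_loci), key=lambda j: (gm.loci[j].chrom, gm.loci[j].pos))
    for j in order:
        locus = gm.loci[j]
        gts = "\t".join(_GT[int(c)] for c in gm.codes[:, j])
        lines.append(
            f"{locus.chrom}\t{locus.pos}\t{locus.id}\t{locus.ref}\t"
            f"{locus.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def read_bed(path) -> List[Tuple[str, str, int, int]]:
    """Read gene intervals from BED (0-based half-open on disk, converted
    to 1-based inclusive).  Returns (name, chrom, start, end) tuples."""
    out = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        parts = raw.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        out.append((name, chrom, start + 1, end))
    return out


def write_bed(path, intervals: Sequence[Tuple[str, str, int, int]]) -> None:
    """Write (name, chrom, start1, end1) gene intervals as BED."""
    lines = [
        f"{chrom}\t{start - 1}\t{end}\t{name}"
        for name, chrom, start, end in intervals
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls_tsv(path, samples: Sequence[str], calls) -> None:
    """Per-subject diplotype calls: sample, allele1, allele2, posterior
    (``NA`` for missing calls)."""
    rows = []
    for s, c in zip(samples, calls):
        if c is None:
            rows.append((s, "NA", "NA", "NA"))
        else:
            post = "NA" if c.posterior is None else f"{c.posterior:.6g}"
            rows.append((s, c.allele1.label, c.allele2.label, post))
    df = pd.DataFrame(rows, columns=["sample", "allele1", "allele2", "posterior"])
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(
    path, allele_dictionary: Optional[Dict[str, Tuple[int, ...]]] = None
):
    """Read a calls TSV; returns (samples, calls) with ``None`` for NA
    rows.  Allele sequences are taken from ``allele_dictionary`` when
    given, else left empty."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    seq = allele_dictionary or {}
    samples, calls = [], []
    for _, row in df.iterrows():
        samples.append(row["sample"])
        if row["allele1"] in ("", "NA"):
            calls.append(None)
            continue
        post = None if row["posterior"] in ("", "NA") else float(row["posterior"])
        a1 = GeneAllele(row["allele1"], tuple(seq.get(row["allele1"], ())))
        a2 = GeneAllele(row["allele2"], tuple(seq.get(row["allele2"], ())))
        calls.append(Diplotype(a1, a2, posterior=post))
    return samples, calls


def write_alleles_tsv(path, alleles: Sequence[GeneAllele], freqs: FrequencyTable):
    """Allele dictionary: label, sequence (allele-code string), frequency."""
    rows = [
        (
            a.label,
            "".join(map(str, a.sequence)),
            repr(float(freqs.freq(a.sequence, 0.0))),
        )
        for a in alleles
    ]
    df = pd.DataFrame(rows, columns=["label", "sequence", "frequency"])
    df.to_csv(path, sep="\t", index=False)


def read_alleles_tsv(path) -> Dict[str, Tuple[int, ...]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row["label"]: tuple(int(c) for c in str(row["sequence"]))
        for _, row in df.iterrows()
    }


def read_phenotypes(path) -> pd.Series:
    """Phenotype TSV (sample, status in {0,1}) as a sample-indexed series."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "status": int})
    if not set(df.columns) >= {"sample", "status"}:
        raise ValueError(f"{path}: expected columns 'sample' and 'status'")
    return df.set_index("sample")["status"]


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------


def write_model(model: PredictionModel, path) -> None:
    """Serialize a prediction model as JSON (lossless round trip)."""
    joint = sorted(
        (
            key.gene_allele.label,
            "".join(map(str, key.snp_haplotype)),
            repr(float(f)),
        )
        for key, f in model.joint_freqs.items()
    )
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "gene": {
            "name": model.gene_name,
            "chrom": model.chrom,
            "start": model.start,
            "end": model.end,
        },
        "flank_size": model.flank_size,
        "snps": [
            {"id": s.id, "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
            for s in model.selected_snps
        ],
        "alleles": {
            lab: "".join(map(str, seq))
            for lab, seq in model.allele_dictionary.items()
        },
        "joint": [
            {"allele": a, "snp_hap": h, "freq": f} for a, h, f in joint
        ],
        "meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def read_model(path) -> PredictionModel:
    """Load a prediction model from JSON; unknown schema versions and
    truncated files raise a clean error."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a valid model file: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unknown model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    alleles = {
        lab: tuple(int(c) for c in seq) for lab, seq in doc["alleles"].items()
    }
    allele_objs = {lab: GeneAllele(lab, seq) for lab, seq in alleles.items()}
    entries = {
        GeneSnpHaplotype(
            allele_objs[rec["allele"]], tuple(int(c) for c in rec["snp_hap"])
        ): float(rec["freq"])
        for rec in doc["joint"]
    }
    gene = doc["gene"]
    return PredictionModel(
        gene_name=gene["name"],
        selected_snps=tuple(
            SnpLocus(s["id"], s["chrom"], s["pos"], s["ref"], s["alt"])
            for s in doc["snps"]
        ),
        joint_freqs=FrequencyTable(entries),
        allele_dictionary=alleles,
        chrom=gene.get("chrom"),
        start=gene.get("start"),
        end=gene.get("end"),
        flank_size=doc.get("flank_size"),
        training_meta=doc.get("meta", {}),
    )


def genotype_columns_for_model(
    model: PredictionModel, gm: GenotypeMatrix
) -> np.ndarray:
    """Genotype codes aligned with ``model.selected_snps`` (matched by
    chrom/pos/ref/alt; loci absent from the data become MISSING columns)."""
    index = {(l.chrom, l.pos, l.ref, l.alt): j for j, l in enumerate(gm.loci)}
    cols = []
    for locus in model.selected_snps:
        j = index.get((locus.chrom, locus.pos, locus.ref, locus.alt))
        if j is None:
            logger.warning(
                "selected SNP %s (%s:%d) absent from genotype data; "
                "treated as missing",
                locus.id, locus.chrom, locus.pos,
            )
            cols.append(np.full(gm.n_samples, MISSING, dtype=np.int8))
        else:
            cols.append(gm.codes[:, j])
    if not cols:
        return np.zeros((gm.n_samples, 0), dtype=np.int8)
    return np.stack(cols, axis=1)


def write_predictions_tsv(path, samples: Sequence[str], calls) -> None:
    """Predictions TSV: sample, allele1, allele2, posterior, called."""
    rows = []
    for s, c in zip(samples, calls):
        if c is None:
            rows.append((s, "NA", "NA", "NA", False))
        else:
            rows.append(
                (s, c.allele1.label, c.allele2.label,
                 f"{c.posterior:.6g}" if c.posterior is not None else "NA", True)
            )
    df = pd.DataFrame(
        rows, columns=["sample", "allele1", "allele2", "posterior", "called"]
    )
    df.to_csv(path, sep="\t", index=False)
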