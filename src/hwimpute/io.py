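"""Reading and writing genotype data and results tables.

Supported formats: VCF (biallelic diploid records, GT only; ``./.`` and
half-calls are missing), a TSV genotype matrix (samples x markers, cells
0/1/2/NA counting copies of the alternate allele), and a TSV count table
(marker_id, nAA, nAB, nBB).  Allele "A" is the VCF REF allele; the TSV
dosage counts ALT copies, so dosage 0 is AA.  All statistics downstream
are invariant to the labeling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .counts import MISSING, GenotypeCounts
from .errors import DataError, DomainError, ParseError
from .imputation import MarkerDataset

logger = logging.getLogger("hwimpute")

__all__ = ["read_genotypes", "read_counts", "write_genotypes_tsv",
           "write_genotypes_vcf", "write_counts", "write_results",
           "attach_flanking"]

_TSV_CODES = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING, ".": MISSING}


def _detect_format(path: str | Path) -> str:
    s = str(path)
    return "vcf" if s.endswith((".vcf", ".vcf.gz")) else "tsv"


def read_genotypes(path: str | Path, fmt: Optional[str] = None,
                   flanking: bool = False) -> list[MarkerDataset]:
    """Read a genotype file into one :class:`MarkerDataset` per marker.

    ``fmt`` is 'vcf' or 'tsv' (auto-detected from the extension by
    default).  With ``flanking=True`` the genotypes of the two physical
    neighbors of each marker are attached as covariate columns.
    """
    fmt = fmt or _detect_format(path)
    if fmt == "vcf":
        datasets = _read_vcf(path)
    elif fmt == "tsv":
        datasets = _read_tsv(path)
    else:
        raise DomainError(f"unknown format '{fmt}' (expected 'vcf' or 'tsv')")
    if flanking:
        attach_flanking(datasets)
    return datasets


def _read_vcf(path: str | Path) -> list[MarkerDataset]:
    datasets: list[MarkerDataset] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("skipping non-biallelic record %s:%s (%s)",
                               rec.chrom, rec.pos, rec.id or ".")
                continue
            g = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    g[i] = MISSING
                else:
                    g[i] = gt[0] + gt[1]
            marker_id = rec.id or f"{rec.chrom}:{rec.pos}"
            datasets.append(MarkerDataset(marker_id=marker_id, genotypes=g,
                                          contig=rec.chrom, pos=rec.pos))
    return datasets


def _read_tsv(path: str | Path) -> list[MarkerDataset]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    datasets: list[MarkerDataset] = []
    columns = list(df.columns)
    for j, marker in enumerate(columns):
        g = np.empty(len(df), dtype=np.int8)
        for i, cell in enumerate(df[marker]):
            key = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                else str(cell).strip()
            if key not in _TSV_CODES:
                raise ParseError(
                    f"{path}: malformed genotype cell {cell!r} at "
                    f"line {i + 2}, column {j + 2} (marker {marker})"
                )
            g[i] = _TSV_CODES[key]
        datasets.append(MarkerDataset(marker_id=marker, genotypes=g,
                                      contig="0", pos=j + 1))
    return datasets


def attach_flanking(datasets: Sequence[MarkerDataset]) -> None:
    """Attach each marker's nearest physical neighbors as flank covariates.

    Neighbors are chosen by position within the same contig, nearest
    first; a marker at the edge of a contig gets the two nearest markers
    on its single side.
    """
    by_contig: dict[str, list[int]] = {}
    for i, ds in enumerate(datasets):
        by_contig.setdefault(ds.contig or "", []).append(i)
    for contig, idx in by_contig.items():
        idx = sorted(idx, key=lambda i: datasets[i].pos or 0)
        for rank, i in enumerate(idx):
            ds = datasets[i]
            pos = ds.pos or 0
            others = [j for j in idx if j != i]
            if not others:
                continue
            others.sort(key=lambda j: abs((datasets[j].pos or 0) - pos))
            nearest = others[:2]
            cov = ds.covariates if ds.covariates is not None else pd.DataFrame(
                index=range(ds.n_samples))
            cov = cov.copy()
            cov["left_flank"] = datasets[nearest[0]].genotypes
            cov["right_flank"] = datasets[nearest[-1]].genotypes
            ds.covariates = cov


def read_counts(path: str | Path) -> list[tuple[str, GenotypeCounts]]:
    """Read a TSV count table (marker_id, nAA, nAB, nBB)."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "nAA", "nAB", "nBB"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: count table must have columns {sorted(required)}")
    return [(str(r.marker_id), GenotypeCounts(int(r.nAA), int(r.nAB), int(r.nBB)))
            for r in df.itertuples()]


def write_genotypes_tsv(datasets: Sequence[MarkerDataset], path: str | Path,
                        sample_ids: Optional[Sequence[str]] = None) -> None:
    """Write a samples x markers 0/1/2/NA matrix."""
    n = datasets[0].n_samples
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(n)]
    data = {}
    for ds in datasets:
        col = ds.genotypes.astype(object)
        col[ds.genotypes == MISSING] = "NA"
        data[ds.marker_id] = col
    pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")).to_csv(
        path, sep="\t")


def write_genotypes_vcf(datasets: Sequence[MarkerDataset], path: str | Path,
                        sample_ids: Optional[Sequence[str]] = None) -> None:
    """Write markers as biallelic SNP records (alleles A/C, GT only)."""
    n = datasets[0].n_samples
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(n)]
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    contigs = sorted({ds.contig or "0" for ds in datasets})
    for c in contigs:
        header.contigs.add(c, length=2_000_000_000)
    for s in sample_ids:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for k, ds in enumerate(datasets):
            rec = out.new_record(contig=ds.contig or "0",
                                 start=(ds.pos or (k + 1)) - 1,
                                 alleles=("A", "C"), id=ds.marker_id)
            for i, s in enumerate(sample_ids):
                rec.samples[s]["GT"] = gt_codes[int(ds.genotypes[i])]
            out.write(rec)


def write_counts(rows: Sequence[tuple[str, GenotypeCounts]],
                 path: str | Path) -> None:
    pd.DataFrame(
        [(mid, c.n_AA, c.n_AB, c.n_BB) for mid, c in rows],
        columns=["marker_id", "nAA", "nAB", "nBB"],
    ).to_csv(path, sep="\t", index=False)


#: Columns given an additional 3-decimal display twin in results files.
_DISPLAY_COLUMNS = ("f_discard", "f_mi", "p_exact_discard_two_sided",
                    "p_chi2_discard", "p_mi_chi2", "p_mi_exact_two_sided")


def write_results(rows: Sequence, path: str | Path) -> None:
    """Write per-marker result rows as TSV.

    One header line, missing values as NA, numeric fields at full
    precision, plus 3-decimal display columns for the headline estimates
    and p-values.
    """
    rows = list(rows)
    if not rows:
        raise DomainError("write_results requires at least one result row")
    df = pd.DataFrame([r.as_dict() for r in rows])
    for col in _DISPLAY_COLUMNS:
        if col in df.columns:
            df[f"{col}_3dp"] = df[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.3f}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
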