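"""Tabular, bedGraph, VCF and JSON input/output.

Conventions: bedGraph intervals are 0-based half-open per the format
standard; printed breakpoint positions are 1-based inclusive.  All
coordinate conversions happen at this boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_depth_matrix",
    "read_depth_matrix",
    "write_bedgraph",
    "read_bedgraph",
    "read_snp_vcf",
    "write_json_report",
]


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """One row per sample: sample_id, genotype columns, phenotype, covariates."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: cohort file must have a sample_id column")
    return df


def write_depth_matrix(path: str | Path, positions: np.ndarray, depth: np.ndarray, sample_ids: list[str]) -> None:
    """Depth matrix as TSV: rows = samples, columns = 0-based base positions."""
    df = pd.DataFrame(depth, index=pd.Index(sample_ids, name="sample_id"), columns=positions)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_depth_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    positions = df.columns.to_numpy(dtype=int)
    return positions, df.to_numpy(dtype=float), df.index.tolist()


def write_bedgraph(path: str | Path, chrom: str, positions: np.ndarray, values: np.ndarray) -> None:
    """Per-sample depth track as bedGraph (0-based half-open), runs merged."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start] or positions[i] != positions[i - 1] + 1:
                fh.write(f"{chrom}\t{positions[start]}\t{positions[i - 1] + 1}\t{values[start]:.10g}\n")
                start = i


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Parse a bedGraph; malformed or inverted intervals are named by line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append((chrom, start, end, float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_snp_vcf(path: str | Path, marker_id: str | None = None) -> pd.DataFrame:
    """SNP genotypes from a VCF as alternate-allele counts (0/1/2, -1 missing).

    Returns a frame with one row per (marker, sample): marker_id, sample_id,
    gt.  Only biallelic SNP records are used; symbolic alleles are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = vcf.samples
    rows = []
    for rec in vcf:
        if rec.ID is not None and marker_id is not None and rec.ID != marker_id:
            continue
        if len(rec.ALT) != 1 or rec.ALT[0].startswith("<"):
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        for sample, gt in zip(samples, rec.gt_types):
            rows.append(
                (rec.ID or f"{rec.CHROM}:{rec.POS}", sample, int(gt) if gt != 3 else -1)
            )
    return pd.DataFrame(rows, columns=["marker_id", "sample_id", "gt"])


def write_json_report(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
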