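"""Readers for the package's external formats.

Genotypes come as either the simple TSV matrix written by
:mod:`linesense.simdata` (rows = variants, columns = lines, values 0/1/NA)
or a VCF of biallelic sites with homozygous genotype calls (inbred lines:
0/0 -> 0, 1/1 -> 1, anything heterozygous or missing -> NA).  Gene models
are BED (0-based half-open on disk, converted to 1-based inclusive
internally); interaction networks are two-column TSV edge lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .netperm import build_graph
from .simdata import GenotypeTable

logger = logging.getLogger(__name__)

_META_COLS = ["variant_id", "chrom", "pos", "vtype"]


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeTable:
    """Load a genotype table from TSV or VCF (auto-detected by suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise DataError(f"unknown genotype format {fmt!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeTable:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    except Exception as exc:  # pandas reports the offending line number
        raise DataError(f"malformed genotype TSV {path}: {exc}") from exc
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise DataError(f"genotype TSV {path} lacks columns {missing}")
    line_ids = [c for c in df.columns if c not in _META_COLS]
    if not line_ids:
        raise DataError(f"genotype TSV {path} has no line columns")
    matrix = df[line_ids].to_numpy(dtype=np.float32)
    bad = ~(np.isnan(matrix) | (matrix == 0) | (matrix == 1))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise DataError(f"genotype TSV {path}: non-0/1 value at data row {row + 1}")
    return GenotypeTable(
        variants=df[_META_COLS].reset_index(drop=True), matrix=matrix, line_ids=line_ids
    )


def _read_genotypes_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, geno = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types
        codes = np.full(len(line_ids), np.nan, dtype=np.float32)
        codes[gt == 0] = 0.0
        codes[gt == 3] = 1.0
        vtype = "snp" if len(rec.REF) == 1 and len(rec.ALT[0]) == 1 else "indel"
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "vtype": vtype,
            }
        )
        geno.append(codes)
    if skipped:
        logger.info("skipped %d multi-allelic VCF record(s)", skipped)
    if not rows:
        raise DataError(f"no usable biallelic records in {path}")
    return GenotypeTable(
        variants=pd.DataFrame(rows), matrix=np.vstack(geno), line_ids=line_ids
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"line_id", "age", "treatment", "block", "mass_mg", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"phenotype CSV {path} lacks columns {sorted(missing)}")
    return df


def read_gene_models_bed(path: str | Path) -> pd.DataFrame:
    """BED -> 1-based inclusive gene models (gene_id, chrom, start, end,
    strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise DataError(f"BED file {path} needs at least 4 columns (chrom start end name)")
    out = pd.DataFrame(
        {
            "gene_id": df[3],
            "chrom": df[0],
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else "+",
        }
    )
    if (out["start"] > out["end"]).any():
        raise DataError(f"BED file {path} contains an empty/inverted interval")
    return out


def read_network(path: str | Path):
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return build_graph(df)
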