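"""Readers and writers for the TSV/VCF interchange formats.

TSV is the canonical interchange: one header row, a participant-ID column,
one numeric column per feature. Genotypes travel as a dosage TSV plus a
variants annotation TSV, or read-only from a VCF carrying DS (imputed
dosage) or GT per genotype.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["read_feature_table", "write_feature_table", "read_dosages", "write_dosages"]


def read_feature_table(path: str | Path, fmt: str = "tsv", view_label: str = "") -> FeatureTable:
    """Load a participants x features table; non-numeric cells become missing."""
    sep = {"tsv": "\t", "csv": ","}[fmt]
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"empty file: {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate participant ID {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_coerced = int((numeric.isna() & df.notna()).sum().sum())
    if n_coerced:
        logger.warning("%s: %d non-numeric cells set to missing", path, n_coerced)
    return FeatureTable(numeric, view_label)


def write_feature_table(table: FeatureTable, path: str | Path, fmt: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[fmt]
    table.data.to_csv(path, sep=sep)


def _read_dosages_tsv(dosage_path: Path, variants_path: Path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    info = pd.read_csv(variants_path, sep="\t", index_col=0)
    return GenotypeMatrix(dos, info)


def _read_dosages_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency; plain-text VCF is fine

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, index, records = [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = var.genotypes
            if gts is None:
                raise ValueError(f"variant {var.ID or var.POS}: neither DS nor GT present")
            dose = np.array([max(g[0], 0) + max(g[1], 0) for g in gts], dtype=float)
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        index.append(vid)
        rows.append(dose)
        af = float(np.mean(dose)) / 2
        records.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "effect_allele": var.ALT[0] if var.ALT else ".",
                "other_allele": var.REF,
                "gene": (var.INFO.get("GENE") or "."),
                "maf": min(af, 1 - af),
                "info": float(var.INFO.get("INFO", 1.0)),
            }
        )
    info = pd.DataFrame(records, index=pd.Index(index, name="variant_id"))
    dos = pd.DataFrame(np.asarray(rows).T, index=pd.Index(samples, name="participant_id"), columns=index)
    return GenotypeMatrix(dos, info)


def read_dosages(path: str | Path, fmt: str = "tsv", variants_path: str | Path | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from a dosage TSV (+ variants TSV) or a VCF.

    For VCF, the DS FORMAT field is used when present, otherwise GT is
    converted to the ALT-allele count; the effect allele is ALT.
    """
    path = Path(path)
    if fmt == "tsv":
        if variants_path is None:
            variants_path = path.with_name("variants.tsv")
        return _read_dosages_tsv(path, Path(variants_path))
    if fmt == "vcf":
        return _read_dosages_vcf(path)
    raise ValueError(f"unknown genotype format: {fmt}")


def write_dosages(g: GenotypeMatrix, dosage_path: str | Path, variants_path: str | Path) -> None:
    g.dosages.to_csv(dosage_path, sep="\t")
    g.variant_info.to_csv(variants_path, sep="\t")
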