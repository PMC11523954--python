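"""File ingestion helpers: VCF genotypes and long-format PSA series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError

__all__ = ["read_vcf_genotypes", "read_psa_series", "write_psa_series"]


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Minor-allele counts (samples × SNPs) from biallelic VCF records.

    The ALT allele count per genotype is flipped to the minor allele
    whenever the ALT frequency in the file exceeds 0.5, so columns always
    count the less common allele. Multi-allelic records are rejected.
    Requires cyvcf2 (optional dependency).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        if len(record.ALT) != 1:
            raise SchemaError(
                f"{path}: multi-allelic record at {record.CHROM}:{record.POS}"
            )
        name = record.ID or f"{record.CHROM}:{record.POS}"
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(record.gt_types)
        if (gt == 2).any():
            raise SchemaError(f"{path}: missing genotype at {name}")
        alt_count = np.where(gt == 3, 2, np.where(gt == 1, 1, 0))
        if alt_count.mean() / 2.0 > 0.5:  # ALT is the major allele here
            alt_count = 2 - alt_count
        columns[name] = alt_count
    if not columns:
        raise SchemaError(f"{path}: no variant records")
    return pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))


def read_psa_series(path: str | Path) -> pd.DataFrame:
    """Long-format PSA table with columns (sample_id, day, psa)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "day", "psa"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: needs columns {sorted(required)}")
    if (df["psa"] < 0).any():
        raise InvalidParameterError(f"{path}: negative PSA values")
    return df.sort_values(["sample_id", "day"]).reset_index(drop=True)


def write_psa_series(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, sep="\t", index=False)
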