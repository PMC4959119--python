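"""PLINK 1 binary (BED/BIM/FAM) reader and writer.

Only SNP-major BED files are supported (third header byte 0x01), per the
PLINK 1 specification: magic bytes 0x6C 0x1B, then one block of
ceil(n_subjects / 4) bytes per SNP, each byte packing four 2-bit genotype
codes little-endian (first sample in the lowest pair of bits):

    00 -> homozygous A1 (dosage 2, counting A1 alleles)
    01 -> missing
    10 -> heterozygous (dosage 1)
    11 -> homozygous A2 (dosage 0)

BIM and FAM are whitespace-delimited text.  Dosages count A1 alleles, with
``numpy.nan`` for missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["read_plink", "write_plink", "read_dosage_tsv", "write_dosage_tsv"]

_MAGIC = bytes([0x6C, 0x1B])
# code index (0b00..0b11) -> dosage; 1 is the missing sentinel
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a BED/BIM/FAM triple given the shared path prefix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "pat", "mat", "sex", "phenotype"],
        dtype={"fid": str, "sample_id": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise ValueError(f"{prefix}.bed: not a PLINK 1 BED file (bad magic bytes)")
    if raw[2] != 0x01:
        raise ValueError(
            f"{prefix}.bed: individual-major BED files are not supported "
            f"(mode byte {raw[2]:#04x}, need 0x01)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed: truncated or padded file — expected {expected} bytes "
            f"({m} SNPs x {bytes_per_snp} bytes + 3), got {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack the four 2-bit codes per byte, lowest bits first
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # subjects x SNPs
    sample_records = pd.DataFrame({"sample_id": fam["sample_id"]})
    sample_records["sex"] = fam["sex"]
    snp_records = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages=dosages, snp_records=snp_records, sample_records=sample_records)


def write_plink(prefix: str | Path, geno: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as a SNP-major BED/BIM/FAM triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_subjects, geno.n_snps
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    dosages = geno.dosages.T
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[dosages == dos] = code
    bad = ~np.isnan(dosages) & ~np.isin(dosages, list(_DOSAGE_TO_CODE))
    if bad.any():
        snp_idx, _ = np.nonzero(bad)
        raise ValueError(f"non-integer dosages cannot be written to BED (SNP {snp_idx[0]})")
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(m, -1, 4)
    shifts = np.arange(4) * 2
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([0x01]))
        fh.write(packed.tobytes())

    bim = geno.snp_records
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in bim.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos}\t{rec.a1}\t{rec.a2}\n")
    samp = geno.sample_records
    sex = samp["sex"] if "sex" in samp else pd.Series(np.zeros(n, dtype=int))
    group = samp["group"] if "group" in samp else pd.Series(np.full(n, -9))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(samp["sample_id"]):
            # FAM sex code: 1=male, 2=female, 0=unknown; phenotype 1/2 case-control
            sex_code = int(sex.iloc[i]) + 1 if sex.iloc[i] in (0, 1) else 0
            pheno = int(group.iloc[i]) + 1 if group.iloc[i] in (0, 1) else -9
            fh.write(f"FAM{i:04d}\t{sid}\t0\t0\t{sex_code}\t{pheno}\n")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV: columns snp_id, chrom, pos, a1, a2, then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "a1", "a2"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(
        dosages=dosages,
        snp_records=df[meta_cols].copy(),
        sample_records=pd.DataFrame({"sample_id": sample_ids}),
    )


def write_dosage_tsv(path: str | Path, geno: GenotypeMatrix) -> None:
    df = geno.snp_records[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    for i, sid in enumerate(geno.sample_records["sample_id"]):
        df[sid] = geno.dosages[i]
    df.to_csv(path, sep="\t", index=False)
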