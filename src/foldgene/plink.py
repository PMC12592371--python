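"""Minimal PLINK 1 bed/bim/fam and TSV dosage I/O.

Genotypes are stored as counts of the A1 (minor) allele in {0, 1, 2}.
Only the SNP-major bed layout is supported, which is what PLINK 1.9/2.0
write by default.  Missing genotypes (code 0b01) are rejected on read:
the synthetic cohorts produced here are complete by construction, and
real input with missingness should be filtered upstream.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.00, SNP-major

# 2-bit code per genotype, LSB-first within each byte:
#   00 -> two A1 alleles (dosage 2), 10 -> het (1), 11 -> two A2 (0), 01 -> missing
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.full(4, -1, dtype=np.int8)
_CODE_TO_DOSAGE[0b00] = 2
_CODE_TO_DOSAGE[0b10] = 1
_CODE_TO_DOSAGE[0b11] = 0  # 0b01 stays -1 (missing)

# byte -> 4 dosages lookup table
_BYTE_TABLE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_TABLE[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0b11]


def write_bed(prefix: str, dosages: np.ndarray, snp_meta: pd.DataFrame,
              subject_ids=None) -> None:
    """Write ``prefix``.bed/.bim/.fam from an n_subjects x n_snps dosage matrix.

    ``snp_meta`` needs columns snp_id, chrom, bp, a1; a2 defaults to the
    complementary placeholder allele 'A2' written as the major allele label.
    """
    dosages = np.asarray(dosages)
    if dosages.ndim != 2:
        raise ValueError("dosages must be 2-D (subjects x SNPs)")
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0,1,2}")
    n, m = dosages.shape
    if len(snp_meta) != m:
        raise ValueError("snp_meta rows must match number of SNPs")
    if subject_ids is None:
        subject_ids = [f"S{i:06d}" for i in range(n)]

    # fam: FID IID father mother sex phenotype
    with open(prefix + ".fam", "w") as fh:
        for sid in subject_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")

    a2 = snp_meta["a2"] if "a2" in snp_meta.columns else ["G"] * m
    with open(prefix + ".bim", "w") as fh:
        for j in range(m):
            row = snp_meta.iloc[j]
            fh.write(f"{int(row['chrom'])}\t{row['snp_id']}\t0\t{int(row['bp'])}"
                     f"\t{row['a1']}\t{a2[j] if not hasattr(a2, 'iloc') else a2.iloc[j]}\n")

    n_bytes = (n + 3) // 4
    codes = np.empty_like(dosages, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[dosages == d] = c
    buf = bytearray(_BED_MAGIC)
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for i in range(4):
        chunk = codes[i::4, :]  # subjects i, i+4, ...
        packed[:, : chunk.shape[0]] |= (chunk.T.astype(np.uint8) << (2 * i))
    buf.extend(packed.tobytes())
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes(buf))


def read_bed(prefix: str):
    """Read ``prefix``.bed/.bim/.fam; returns (dosages, snp_meta, subject_ids)."""
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"])
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK v1 bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * n_bytes:
        raise ValueError("bed payload size inconsistent with bim/fam")
    dosages = _BYTE_TABLE[raw.reshape(m, n_bytes)].reshape(m, -1)[:, :n].T
    if (dosages < 0).any():
        raise ValueError("missing genotypes present; not supported")
    meta = bim[["snp_id", "chrom", "bp", "a1", "a2"]].copy()
    return dosages.astype(np.int8), meta, fam["iid"].tolist()


def write_dosage_tsv(path: str, dosages: np.ndarray, snp_meta: pd.DataFrame,
                     subject_ids=None) -> None:
    """TSV fallback: one row per subject, one column per SNP id."""
    n = dosages.shape[0]
    if subject_ids is None:
        subject_ids = [f"S{i:06d}" for i in range(n)]
    df = pd.DataFrame(np.asarray(dosages), columns=snp_meta["snp_id"].tolist())
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, sep="\t", index=False)
    meta_path = os.path.splitext(path)[0] + ".snps.tsv"
    snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(path: str):
    df = pd.read_csv(path, sep="\t")
    subject_ids = df["subject_id"].tolist()
    dosages = df.drop(columns="subject_id").to_numpy(dtype=np.int8)
    meta_path = os.path.splitext(path)[0] + ".snps.tsv"
    meta = pd.read_csv(meta_path, sep="\t") if os.path.exists(meta_path) else None
    return dosages, meta, subject_ids
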