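"""PLINK1 binary (bed/bim/fam) and TSV dosage I/O.

The .bed codec is the SNP-major 2-bit layout: magic bytes 0x6C 0x1B, mode
byte 0x01, then ceil(n/4) bytes per SNP.  Within a byte the two-bit codes
are packed little-endian (first sample in the lowest bits):

    00 -> homozygous a1 (dosage 2)
    01 -> missing
    10 -> heterozygous (dosage 1)
    11 -> homozygous a2 (dosage 0)
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SnpRecord

__all__ = ["write_plink", "read_plink", "read_dosage_tsv", "write_dosage_tsv"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> dosage of a1 (nan = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as PLINK1 ``prefix.bed/.bim/.fam``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = G.dosages.shape

    # fam: FID IID PAT MAT SEX PHENO
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")

    # bim: CHR ID CM POS A1 A2
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in G.snps:
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\t{rec.a1}\t{rec.a2}\n")

    # bed, SNP-major
    codes = np.full((p, n), 1, dtype=np.uint8)  # default missing (01)
    D = G.dosages.T
    codes[D == 2.0] = 0b00
    codes[D == 1.0] = 0b10
    codes[D == 0.0] = 0b11

    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | os.PathLike, info_r2: dict[str, float] | None = None) -> GenotypeMatrix:
    """Read PLINK1 ``prefix.bed/.bim/.fam`` into a GenotypeMatrix.

    ``info_r2`` optionally attaches per-SNP imputation quality by rsID.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    sample_ids = fam["iid"].tolist()
    info_r2 = info_r2 or {}
    snps = [
        SnpRecord(id=row.id, chrom=str(row.chrom), pos=int(row.pos),
                  a1=row.a1, a2=row.a2, info_r2=info_r2.get(row.id))
        for row in bim.itertuples()
    ]
    n, p = len(sample_ids), len(snps)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK1 bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != p * n_bytes:
        raise ValueError(f"{prefix}.bed: size mismatch (expected {p * n_bytes} body bytes)")
    body = body.reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    G = GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosages=dosages)
    G.check_positions_sorted()
    return G


def write_dosage_tsv(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write dosages as TSV: sample_id column + one column per SNP ID."""
    df = G.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | os.PathLike,
                    snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a TSV dosage matrix (sample_id + SNP columns).

    ``snp_meta`` optionally supplies chrom/pos/a1/a2 per SNP ID; otherwise
    placeholder metadata is synthesized (chrom "1", sequential positions).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    meta = {}
    if snp_meta is not None:
        meta = {row.id: row for row in snp_meta.itertuples()}
    snps = []
    for j, sid in enumerate(df.columns):
        if sid in meta:
            row = meta[sid]
            snps.append(SnpRecord(id=sid, chrom=str(row.chrom), pos=int(row.pos),
                                  a1=str(row.a1), a2=str(row.a2),
                                  info_r2=getattr(row, "info_r2", None)))
        else:
            snps.append(SnpRecord(id=sid, chrom="1", pos=j + 1, a1="A", a2="B"))
    return GenotypeMatrix(sample_ids=[str(s) for s in df.index],
                          snps=snps, dosages=df.to_numpy(dtype=float))
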