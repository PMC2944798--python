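"""Genotype panel readers: PLINK text, PLINK 1 binary, and dosage tables.

All readers return the same triple: an (individuals x SNPs) dosage matrix
(float, counting copies of ``allele_1``, NaN for missing), a list of
:class:`SNPMeta`, and a phenotype vector coded 1 = case, 0 = control, NaN =
missing, following the PLINK convention (2 = case, 1 = control, 0/-9 =
missing) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SNPMeta", "read_genotypes", "read_ped", "read_bed", "read_dosage_table"]


@dataclass(frozen=True)
class SNPMeta:
    """Per-SNP metadata as carried in .map/.bim files.

    ``position`` is 1-based; dosages elsewhere in the package count copies
    of ``allele_1``.
    """

    id: str
    chrom: str
    position: int
    allele_1: str = "A"
    allele_2: str = "B"
    gene: str | None = None
    pathway: str | None = None


class FormatError(ValueError):
    """File does not parse under the declared format."""


def _decode_phenotype(raw: np.ndarray) -> np.ndarray:
    pheno = np.full(len(raw), np.nan)
    pheno[raw == 2] = 1.0
    pheno[raw == 1] = 0.0
    return pheno


def read_ped(prefix) -> tuple[np.ndarray, list[SNPMeta], np.ndarray]:
    """Read a PLINK text fileset ``<prefix>.ped`` + ``<prefix>.map``.

    ``allele_1`` is taken as the minor allele (lexicographic tie-break),
    since .map files carry no allele columns.
    """
    prefix = Path(prefix)
    map_rows = []
    for line in Path(f"{prefix}.map").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f".map line has {len(parts)} fields, expected >= 4")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    allele_pairs: list[list[tuple[str, str]]] = []
    phenos = []
    for line in Path(f"{prefix}.ped").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f".ped line has {len(parts)} fields, expected {6 + 2 * m} "
                f"for {m} SNPs"
            )
        phenos.append(float(parts[5]))
        allele_pairs.append(
            [(parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(m)]
        )
    n = len(allele_pairs)

    dosages = np.full((n, m), np.nan)
    meta = []
    for k, (chrom, snp_id, pos) in enumerate(map_rows):
        col = [allele_pairs[i][k] for i in range(n)]
        observed = [a for pair in col for a in pair if a != "0"]
        alleles = sorted(set(observed))
        if len(alleles) > 2:
            raise FormatError(f"SNP {snp_id} has >2 alleles: {alleles}")
        if not alleles:
            a1, a2 = "A", "B"
        elif len(alleles) == 1:
            a1, a2 = alleles[0], "?"
        else:
            counts = {a: observed.count(a) for a in alleles}
            # minor allele first; lexicographic on ties
            a1, a2 = sorted(alleles, key=lambda a: (counts[a], a))
        meta.append(SNPMeta(id=snp_id, chrom=chrom, position=pos,
                            allele_1=a1, allele_2=a2))
        for i, (x, y) in enumerate(col):
            if x == "0" or y == "0":
                continue
            dosages[i, k] = (x == a1) + (y == a1)
    return dosages, meta, _decode_phenotype(np.array(phenos))


_BED_MAGIC = bytes([0x6C, 0x1B])


def read_bed(prefix) -> tuple[np.ndarray, list[SNPMeta], np.ndarray]:
    """Read a PLINK 1 binary fileset ``<prefix>.bed/.bim/.fam`` (SNP-major).

    Two-bit codes per individual: 00 = homozygous allele_1 (dosage 2),
    10 = heterozygous, 11 = homozygous allele_2 (dosage 0), 01 = missing.
    """
    prefix = Path(prefix)
    meta = []
    for line in Path(f"{prefix}.bim").read_text().splitlines():
        if not line.strip():
            continue
        chrom, snp_id, _cm, pos, a1, a2 = line.split()[:6]
        meta.append(SNPMeta(id=snp_id, chrom=chrom, position=int(pos),
                            allele_1=a1, allele_2=a2))
    phenos = []
    for line in Path(f"{prefix}.fam").read_text().splitlines():
        if not line.strip():
            continue
        phenos.append(float(line.split()[5]))
    n, m = len(phenos), len(meta)

    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(".bed magic bytes missing")
    if raw[2] != 0x01:
        raise FormatError(".bed is not in SNP-major mode")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise FormatError(
            f".bed size {len(body)} bytes does not match {n} individuals "
            f"x {m} SNPs"
        )
    codes = body.reshape(m, bytes_per_snp)
    # expand 2-bit fields, least-significant pair = first individual
    shifts = 2 * np.arange(4, dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[two_bit].T.copy()
    return dosages, meta, _decode_phenotype(np.array(phenos))


def read_dosage_table(path) -> tuple[np.ndarray, list[SNPMeta], np.ndarray]:
    """Read a tab-separated dosage table.

    Header ``IID<TAB>PHENO<TAB><snp ids...>``; one row per individual with
    dosages in {0, 1, 2} or NA, phenotype in PLINK coding.  Positions are
    assigned sequentially since the format carries none.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["IID", "PHENO"]:
        raise FormatError("dosage table must start with IID and PHENO columns")
    snp_ids = list(df.columns[2:])
    dosages = df[snp_ids].to_numpy(dtype=float)
    bad = dosages[~np.isnan(dosages)]
    if not np.isin(bad, [0.0, 1.0, 2.0]).all():
        raise FormatError("dosage values must be 0, 1, 2 or NA")
    meta = [
        SNPMeta(id=s, chrom="0", position=k + 1) for k, s in enumerate(snp_ids)
    ]
    return dosages, meta, _decode_phenotype(df["PHENO"].to_numpy(dtype=float))


def read_genotypes(path, format: str | None = None):
    """Dispatch to the reader for ``format`` in {"ped", "bed", "dosage"}.

    With ``format=None`` the format is inferred: a ``<path>.bed`` file means
    bed, a ``<path>.ped`` file means ped, otherwise the path is read as a
    dosage table.
    """
    if format is None:
        if Path(f"{path}.bed").exists():
            format = "bed"
        elif Path(f"{path}.ped").exists():
            format = "ped"
        else:
            format = "dosage"
    readers = {"ped": read_ped, "bed": read_bed, "dosage": read_dosage_table}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}")
    return readers[format](path)
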