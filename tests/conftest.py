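"""Shared fixtures and fixture writers for the test suite.

All genotype filesets are generated programmatically at test time; the
PLINK text/binary writers here are deliberately independent of the package
readers so round-trips exercise both directions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_plink_text(prefix: Path, dosages, meta, phenotype) -> None:
    """Write .ped/.map for a dosage matrix (dosage counts allele_1)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    with open(f"{prefix}.map", "w") as fh:
        for s in meta:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.position}\n")
    # dosage -> allele pair strings
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(n):
            ph = phenotype[i]
            code = "0" if np.isnan(ph) else ("2" if ph == 1 else "1")
            fields = [f"F{i}", f"I{i}", "0", "0", "1", code]
            for k in range(m):
                d = dosages[i, k]
                a1, a2 = meta[k].allele_1, meta[k].allele_2
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    fields += [a1] * int(d) + [a2] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")


def write_plink_bed(prefix: Path, dosages, meta, phenotype) -> None:
    """Write .bed/.bim/.fam (SNP-major PLINK 1 binary)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    with open(f"{prefix}.bim", "w") as fh:
        for s in meta:
            fh.write(
                f"{s.chrom}\t{s.id}\t0\t{s.position}\t{s.allele_1}\t{s.allele_2}\n"
            )
    with open(f"{prefix}.fam", "w") as fh:
        for i in range(n):
            ph = phenotype[i]
            code = "-9" if np.isnan(ph) else ("2" if ph == 1 else "1")
            fh.write(f"F{i} I{i} 0 0 1 {code}\n")
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    body = bytearray([0x6C, 0x1B, 0x01])
    for k in range(m):
        for start in range(0, n, 4):
            byte = 0
            for off, i in enumerate(range(start, min(start + 4, n))):
                d = dosages[i, k]
                two = 0b01 if np.isnan(d) else code_of[d]
                byte |= two << (2 * off)
            body.append(byte)
    Path(f"{prefix}.bed").write_bytes(bytes(body))
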