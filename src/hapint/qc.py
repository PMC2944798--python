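"""Per-SNP quality control for genotype panels.

Filters mirror standard GWAS practice: call-rate (missing fraction), minor
allele frequency, Hardy-Weinberg equilibrium, and duplicated marker ids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SNPMeta

__all__ = ["hwe_chi2_p", "hwe_exact_p", "qc_filter"]


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square HWE p-value from genotype counts (dosage 0/1/2)."""
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p1 = (2 * n2 + n1) / (2 * n)
    if p1 in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p1) ** 2, 2 * n * p1 * (1 - p1), n * p1**2])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(sps.chi2.sf(chi2, df=1))


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test (two-sided, summing genotype configurations with
    probability <= the observed one, conditional on allele counts)."""
    n = n0 + n1 + n2
    n_rare = min(2 * n2 + n1, 2 * n0 + n1)
    if n == 0 or n_rare == 0:
        return 1.0
    from scipy.special import gammaln

    # log-probabilities of each possible heterozygote count conditional on
    # the observed allele counts
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = []
    for h in het_values:
        r = (n_rare - h) // 2
        c = (2 * n - n_rare - h) // 2
        lp = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(r + 1)
            - gammaln(c + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )
        logp.append(lp)
    probs = np.exp(np.array(logp) - max(logp))
    probs /= probs.sum()
    obs_het = n1
    p_obs = probs[het_values == obs_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    dosages: np.ndarray,
    meta: list[SNPMeta],
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-4,
    phenotype: np.ndarray | None = None,
    hwe_controls_only: bool = False,
    hwe_exact: bool = False,
) -> tuple[np.ndarray, list[SNPMeta], pd.DataFrame]:
    """Drop SNPs failing missingness, MAF, HWE or duplicate-id filters.

    Returns the filtered matrix and metadata plus a removal log with one
    row per dropped SNP and the first failing reason among
    ``duplicate > missing > maf > hwe``.  ``hwe_controls_only`` restricts
    the HWE test to control individuals (requires ``phenotype``);
    ``hwe_exact`` switches from the 1-df chi-square to the exact test.
    """
    dosages = np.asarray(dosages, dtype=float)
    n_ind, m = dosages.shape
    if m != len(meta):
        raise ValueError("metadata length does not match matrix width")
    if m == 0 or n_ind == 0:
        raise ValueError("empty genotype panel")

    hwe_rows = np.ones(n_ind, dtype=bool)
    if hwe_controls_only:
        if phenotype is None:
            raise ValueError("hwe_controls_only requires a phenotype vector")
        hwe_rows = np.asarray(phenotype) == 0
    hwe_test = hwe_exact_p if hwe_exact else hwe_chi2_p

    seen: set[str] = set()
    keep = np.ones(m, dtype=bool)
    removed = []

    def drop(k: int, reason: str) -> None:
        keep[k] = False
        removed.append({"snp_id": meta[k].id, "reason": reason})

    for k in range(m):
        if meta[k].id in seen:
            drop(k, "duplicate")
            continue
        seen.add(meta[k].id)
        col = dosages[:, k]
        miss_frac = float(np.isnan(col).mean())
        if miss_frac > miss_max:
            drop(k, "missing")
            continue
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            drop(k, "missing")
            continue
        af1 = float(obs.mean() / 2)
        if min(af1, 1 - af1) < maf_min:
            drop(k, "maf")
            continue
        hcol = col[hwe_rows]
        hobs = hcol[~np.isnan(hcol)]
        counts = [int((hobs == d).sum()) for d in (0, 1, 2)]
        if hwe_test(*counts) < hwe_p_min:
            drop(k, "hwe")

    log = pd.DataFrame(removed, columns=["snp_id", "reason"])
    filtered_meta = [meta[k] for k in range(m) if keep[k]]
    return dosages[:, keep], filtered_meta, log
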