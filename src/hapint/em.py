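"""Two-locus pseudohaplotype frequency estimation by EM.

For two biallelic loci G (alleles G1/G2) and H (alleles H1/H2), unphased
genotype data determine the four haplotype counts unambiguously for every
genotype combination except the double heterozygote, whose two haplotypes are
either (G1H1, G2H2) ("cis") or (G1H2, G2H1) ("trans").  The EM algorithm
resolves this ambiguity by iterating the posterior phase probability

    phi = p11*p22 / (p11*p22 + p12*p21)

against the haplotype-frequency M-step.  For unlinked loci the estimated
quantities are *pseudo*-haplotype frequencies: joint frequencies of alleles
carried on the same parental gamete, estimable by exactly the same machinery.

The batch kernels at the bottom operate on stacked 3x3 tables and are the
workhorses of the simulation and genome-scan code paths; the dataclass API on
top of them serves single-pair analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoLocusCounts",
    "HaplotypeFreqs",
    "cross_tabulate",
    "em_haplotype_frequencies",
    "ld_coefficient",
]

#: frequencies below this are reported as exactly 0
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 cross-table of genotype combinations at two biallelic SNPs.

    ``n[i, j]`` counts individuals carrying ``i`` copies of allele G1 at the
    first locus and ``j`` copies of allele H1 at the second, ``i, j in
    {0, 1, 2}``.  Individuals with a missing genotype at either locus are not
    represented.
    """

    n: np.ndarray  # (3, 3) int array
    n_total: int

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=np.int64)
        if n.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {n.shape}")
        if (n < 0).any():
            raise ValueError("negative cell count")
        if int(n.sum()) != self.n_total:
            raise ValueError("cell counts do not sum to n_total")
        object.__setattr__(self, "n", n)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """EM-estimated frequencies of the four (pseudo)haplotypes.

    ``p11, p12, p21, p22`` are the frequencies of G1H1, G1H2, G2H1, G2H2.
    ``n_hap`` is the number of haplotypes behind the estimate (twice the
    number of complete individuals); ``loglik`` the final observed-data
    log-likelihood (up to data-dependent constants).
    """

    p11: float
    p12: float
    p21: float
    p22: float
    n_hap: int
    loglik: float
    converged: bool
    iterations: int

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p21, self.p22])

    @property
    def p_G1(self) -> float:
        """Marginal frequency of allele G1 implied by the haplotypes."""
        return self.p11 + self.p12

    @property
    def p_H1(self) -> float:
        return self.p11 + self.p21


_MISSING_OK = frozenset({0.0, 1.0, 2.0})


def _clean_dosages(g, h) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape or g.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    # missing may be encoded as NaN or any negative sentinel (-1, -9)
    miss = np.isnan(g) | np.isnan(h) | (g < 0) | (h < 0)
    gv, hv = g[~miss], h[~miss]
    for v in (gv, hv):
        bad = ~np.isin(v, list(_MISSING_OK))
        if bad.any():
            raise ValueError(f"invalid dosage code(s): {np.unique(v[bad])}")
    return gv, hv


def cross_tabulate(g, h) -> TwoLocusCounts:
    """Cross-tabulate dosage vectors at two loci into a :class:`TwoLocusCounts`.

    Dosages are counts of the reference allele in {0, 1, 2}; missing values
    (NaN or negative codes) at either locus drop the individual from the
    table (pairwise complete-case deletion).
    """
    gv, hv = _clean_dosages(g, h)
    table = np.bincount((gv * 3 + hv).astype(np.int64), minlength=9).reshape(3, 3)
    return TwoLocusCounts(n=table, n_total=int(table.sum()))


def _unambiguous_counts(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split stacked 3x3 tables into phase-known haplotype counts and the
    double-heterozygote count.

    Returns ``(a, d)`` with ``a[..., k]`` the counts of haplotypes
    (G1H1, G1H2, G2H1, G2H2) contributed by the eight unambiguous cells and
    ``d`` the number of double heterozygotes.
    """
    n = tables
    a11 = 2 * n[..., 2, 2] + n[..., 2, 1] + n[..., 1, 2]
    a12 = 2 * n[..., 2, 0] + n[..., 2, 1] + n[..., 1, 0]
    a21 = 2 * n[..., 0, 2] + n[..., 0, 1] + n[..., 1, 2]
    a22 = 2 * n[..., 0, 0] + n[..., 0, 1] + n[..., 1, 0]
    a = np.stack([a11, a12, a21, a22], axis=-1).astype(float)
    d = n[..., 1, 1].astype(float)
    return a, d


def _loglik(p: np.ndarray, a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Observed-data log-likelihood up to additive constants."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, a * np.log(np.where(p > 0, p, 1.0)), 0.0)
        # a > 0 with p == 0 has likelihood 0
        terms = np.where((a > 0) & (p <= 0), -np.inf, terms)
    dh = p[..., 0] * p[..., 3] + p[..., 1] * p[..., 2]
    with np.errstate(divide="ignore"):
        dh_term = np.where(d > 0, d * np.log(np.where(dh > 0, dh, 1.0)), 0.0)
        dh_term = np.where((d > 0) & (dh <= 0), -np.inf, dh_term)
    return terms.sum(axis=-1) + dh_term


def em_batch(
    tables: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over stacked genotype tables.

    Parameters
    ----------
    tables
        Integer array of shape ``(..., 3, 3)``.
    tol
        Convergence threshold on the maximum absolute frequency change.
    max_iter
        Iteration cap; tables still moving at the cap are flagged.

    Returns
    -------
    p, loglik, converged, iterations
        ``p`` has shape ``(..., 4)`` ordered (p11, p12, p21, p22).
    """
    tables = np.asarray(tables)
    a, d = _unambiguous_counts(tables)
    n_hap = a.sum(axis=-1) + 2 * d
    if (n_hap == 0).any():
        raise ValueError("empty genotype table (n_total = 0)")

    # linkage-equilibrium initialization from observed allele frequencies
    pG = (a[..., 0] + a[..., 1] + d) / n_hap
    pH = (a[..., 0] + a[..., 2] + d) / n_hap
    p = np.stack([pG * pH, pG * (1 - pH), (1 - pG) * pH, (1 - pG) * (1 - pH)], axis=-1)

    converged = np.zeros(p.shape[:-1], dtype=bool)
    iterations = np.zeros(p.shape[:-1], dtype=np.int64)
    nh = n_hap[..., None]
    for it in range(1, max_iter + 1):
        active = ~converged
        if not active.any():
            break
        cis = p[..., 0] * p[..., 3]
        trans = p[..., 1] * p[..., 2]
        den = cis + trans
        # both phase products zero: symmetric split
        phi = np.where(den > 0, cis / np.where(den > 0, den, 1.0), 0.5)
        w = np.stack([phi, 1 - phi, 1 - phi, phi], axis=-1)
        p_new = (a + d[..., None] * w) / nh
        delta = np.abs(p_new - p).max(axis=-1)
        newly = active & (delta < tol)
        iterations = np.where(active, it, iterations)
        converged |= newly
        p = np.where(active[..., None], p_new, p)

    p = np.where(p < _ZERO_TOL, 0.0, p)
    p = p / p.sum(axis=-1, keepdims=True)
    return p, _loglik(p, a, d), converged, iterations


def em_haplotype_frequencies(
    counts: TwoLocusCounts, tol: float = 1e-10, max_iter: int = 1000
) -> HaplotypeFreqs:
    """Maximum-likelihood (pseudo)haplotype frequencies for one table.

    All cells but the double heterozygote contribute phase-known haplotype
    counts; the double heterozygotes are fractionally assigned in the E-step
    with posterior weight ``p11*p22 / (p11*p22 + p12*p21)`` on the cis phase.
    The observed-data log-likelihood is non-decreasing across iterations.

    Raises
    ------
    ValueError
        If the table is empty (``n_total == 0``).
    """
    if counts.n_total == 0:
        raise ValueError("cannot estimate haplotype frequencies from 0 individuals")
    p, ll, conv, iters = em_batch(counts.n[None], tol=tol, max_iter=max_iter)
    return HaplotypeFreqs(
        p11=float(p[0, 0]),
        p12=float(p[0, 1]),
        p21=float(p[0, 2]),
        p22=float(p[0, 3]),
        n_hap=2 * counts.n_total,
        loglik=float(ll[0]),
        converged=bool(conv[0]),
        iterations=int(iters[0]),
    )


def ld_coefficient(freqs: HaplotypeFreqs) -> float:
    """Linkage-disequilibrium coefficient D = p11 - pG1 * pH1.

    Zero iff the G1H1 haplotype frequency equals the product of its allele
    frequencies; bounded in [-0.25, 0.25].
    """
    return float(freqs.p11 - freqs.p_G1 * freqs.p_H1)
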