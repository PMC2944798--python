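"""Interaction tests for pairs of biallelic loci in case-control data.

The central statistic, here tagged ``T_IH``, measures multiplicative
gene-gene interaction on the odds scale through (pseudo)haplotype
frequencies: with case frequencies (p11, p12, p21, p22) and control
frequencies (q11, q12, q21, q22),

    I = ln[(p11 p22)/(p12 p21)] - ln[(q11 q22)/(q12 q21)]

is zero exactly when the haplotype cross-ratio is the same in cases and
controls — the no-interaction condition.  The delta method gives

    Var(I) = (1/2nA) * sum(1/p) + (1/2nG) * sum(1/q)

with nA, nG the case and control sample sizes, and T = I^2 / Var(I) is
asymptotically chi-square with 1 df under the null.  A case-only variant
drops the control term (valid for unlinked loci), and two comparators are
provided: the allele-based "fast-epistasis" test (no EM phase resolution;
double heterozygotes split half-and-half) and the logistic-regression Wald
test for a product term under recessive / dominant / additive codings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .em import (
    HaplotypeFreqs,
    TwoLocusCounts,
    _unambiguous_counts,
    cross_tabulate,
    em_batch,
    em_haplotype_frequencies,
)

__all__ = [
    "InteractionResult",
    "interaction_measure",
    "interaction_variance",
    "haplotype_sampling_variance",
    "unphased_sampling_variance",
    "test_interaction",
    "test_interaction_case_only",
    "fast_epistasis",
    "code_genotypes",
    "logistic_interaction",
]

#: EM frequencies below this trigger the continuity correction
ZERO_FREQ_TOL = 1e-8

_METHODS = (
    "T_IH",
    "T_IH_case_only",
    "fast_epistasis",
    "logistic_recessive",
    "logistic_dominant",
    "logistic_additive",
)


class ZeroCellError(ValueError):
    """A haplotype frequency or allele-table cell is zero and no correction
    was applied; the log odds-ratio / variance is undefined."""


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of one pairwise interaction test.

    ``statistic`` is chi-square with 1 df; for the odds-ratio based methods
    it equals ``measure**2 / variance``.  ``evaluable=False`` marks pairs
    where the test could not be computed (degenerate table, separation, ...)
    with the reason in ``reason``.
    """

    measure: float
    variance: float
    statistic: float
    p_value: float
    method: str
    df: int = 1
    correction_applied: bool = False
    evaluable: bool = True
    reason: str | None = None
    case_freqs: HaplotypeFreqs | None = field(default=None, repr=False)
    ctrl_freqs: HaplotypeFreqs | None = field(default=None, repr=False)


def _not_evaluable(method: str, reason: str) -> InteractionResult:
    return InteractionResult(
        measure=np.nan,
        variance=np.nan,
        statistic=np.nan,
        p_value=np.nan,
        method=method,
        evaluable=False,
        reason=reason,
    )


def _chi2_sf(statistic):
    p = sps.chi2.sf(statistic, df=1)
    # clamp underflow into the open-at-zero interval the result contract wants
    return np.maximum(p, np.finfo(float).tiny)


def interaction_measure(case: HaplotypeFreqs, ctrl: HaplotypeFreqs) -> float:
    """Difference of log haplotype cross-ratios, cases minus controls.

    Raises :class:`ZeroCellError` if any of the eight frequencies is zero;
    callers apply a continuity correction first (see :func:`test_interaction`)
    or treat the pair as non-evaluable.
    """
    p = case.as_array()
    q = ctrl.as_array()
    if (p <= 0).any() or (q <= 0).any():
        raise ZeroCellError("zero haplotype frequency; apply a continuity correction")
    return float(
        np.log(p[0] * p[3] / (p[1] * p[2])) - np.log(q[0] * q[3] / (q[1] * q[2]))
    )


def haplotype_sampling_variance(freqs: HaplotypeFreqs, n: int) -> float:
    """Variance of one group's log cross-ratio if haplotypes were observed.

    ``(1/2n) * sum_k 1/p_k`` — the delta-method variance under direct
    multinomial sampling of 2n haplotypes.  This understates the sampling
    variance of EM estimates from *unphased* genotypes, where double
    heterozygotes carry no information about the cross-ratio; see
    :func:`unphased_sampling_variance`.
    """
    p = freqs.as_array()
    if (p <= 0).any():
        raise ZeroCellError("zero haplotype frequency; apply a continuity correction")
    return float((1 / p).sum() / (2 * n))


# haplotype a carries G1 for a in {0,1}, H1 for a in {0,2}
_G_DOSE = np.array([1, 1, 0, 0])
_H_DOSE = np.array([1, 0, 1, 0])
# genotype cell index (3*i + j) reached by an unordered pair of haplotypes
_CELL = 3 * (_G_DOSE[:, None] + _G_DOSE[None, :]) + (
    _H_DOSE[:, None] + _H_DOSE[None, :]
)
# T[c, a, b] = 1 if haplotype pair (a, b) produces genotype cell c
_PAIR_TO_CELL = np.zeros((9, 4, 4))
for _a in range(4):
    for _b in range(4):
        _PAIR_TO_CELL[_CELL[_a, _b], _a, _b] = 1.0
# free parameters theta = (p11, p12, p21); dp/dtheta
_DP_DTHETA = np.array(
    [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [-1.0, -1.0, -1.0]]
)


def unphased_sampling_variance(p: np.ndarray, n) -> np.ndarray:
    """Asymptotic variance of the log cross-ratio from unphased genotypes.

    Delta method through the expected Fisher information of the observed
    multinomial genotype likelihood under random union of gametes: with
    genotype cell probabilities pi_c(theta) quadratic in the haplotype
    frequencies (theta the three free frequencies),

        J = n * sum_c (d pi_c/d theta)(d pi_c/d theta)' / pi_c
        Var = g' J^{-1} g,   g = d log cross-ratio / d theta.

    Unlike the phase-known form this accounts for the information lost to
    double-heterozygote phase ambiguity.  Vectorized over leading axes of
    ``p`` (shape (..., 4)); ``n`` broadcasts.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.einsum("cab,...a,...b->...c", _PAIR_TO_CELL, p, p)
    dpi_dp = 2 * np.einsum("cab,...b->...ca", _PAIR_TO_CELL, p)
    dpi = dpi_dp @ _DP_DTHETA  # (..., 9, 3)
    pi_safe = np.maximum(pi, 1e-300)
    J = np.einsum("...ca,...cb->...ab", dpi / pi_safe[..., None], dpi)
    J = J * n[..., None, None]
    g_p = np.stack(
        [1 / p[..., 0], -1 / p[..., 1], -1 / p[..., 2], 1 / p[..., 3]], axis=-1
    )
    g = g_p @ _DP_DTHETA  # (..., 3)
    sol = np.linalg.solve(J, g[..., None])[..., 0]
    return np.einsum("...a,...a->...", g, sol)


def interaction_variance(
    case: HaplotypeFreqs,
    ctrl: HaplotypeFreqs,
    n_cases: int,
    n_controls: int,
    phase_known: bool = False,
) -> float:
    """Delta-method variance of the interaction measure.

    By default each group contributes the variance of its log cross-ratio
    under the observed unphased-genotype likelihood
    (:func:`unphased_sampling_variance`), which is what keeps the T_IH null
    distribution chi-square(1).  ``phase_known=True`` instead uses the
    direct-haplotype form ``(1/2nA) sum 1/p + (1/2nG) sum 1/q``, appropriate
    when phase is actually observed.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("sample sizes must be >= 1")
    p = case.as_array()
    q = ctrl.as_array()
    if (p <= 0).any() or (q <= 0).any():
        raise ZeroCellError("zero haplotype frequency; apply a continuity correction")
    if phase_known:
        return haplotype_sampling_variance(case, n_cases) + haplotype_sampling_variance(
            ctrl, n_controls
        )
    return float(
        unphased_sampling_variance(p, np.asarray(float(n_cases)))
        + unphased_sampling_variance(q, np.asarray(float(n_controls)))
    )


def _correct_freqs(p: np.ndarray, n_hap: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Haldane-Anscombe style continuity correction, vectorized.

    Where any frequency is (numerically) zero, add 0.5 to each of the four
    expected haplotype counts and renormalize.  Returns corrected
    frequencies and a boolean mask of groups that were corrected.
    """
    needs = (p < ZERO_FREQ_TOL).any(axis=-1)
    nh = n_hap[..., None] if np.ndim(n_hap) else np.asarray(n_hap, float)
    corrected = (p * nh + 0.5) / (nh + 2.0)
    out = np.where(needs[..., None], corrected, p)
    return out, needs


def tih_batch(
    case_tables: np.ndarray, ctrl_tables: np.ndarray | None
) -> dict[str, np.ndarray]:
    """Vectorized T_IH over stacked case/control genotype tables.

    ``ctrl_tables=None`` gives the case-only statistic.  Returns arrays
    ``measure, variance, statistic, p_value, corrected`` keyed by name.
    """
    case_tables = np.asarray(case_tables)
    p, _, _, _ = em_batch(case_tables)
    n_case = case_tables.sum(axis=(-1, -2))
    p, corr_case = _correct_freqs(p, 2 * n_case)
    logcr_case = np.log(p[..., 0] * p[..., 3] / (p[..., 1] * p[..., 2]))
    var_case = unphased_sampling_variance(p, n_case)

    if ctrl_tables is None:
        measure = logcr_case
        variance = var_case
        corrected = corr_case
    else:
        ctrl_tables = np.asarray(ctrl_tables)
        q, _, _, _ = em_batch(ctrl_tables)
        n_ctrl = ctrl_tables.sum(axis=(-1, -2))
        q, corr_ctrl = _correct_freqs(q, 2 * n_ctrl)
        logcr_ctrl = np.log(q[..., 0] * q[..., 3] / (q[..., 1] * q[..., 2]))
        measure = logcr_case - logcr_ctrl
        variance = var_case + unphased_sampling_variance(q, n_ctrl)
        corrected = corr_case | corr_ctrl

    statistic = measure**2 / variance
    return {
        "measure": measure,
        "variance": variance,
        "statistic": statistic,
        "p_value": _chi2_sf(statistic),
        "corrected": corrected,
    }


def _freqs_with_correction(
    counts: TwoLocusCounts,
) -> tuple[HaplotypeFreqs, bool]:
    f = em_haplotype_frequencies(counts)
    p = f.as_array()
    p_corr, needs = _correct_freqs(p, np.asarray(float(f.n_hap)))
    if bool(needs):
        f = HaplotypeFreqs(
            p11=float(p_corr[0]),
            p12=float(p_corr[1]),
            p21=float(p_corr[2]),
            p22=float(p_corr[3]),
            n_hap=f.n_hap,
            loglik=f.loglik,
            converged=f.converged,
            iterations=f.iterations,
        )
    return f, bool(needs)


def test_interaction(case_g, case_h, ctrl_g, ctrl_h) -> InteractionResult:
    """Case-control pseudohaplotype odds-ratio interaction test (T_IH).

    Pipeline: cross-tabulate each group, EM haplotype frequencies per group,
    continuity correction for zero frequencies, interaction measure and
    delta-method variance, T = I^2/Var against chi-square(1).
    """
    try:
        case_counts = cross_tabulate(case_g, case_h)
        ctrl_counts = cross_tabulate(ctrl_g, ctrl_h)
    except ValueError as exc:
        return _not_evaluable("T_IH", str(exc))
    if case_counts.n_total == 0 or ctrl_counts.n_total == 0:
        return _not_evaluable("T_IH", "no complete individuals in a group")

    case_f, corr1 = _freqs_with_correction(case_counts)
    ctrl_f, corr2 = _freqs_with_correction(ctrl_counts)
    measure = interaction_measure(case_f, ctrl_f)
    variance = interaction_variance(
        case_f, ctrl_f, case_counts.n_total, ctrl_counts.n_total
    )
    statistic = measure**2 / variance
    return InteractionResult(
        measure=measure,
        variance=variance,
        statistic=statistic,
        p_value=float(_chi2_sf(statistic)),
        method="T_IH",
        correction_applied=corr1 or corr2,
        case_freqs=case_f,
        ctrl_freqs=ctrl_f,
    )


def test_interaction_case_only(case_g, case_h) -> InteractionResult:
    """Case-only interaction test: the case log cross-ratio against its own
    delta-method variance.  Valid for unlinked loci (population-level
    linkage equilibrium), where the control cross-ratio is 1 by assumption.
    """
    try:
        counts = cross_tabulate(case_g, case_h)
    except ValueError as exc:
        return _not_evaluable("T_IH_case_only", str(exc))
    if counts.n_total == 0:
        return _not_evaluable("T_IH_case_only", "no complete individuals")
    f, corr = _freqs_with_correction(counts)
    p = f.as_array()
    measure = float(np.log(p[0] * p[3] / (p[1] * p[2])))
    variance = float(unphased_sampling_variance(p, np.asarray(float(counts.n_total))))
    statistic = measure**2 / variance
    return InteractionResult(
        measure=measure,
        variance=variance,
        statistic=statistic,
        p_value=float(_chi2_sf(statistic)),
        method="T_IH_case_only",
        correction_applied=corr,
        case_freqs=f,
    )


def _allele_pair_table(tables: np.ndarray) -> np.ndarray:
    """2x2 allele-pair count tables: phase-known haplotypes counted directly,
    each double heterozygote's two haplotypes split 0.5/0.5 between the cis
    and trans resolutions (no EM).  Shape (..., 4) ordered as em counts."""
    a, d = _unambiguous_counts(np.asarray(tables))
    return a + 0.5 * d[..., None]


def fast_epistasis_batch(
    case_tables: np.ndarray, ctrl_tables: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized allele-based (Woolf-type) interaction test."""
    out = []
    corrected = None
    for tables in (case_tables, ctrl_tables):
        c = _allele_pair_table(tables)
        zero = (c == 0).any(axis=-1)
        c = np.where(zero[..., None], c + 0.5, c)
        corrected = zero if corrected is None else (corrected | zero)
        ln_or = np.log(c[..., 0] * c[..., 3] / (c[..., 1] * c[..., 2]))
        se2 = (1 / c).sum(axis=-1)
        out.append((ln_or, se2))
    (or_case, se2_case), (or_ctrl, se2_ctrl) = out
    measure = or_case - or_ctrl
    variance = se2_case + se2_ctrl
    statistic = measure**2 / variance
    return {
        "measure": measure,
        "variance": variance,
        "statistic": statistic,
        "p_value": _chi2_sf(statistic),
        "corrected": corrected,
    }


def fast_epistasis(case_g, case_h, ctrl_g, ctrl_h) -> InteractionResult:
    """Allele-based odds-ratio interaction comparator ("fast-epistasis").

    Compares the log allele-pair odds ratio between cases and controls with
    Woolf SEs (sum of reciprocal cell counts); double heterozygotes are
    split equally between phases rather than EM-resolved, which is what
    distinguishes it from T_IH.  Zero cells get the 0.5 table-wide
    continuity correction.
    """
    try:
        case_counts = cross_tabulate(case_g, case_h)
        ctrl_counts = cross_tabulate(ctrl_g, ctrl_h)
    except ValueError as exc:
        return _not_evaluable("fast_epistasis", str(exc))
    if case_counts.n_total == 0 or ctrl_counts.n_total == 0:
        return _not_evaluable("fast_epistasis", "no complete individuals in a group")
    r = fast_epistasis_batch(case_counts.n[None], ctrl_counts.n[None])
    return InteractionResult(
        measure=float(r["measure"][0]),
        variance=float(r["variance"][0]),
        statistic=float(r["statistic"][0]),
        p_value=float(r["p_value"][0]),
        method="fast_epistasis",
        correction_applied=bool(r["corrected"][0]),
    )


_CODINGS = {
    "recessive": np.array([0.0, 0.0, 1.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "additive": np.array([0.0, 1.0, 2.0]),
}


def code_genotypes(g, model: str) -> np.ndarray:
    """Recode risk-allele dosages under a genetic model.

    recessive: (0,1,2) -> (0,0,1); dominant: -> (0,1,1); additive: -> (0,1,2).
    Missing values (NaN / negative) propagate as NaN.
    """
    if model not in _CODINGS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_CODINGS)}")
    g = np.asarray(g, dtype=float)
    miss = np.isnan(g) | (g < 0)
    idx = np.where(miss, 0, g).astype(np.int64)
    if not np.isin(g[~miss], [0.0, 1.0, 2.0]).all():
        raise ValueError("dosages must be in {0, 1, 2} or missing")
    coded = _CODINGS[model][idx]
    return np.where(miss, np.nan, coded)


def _grouped_design(case_t: np.ndarray, ctrl_t: np.ndarray, coding: str):
    """Collapse case/control 3x3 tables to the 9 genotype patterns for a
    binomial GLM fit (identical likelihood to individual-level logistic)."""
    i, j = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    gc = _CODINGS[coding][i.ravel()]
    hc = _CODINGS[coding][j.ravel()]
    X = np.column_stack([np.ones(9), gc, hc, gc * hc])
    y_case = case_t.ravel().astype(float)
    y_ctrl = ctrl_t.ravel().astype(float)
    keep = (y_case + y_ctrl) > 0
    return X[keep], y_case[keep], y_ctrl[keep]


def logistic_interaction(
    case_g, case_h, ctrl_g, ctrl_h, coding: str = "additive", lrt: bool = False
) -> InteractionResult:
    """Logistic-regression interaction comparator.

    Fits logit P(case) = b0 + b1*G + b2*H + b3*G*H on genotypes coded under
    ``coding`` and tests b3 = 0 with a 1-df Wald chi-square (or a
    likelihood-ratio test when ``lrt=True``).  Fit by ML on the nine
    genotype-pattern binomial counts, which is likelihood-identical to the
    individual-level fit.
    """
    import statsmodels.api as sm

    if coding not in _CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    method = f"logistic_{coding}"
    try:
        case_counts = cross_tabulate(case_g, case_h)
        ctrl_counts = cross_tabulate(ctrl_g, ctrl_h)
    except ValueError as exc:
        return _not_evaluable(method, str(exc))
    if case_counts.n_total == 0 or ctrl_counts.n_total == 0:
        return _not_evaluable(method, "no complete individuals in a group")

    X, y_case, y_ctrl = _grouped_design(case_counts.n, ctrl_counts.n, coding)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _not_evaluable(method, "rank-deficient design after coding")
    endog = np.column_stack([y_case, y_ctrl])
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            b3 = float(fit.params[3])
            se3 = float(fit.bse[3])
            if lrt:
                null = sm.GLM(endog, X[:, :3], family=sm.families.Binomial()).fit()
                statistic = float(2 * (fit.llf - null.llf))
            else:
                statistic = (b3 / se3) ** 2
    except Exception as exc:  # separation / non-convergence
        return _not_evaluable(method, f"fit failed: {exc}")
    if not np.isfinite(statistic) or se3 > 1e6:
        return _not_evaluable(method, "separation or unstable fit")
    return InteractionResult(
        measure=b3,
        variance=se3**2,
        statistic=statistic,
        p_value=float(_chi2_sf(statistic)),
        method=method,
    )
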