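"""Two-locus population simulation, type-I-error and power estimation.

Populations are parameterized by the two allele frequencies and the linkage
disequilibrium coefficient D; individuals are random unions of two gametes
drawn from the implied four-haplotype distribution (Hardy-Weinberg at the
haplotype level).  Disease status follows a two-locus multiplicative-odds
penetrance model

    odds(i, j) = delta * lambda1^x(i) * lambda2^y(j) * lambda3^(x(i)*y(j))

with x, y the recessive / dominant / additive scores of the genotypes and
the baseline delta solved so the population prevalence equals f0.

Null calibration follows the finite-population design: a general population
is generated once and each replicate samples "cases" and "controls" from it
at random with no phenotype model, making the null exact.  Power is
estimated by ascertaining case-control samples under a disease model and
applying the chosen test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats
from .em import em_batch

__all__ = [
    "PopulationSpec",
    "DiseaseModel",
    "haplotype_distribution",
    "genotype_distribution",
    "simulate_genotypes",
    "penetrance_table",
    "ascertain",
    "estimate_type1_error",
    "estimate_power",
    "write_report",
    "read_report",
]

#: default null-calibration scenarios: common alleles with LD (two
#: frequency settings), used by the calibration suite and acceptance script
NULL_SCENARIOS = {
    "scenario1": dict(p_G1=0.5, p_H1=0.5, D=0.1),
    "scenario2": dict(p_G1=0.3, p_H1=0.3, D=0.05),
}

REPORT_COLUMNS = [
    "test", "model", "lambda1", "lambda2", "lambda3", "f0",
    "pG", "pH", "D", "n", "alpha", "reps", "seed", "rate", "mc_se",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Two-locus population: allele frequencies and LD coefficient.

    ``p_G1`` and ``p_H1`` are the frequencies of alleles G1 and H1; ``D`` is
    the disequilibrium coefficient so that the G1H1 haplotype frequency is
    ``p_G1 * p_H1 + D``.  D must respect the Frechet bounds that keep all
    four haplotype frequencies in [0, 1].
    """

    p_G1: float = 0.5
    p_H1: float = 0.5
    D: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.p_G1 < 1 and 0 < self.p_H1 < 1):
            raise ValueError("allele frequencies must be in (0, 1)")
        lo = max(-self.p_G1 * self.p_H1, -(1 - self.p_G1) * (1 - self.p_H1))
        hi = min(self.p_G1 * (1 - self.p_H1), (1 - self.p_G1) * self.p_H1)
        if not (lo <= self.D <= hi):
            raise ValueError(
                f"D={self.D} outside Frechet bounds [{lo:.4g}, {hi:.4g}]"
            )


def haplotype_distribution(spec: PopulationSpec) -> np.ndarray:
    """Haplotype probabilities (p11, p12, p21, p22) implied by the spec."""
    pG, pH, D = spec.p_G1, spec.p_H1, spec.D
    probs = np.array(
        [pG * pH + D, pG * (1 - pH) - D, (1 - pG) * pH - D, (1 - pG) * (1 - pH) + D]
    )
    # Frechet bounds already validated; clip numerical dust only
    return np.clip(probs, 0.0, 1.0)


def genotype_distribution(hap_probs: np.ndarray) -> np.ndarray:
    """3x3 joint genotype distribution under random union of gametes.

    Entry (i, j) is the probability of carrying i copies of G1 and j copies
    of H1 given two independent haplotype draws.
    """
    q = np.asarray(hap_probs, dtype=float)
    # haplotype k carries G1 for k in {0,1} and H1 for k in {0,2}
    g_dose = np.array([1, 1, 0, 0])
    h_dose = np.array([1, 0, 1, 0])
    P = np.zeros((3, 3))
    for a in range(4):
        for b in range(4):
            P[g_dose[a] + g_dose[b], h_dose[a] + h_dose[b]] += q[a] * q[b]
    return P


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    n: int, spec: PopulationSpec, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage vectors at both loci for ``n`` random-mating individuals.

    Each individual is the union of two haplotypes drawn i.i.d. from the
    population haplotype distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    probs = haplotype_distribution(spec)
    haps = rng.choice(4, size=(n, 2), p=probs)
    g = (haps <= 1).sum(axis=1)  # haplotypes 0,1 carry G1
    h = ((haps == 0) | (haps == 2)).sum(axis=1)  # haplotypes 0,2 carry H1
    return g.astype(np.int64), h.astype(np.int64)


_SCORES = {
    "recessive": np.array([0.0, 0.0, 1.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "additive": np.array([0.0, 1.0, 2.0]),
}


@dataclass(frozen=True)
class DiseaseModel:
    """Two-locus multiplicative-odds disease model.

    ``lambda1``/``lambda2`` are the marginal genotype odds ratios at the two
    loci, ``lambda3`` the interaction odds ratio, applied on the scale of
    the mode-specific genotype scores; ``f0`` is the population prevalence
    the baseline odds is calibrated to.
    """

    mode_G: str = "dominant"
    mode_H: str = "dominant"
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    f0: float = 0.1

    def __post_init__(self) -> None:
        for mode in (self.mode_G, self.mode_H):
            if mode not in _SCORES:
                raise ValueError(f"unknown mode {mode!r}")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("odds ratios must be >= 0")
        if not (0 < self.f0 < 1):
            raise ValueError("prevalence f0 must be in (0, 1)")


def penetrance_table(
    model: DiseaseModel, spec: PopulationSpec, tol: float = 1e-12
) -> np.ndarray:
    """3x3 penetrance matrix with baseline solved to match prevalence f0.

    Cell (i, j) is P(disease | i copies of risk allele at locus 1, j at
    locus 2) = odds/(1+odds) with odds = delta * lambda1^x * lambda2^y *
    lambda3^(x*y); delta > 0 is found by bisection so that the prevalence
    E[f] under the genotype distribution implied by ``spec`` equals f0.
    """
    x = _SCORES[model.mode_G]
    y = _SCORES[model.mode_H]
    mult = (
        model.lambda1 ** x[:, None]
        * model.lambda2 ** y[None, :]
        * model.lambda3 ** (x[:, None] * y[None, :])
    )
    if not np.all(np.isfinite(mult)) or np.all(mult == 0):
        raise ValueError("degenerate odds-ratio parameters")
    P = genotype_distribution(haplotype_distribution(spec))

    def prevalence(delta: float) -> float:
        odds = delta * mult
        return float((P * (odds / (1 + odds))).sum())

    lo, hi = 1e-12, 1e12
    if not (prevalence(lo) <= model.f0 <= prevalence(hi)):
        raise ValueError("no admissible baseline odds for this prevalence")
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < model.f0:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    odds = delta * mult
    return odds / (1 + odds)


def ascertain(
    n_case: int,
    n_ctrl: int,
    spec: PopulationSpec,
    model: DiseaseModel,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Case-control sample by rejection sampling from the population.

    Individuals are drawn from the population, assigned affected status with
    probability given by the penetrance of their joint genotype, and
    accumulated until both groups are filled.  Returns ``(cases, controls)``
    as (n, 2) dosage matrices with columns (locus G, locus H).
    """
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("group sizes must be >= 1")
    rng = _as_rng(seed)
    f = penetrance_table(model, spec)
    prev = float((genotype_distribution(haplotype_distribution(spec)) * f).sum())
    if prev <= 0 or prev >= 1:
        raise ValueError("ascertainment impossible: prevalence at boundary")
    probs = haplotype_distribution(spec)
    cases, ctrls = [], []
    need_case, need_ctrl = n_case, n_ctrl
    while need_case > 0 or need_ctrl > 0:
        batch = max(4096, int(2 * (need_case / max(prev, 1e-6) + need_ctrl)))
        haps = rng.choice(4, size=(batch, 2), p=probs)
        g = (haps <= 1).sum(axis=1)
        h = ((haps == 0) | (haps == 2)).sum(axis=1)
        affected = rng.random(batch) < f[g, h]
        geno = np.column_stack([g, h])
        if need_case > 0:
            take = geno[affected][:need_case]
            cases.append(take)
            need_case -= len(take)
        if need_ctrl > 0:
            take = geno[~affected][:need_ctrl]
            ctrls.append(take)
            need_ctrl -= len(take)
    return np.concatenate(cases), np.concatenate(ctrls)


def _population_table(
    rng: np.random.Generator, spec: PopulationSpec, pop_size: int
) -> np.ndarray:
    """9-cell genotype counts of a finite general population."""
    g, h = simulate_genotypes(pop_size, spec, rng)
    return np.bincount(g * 3 + h, minlength=9).reshape(3, 3)


def _pvalues_for_tables(
    case_tables: np.ndarray, ctrl_tables: np.ndarray, test: str
) -> np.ndarray:
    """Dispatch a named test over stacked case/control genotype tables."""
    if test == "tih":
        return _stats.tih_batch(case_tables, ctrl_tables)["p_value"]
    if test == "case_only":
        return _stats.tih_batch(case_tables, None)["p_value"]
    if test == "fast":
        return _stats.fast_epistasis_batch(case_tables, ctrl_tables)["p_value"]
    if test.startswith("logistic_"):
        coding = test.removeprefix("logistic_")
        pvals = np.empty(len(case_tables))
        for k in range(len(case_tables)):
            res = _logistic_from_tables(case_tables[k], ctrl_tables[k], coding)
            pvals[k] = res
        return pvals
    raise ValueError(f"unknown test tag {test!r}")


def _logistic_from_tables(case_t, ctrl_t, coding: str) -> float:
    """p-value of the logistic Wald interaction test from 3x3 count tables;
    NaN when not evaluable."""
    import statsmodels.api as sm
    from scipy import stats as sps

    X, y_case, y_ctrl = _stats._grouped_design(case_t, ctrl_t, coding)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return np.nan
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(
                np.column_stack([y_case, y_ctrl]), X, family=sm.families.Binomial()
            ).fit()
        z2 = (fit.params[3] / fit.bse[3]) ** 2
    except Exception:
        return np.nan
    if not np.isfinite(z2) or fit.bse[3] > 1e6:
        return np.nan
    return float(sps.chi2.sf(z2, df=1))


def estimate_type1_error(
    spec: PopulationSpec,
    n_per_group: int,
    reps: int = 10_000,
    alphas=(0.05, 0.01, 0.001),
    seed=None,
    pop_size: int = 100_000,
    test: str = "tih",
) -> pd.DataFrame:
    """Empirical type I error of an interaction test under the exact null.

    A finite general population of ``pop_size`` individuals is generated
    from ``spec``; each replicate samples ``n_per_group`` "cases" and
    ``n_per_group`` "controls" from it without replacement (no phenotype
    model, so no interaction exists by construction), applies the test, and
    records rejection at each nominal level.

    Returns a tidy report with one row per alpha (columns
    :data:`REPORT_COLUMNS`), including the Monte-Carlo standard error
    ``sqrt(rate*(1-rate)/reps)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _as_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    pop = _population_table(rng, spec, pop_size).ravel()

    case_tables = np.empty((reps, 3, 3), dtype=np.int64)
    ctrl_tables = np.empty((reps, 3, 3), dtype=np.int64)
    for r in range(reps):
        c1 = rng.multivariate_hypergeometric(pop, n_per_group)
        c2 = rng.multivariate_hypergeometric(pop - c1, n_per_group)
        case_tables[r] = c1.reshape(3, 3)
        ctrl_tables[r] = c2.reshape(3, 3)

    pvals = _pvalues_for_tables(case_tables, ctrl_tables, test)
    ok = np.isfinite(pvals)
    rows = []
    for alpha in alphas:
        rate = float((pvals[ok] < alpha).mean()) if alpha < 1.0 else 1.0
        rows.append({
            "test": test, "model": "null",
            "lambda1": 1.0, "lambda2": 1.0, "lambda3": 1.0, "f0": np.nan,
            "pG": spec.p_G1, "pH": spec.p_H1, "D": spec.D,
            "n": n_per_group, "alpha": alpha, "reps": reps, "seed": seed_repr,
            "rate": rate, "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _ascertain_tables(
    rng: np.random.Generator,
    n_case: int,
    n_ctrl: int,
    P: np.ndarray,
    f: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype count tables of an ascertained case-control sample.

    Sequential rejection sampling conditioned on the two group totals makes
    the case (control) genotype counts exactly multinomial with cell
    probabilities proportional to P*f (P*(1-f)); sampled directly.
    """
    w_case = (P * f).ravel()
    w_ctrl = (P * (1 - f)).ravel()
    c_case = rng.multinomial(n_case, w_case / w_case.sum()).reshape(3, 3)
    c_ctrl = rng.multinomial(n_ctrl, w_ctrl / w_ctrl.sum()).reshape(3, 3)
    return c_case, c_ctrl


def estimate_power(
    spec: PopulationSpec,
    model: DiseaseModel,
    lambda3_grid,
    test: str = "tih",
    n_per_group: int = 1000,
    reps: int = 2000,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Power of a named test across a grid of interaction odds ratios.

    For each ``lambda3`` in the grid, ``reps`` case-control samples of
    ``n_per_group`` per group are ascertained under the disease model (with
    ``model.lambda3`` replaced by the grid value) and the test applied at
    level ``alpha``; the rejection fraction and its MC standard error are
    reported per grid point.
    """
    from dataclasses import replace

    lambda3_grid = list(lambda3_grid)
    if not lambda3_grid:
        raise ValueError("lambda3_grid must be nonempty")
    rng = _as_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    P = genotype_distribution(haplotype_distribution(spec))

    rows = []
    for lam3 in lambda3_grid:
        m = replace(model, lambda3=float(lam3))
        f = penetrance_table(m, spec)
        case_tables = np.empty((reps, 3, 3), dtype=np.int64)
        ctrl_tables = np.empty((reps, 3, 3), dtype=np.int64)
        for r in range(reps):
            case_tables[r], ctrl_tables[r] = _ascertain_tables(
                rng, n_per_group, n_per_group, P, f
            )
        pvals = _pvalues_for_tables(case_tables, ctrl_tables, test)
        ok = np.isfinite(pvals)
        rate = float((pvals[ok] < alpha).mean())
        rows.append({
            "test": test, "model": f"{m.mode_G}x{m.mode_H}",
            "lambda1": m.lambda1, "lambda2": m.lambda2, "lambda3": float(lam3),
            "f0": m.f0, "pG": spec.p_G1, "pH": spec.p_H1, "D": spec.D,
            "n": n_per_group, "alpha": alpha, "reps": reps, "seed": seed_repr,
            "rate": rate, "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


#: default conditions for the power comparisons, one per two-locus model
#: family; chosen so the haplotype statistic's linked-loci regime (where its
#: power advantage over genotype-level tests appears) is represented
POWER_CONDITIONS = {
    "dominant": dict(
        spec=PopulationSpec(0.5, 0.5, 0.05),
        model=DiseaseModel("dominant", "dominant", 2.0, 2.0, 1.0, 0.1),
        n_per_group=1000,
    ),
    "recessive": dict(
        spec=PopulationSpec(0.6, 0.6, 0.1),
        model=DiseaseModel("recessive", "recessive", 2.0, 2.0, 1.0, 0.1),
        n_per_group=2000,
    ),
    "additive": dict(
        spec=PopulationSpec(0.5, 0.5, 0.05),
        model=DiseaseModel("additive", "additive", 1.5, 1.5, 1.0, 0.1),
        n_per_group=1000,
    ),
}


def compare_power(
    spec: PopulationSpec,
    model: DiseaseModel,
    lambda3_grid,
    tests=("tih", "fast"),
    n_per_group: int = 1000,
    reps: int = 2000,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Paired power comparison: all tests applied to the same replicates.

    Like :func:`estimate_power` but a single simulation stream feeds every
    test, so power differences between tests are free of between-stream
    Monte-Carlo noise.  Returns the same tidy report with one row per
    (lambda3, test).
    """
    from dataclasses import replace

    rng = _as_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    P = genotype_distribution(haplotype_distribution(spec))
    rows = []
    for lam3 in lambda3_grid:
        m = replace(model, lambda3=float(lam3))
        f = penetrance_table(m, spec)
        case_tables = np.empty((reps, 3, 3), dtype=np.int64)
        ctrl_tables = np.empty((reps, 3, 3), dtype=np.int64)
        for r in range(reps):
            case_tables[r], ctrl_tables[r] = _ascertain_tables(
                rng, n_per_group, n_per_group, P, f
            )
        for test in tests:
            pvals = _pvalues_for_tables(case_tables, ctrl_tables, test)
            ok = np.isfinite(pvals)
            rate = float((pvals[ok] < alpha).mean())
            rows.append({
                "test": test, "model": f"{m.mode_G}x{m.mode_H}",
                "lambda1": m.lambda1, "lambda2": m.lambda2,
                "lambda3": float(lam3), "f0": m.f0,
                "pG": spec.p_G1, "pH": spec.p_H1, "D": spec.D,
                "n": n_per_group, "alpha": alpha, "reps": reps,
                "seed": seed_repr, "rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path) -> None:
    """Write a simulation report as a tab-separated table."""
    report.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
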