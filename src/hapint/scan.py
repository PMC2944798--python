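"""Pairwise genome-scan harness: pair enumeration, chunked testing,
p-value storage thresholding, BH-FDR, QQ diagnostics, and replication.

At genome scale the number of SNP pairs (m(m-1)/2) makes storing every
result impossible, so the scanner only emits pairs with p at or below a
storage threshold while carrying the *total* number of tested pairs in its
metadata — the FDR step must use that total as the family size, not the
number of stored results.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from . import stats as _stats
from .io import SNPMeta
from .simulate import _logistic_from_tables

__all__ = [
    "pair_count",
    "enumerate_pairs",
    "scan",
    "bh_fdr",
    "qq_points",
    "ReplicationReport",
    "two_stage_bonferroni_replication",
    "replication_intersect",
]

RESULT_COLUMNS = [
    "snp1", "snp2", "chrom1", "pos1", "chrom2", "pos2",
    "method", "statistic", "p_value", "flags",
]


def pair_count(m: int) -> int:
    """Number of unordered SNP pairs, m(m-1)/2."""
    return m * (m - 1) // 2


def enumerate_pairs(
    snp_ids: list[str],
    source: str = "all",
    pairs: Iterable[tuple[str, str]] | None = None,
) -> tuple[Iterator[tuple[str, str]], int]:
    """Stream each unordered SNP pair exactly once, with its total count.

    ``source="all"`` enumerates all m(m-1)/2 pairs in the given id order;
    ``source="pair-file"`` restricts to the supplied ``pairs``, each emitted
    in the canonical orientation of the id list.
    """
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("snp ids must be unique")
    if source in ("all", "within-list"):
        return itertools.combinations(snp_ids, 2), pair_count(len(snp_ids))
    if source == "pair-file":
        if pairs is None:
            raise ValueError("pair-file source requires pairs")
        order = {s: k for k, s in enumerate(snp_ids)}
        canonical = []
        for a, b in pairs:
            if a not in order or b not in order:
                raise ValueError(f"unknown snp id in pair ({a}, {b})")
            canonical.append((a, b) if order[a] < order[b] else (b, a))
        return iter(canonical), len(canonical)
    raise ValueError(f"unknown pair source {source!r}")


def _canonical_order(meta: list[SNPMeta]) -> list[int]:
    """Stable SNP ordering by (chromosome, position, id) for pair keying."""
    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    return sorted(
        range(len(meta)), key=lambda k: (chrom_key(meta[k].chrom),
                                         meta[k].position, meta[k].id)
    )


def _pair_tables(
    matrix: np.ndarray, idx_pairs: list[tuple[int, int]]
) -> np.ndarray:
    """3x3 genotype tables for each index pair, with pairwise complete-case
    deletion of missing genotypes."""
    tables = np.empty((len(idx_pairs), 3, 3), dtype=np.int64)
    for k, (i, j) in enumerate(idx_pairs):
        g, h = matrix[:, i], matrix[:, j]
        ok = ~(np.isnan(g) | np.isnan(h))
        code = (g[ok] * 3 + h[ok]).astype(np.int64)
        tables[k] = np.bincount(code, minlength=9).reshape(3, 3)
    return tables


def scan(
    case_matrix: np.ndarray,
    ctrl_matrix: np.ndarray,
    meta: list[SNPMeta],
    method: str = "tih",
    store_threshold: float = 1e-4,
    pairs: Iterable[tuple[str, str]] | None = None,
    coding: str = "additive",
    chunk_size: int = 4096,
) -> tuple[pd.DataFrame, dict]:
    """Apply an interaction test to every SNP pair, storing small p-values.

    Both matrices must share the SNP order of ``meta``.  SNPs are re-keyed
    into canonical (chromosome, position, id) order so results are invariant
    to input column order; pairs are processed in fixed-size chunks through
    the vectorized kernels, so results are also invariant to ``chunk_size``.

    Returns the stored results (p <= ``store_threshold``) and a metadata
    dict with the total pair count (the FDR family size), the evaluated and
    stored counts, and per-pair failures.
    """
    meta = list(meta)
    if case_matrix.shape[1] != len(meta) or ctrl_matrix.shape[1] != len(meta):
        raise ValueError("matrix width does not match metadata")
    order = _canonical_order(meta)
    meta_sorted = [meta[k] for k in order]
    ids = [s.id for s in meta_sorted]
    case_m = np.asarray(case_matrix, dtype=float)[:, order]
    ctrl_m = np.asarray(ctrl_matrix, dtype=float)[:, order]

    pos = {s: k for k, s in enumerate(ids)}
    if pairs is None:
        stream, total = enumerate_pairs(ids)
    else:
        stream, total = enumerate_pairs(ids, source="pair-file", pairs=pairs)

    rows: list[dict] = []
    failures: list[dict] = []
    n_eval = 0
    while True:
        chunk = list(itertools.islice(stream, chunk_size))
        if not chunk:
            break
        idx_pairs = [(pos[a], pos[b]) for a, b in chunk]
        case_t = _pair_tables(case_m, idx_pairs)
        ctrl_t = _pair_tables(ctrl_m, idx_pairs)
        empty = (case_t.sum(axis=(1, 2)) == 0) | (ctrl_t.sum(axis=(1, 2)) == 0)

        stat = np.full(len(chunk), np.nan)
        pval = np.full(len(chunk), np.nan)
        corr = np.zeros(len(chunk), dtype=bool)
        ok = ~empty
        if ok.any():
            if method == "tih":
                r = _stats.tih_batch(case_t[ok], ctrl_t[ok])
                stat[ok], pval[ok], corr[ok] = (
                    r["statistic"], r["p_value"], r["corrected"]
                )
            elif method == "fast":
                r = _stats.fast_epistasis_batch(case_t[ok], ctrl_t[ok])
                stat[ok], pval[ok], corr[ok] = (
                    r["statistic"], r["p_value"], r["corrected"]
                )
            elif method == "logistic":
                for k in np.flatnonzero(ok):
                    from scipy import stats as sps

                    p = _logistic_from_tables(case_t[k], ctrl_t[k], coding)
                    pval[k] = p
                    stat[k] = sps.chi2.isf(p, df=1) if np.isfinite(p) else np.nan
            else:
                raise ValueError(f"unknown method {method!r}")

        for k, (a, b) in enumerate(chunk):
            if not np.isfinite(pval[k]):
                reason = "empty table" if empty[k] else "test not evaluable"
                failures.append({"snp1": a, "snp2": b, "reason": reason})
                continue
            n_eval += 1
            if pval[k] <= store_threshold:
                m1, m2 = meta_sorted[pos[a]], meta_sorted[pos[b]]
                rows.append({
                    "snp1": a, "snp2": b,
                    "chrom1": m1.chrom, "pos1": m1.position,
                    "chrom2": m2.chrom, "pos2": m2.position,
                    "method": method, "statistic": stat[k],
                    "p_value": pval[k],
                    "flags": "corrected" if corr[k] else "",
                })

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    scan_meta = {
        "n_pairs_total": total,
        "n_evaluated": n_eval,
        "n_stored": len(results),
        "store_threshold": store_threshold,
        "method": method,
        "failures": failures,
    }
    return results, scan_meta


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in input order.

    ``m`` is the size of the tested family; pass the total pair count when
    ``p_values`` is a storage-thresholded subset (the stored values are the
    smallest of the family, so their ranks are unchanged).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than len(p_values)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qq_points(
    p_values, min_neg_log10: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Expected quantiles are -log10(rank/(m+1)) for ranks of the sorted
    p-values; points with observed -log10 below ``min_neg_log10`` are
    dropped (matching plots built from storage-thresholded scans).  Zero
    p-values are clamped to the smallest positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-values clamped for -log10 transform")
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    p_sorted = np.sort(p)
    observed = -np.log10(p_sorted)
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    keep = observed >= min_neg_log10
    return expected[keep], observed[keep]


@dataclass(frozen=True)
class ReplicationReport:
    """Two-stage Bonferroni replication outcome."""

    stage1_threshold: float
    n_selected: int
    stage2_threshold: float
    replicated: pd.DataFrame  # snp1, snp2, p1, p2


def two_stage_bonferroni_replication(
    results1: pd.DataFrame,
    m1_pairs: int,
    dataset2_tester: Callable[[str, str], float],
    alpha: float = 0.05,
) -> ReplicationReport:
    """Discover in dataset 1, confirm in dataset 2.

    Stage 1 selects pairs from ``results1`` with p <= alpha/m1_pairs (the
    Bonferroni threshold over all tested pairs); stage 2 retests only the
    selected pairs in dataset 2 via ``dataset2_tester(snp1, snp2) -> p`` and
    declares replication at alpha/(number selected).
    """
    thr1 = alpha / m1_pairs
    selected = results1[results1["p_value"] <= thr1]
    if len(selected) == 0:
        return ReplicationReport(
            stage1_threshold=thr1, n_selected=0, stage2_threshold=np.nan,
            replicated=pd.DataFrame(columns=["snp1", "snp2", "p1", "p2"]),
        )
    thr2 = alpha / len(selected)
    rows = []
    for _, rec in selected.iterrows():
        p2 = dataset2_tester(rec["snp1"], rec["snp2"])
        if np.isfinite(p2) and p2 <= thr2:
            rows.append({"snp1": rec["snp1"], "snp2": rec["snp2"],
                         "p1": rec["p_value"], "p2": p2})
    return ReplicationReport(
        stage1_threshold=thr1,
        n_selected=len(selected),
        stage2_threshold=thr2,
        replicated=pd.DataFrame(rows, columns=["snp1", "snp2", "p1", "p2"]),
    )


def replication_intersect(
    results1: pd.DataFrame, results2: pd.DataFrame, fdr_threshold: float
) -> pd.DataFrame:
    """Pairs significant at ``q <= fdr_threshold`` in both result sets.

    Both frames must carry canonical (snp1, snp2) keys and a ``q_value``
    column.
    """
    sig1 = results1[results1["q_value"] <= fdr_threshold]
    sig2 = results2[results2["q_value"] <= fdr_threshold]
    return sig1.merge(
        sig2, on=["snp1", "snp2"], suffixes=("_1", "_2"), how="inner"
    )
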