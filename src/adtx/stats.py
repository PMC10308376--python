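"""Shared statistical machinery: rank tests, BH FDR, hypergeometric ORA.

Design notes
------------
* All p-values are two-sided.
* The rank-sum test uses the exact null distribution for small samples
  (combined n <= 25, no ties) and the normal approximation with midrank
  tie correction otherwise.
* BH q-values are computed on ranks and returned in input order.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TEST_KINDS = ("rank_sum", "signed_rank", "t")


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    Raises ValueError for p outside [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def rank_tests(a: Sequence[float], b: Sequence[float], kind: str = "rank_sum") -> float:
    """Two-sided p-value for a two-sample comparison.

    kind:
      rank_sum    Wilcoxon–Mann–Whitney rank-sum (unpaired).
      signed_rank Wilcoxon signed-rank with pairing by rank order; requires
                  equal sample sizes.
      t           Student's pooled-variance two-sample t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind not in TEST_KINDS:
        raise ValueError(f"unknown test kind {kind!r}")
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")

    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        logger.debug("all observations tied; p = 1")
        return 1.0

    if kind == "rank_sum":
        n = a.size + b.size
        has_ties = np.unique(combined).size < n
        method = "exact" if (n <= 25 and not has_ties) else "asymptotic"
        return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)

    if kind == "signed_rank":
        if a.size != b.size:
            raise ValueError("signed_rank pairing requires equal group sizes")
        d = np.sort(a) - np.sort(b)
        if np.all(d == 0):
            return 1.0
        return float(sps.wilcoxon(np.sort(a), np.sort(b)).pvalue)

    # Student's t; degenerate zero-variance cases resolved by the mean difference
    res = sps.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        logger.debug("degenerate t-test variance; p set to %s", p)
    return p


# ---------------------------------------------------------------------------
# Vectorised row-wise tests used by the differential modules
# ---------------------------------------------------------------------------

def rank_sum_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values (normal approximation, tie-corrected).

    Rows constant across both groups get p = 1.
    """
    p = sps.mannwhitneyu(A, B, axis=1, alternative="two-sided", method="asymptotic").pvalue
    const = np.all(np.concatenate([A, B], axis=1) ==
                   np.concatenate([A, B], axis=1)[:, :1], axis=1)
    if const.any():
        logger.info("%d constant rows in rank-sum testing; p set to 1", int(const.sum()))
    return np.where(const | ~np.isfinite(p), 1.0, p)


def ttest_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values.

    Degenerate rows (zero pooled variance) get p = 1 when group means agree
    and p = 0 otherwise.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p = sps.ttest_ind(A, B, axis=1, equal_var=True).pvalue
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.isclose(A[bad].mean(axis=1), B[bad].mean(axis=1))
        p = p.copy()
        p[np.flatnonzero(bad)[same]] = 1.0
        p[np.flatnonzero(bad)[~same]] = 0.0
        logger.info("%d degenerate-variance rows in t-testing", int(bad.sum()))
    return p


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(query: set[str], sets: Mapping[str, set[str]], universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of `query` in each gene set.

    The upper-tail p-value is P[X >= k] with X ~ Hypergeom(N, K, n) where
    N = |universe|, K = |set ∩ universe|, n = |query|, k = |query ∩ set|.
    Gene sets are intersected with the universe; the query must be a subset
    of the universe. Returns one row per set, sorted by p, with BH FDR.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & set(universe)
        K = len(members)
        k = len(query & members)
        if n == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


# ---------------------------------------------------------------------------
# GMT gene-set I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file (name, description, members...) into {name: members}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str, description: str = "adtx") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
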