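"""Differential transcript expression and transcript/host-gene relationships.

Expression matrices are pandas DataFrames: rows = transcript (or gene, or
RBP) ids, columns = sample ids, values = TPM. Group membership is a pandas
Series mapping sample_id -> diagnosis label (see `cohort`).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as adstats

logger = logging.getLogger(__name__)

FC_UP = 1.5
FC_DOWN = 0.67
FC_EPS = 0.01  # TPM pseudocount in the fold-change ratio


def _group_columns(x: pd.DataFrame, labels: pd.Series, group: str) -> list[str]:
    cols = [s for s in x.columns if labels.get(s) == group]
    if not cols:
        raise ValueError(f"no samples with label {group!r} in the matrix")
    return cols


def det_test(
    x: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = 0.05,
    eps: float = FC_EPS,
) -> pd.DataFrame:
    """Differential expression of group_b relative to group_a.

    Per row: two-sided Wilcoxon rank-sum p-value, fold change
    (mean_b + eps) / (mean_a + eps), BH FDR over all tested rows, and a
    direction call: up iff fc > fc_up and fdr < alpha, down iff fc < fc_down
    and fdr < alpha, else none.
    """
    ca = _group_columns(x, labels, group_a)
    cb = _group_columns(x, labels, group_b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("both groups need at least 2 samples")
    A = x[ca].to_numpy(dtype=float)
    B = x[cb].to_numpy(dtype=float)
    p = adstats.rank_sum_rows(A, B)
    fc = (B.mean(axis=1) + eps) / (A.mean(axis=1) + eps)
    fdr = adstats.bh_fdr(p)
    direction = np.where(
        (fc > fc_up) & (fdr < alpha), "up",
        np.where((fc < fc_down) & (fdr < alpha), "down", "none"),
    )
    return pd.DataFrame(
        {
            "transcript_id": x.index,
            "fold_change": fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("transcript_id")


def twenty_percent_sets(
    x: pd.DataFrame,
    labels: pd.Series,
    group_ref: str,
    group_a: str,
    group_b: str,
    threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-change classification of each transcript vs a reference group.

    For each transcript the group-mean change relative to the reference mean
    is classified as up (> +threshold), down (< -threshold) or flat in each
    of the two disease groups. Returns (per-transcript table, 3x3 cross-tab
    with up/down/flat rows for group_a and columns for group_b). Transcripts
    whose reference mean is 0 are excluded (logged).
    """
    ref = x[_group_columns(x, labels, group_ref)].mean(axis=1)
    ma = x[_group_columns(x, labels, group_a)].mean(axis=1)
    mb = x[_group_columns(x, labels, group_b)].mean(axis=1)
    ok = ref > 0
    if (~ok).any():
        logger.info("twenty_percent_sets: excluded %d rows with zero reference mean",
                    int((~ok).sum()))
    rel_a = (ma[ok] - ref[ok]) / ref[ok]
    rel_b = (mb[ok] - ref[ok]) / ref[ok]

    def _cls(rel: pd.Series) -> pd.Series:
        return pd.Series(
            np.where(rel > threshold, "up", np.where(rel < -threshold, "down", "flat")),
            index=rel.index,
        )

    table = pd.DataFrame(
        {
            "change_a": rel_a,
            "change_b": rel_b,
            "class_a": _cls(rel_a),
            "class_b": _cls(rel_b),
        }
    ).rename_axis("transcript_id")
    order = ["up", "down", "flat"]
    crosstab = (
        pd.crosstab(table["class_a"], table["class_b"])
        .reindex(index=order, columns=order, fill_value=0)
        .rename_axis(index=f"class_{group_a}", columns=f"class_{group_b}")
    )
    return table, crosstab


def gene_sums(x: pd.DataFrame, tx2gene: Mapping[str, str]) -> pd.DataFrame:
    """Gene-level expression as the sum of member-transcript TPMs."""
    rows = x.loc[[t for t in x.index if t in tx2gene]]
    genes = pd.Series({t: tx2gene[t] for t in rows.index}, name="gene_id")
    return rows.groupby(genes).sum()


def host_gene_correlation(
    xt: pd.DataFrame,
    tx2gene: Mapping[str, str],
    gene_expr: pd.DataFrame | None = None,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each transcript with its host gene across samples.

    Host-gene expression defaults to the sum of member-transcript TPMs from
    the same matrix; an independent gene-level matrix may be supplied
    instead. Labels: positive iff r > r_min and p < alpha; negative iff
    r < -r_min and p < alpha; otherwise irrelevant. Zero-variance transcript
    or gene vectors are labelled irrelevant (logged).
    """
    if xt.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    if gene_expr is None:
        gene_expr = gene_sums(xt, tx2gene)
    rows = []
    for tid in xt.index:
        gid = tx2gene.get(tid)
        if gid is None or gid not in gene_expr.index:
            continue
        tv = xt.loc[tid].to_numpy(dtype=float)
        gv = gene_expr.loc[gid, xt.columns].to_numpy(dtype=float)
        if np.std(tv) == 0 or np.std(gv) == 0:
            logger.debug("zero variance for %s / %s; labelled irrelevant", tid, gid)
            rows.append({"transcript_id": tid, "gene_id": gid,
                         "r": np.nan, "p_value": np.nan, "label": "irrelevant"})
            continue
        r, p = sps.pearsonr(tv, gv)
        if p < alpha and r > r_min:
            label = "positive"
        elif p < alpha and r < -r_min:
            label = "negative"
        else:
            label = "irrelevant"
        rows.append({"transcript_id": tid, "gene_id": gid, "r": r, "p_value": p,
                     "label": label})
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "r", "p_value", "label"]
    ).set_index("transcript_id")


def expression_fraction(
    xt: pd.DataFrame, tx2gene: Mapping[str, str], corr: pd.DataFrame
) -> pd.DataFrame:
    """Share of host-gene expression carried by positively correlated transcripts.

    Per gene: sum of mean TPM over transcripts labelled positive divided by
    the gene's mean TPM (sum over member transcripts present in the matrix),
    together with the member-transcript count for stratification. Genes with
    zero mean expression are excluded.
    """
    mean_tpm = xt.mean(axis=1)
    rows = []
    gene_members: dict[str, list[str]] = {}
    for t in xt.index:
        g = tx2gene.get(t)
        if g is not None:
            gene_members.setdefault(g, []).append(t)
    positive = set(corr.index[corr["label"] == "positive"])
    for gid, members in gene_members.items():
        total = mean_tpm[members].sum()
        if total <= 0:
            continue
        pos_sum = mean_tpm[[t for t in members if t in positive]].sum()
        rows.append({"gene_id": gid, "n_transcripts": len(members),
                     "positive_fraction": pos_sum / total})
    return pd.DataFrame(
        rows, columns=["gene_id", "n_transcripts", "positive_fraction"]
    ).set_index("gene_id")
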