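"""Isoform-switch detection from isoform fractions (IF).

IF(t, s) = TPM(t, s) / sum over the host gene's transcripts of TPM(., s);
undefined (NaN) when the gene is unexpressed in the sample. dIF is the
difference of group means of IF; a transcript switches usage when
|dIF| > 0.1 at FDR < 0.05, and a gene has an isoform-switching event when
any member transcript does.

Samples where the host gene is unexpressed are dropped per test rather
than imputed as IF = 0: absence of the gene is not evidence about the
isoform balance.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as adstats
from .diffexpr import det_test, gene_sums

logger = logging.getLogger(__name__)


def compute_if(xt: pd.DataFrame, tx2gene: Mapping[str, str]) -> pd.DataFrame:
    """Transcript x sample isoform fractions.

    Rows of the input without a host-gene mapping (e.g. RBP pseudo-genes)
    are omitted from the result.
    """
    keep = [t for t in xt.index if t in tx2gene]
    sub = xt.loc[keep]
    genes = pd.Series({t: tx2gene[t] for t in keep})
    totals = sub.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ifm = sub / totals.where(totals > 0)
    return ifm


def detect_switches(
    ifm: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    tx2gene: Mapping[str, str],
    dif_min: float = 0.1,
    alpha: float = 0.05,
    welch: bool = False,
    per_gene_fdr: bool = False,
) -> pd.DataFrame:
    """Isoform-usage change of group_b relative to group_a.

    Per transcript: dif = mean IF(b) - mean IF(a) over non-missing values,
    two-sided Student's t-test (Welch optional), BH FDR pooled across all
    transcripts (or within genes with per_gene_fdr), and a usage call:
    increased/decreased iff |dif| > dif_min and fdr < alpha. The output also
    carries the per-gene switching flag (any member transcript switching).
    """
    ca = [s for s in ifm.columns if labels.get(s) == group_a]
    cb = [s for s in ifm.columns if labels.get(s) == group_b]
    if not ca or not cb:
        raise ValueError("both groups must have samples in the IF matrix")
    A = ifm[ca].to_numpy(dtype=float)
    B = ifm[cb].to_numpy(dtype=float)

    ids, difs, pvals = [], [], []
    complete = not (np.isnan(A).any() or np.isnan(B).any())
    if complete and not welch:
        ids = list(ifm.index)
        difs = list(B.mean(axis=1) - A.mean(axis=1))
        pvals = list(adstats.ttest_rows(A, B))
    else:
        from scipy import stats as sps

        skipped = 0
        for idx, tid in enumerate(ifm.index):
            a = A[idx][~np.isnan(A[idx])]
            b = B[idx][~np.isnan(B[idx])]
            if a.size < 2 or b.size < 2:
                skipped += 1
                continue
            ids.append(tid)
            difs.append(float(b.mean() - a.mean()))
            res = sps.ttest_ind(a, b, equal_var=not welch)
            p = float(res.pvalue)
            if np.isnan(p):
                p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            # ttest_ind(a, b) tests a vs b; two-sided p is symmetric
            pvals.append(p)
        if skipped:
            logger.info("detect_switches skipped %d transcripts with insufficient data",
                        skipped)

    out = pd.DataFrame({"transcript_id": ids, "dif": difs, "p_value": pvals})
    out["gene_id"] = [tx2gene.get(t, "") for t in out["transcript_id"]]
    if per_gene_fdr and len(out):
        out["fdr"] = (
            out.groupby("gene_id")["p_value"].transform(lambda s: adstats.bh_fdr(s.to_numpy()))
        )
    else:
        out["fdr"] = adstats.bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out["usage"] = np.where(
        (out["dif"].abs() > dif_min) & (out["fdr"] < alpha),
        np.where(out["dif"] > 0, "increased", "decreased"),
        "none",
    )
    switching_genes = set(out.loc[out["usage"] != "none", "gene_id"])
    out["gene_switches"] = out["gene_id"].isin(switching_genes)
    return out.set_index("transcript_id")[
        ["gene_id", "dif", "p_value", "fdr", "usage", "gene_switches"]
    ]


def switch_vs_gene_expression(
    xt: pd.DataFrame,
    tx2gene: Mapping[str, str],
    switches: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast isoform switching with host-gene differential expression.

    For each switching gene, runs the differential-expression test on gene-
    summed TPMs and flags genes whose isoform usage changes while the gene
    itself does not (switch_without_expression_change) — the pattern where
    transcript-level analysis sees what gene-level analysis misses.
    """
    genes = sorted(set(switches.loc[switches["usage"] != "none", "gene_id"]))
    gx = gene_sums(xt, tx2gene)
    if not genes:
        return pd.DataFrame(
            columns=["gene_is_det", "gene_fold_change", "gene_fdr",
                     "switch_without_expression_change"]
        ).rename_axis("gene_id")
    det = det_test(gx, labels, group_a, group_b, alpha=alpha)
    det = det.loc[[g for g in genes if g in det.index]]
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["gene_is_det"] = [
        det.loc[g, "direction"] != "none" if g in det.index else False for g in genes
    ]
    out["gene_fold_change"] = [
        det.loc[g, "fold_change"] if g in det.index else np.nan for g in genes
    ]
    out["gene_fdr"] = [det.loc[g, "fdr"] if g in det.index else np.nan for g in genes]
    out["switch_without_expression_change"] = ~out["gene_is_det"]
    return out
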