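"""RBP–splicing-event regulatory networks.

Candidate regulators are RNA-binding proteins (RBPs) whose expression
changes by at least 10% between the compared groups. An RBP is linked to a
differentially spliced event when (i) it has CLIP binding evidence within
±300 bp of one of the event's defining splice sites and (ii) its TPM is
Spearman-correlated with the event's PSI (|rho| > 0.5, p < 0.05) across
the samples of the two compared groups. Binding is a hard, deterministic
filter: no binding evidence, no edge, whatever the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from . import stats as adstats
from .splicing import SpliceEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    rbp_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("binding site start > end")


def sites_from_bed(bed: pd.DataFrame, rbp_ids: Iterable[str] | None = None) -> list[BindingSite]:
    """BindingSites from a BED table read by `annotation.read_bed`.

    The BED name field carries the RBP id; records naming unknown RBPs are
    dropped (logged) when an RBP list is supplied.
    """
    known = set(rbp_ids) if rbp_ids is not None else None
    out, dropped = [], 0
    for row in bed.itertuples(index=False):
        if known is not None and row.name not in known:
            dropped += 1
            continue
        out.append(BindingSite(str(row.chrom), int(row.start), int(row.end), str(row.name)))
    if dropped:
        logger.info("dropped %d binding sites naming unlisted RBPs", dropped)
    return out


def rbp_expression_filter(
    xr: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    min_change: float = 0.1,
) -> pd.DataFrame:
    """RBPs with at least `min_change` relative mean expression change.

    change = (mean_b - mean_a) / mean_a; an RBP passes iff |change| >=
    min_change ("no less than 10%" is inclusive). RBPs with zero reference
    mean are excluded (logged).
    """
    ca = [s for s in xr.columns if labels.get(s) == group_a]
    cb = [s for s in xr.columns if labels.get(s) == group_b]
    if not ca or not cb:
        raise ValueError("both groups must have samples")
    ma = xr[ca].mean(axis=1)
    mb = xr[cb].mean(axis=1)
    ok = ma > 0
    if (~ok).any():
        logger.info("excluded %d RBPs with zero mean in %s", int((~ok).sum()), group_a)
    change = (mb[ok] - ma[ok]) / ma[ok]
    out = pd.DataFrame({"change": change})
    out["passes"] = change.abs() >= min_change
    out["direction"] = np.where(change >= 0, "up", "down")
    return out.rename_axis("rbp_id")


def _merged_windows(e: SpliceEvent, window_bp: int) -> list[tuple[int, int]]:
    """±window intervals around the defining sites, merged where overlapping."""
    spans = sorted((s - window_bp, s + window_bp) for s in e.defining_sites)
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]


def binding_evidence(
    e: SpliceEvent, sites: Sequence[BindingSite], window_bp: int = 300
) -> dict[str, int]:
    """Per-RBP count of binding intervals overlapping the event's windows.

    Windows are the ±window_bp neighbourhoods of the defining splice sites,
    merged before counting so one CLIP peak is never counted twice; overlap
    means non-empty interval intersection.
    """
    counts: dict[str, set[int]] = {}
    windows = _merged_windows(e, window_bp)
    for i, s in enumerate(sites):
        if s.chrom != e.chrom:
            continue
        for lo, hi in windows:
            if s.start <= hi and lo <= s.end:
                counts.setdefault(s.rbp_id, set()).add(i)
                break
    return {rbp: len(ix) for rbp, ix in counts.items()}


def binding_evidence_all(
    events: Sequence[SpliceEvent], sites: Sequence[BindingSite], window_bp: int = 300
) -> dict[str, dict[str, int]]:
    """binding_evidence for many events, indexed by event_id.

    Builds one interval tree of binding sites per chromosome so the pass
    over a large catalog stays near-linear.
    """
    trees: dict[str, IntervalTree] = {}
    for i, s in enumerate(sites):
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end + 1, (i, s.rbp_id))
    out: dict[str, dict[str, int]] = {}
    for e in events:
        tree = trees.get(e.chrom)
        hits: dict[str, set[int]] = {}
        if tree is not None:
            for lo, hi in _merged_windows(e, window_bp):
                for iv in tree.overlap(lo, hi + 1):
                    idx, rbp = iv.data
                    hits.setdefault(rbp, set()).add(idx)
        out[e.event_id] = {rbp: len(ix) for rbp, ix in hits.items()}
    return out


def build_network(
    psi: pd.DataFrame,
    xr: pd.DataFrame,
    events: Sequence[SpliceEvent],
    sites: Sequence[BindingSite],
    diff_event_ids: Iterable[str],
    labels: pd.Series,
    group_a: str,
    group_b: str,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    window_bp: int = 300,
    min_change: float = 0.1,
    use_bh: bool = False,
    all_samples: bool = False,
) -> pd.DataFrame:
    """RBP -> event regulatory edges for one group comparison.

    Pipeline: expression-filter the RBPs, keep (RBP, differential event)
    pairs with >= 1 binding site within the ±window of the event's splice
    sites, then Spearman-correlate RBP TPM with event PSI across the two
    compared groups' samples (all samples with `all_samples`); an edge needs
    |rho| > rho_min and p < alpha (raw p by default; `use_bh` applies BH
    across candidate pairs). Pairs with < 3 paired observations are skipped.
    """
    rbp_table = rbp_expression_filter(xr, labels, group_a, group_b, min_change=min_change)
    passing = rbp_table[rbp_table["passes"]]
    diff_ids = [i for i in diff_event_ids if i in psi.index]
    ev_by_id = {e.event_id: e for e in events}
    if all_samples:
        cols = [s for s in psi.columns if s in xr.columns]
    else:
        cols = [s for s in psi.columns
                if labels.get(s) in (group_a, group_b) and s in xr.columns]
    evidence = binding_evidence_all(
        [ev_by_id[i] for i in diff_ids if i in ev_by_id], sites, window_bp
    )

    rows = []
    for eid in diff_ids:
        ev_counts = evidence.get(eid, {})
        psi_row = psi.loc[eid, cols].to_numpy(dtype=float)
        for rbp in passing.index:
            n_sites = ev_counts.get(rbp, 0)
            if n_sites < 1 or rbp not in xr.index:
                continue
            x = xr.loc[rbp, cols].to_numpy(dtype=float)
            mask = ~np.isnan(psi_row)
            if mask.sum() < 3:
                logger.info("pair (%s, %s): <3 paired observations, skipped", rbp, eid)
                continue
            rho, p = sps.spearmanr(x[mask], psi_row[mask])
            rows.append(
                {
                    "rbp_id": rbp,
                    "event_id": eid,
                    "rho": float(rho),
                    "p_value": float(p),
                    "n_binding_sites": n_sites,
                    "rbp_direction": passing.loc[rbp, "direction"],
                }
            )
    edges = pd.DataFrame(
        rows, columns=["rbp_id", "event_id", "rho", "p_value",
                       "n_binding_sites", "rbp_direction"],
    )
    if len(edges):
        edges["fdr"] = adstats.bh_fdr(edges["p_value"].to_numpy())
        sig_p = edges["fdr"] if use_bh else edges["p_value"]
        edges = edges[(edges["rho"].abs() > rho_min) & (sig_p < alpha)]
    return edges.reset_index(drop=True)


def rbp_summary(
    edges: pd.DataFrame,
    events: Sequence[SpliceEvent],
    gene_sets: Mapping[str, set[str]] | None = None,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-RBP summary: regulated events/genes, and enriched pathways if
    gene sets and a universe are supplied (hypergeometric ORA at `alpha`)."""
    gene_of = {e.event_id: e.gene_id for e in events}
    rows = []
    for rbp, sub in edges.groupby("rbp_id"):
        genes = {gene_of[eid] for eid in sub["event_id"] if eid in gene_of}
        row = {
            "rbp_id": rbp,
            "n_events": int(len(sub)),
            "n_genes": len(genes),
            "direction": sub["rbp_direction"].iloc[0],
        }
        if gene_sets is not None and universe is not None:
            res = adstats.ora(genes & universe, gene_sets, universe)
            row["n_enriched_pathways"] = int((res["p_value"] < alpha).sum())
        rows.append(row)
    cols = ["rbp_id", "n_events", "n_genes", "direction"]
    if gene_sets is not None and universe is not None:
        cols.append("n_enriched_pathways")
    return pd.DataFrame(rows, columns=cols).set_index("rbp_id")
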