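"""Local alternative-splicing events: inference, PSI, differential splicing.

Events are inferred from pairwise comparison of transcript exon structures
within a gene, following the standard local-event taxonomy:

  SE  skipped exon            A5  alternative 5' splice site
  A3  alternative 3' splice site   MX  mutually exclusive exons
  RI  retained intron         AF  alternative first exon
  AL  alternative last exon

Detection runs on genomic coordinates (as if on the + strand); for minus-
strand genes the side-sensitive types are swapped (A5<->A3, AF<->AL), so
strand-mirrored gene structures yield identical event types. Candidate
events from different transcript pairs that share a coordinate signature
are merged, unioning their inclusion/exclusion transcript sets.

PSI of an event in a sample is the transcript-abundance share of the
inclusion form: sum TPM(inclusion) / sum TPM(inclusion + exclusion),
undefined (NaN) when the denominator is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as adstats
from .annotation import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")

# genomic-side classification -> strand-resolved type
_MINUS_SWAP = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF",
               "SE": "SE", "RI": "RI", "MX": "MX"}


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]
    defining_sites: tuple[int, ...]
    variable_region: tuple[int, int]
    variable_region_length: int
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError("inclusion and exclusion sets must be non-empty")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError("inclusion and exclusion sets must be disjoint")
        if not self.defining_sites:
            raise ValueError("defining_sites must be non-empty")


# ---------------------------------------------------------------------------
# Pairwise candidate detection (genomic orientation)
# ---------------------------------------------------------------------------

def _pair_candidates(t1: TranscriptModel, t2: TranscriptModel, strand: str):
    """Candidate events from one transcript pair.

    Yields (genomic_type, sites, inclusion_tid, exclusion_tid, var_region).
    `sites` is the canonical (sorted) defining-coordinate signature used for
    deduplication; inclusion is resolved strand-aware where the definition
    requires it (MX, AF, AL).
    """
    out = []
    pair = [(t1, t2), (t2, t1)]

    def _intron_index(t: TranscriptModel) -> dict[tuple[int, int], int]:
        return {iv: i for i, iv in enumerate(t.introns())}

    # --- SE: internal exon of t_in absent from t_ex, flanks shared --------
    for t_in, t_ex in pair:
        ex_introns = set(t_ex.introns())
        for i in range(1, len(t_in.exons) - 1):
            P, E, N = t_in.exons[i - 1], t_in.exons[i], t_in.exons[i + 1]
            if (P.end + 1, N.start - 1) in ex_introns:
                sites = (P.end, E.start, E.end, N.start)
                out.append(("SE", sites, t_in.transcript_id, t_ex.transcript_id,
                            (E.start, E.end)))

    # --- RI: one exon of t_ret spans t_spl's exon-intron-exon block -------
    for t_ret, t_spl in pair:
        exon_keys = {(e.start, e.end) for e in t_ret.exons}
        for j in range(len(t_spl.exons) - 1):
            A, B = t_spl.exons[j], t_spl.exons[j + 1]
            if (A.start, B.end) in exon_keys:
                sites = (A.start, A.end, B.start, B.end)
                out.append(("RI", sites, t_ret.transcript_id, t_spl.transcript_id,
                            (A.end + 1, B.start - 1)))

    # --- A5/A3 (genomic left/right alternative intron boundary) -----------
    in1 = t1.introns()
    in2 = t2.introns()
    for i, (a1, b1) in enumerate(in1):
        for j, (a2, b2) in enumerate(in2):
            if a1 == a2 and b1 == b2:
                continue
            if b1 == b2 and a1 != a2:
                # alternative left boundary; flanking upstream exons must overlap
                e1, e2 = t1.exons[i], t2.exons[j]
                if e1.overlaps(e2):
                    d_long = max(a1, a2) - 1  # boundary of the longer exon form
                    d_short = min(a1, a2) - 1
                    sites = (d_short, d_long, b1 + 1)
                    inc, exc = (t1, t2) if a1 > a2 else (t2, t1)  # shorter intron includes
                    out.append(
                        ("A5", sites, inc.transcript_id, exc.transcript_id,
                         (d_short + 1, d_long))
                    )
            elif a1 == a2 and b1 != b2:
                e1, e2 = t1.exons[i + 1], t2.exons[j + 1]
                if e1.overlaps(e2):
                    acc_short = min(b1, b2) + 1
                    acc_long = max(b1, b2) + 1
                    sites = (a1 - 1, acc_short, acc_long)
                    inc, exc = (t1, t2) if b1 < b2 else (t2, t1)
                    out.append(
                        ("A3", sites, inc.transcript_id, exc.transcript_id,
                         (acc_short, acc_long - 1))
                    )

    # --- MX: non-overlapping internal exons with shared outer flanks ------
    for i in range(1, len(t1.exons) - 1):
        P1, E1, N1 = t1.exons[i - 1], t1.exons[i], t1.exons[i + 1]
        for j in range(1, len(t2.exons) - 1):
            P2, E2, N2 = t2.exons[j - 1], t2.exons[j], t2.exons[j + 1]
            if (P1.end == P2.end and N1.start == N2.start
                    and (E1.start, E1.end) != (E2.start, E2.end)
                    and not E1.overlaps(E2)):
                left, right = sorted([E1, E2], key=lambda e: e.start)
                sites = (P1.end, left.start, left.end, right.start, right.end, N1.start)
                # inclusion carries the 5'-most alternative exon
                inc_exon = left if strand == "+" else right
                inc_t = t1 if inc_exon is E1 else t2
                exc_t = t2 if inc_t is t1 else t1
                out.append(("MX", sites, inc_t.transcript_id, exc_t.transcript_id,
                            (inc_exon.start, inc_exon.end)))

    # --- AF/AL: alternative terminal exons sharing the next junction ------
    if len(t1.exons) >= 2 and len(t2.exons) >= 2:
        F1, F2 = t1.exons[0], t2.exons[0]
        if (t1.exons[1].start == t2.exons[1].start
                and (F1.start, F1.end) != (F2.start, F2.end)):
            if F1.overlaps(F2):
                logger.debug(
                    "ambiguous alternative-first exons overlap (%s vs %s); discarded",
                    t1.transcript_id, t2.transcript_id)
            else:
                left, right = sorted([F1, F2], key=lambda e: e.start)
                sites = (left.start, left.end, right.start, right.end,
                         t1.exons[1].start)
                # on + this is AF with 5'-most first exon = genomic-leftmost;
                # on - it becomes AL whose 3'-most last exon is also the
                # genomic-leftmost, so inclusion is the outer-left exon always
                inc_exon = left
                inc_t = t1 if inc_exon is F1 else t2
                exc_t = t2 if inc_t is t1 else t1
                out.append(("AF", sites, inc_t.transcript_id, exc_t.transcript_id,
                            (inc_exon.start, inc_exon.end)))
        L1, L2 = t1.exons[-1], t2.exons[-1]
        if (t1.exons[-2].end == t2.exons[-2].end
                and (L1.start, L1.end) != (L2.start, L2.end)):
            if L1.overlaps(L2):
                logger.debug(
                    "ambiguous alternative-last exons overlap (%s vs %s); discarded",
                    t1.transcript_id, t2.transcript_id)
            else:
                left, right = sorted([L1, L2], key=lambda e: e.start)
                sites = (t1.exons[-2].end, left.start, left.end, right.start, right.end)
                # AL on + takes the 3'-most (genomic-rightmost) terminal exon;
                # on - this block is AF and its 5'-most first exon is likewise
                # the genomic-rightmost, so inclusion is the outer-right exon
                inc_exon = right
                inc_t = t1 if inc_exon is L1 else t2
                exc_t = t2 if inc_t is t1 else t1
                out.append(("AL", sites, inc_t.transcript_id, exc_t.transcript_id,
                            (inc_exon.start, inc_exon.end)))
    return out


def infer_events(g: GeneModel) -> list[SpliceEvent]:
    """Infer local splicing events for one gene.

    Pairwise transcript comparison, deduplicated by (type, coordinate
    signature); inclusion/exclusion transcript sets are unioned across all
    supporting pairs. Genes with fewer than two transcripts yield no events.
    Output order is deterministic and independent of transcript input order.
    """
    if len(g.transcripts) < 2:
        return []
    strand = g.strand
    merged: dict[tuple[str, tuple[int, ...]], dict] = {}
    txs = sorted(g.transcripts, key=lambda t: t.transcript_id)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for gtype, sites, inc, exc, region in _pair_candidates(txs[i], txs[j], strand):
                key = (gtype, sites)
                slot = merged.setdefault(
                    key, {"inc": set(), "exc": set(), "region": region}
                )
                slot["inc"].add(inc)
                slot["exc"].add(exc)
    events = []
    for (gtype, sites), slot in merged.items():
        inc, exc = slot["inc"], slot["exc"]
        if inc & exc:
            # a transcript supporting both forms of one signature is contradictory
            logger.debug("dropping contradictory event %s %s in %s", gtype, sites, g.gene_id)
            continue
        etype = _MINUS_SWAP[gtype] if strand == "-" else gtype
        region = slot["region"]
        vlen = region[1] - region[0] + 1
        event_id = (
            f"{g.gene_id};{etype};{g.chrom}:" + "-".join(map(str, sites)) + f":{strand}"
        )
        events.append(
            SpliceEvent(
                event_id=event_id,
                event_type=etype,
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=strand,
                inclusion_transcripts=frozenset(inc),
                exclusion_transcripts=frozenset(exc),
                defining_sites=tuple(sites),
                variable_region=region,
                variable_region_length=vlen,
                biotype=g.biotype,
            )
        )
    events.sort(key=lambda e: (e.event_type, e.defining_sites))
    return events


def infer_all_events(models: Iterable[GeneModel]) -> list[SpliceEvent]:
    out: list[SpliceEvent] = []
    for g in models:
        out.extend(infer_events(g))
    return out


# ---------------------------------------------------------------------------
# PSI quantification and differential splicing
# ---------------------------------------------------------------------------

def compute_psi(events: Sequence[SpliceEvent], xt: pd.DataFrame) -> pd.DataFrame:
    """Event x sample PSI from transcript TPMs.

    PSI = sum TPM(inclusion) / sum TPM(inclusion | exclusion); NaN when the
    event's transcripts carry no expression in a sample. All transcripts
    referenced by an event must be present in the matrix.
    """
    rows = {}
    for e in events:
        inc = sorted(e.inclusion_transcripts)
        exc = sorted(e.exclusion_transcripts)
        missing = [t for t in inc + exc if t not in xt.index]
        if missing:
            raise KeyError(f"event {e.event_id}: transcripts absent from matrix: {missing}")
        inc_sum = xt.loc[inc].to_numpy(dtype=float).sum(axis=0)
        tot = inc_sum + xt.loc[exc].to_numpy(dtype=float).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(tot > 0, inc_sum / tot, np.nan)
        rows[e.event_id] = psi
    return pd.DataFrame.from_dict(rows, orient="index", columns=xt.columns).rename_axis(
        "event_id"
    )


def filter_events(
    psi: pd.DataFrame, psi_min: float = 0.1, frac_min: float = 0.05
) -> pd.DataFrame:
    """Keep events with PSI > psi_min in at least ceil(frac_min * n) samples.

    Missing PSI values never count toward the threshold.
    """
    need = math.ceil(frac_min * psi.shape[1])
    keep = (psi.to_numpy() > psi_min).sum(axis=1) >= need
    out = psi.loc[keep]
    logger.info("event filter kept %d/%d events", out.shape[0], psi.shape[0])
    return out


def diff_splice(
    psi: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    dpsi_min: float = 0.1,
    alpha: float = 0.05,
    test: str = "rank_sum",
) -> pd.DataFrame:
    """Differential splicing of group_b vs group_a on the PSI matrix.

    Per event: two-sided rank-based two-sample test on non-missing PSI
    (unpaired rank-sum by default; `test="signed_rank"` pairs by rank order
    and requires equal group sizes), delta_psi = median_b - median_a, BH FDR
    over tested events; significant iff |delta_psi| > dpsi_min and
    fdr < alpha. Events with fewer than two non-missing values in either
    group are skipped (logged).
    """
    ca = [s for s in psi.columns if labels.get(s) == group_a]
    cb = [s for s in psi.columns if labels.get(s) == group_b]
    if not ca or not cb:
        raise ValueError("both groups must have samples in the PSI matrix")
    A = psi[ca].to_numpy(dtype=float)
    B = psi[cb].to_numpy(dtype=float)

    ids, dpsi, pvals = [], [], []
    complete = not (np.isnan(A).any() or np.isnan(B).any())
    if complete and test == "rank_sum":
        p_all = adstats.rank_sum_rows(A, B)
        ids = list(psi.index)
        dpsi = list(np.median(B, axis=1) - np.median(A, axis=1))
        pvals = list(p_all)
    else:
        skipped = 0
        for idx, eid in enumerate(psi.index):
            a = A[idx][~np.isnan(A[idx])]
            b = B[idx][~np.isnan(B[idx])]
            if a.size < 2 or b.size < 2:
                skipped += 1
                continue
            ids.append(eid)
            dpsi.append(float(np.median(b) - np.median(a)))
            pvals.append(adstats.rank_tests(a, b, kind=test))
        if skipped:
            logger.info("diff_splice skipped %d events with insufficient data", skipped)

    out = pd.DataFrame({"event_id": ids, "delta_psi": dpsi, "p_value": pvals})
    out["fdr"] = adstats.bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = (out["delta_psi"].abs() > dpsi_min) & (out["fdr"] < alpha)
    return out.set_index("event_id")


# ---------------------------------------------------------------------------
# Frame preservation and summaries
# ---------------------------------------------------------------------------

def intact_codon(e: SpliceEvent) -> bool | None:
    """Whether the event's variable region preserves reading frame.

    True iff the variable genomic region length is a multiple of 3.
    Evaluated for events in protein-coding genes only; returns None
    (not applicable) otherwise. This is a length-based check on the genomic
    region, not a CDS-projected one.
    """
    if e.biotype != "protein_coding":
        return None
    return e.variable_region_length % 3 == 0


def event_summary(
    events: Sequence[SpliceEvent],
    psi: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    psi_min: float = 0.1,
    frac_min: float = 0.05,
) -> pd.DataFrame:
    """Counts and within-biotype percentages of event types.

    Without a PSI matrix, tabulates the full catalog by type x biotype
    (group = "all"). With PSI and labels, tabulates per sample group the
    events that pass the expression filter within that group's samples.
    """
    def _tab(evts: Sequence[SpliceEvent], group: str) -> list[dict]:
        rows = []
        by: dict[tuple[str, str], int] = {}
        for e in evts:
            by[(e.biotype, e.event_type)] = by.get((e.biotype, e.event_type), 0) + 1
        for (bt, et), n in by.items():
            rows.append({"group": group, "biotype": bt, "event_type": et, "count": n})
        return rows

    rows: list[dict] = []
    if psi is None or labels is None:
        rows.extend(_tab(list(events), "all"))
    else:
        by_id = {e.event_id: e for e in events}
        for group in sorted(set(labels)):
            cols = [s for s in psi.columns if labels.get(s) == group]
            if not cols:
                continue
            kept = filter_events(psi[cols], psi_min=psi_min, frac_min=frac_min)
            rows.extend(_tab([by_id[i] for i in kept.index if i in by_id], group))
    df = pd.DataFrame(rows, columns=["group", "biotype", "event_type", "count"])
    if df.empty:
        df["percent"] = []
        return df
    df["percent"] = (
        100.0 * df["count"]
        / df.groupby(["group", "biotype"])["count"].transform("sum")
    )
    return df.sort_values(["group", "biotype", "event_type"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

def events_to_table(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "event_type": e.event_type,
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "defining_sites": ",".join(map(str, e.defining_sites)),
                "variable_region": f"{e.variable_region[0]}-{e.variable_region[1]}",
                "variable_region_length": e.variable_region_length,
                "biotype": e.biotype,
                "inclusion_transcripts": ",".join(sorted(e.inclusion_transcripts)),
                "exclusion_transcripts": ",".join(sorted(e.exclusion_transcripts)),
            }
            for e in events
        ]
    )


def write_ioe(events: Sequence[SpliceEvent], path: str) -> None:
    """Two-column event -> transcripts mapping (inclusion set), IOE-style."""
    with open(path, "w") as fh:
        fh.write("event_id\tinclusion_transcripts\n")
        for e in events:
            fh.write(f"{e.event_id}\t{','.join(sorted(e.inclusion_transcripts))}\n")
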