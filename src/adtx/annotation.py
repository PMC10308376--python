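"""Exon-resolved gene and transcript models, with GTF and BED I/O.

Coordinates are GTF-native throughout the package: 1-based, inclusive on
both ends. BED input (0-based, half-open) is converted on read and
converted back on write, so no other module ever sees a BED coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


def normalize_biotype(raw: str | None) -> str:
    """Map an annotation biotype string onto the four-level scheme used here."""
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA", "antisense", "long_noncoding_RNA"):
        return "lncRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    return "other"


@dataclass(frozen=True, order=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Exon") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.transcript_id} mixes chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"transcript {self.transcript_id} has overlapping exons")
        if self.biotype not in BIOTYPES:
            self.biotype = normalize_biotype(self.biotype)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive; [] for single-exon."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]


def introns(t: TranscriptModel) -> list[tuple[int, int]]:
    return t.introns()


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"gene {self.gene_id} has duplicate transcript ids")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {self.gene_id} mixes chrom/strand")
        if self.biotype not in BIOTYPES:
            self.biotype = normalize_biotype(self.biotype)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def transcript_to_gene(models: Iterable[GeneModel]) -> dict[str, str]:
    """Transcript id -> host gene id mapping over a model collection."""
    out: dict[str, str] = {}
    for g in models:
        for t in g.transcripts:
            out[t.transcript_id] = g.gene_id
    return out


def gene_biotypes(models: Iterable[GeneModel]) -> dict[str, str]:
    return {g.gene_id: g.biotype for g in models}


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE dialect)
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[GeneModel]:
    """Parse a GENCODE-style GTF into GeneModels.

    Only ``exon`` features are used to build structures; gene biotype is
    taken from the ``gene_type`` (or ``gene_biotype``) attribute. Genes and
    transcripts are returned in order of first appearance; exons are sorted
    by genomic start.
    """
    tx_exons: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    gene_order: list[str] = []
    gene_tx: dict[str, list[str]] = {}
    gene_bt: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
                raise ValueError(f"malformed GTF line {lineno}: expected 9 "
                                 "tab-separated fields with integer coordinates")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            gene_ids = attrs.get("gene_id", [])
            tx_ids = attrs.get("transcript_id", [])
            if not gene_ids:
                raise ValueError(f"GTF line {lineno}: exon without gene_id")
            if not tx_ids:
                raise ValueError(f"GTF line {lineno}: exon without transcript_id")
            gid, tid = gene_ids[0], tx_ids[0]
            bt_raw = (attrs.get("gene_type") or attrs.get("gene_biotype") or [None])[0]
            exon = Exon(feat.seqid, feat.start, feat.end, feat.strand)
            if tid not in tx_exons:
                tx_exons[tid] = []
                tx_gene[tid] = gid
                if gid not in gene_tx:
                    gene_tx[gid] = []
                    gene_order.append(gid)
                gene_tx[gid].append(tid)
            tx_exons[tid].append(exon)
            tx_biotype[tid] = normalize_biotype(bt_raw)
            gene_bt.setdefault(gid, normalize_biotype(bt_raw))

    models = []
    for gid in gene_order:
        transcripts = [
            TranscriptModel(tid, gid, tx_biotype[tid], tx_exons[tid])
            for tid in gene_tx[gid]
        ]
        models.append(GeneModel(gid, gene_bt[gid], transcripts))
    return models


def write_gtf(models: Iterable[GeneModel], path: str) -> None:
    """Write GeneModels as GENCODE-dialect GTF (gene/transcript/exon lines)."""
    with open(path, "w") as fh:
        for g in models:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tadtx\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "{g.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tadtx\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tadtx\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# BED I/O (shared with the binding-site machinery)
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED6 file and convert intervals to 1-based inclusive.

    Returns a DataFrame with columns chrom/start/end/name/score/strand where
    start/end follow the package-wide GTF convention.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=BED_COLUMNS,
        dtype={"chrom": str, "name": str},
    )
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    """Write a 1-based inclusive interval table as BED6 (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
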