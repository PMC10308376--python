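"""Synthetic cohort generator with known planted effects.

Emulates the five inputs of the analysis — transcript annotation (GTF),
transcript TPM matrix, sample metadata (CERAD/Braak/MMSE), RBP binding
sites (BED) and gene sets (GMT) — for a three-group brain cohort
(control / AsymAD / AD), with ground truth for every planted effect:

* multi-transcript genes built from template transcript pairs that
  instantiate each of the seven local splicing-event types;
* log-normal TPM noise around per-transcript baselines;
* planted differential transcripts (group mean multiplied by a fold
  change on the log scale);
* planted reciprocal isoform switches in two-transcript genes: the
  isoform-fraction of one transcript rises by `planted_dif` in the
  disease groups while its sibling falls by the same amount, with the
  gene's total expression conserved by construction (transcript values
  share one gene-level noise draw, so gene sums do not depend on the
  planted shares). In a two-transcript gene this shifts the gene's single
  splicing event's PSI by exactly ±planted_dif, so the switch genes'
  events are also the planted differentially spliced events;
* RBP drivers: a per-RBP latent sample variable tilts the inclusion /
  exclusion balance of driven events and the RBP's own log-expression,
  with weight `driver_strength`; every RBP additionally gets a ±25%
  group expression shift so all RBPs pass the 10%-change regulator
  filter and binding evidence is what separates drivers from decoys;
* binding sites inside the ±window of driver events' splice sites,
  decoy sites strictly outside every window for designated non-driver
  pairs, and random background sites inside windows of non-driven
  events so a driver-free network is tested against real candidates;
* metadata drawn uniformly from the defining score ranges of each
  sample's intended group (never from the ambiguous CERAD=3/Braak=3
  cell), so classification recovers the intended groups exactly.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .annotation import Exon, GeneModel, TranscriptModel, write_gtf, write_bed
from .splicing import infer_all_events, infer_events
from . import stats as adstats

EVENT_CYCLE = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")
_MINUS_SWAP = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF",
               "SE": "SE", "RI": "RI", "MX": "MX"}
_GENE_SPACING = 10_000
_FIRST_OFFSET = 20_000
_BIOTYPE_P = {"protein_coding": 0.8, "lncRNA": 0.1, "pseudogene": 0.07, "other": 0.03}


@dataclass
class SimulationConfig:
    n_genes: int = 500
    transcripts_per_gene: tuple[int, int] = (2, 2)
    n_control: int = 60
    n_asymad: int = 60
    n_ad: int = 60
    tpm_log_mean: float = 1.0
    tpm_log_sd: float = 0.5
    frac_det: float = 0.05
    planted_fc: float = 3.0
    frac_switch: float = 0.05
    planted_dif: float = 0.3
    n_rbp: int = 20
    frac_driven_events: float = 0.1
    driver_strength: float = 0.8
    binding_window_bp: int = 300
    frac_frame_preserving: float = 1.0 / 3.0
    affected_groups: tuple[str, ...] = ("asymad", "ad")
    n_random_gene_sets: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_det", "frac_switch", "frac_driven_events",
                     "frac_frame_preserving", "driver_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes <= 0 or self.n_rbp < 0:
            raise ValueError("counts must be positive")
        if min(self.n_control, self.n_asymad, self.n_ad) <= 0:
            raise ValueError("sample counts must be positive")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must exceed 1")
        if not 0 < self.planted_dif <= 0.5:
            raise ValueError("planted_dif must lie in (0, 0.5]")
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid transcripts_per_gene range")


@dataclass
class GroundTruth:
    det_up: set[str] = field(default_factory=set)
    det_down: set[str] = field(default_factory=set)
    switch_up: set[str] = field(default_factory=set)
    switch_down: set[str] = field(default_factory=set)
    differential_events: set[str] = field(default_factory=set)
    driver_edges: set[tuple[str, str]] = field(default_factory=set)
    decoy_pairs: set[tuple[str, str]] = field(default_factory=set)
    background_pairs: set[tuple[str, str]] = field(default_factory=set)
    rbp_directions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "det_up": sorted(self.det_up),
            "det_down": sorted(self.det_down),
            "switch_up": sorted(self.switch_up),
            "switch_down": sorted(self.switch_down),
            "differential_events": sorted(self.differential_events),
            "driver_edges": sorted(map(list, self.driver_edges)),
            "decoy_pairs": sorted(map(list, self.decoy_pairs)),
            "background_pairs": sorted(map(list, self.background_pairs)),
            "rbp_directions": dict(sorted(self.rbp_directions.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            det_up=set(d["det_up"]), det_down=set(d["det_down"]),
            switch_up=set(d["switch_up"]), switch_down=set(d["switch_down"]),
            differential_events=set(d["differential_events"]),
            driver_edges={tuple(e) for e in d["driver_edges"]},
            decoy_pairs={tuple(e) for e in d["decoy_pairs"]},
            background_pairs={tuple(e) for e in d["background_pairs"]},
            rbp_directions=d["rbp_directions"],
        )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _vlen(rng: np.random.Generator, frame_ok: bool, lo: int = 60, hi: int = 240) -> int:
    """Variable-region length with controlled mod-3 residue."""
    v = int(rng.integers(lo, hi))
    r = v % 3
    if frame_ok:
        v -= r
    elif r == 0:
        v += 1
    return v


def _template(kind: str, o: int, rng: np.random.Generator, frame_ok: bool):
    """Exon coordinate lists (t1, t2) for one genomic-orientation template.

    t1 carries the inclusion-form structure; the variable-region length is
    frame-controlled.
    """
    e1 = int(rng.integers(80, 200))
    e2 = int(rng.integers(80, 200))
    e3 = int(rng.integers(80, 200))
    i1 = int(rng.integers(100, 400))
    i2 = int(rng.integers(100, 400))
    i3 = int(rng.integers(100, 400))
    v = _vlen(rng, frame_ok)
    if kind == "SE":
        p = o + e1 + i1
        q = p + v + i2
        return ([(o, o + e1 - 1), (p, p + v - 1), (q, q + e3 - 1)],
                [(o, o + e1 - 1), (q, q + e3 - 1)])
    if kind == "RI":
        return ([(o, o + e1 + v + e2 - 1)],
                [(o, o + e1 - 1), (o + e1 + v, o + e1 + v + e2 - 1)])
    if kind == "A5":  # genomic-left alternative boundary
        c = o + e1 + v + i1
        return ([(o, o + e1 + v - 1), (c, c + e2 - 1)],
                [(o, o + e1 - 1), (c, c + e2 - 1)])
    if kind == "A3":  # genomic-right alternative boundary
        c = o + e1 + i1 + v
        return ([(o, o + e1 - 1), (c - v, c + e2 - 1)],
                [(o, o + e1 - 1), (c, c + e2 - 1)])
    if kind == "MX":
        v2 = _vlen(rng, frame_ok)
        p = o + e1 + i1
        r = p + v + i2
        q = r + v2 + i3
        return ([(o, o + e1 - 1), (p, p + v - 1), (q, q + e3 - 1)],
                [(o, o + e1 - 1), (r, r + v2 - 1), (q, q + e3 - 1)])
    if kind == "AF":  # genomic-left alternative first exon
        p = o + v + i1
        c = p + e1 + i2
        return ([(o, o + v - 1), (c, c + e2 - 1)],
                [(p, p + e1 - 1), (c, c + e2 - 1)])
    if kind == "AL":  # genomic-right alternative last exon
        c1 = o + e1 + i1
        c2 = c1 + e2 + i2
        return ([(o, o + e1 - 1), (c2, c2 + v - 1)],
                [(o, o + e1 - 1), (c1, c1 + e2 - 1)])
    raise ValueError(f"unknown template kind {kind!r}")


def simulate_annotation(cfg: SimulationConfig) -> list[GeneModel]:
    """Gene models whose transcript pairs instantiate the seven event types.

    Multi-transcript genes cycle through the seven types (on either strand;
    side-sensitive templates are mirrored on '-' so the realised type is the
    intended one). Additional transcripts beyond the template pair copy the
    inclusion structure. `frac_frame_preserving` of the variable regions
    have length divisible by 3.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.transcripts_per_gene
    models = []
    type_idx = 0
    bt_names = list(_BIOTYPE_P)
    bt_probs = np.array(list(_BIOTYPE_P.values()))
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:05d}"
        o = _FIRST_OFFSET + i * _GENE_SPACING
        n_tx = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = bt_names[int(rng.choice(len(bt_names), p=bt_probs))]
        frame_ok = rng.random() < cfg.frac_frame_preserving
        if n_tx == 1:
            e1 = int(rng.integers(80, 200))
            e2 = int(rng.integers(80, 200))
            i1 = int(rng.integers(100, 400))
            exons = [(o, o + e1 - 1), (o + e1 + i1, o + e1 + i1 + e2 - 1)]
            txs = [TranscriptModel(f"{gid}.t1", gid, biotype,
                                   [Exon("chr1", s, e, strand) for s, e in exons])]
        else:
            etype = EVENT_CYCLE[type_idx % len(EVENT_CYCLE)]
            type_idx += 1
            genomic_kind = _MINUS_SWAP[etype] if strand == "-" else etype
            ex1, ex2 = _template(genomic_kind, o, rng, frame_ok)
            structures = [ex1, ex2] + [ex1] * (n_tx - 2)
            txs = [
                TranscriptModel(
                    f"{gid}.t{k + 1}", gid, biotype,
                    [Exon("chr1", s, e, strand) for s, e in ex],
                )
                for k, ex in enumerate(structures)
            ]
        models.append(GeneModel(gid, biotype, txs))
    return models


# ---------------------------------------------------------------------------
# Expression, metadata, ground truth
# ---------------------------------------------------------------------------

_GROUP_SCORES = {
    # (cerad choices, braak choices, mmse range inclusive)
    "control": ((3, 4), (0, 1, 2), (24, 30)),
    "asymad": ((1, 2, 3), (3, 4, 5, 6), (24, 30)),
    "ad": ((1, 2), (3, 4, 5, 6), (0, 23)),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_expression(
    models: list[GeneModel], cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """TPM matrix (transcripts + RBP pseudo-genes), metadata, ground truth.

    Returns (expression, metadata, truth). Expression columns are sample
    ids; metadata has columns sample_id/cerad/braak/mmse plus the intended
    group for reference.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    groups = (["control"] * cfg.n_control + ["asymad"] * cfg.n_asymad
              + ["ad"] * cfg.n_ad)
    sample_ids = (
        [f"ctrl_{i + 1:03d}" for i in range(cfg.n_control)]
        + [f"asymad_{i + 1:03d}" for i in range(cfg.n_asymad)]
        + [f"ad_{i + 1:03d}" for i in range(cfg.n_ad)]
    )
    n_s = len(sample_ids)
    group_arr = np.array(groups)
    disease_mask = np.isin(group_arr, list(cfg.affected_groups))

    tx_ids = [t.transcript_id for g in models for t in g.transcripts]
    tx_index = {t: i for i, t in enumerate(tx_ids)}
    rbp_ids = [f"RBP{r + 1:03d}" for r in range(cfg.n_rbp)]
    n_tx = len(tx_ids)

    # --- effect assignment (dedicated stream so sizes don't shift noise) ---
    arng = np.random.default_rng([cfg.seed, 11])
    two_tx = [g for g in models if len(g.transcripts) == 2]
    n_switch = int(round(cfg.frac_switch * cfg.n_genes))
    switch_genes = list(
        arng.choice([g.gene_id for g in two_tx], size=min(n_switch, len(two_tx)),
                    replace=False)
    ) if (n_switch and two_tx) else []
    switch_set = set(switch_genes)

    # fold changes are planted on whole host genes (every member transcript
    # scaled together) so isoform fractions and PSI stay untouched; each
    # member transcript is recorded as a planted DET
    eligible_genes = [g.gene_id for g in models if g.gene_id not in switch_set]
    n_det = int(round(cfg.frac_det * n_tx))
    det_up: set[str] = set()
    det_down: set[str] = set()
    det_hosts: set[str] = set()
    if n_det and eligible_genes:
        order = list(arng.permutation(eligible_genes))
        gene_by_id_tmp = {g.gene_id: g for g in models}
        planted = 0
        for k, gid in enumerate(order):
            if planted >= n_det:
                break
            txs = [t.transcript_id for t in gene_by_id_tmp[gid].transcripts]
            (det_up if k % 2 == 0 else det_down).update(txs)
            det_hosts.add(gid)
            planted += len(txs)

    driven_eligible = [g for g in two_tx
                       if g.gene_id not in switch_set and g.gene_id not in det_hosts]
    n_driven = int(round(cfg.frac_driven_events * len(driven_eligible)))
    driven_genes = list(
        arng.choice([g.gene_id for g in driven_eligible],
                    size=min(n_driven, len(driven_eligible)), replace=False)
    ) if (n_driven and cfg.n_rbp and driven_eligible) else []
    gene_by_id = {g.gene_id: g for g in models}
    driver_of: dict[str, str] = {
        gid: rbp_ids[k % cfg.n_rbp] for k, gid in enumerate(driven_genes)
    }

    # --- baselines and noise ---------------------------------------------
    mu = cfg.tpm_log_mean + rng.normal(0.0, 1.0, n_tx)
    eps = rng.normal(0.0, 1.0, (n_tx, n_s))
    mu_r = cfg.tpm_log_mean + rng.normal(0.0, 1.0, cfg.n_rbp)
    eps_r = rng.normal(0.0, 1.0, (cfg.n_rbp, n_s))
    z = rng.normal(0.0, 1.0, (cfg.n_rbp, n_s))  # latent driver variables

    log_fc = np.log(cfg.planted_fc)
    beta = np.zeros((n_tx, n_s))
    for t in det_up:
        beta[tx_index[t], disease_mask] = log_fc
    for t in det_down:
        beta[tx_index[t], disease_mask] = -log_fc

    X = np.exp(mu[:, None] + beta + cfg.tpm_log_sd * eps)

    # --- paired genes: switches and driver-tilted events -------------------
    # both transcripts share one gene-level noise draw, so the per-sample
    # gene sum never depends on the planted shares or tilt
    amp = 2.0 * cfg.driver_strength
    sd_logit = np.sqrt(2.0) * cfg.tpm_log_sd
    rbp_pos = {r: i for i, r in enumerate(rbp_ids)}
    for gid in list(switch_genes) + list(driven_genes):
        g = gene_by_id[gid]
        i1 = tx_index[g.transcripts[0].transcript_id]
        i2 = tx_index[g.transcripts[1].transcript_id]
        pair_total = np.exp(mu[i1]) + np.exp(mu[i2])
        gene_noise = np.exp(cfg.tpm_log_sd * eps[i1])
        base_share = np.full(n_s, 0.5)
        tilt = np.zeros(n_s)
        if gid in switch_set:
            base_share = np.where(disease_mask, 0.5 + cfg.planted_dif / 2,
                                  0.5 - cfg.planted_dif / 2)
        else:
            tilt = amp * z[rbp_pos[driver_of[gid]]]
        logit = np.log(base_share / (1 - base_share))
        q = _sigmoid(logit + tilt + sd_logit * eps[i2])
        X[i1] = pair_total * gene_noise * q
        X[i2] = pair_total * gene_noise * (1 - q)

    # --- RBP pseudo-genes ---------------------------------------------------
    driver_rbps = set(driver_of.values())
    rbp_directions = {r: ("up" if i % 2 == 0 else "down") for i, r in enumerate(rbp_ids)}
    shift = np.log(1.25)
    ds = cfg.driver_strength
    R = np.empty((cfg.n_rbp, n_s))
    for i, r in enumerate(rbp_ids):
        delta = np.where(disease_mask, shift if rbp_directions[r] == "up" else -shift, 0.0)
        if r in driver_rbps:
            noise = cfg.tpm_log_sd * (ds * z[i] + np.sqrt(1 - ds**2) * eps_r[i])
        else:
            noise = cfg.tpm_log_sd * eps_r[i]
        R[i] = np.exp(mu_r[i] + delta + noise)

    expr = pd.DataFrame(
        np.vstack([X, R]) if cfg.n_rbp else X,
        index=pd.Index(tx_ids + rbp_ids, name="transcript_id"),
        columns=sample_ids,
    )

    # --- metadata -----------------------------------------------------------
    mrng = np.random.default_rng([cfg.seed, 12])
    rows = []
    for sid, grp in zip(sample_ids, groups):
        cerads, braaks, (m_lo, m_hi) = _GROUP_SCORES[grp]
        rows.append({
            "sample_id": sid,
            "cerad": int(mrng.choice(cerads)),
            "braak": int(mrng.choice(braaks)),
            "mmse": int(mrng.integers(m_lo, m_hi + 1)),
            "intended_group": grp,
        })
    metadata = pd.DataFrame(rows)

    # --- ground truth -------------------------------------------------------
    truth = GroundTruth(det_up=det_up, det_down=det_down,
                        rbp_directions=rbp_directions)
    for gid in switch_genes:
        g = gene_by_id[gid]
        truth.switch_up.add(g.transcripts[0].transcript_id)
        truth.switch_down.add(g.transcripts[1].transcript_id)
        for e in infer_events(g):
            truth.differential_events.add(e.event_id)
    for gid, rbp in driver_of.items():
        for e in infer_events(gene_by_id[gid]):
            truth.driver_edges.add((rbp, e.event_id))
    return expr, metadata, truth


# ---------------------------------------------------------------------------
# Binding sites
# ---------------------------------------------------------------------------

def simulate_binding_sites(
    models: list[GeneModel], truth: GroundTruth, cfg: SimulationConfig,
    site_width: int = 20, frac_background_bound: float = 0.25,
) -> pd.DataFrame:
    """Binding-site intervals (1-based inclusive) with rbp ids in `name`.

    Driver pairs get >= 1 interval inside the ±window of one defining site
    (containing the site exactly when the window is 0). Decoy intervals for
    designated non-driver pairs sit strictly farther than the window from
    every defining site of their event. Background pairs put a non-driver
    RBP inside the window of a non-driven event so correlation, not
    binding, decides those edges. Updates truth.decoy_pairs /
    truth.background_pairs in place.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    events = infer_all_events(models)
    by_id = {e.event_id: e for e in events}
    rbp_ids = sorted(truth.rbp_directions) or [f"RBP{r + 1:03d}" for r in range(cfg.n_rbp)]
    w = cfg.binding_window_bp
    rows = []

    def _inside(site: int) -> tuple[int, int]:
        if w == 0:
            return site, site
        width = min(site_width, 2 * w + 1)
        lo = site - w
        hi = site + w - width + 1
        start = int(rng.integers(lo, hi + 1))
        return start, start + width - 1

    driven_events = {eid for _, eid in truth.driver_edges}
    for rbp, eid in sorted(truth.driver_edges):
        e = by_id[eid]
        site = int(rng.choice(e.defining_sites))
        start, end = _inside(site)
        rows.append({"chrom": e.chrom, "start": start, "end": end,
                     "name": rbp, "score": 0, "strand": e.strand})
        # decoy: a non-driver RBP strictly outside every window of this event
        others = [r for r in rbp_ids if (r, eid) not in truth.driver_edges]
        if others:
            decoy_rbp = str(rng.choice(others))
            end_d = min(e.defining_sites) - w - 1 - int(rng.integers(100, 500))
            rows.append({"chrom": e.chrom, "start": max(1, end_d - site_width + 1),
                         "end": max(1, end_d), "name": decoy_rbp, "score": 0,
                         "strand": e.strand})
            truth.decoy_pairs.add((decoy_rbp, eid))

    if rbp_ids:
        for e in events:
            if e.event_id in driven_events:
                continue
            if rng.random() < frac_background_bound:
                rbp = str(rng.choice(rbp_ids))
                site = int(rng.choice(e.defining_sites))
                start, end = _inside(site)
                rows.append({"chrom": e.chrom, "start": start, "end": end,
                             "name": rbp, "score": 0, "strand": e.strand})
                truth.background_pairs.add((rbp, e.event_id))

    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    models: list[GeneModel], truth: GroundTruth, cfg: SimulationConfig
) -> dict[str, set[str]]:
    """GMT-style gene sets: one per planted-effect category plus random sets."""
    rng = np.random.default_rng([cfg.seed, 3])
    tx_host = {t.transcript_id: g.gene_id for g in models for t in g.transcripts}
    all_genes = sorted({g.gene_id for g in models})
    ev_gene = lambda eid: eid.split(";", 1)[0]  # noqa: E731
    sets: dict[str, set[str]] = {
        "planted_det_up": {tx_host[t] for t in truth.det_up},
        "planted_det_down": {tx_host[t] for t in truth.det_down},
        "planted_switch": {tx_host[t] for t in truth.switch_up | truth.switch_down},
        "planted_driven": {ev_gene(eid) for _, eid in truth.driver_edges},
    }
    sets = {k: v for k, v in sets.items() if v}
    for i in range(cfg.n_random_gene_sets):
        size = int(rng.integers(20, 51))
        size = min(size, len(all_genes))
        sets[f"random_set_{i + 1:02d}"] = set(rng.choice(all_genes, size=size,
                                                         replace=False))
    return sets


# ---------------------------------------------------------------------------
# Bundled cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    models: list[GeneModel]
    expression: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth
    binding: pd.DataFrame
    gene_sets: dict[str, set[str]]
    rbp_ids: list[str]

    @property
    def intended_labels(self) -> pd.Series:
        return self.metadata.set_index("sample_id")["intended_group"].rename("label")

    def write(self, outdir: str) -> dict[str, str]:
        """Write every artifact and a YAML manifest of the paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gtf": os.path.join(outdir, "annotation.gtf"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "metadata": os.path.join(outdir, "metadata.tsv"),
            "binding": os.path.join(outdir, "binding_sites.bed"),
            "rbp_list": os.path.join(outdir, "rbps.txt"),
            "gene_sets": os.path.join(outdir, "gene_sets.gmt"),
            "ground_truth": os.path.join(outdir, "ground_truth.json"),
            "config": os.path.join(outdir, "inputs.yaml"),
        }
        write_gtf(self.models, paths["gtf"])
        self.expression.to_csv(paths["expression"], sep="\t")
        self.metadata[["sample_id", "cerad", "braak", "mmse"]].to_csv(
            paths["metadata"], sep="\t", index=False
        )
        write_bed(self.binding, paths["binding"])
        with open(paths["rbp_list"], "w") as fh:
            fh.write("\n".join(self.rbp_ids) + ("\n" if self.rbp_ids else ""))
        adstats.write_gmt(self.gene_sets, paths["gene_sets"])
        self.truth.to_json(paths["ground_truth"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(
                {"paths": {k: os.path.basename(v) for k, v in paths.items()
                           if k != "config"},
                 "seed": self.config.seed}, fh, sort_keys=True)
        return paths


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Run the three generators and bundle the full synthetic cohort."""
    models = simulate_annotation(cfg)
    expr, metadata, truth = simulate_expression(models, cfg)
    binding = simulate_binding_sites(models, truth, cfg)
    gene_sets = simulate_gene_sets(models, truth, cfg)
    rbp_ids = sorted(truth.rbp_directions)
    return SimulatedCohort(cfg, models, expr, metadata, truth, binding, gene_sets, rbp_ids)
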