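"""End-to-end orchestration: simulate/load -> classify -> filter -> DET ->
events -> PSI -> differential splicing -> switches -> RBP network -> ORA.

Every stage writes a TSV whose first line is a comment embedding the
effective configuration, plus a JSON run manifest with row counts per
stage. Outputs are byte-reproducible under a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, cohort, diffexpr, rbpnet, splicing
from . import simulate as sim
from . import stats as adstats
from . import switch as sw

logger = logging.getLogger(__name__)

VALID_GROUPS = ("control", "asymad", "ad")
DEFAULT_COMPARISONS = (("control", "asymad"), ("control", "ad"), ("asymad", "ad"))


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run.

    Threshold defaults are the analysis' canonical values: TPM filter
    0.1/5%, DET fold change 1.5 / 0.67 at FDR 0.05, PSI filter 0.1/5%,
    |dPSI| 0.1, |dIF| 0.1, |rho| 0.5, binding window ±300 bp, RBP
    expression change 10%.
    """

    # input paths (ignored when simulating)
    gtf: str | None = None
    expression: str | None = None
    metadata: str | None = None
    binding: str | None = None
    rbp_list: str | None = None
    gene_sets: str | None = None
    # thresholds
    tpm_min: float = 0.1
    frac_min: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.67
    fdr: float = 0.05
    psi_min: float = 0.1
    dpsi_min: float = 0.1
    dif_min: float = 0.1
    rho_min: float = 0.5
    window_bp: int = 300
    rbp_change_min: float = 0.1
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    splice_test: str = "rank_sum"
    precedence: tuple[str, ...] = cohort.DEFAULT_PRECEDENCE
    seed: int = 0
    simulation: sim.SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("tpm_min", "frac_min", "fdr", "psi_min", "dpsi_min",
                     "dif_min", "rho_min", "rbp_change_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.comparisons = tuple(tuple(c) for c in self.comparisons)
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in VALID_GROUPS:
                    raise ValueError(f"unknown group label {g!r} in comparisons")

    def thresholds(self) -> dict:
        keys = ("tpm_min", "frac_min", "fc_up", "fc_down", "fdr", "psi_min",
                "dpsi_min", "dif_min", "rho_min", "window_bp", "rbp_change_min")
        return {k: getattr(self, k) for k in keys}

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simcfg = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if simcfg:
            if "transcripts_per_gene" in simcfg:
                simcfg["transcripts_per_gene"] = tuple(simcfg["transcripts_per_gene"])
            if "affected_groups" in simcfg:
                simcfg["affected_groups"] = tuple(simcfg["affected_groups"])
            cfg.simulation = sim.SimulationConfig(**simcfg)
        return cfg


def _write_table(df: pd.DataFrame, path: str, cfg: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("# adtx " + json.dumps(
            {"version": __version__, "seed": cfg.seed, **cfg.thresholds()},
            sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_expression(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_metadata(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"sample_id": str, "cerad": int, "braak": int, "mmse": int})


def run_all(cfg: RunConfig, run_dir: str, simulate: bool = False) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    With `simulate`, inputs are generated under <run_dir>/inputs from
    cfg.simulation (defaults if unset); otherwise cfg paths must exist.
    Fails before any computation on invalid group labels; a failing stage
    leaves earlier outputs in place.
    """
    os.makedirs(run_dir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "comparisons": [list(c) for c in cfg.comparisons],
        "versions": {"adtx": __version__},
        "stages": {},
    }

    def record(stage: str, rows: int, path: str | None = None) -> None:
        manifest["stages"][stage] = {
            "rows": int(rows),
            **({"path": os.path.relpath(path, run_dir)} if path else {}),
        }
        logger.info("stage %-22s rows=%d", stage, rows)

    # --- inputs -----------------------------------------------------------
    gene_sets: dict[str, set[str]] | None = None
    binding_df: pd.DataFrame | None = None
    rbp_ids: list[str] = []
    if simulate:
        simcfg = cfg.simulation or sim.SimulationConfig(seed=cfg.seed)
        cohort_data = sim.simulate_cohort(simcfg)
        paths = cohort_data.write(os.path.join(run_dir, "inputs"))
        models = cohort_data.models
        expr = cohort_data.expression
        metadata = cohort_data.metadata[["sample_id", "cerad", "braak", "mmse"]]
        binding_df = cohort_data.binding
        rbp_ids = cohort_data.rbp_ids
        gene_sets = cohort_data.gene_sets
        manifest["inputs"] = {k: os.path.relpath(v, run_dir) for k, v in paths.items()}
    else:
        if not (cfg.gtf and cfg.expression and cfg.metadata):
            raise ValueError("gtf, expression and metadata paths are required "
                             "unless simulating")
        models = annotation.read_gtf(cfg.gtf)
        expr = read_expression(cfg.expression)
        metadata = read_metadata(cfg.metadata)
        if cfg.binding:
            binding_df = annotation.read_bed(cfg.binding)
        if cfg.rbp_list:
            with open(cfg.rbp_list) as fh:
                rbp_ids = [ln.strip() for ln in fh if ln.strip()]
        if cfg.gene_sets:
            gene_sets = adstats.read_gmt(cfg.gene_sets)
    tx2gene = annotation.transcript_to_gene(models)
    biotype_of = annotation.gene_biotypes(models)

    # --- classify ---------------------------------------------------------
    labels = cohort.classify_table(metadata, precedence=tuple(cfg.precedence))
    _write_table(labels.to_frame(), os.path.join(run_dir, "labels.tsv"), cfg)
    record("classify", len(labels), os.path.join(run_dir, "labels.tsv"))
    present = set(labels)
    for a, b in cfg.comparisons:
        if a not in present or b not in present:
            logger.warning("comparison (%s, %s): group absent from cohort", a, b)

    # --- expression filter -------------------------------------------------
    expr_f = cohort.filter_low_expression(expr, cfg.tpm_min, cfg.frac_min)
    _write_table(expr_f, os.path.join(run_dir, "expression_filtered.tsv"), cfg)
    record("filter", expr_f.shape[0], os.path.join(run_dir, "expression_filtered.tsv"))

    comparisons = [(a, b) for a, b in cfg.comparisons if a in present and b in present]

    # --- differential transcript expression --------------------------------
    det_tables: dict[tuple[str, str], pd.DataFrame] = {}
    tx_rows = expr_f.loc[[t for t in expr_f.index if t in tx2gene]]
    for a, b in comparisons:
        det = diffexpr.det_test(tx_rows, labels, a, b, fc_up=cfg.fc_up,
                                fc_down=cfg.fc_down, alpha=cfg.fdr)
        det_tables[(a, b)] = det
        p = os.path.join(run_dir, f"det_{a}_vs_{b}.tsv")
        _write_table(det, p, cfg)
        record(f"det_{a}_vs_{b}", len(det), p)

    if {"control", "asymad", "ad"} <= present:
        _, crosstab = diffexpr.twenty_percent_sets(tx_rows, labels, "control",
                                                   "asymad", "ad")
        p = os.path.join(run_dir, "twenty_percent_crosstab.tsv")
        _write_table(crosstab, p, cfg)
        record("twenty_percent", int(crosstab.to_numpy().sum()), p)

    # --- transcript / host-gene correlation ---------------------------------
    corr = diffexpr.host_gene_correlation(tx_rows, tx2gene)
    _write_table(corr, os.path.join(run_dir, "host_correlation.tsv"), cfg)
    record("host_correlation", len(corr), os.path.join(run_dir, "host_correlation.tsv"))
    frac = diffexpr.expression_fraction(tx_rows, tx2gene, corr)
    _write_table(frac, os.path.join(run_dir, "expression_fraction.tsv"), cfg)
    record("expression_fraction", len(frac),
           os.path.join(run_dir, "expression_fraction.tsv"))

    # --- splicing events and PSI -------------------------------------------
    events = splicing.infer_all_events(models)
    events = [e for e in events
              if set(e.inclusion_transcripts | e.exclusion_transcripts)
              <= set(expr_f.index)]
    ev_table = splicing.events_to_table(events)
    _write_table(ev_table, os.path.join(run_dir, "events.tsv"), cfg, index=False)
    splicing.write_ioe(events, os.path.join(run_dir, "events.ioe"))
    record("events", len(events), os.path.join(run_dir, "events.tsv"))

    psi = splicing.compute_psi(events, expr_f)
    psi = splicing.filter_events(psi, psi_min=cfg.psi_min, frac_min=cfg.frac_min)
    _write_table(psi, os.path.join(run_dir, "psi.tsv"), cfg)
    record("psi", psi.shape[0], os.path.join(run_dir, "psi.tsv"))

    frame = pd.DataFrame(
        [{"event_id": e.event_id,
          "intact_codon": splicing.intact_codon(e)} for e in events]
    ).set_index("event_id")
    _write_table(frame, os.path.join(run_dir, "intact_codon.tsv"), cfg)
    record("intact_codon", len(frame), os.path.join(run_dir, "intact_codon.tsv"))

    diff_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in comparisons:
        ds = splicing.diff_splice(psi, labels, a, b, dpsi_min=cfg.dpsi_min,
                                  alpha=cfg.fdr, test=cfg.splice_test)
        diff_tables[(a, b)] = ds
        p = os.path.join(run_dir, f"diffsplice_{a}_vs_{b}.tsv")
        _write_table(ds, p, cfg)
        record(f"diffsplice_{a}_vs_{b}", len(ds), p)

    # --- isoform switches ---------------------------------------------------
    ifm = sw.compute_if(expr_f, tx2gene)
    for a, b in comparisons:
        res = sw.detect_switches(ifm, labels, a, b, tx2gene,
                                 dif_min=cfg.dif_min, alpha=cfg.fdr)
        p = os.path.join(run_dir, f"switch_{a}_vs_{b}.tsv")
        _write_table(res, p, cfg)
        record(f"switch_{a}_vs_{b}", len(res), p)
        rep = sw.switch_vs_gene_expression(tx_rows, tx2gene, res, labels, a, b,
                                           alpha=cfg.fdr)
        p2 = os.path.join(run_dir, f"switch_gene_expression_{a}_vs_{b}.tsv")
        _write_table(rep, p2, cfg)
        record(f"switch_gene_expr_{a}_vs_{b}", len(rep), p2)

    # --- RBP network --------------------------------------------------------
    if binding_df is not None and rbp_ids:
        sites = rbpnet.sites_from_bed(binding_df, rbp_ids)
        xr = expr_f.loc[[r for r in rbp_ids if r in expr_f.index]]
        for a, b in comparisons:
            diff_ids = diff_tables[(a, b)].index[
                diff_tables[(a, b)]["significant"]]
            edges = rbpnet.build_network(
                psi, xr, events, sites, diff_ids, labels, a, b,
                rho_min=cfg.rho_min, alpha=0.05, window_bp=cfg.window_bp,
                min_change=cfg.rbp_change_min,
            )
            p = os.path.join(run_dir, f"rbp_edges_{a}_vs_{b}.tsv")
            _write_table(edges, p, cfg, index=False)
            record(f"rbpnet_{a}_vs_{b}", len(edges), p)
            universe = {tx2gene[t] for t in tx_rows.index}
            summary = rbpnet.rbp_summary(edges, events, gene_sets, universe)
            p2 = os.path.join(run_dir, f"rbp_summary_{a}_vs_{b}.tsv")
            _write_table(summary, p2, cfg)
            record(f"rbp_summary_{a}_vs_{b}", len(summary), p2)

    # --- over-representation of DET host genes ------------------------------
    if gene_sets:
        universe = {tx2gene[t] for t in tx_rows.index
                    if biotype_of.get(tx2gene[t]) == "protein_coding"}
        for (a, b), det in det_tables.items():
            hits = {tx2gene[t] for t in det.index[det["direction"] != "none"]
                    if tx2gene[t] in universe}
            if not universe:
                continue
            res = adstats.ora(hits, gene_sets, universe)
            p = os.path.join(run_dir, f"ora_det_{a}_vs_{b}.tsv")
            _write_table(res, p, cfg, index=False)
            record(f"ora_det_{a}_vs_{b}", len(res), p)

    with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(run_dir: str) -> dict[str, pd.DataFrame]:
    """Summary tables from a completed run directory.

    Produces the cross-comparison DET overlap table (shared/specific and
    discordant up/down classes for AsymAD vs AD), event-type tabulations,
    switch usage counts and RBP target counts. Missing stage outputs are
    listed as absent rather than failing. Tables are written under
    <run_dir>/report and returned.
    """
    out: dict[str, pd.DataFrame] = {}
    missing: list[str] = []
    rep_dir = os.path.join(run_dir, "report")
    os.makedirs(rep_dir, exist_ok=True)

    def _load(name: str, index_col=0) -> pd.DataFrame | None:
        path = os.path.join(run_dir, name)
        if not os.path.exists(path):
            missing.append(name)
            return None
        return read_table(path, index_col=index_col)

    det_a = _load("det_control_vs_asymad.tsv")
    det_b = _load("det_control_vs_ad.tsv")
    if det_a is not None and det_b is not None:
        joint = det_a[["direction"]].join(det_b[["direction"]],
                                          lsuffix="_asymad", rsuffix="_ad", how="outer")
        joint = joint.fillna("none")
        order = ["up", "down", "none"]
        overlap = (
            pd.crosstab(joint["direction_asymad"], joint["direction_ad"])
            .reindex(index=order, columns=order, fill_value=0)
            .rename_axis(index="asymad", columns="ad")
        )
        out["det_overlap"] = overlap

    ev = _load("events.tsv", index_col=None)
    if ev is not None and len(ev):
        tab = (ev.groupby(["biotype", "event_type"]).size()
               .rename("count").reset_index())
        tab["percent"] = (100.0 * tab["count"]
                          / tab.groupby("biotype")["count"].transform("sum"))
        out["event_types"] = tab

    frame = _load("intact_codon.tsv")
    if frame is not None and len(frame):
        applicable = frame.dropna(subset=["intact_codon"])
        if len(applicable):
            out["intact_codon"] = pd.DataFrame(
                {"n_events": [len(applicable)],
                 "fraction_intact": [float(applicable["intact_codon"].mean())]}
            )

    for a, b in DEFAULT_COMPARISONS:
        swt = _load(f"switch_{a}_vs_{b}.tsv")
        if swt is not None and len(swt):
            counts = swt["usage"].value_counts()
            out[f"switch_usage_{a}_vs_{b}"] = counts.rename_axis("usage").to_frame("count")
        summ = _load(f"rbp_summary_{a}_vs_{b}.tsv")
        if summ is not None and len(summ):
            out[f"rbp_summary_{a}_vs_{b}"] = summ

    for name, df in out.items():
        df.to_csv(os.path.join(rep_dir, f"{name}.tsv"), sep="\t")
    with open(os.path.join(rep_dir, "missing.txt"), "w") as fh:
        fh.write("\n".join(missing) + ("\n" if missing else ""))
    if missing:
        logger.warning("report: %d stage outputs absent: %s", len(missing), missing)
    return out
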