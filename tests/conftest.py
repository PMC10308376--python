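"""Shared fixtures: hand-built splicing-event templates and small cohorts.

The seven-template annotation is constructed by hand (independent of the
simulator) with expected event coordinates enumerated from the local-event
definitions, so event inference is checked against a human-derived oracle.
"""

from __future__ import annotations

import pytest

from adtx.annotation import Exon, GeneModel, TranscriptModel
from adtx.simulate import SimulationConfig, simulate_cohort


def _gene(gene_id, biotype, strand, structures, chrom="chr1"):
    txs = [
        TranscriptModel(
            f"{gene_id}.t{i + 1}", gene_id, biotype,
            [Exon(chrom, s, e, strand) for s, e in ex],
        )
        for i, ex in enumerate(structures)
    ]
    return GeneModel(gene_id, biotype, txs)


# expected: type, defining sites, variable-region length, inclusion tx index
SEVEN_TEMPLATES = {
    "SE": dict(
        structures=[[(1, 100), (200, 300), (400, 500)], [(1, 100), (400, 500)]],
        sites=(100, 200, 300, 400), var_len=101, inclusion=0,
    ),
    "RI": dict(
        structures=[[(1, 100), (200, 300)], [(1, 300)]],
        sites=(1, 100, 200, 300), var_len=99, inclusion=1,
    ),
    "A5": dict(
        structures=[[(1, 150), (300, 400)], [(1, 100), (300, 400)]],
        sites=(100, 150, 300), var_len=50, inclusion=0,
    ),
    "A3": dict(
        structures=[[(1, 100), (250, 400)], [(1, 100), (300, 400)]],
        sites=(100, 250, 300), var_len=50, inclusion=0,
    ),
    "MX": dict(
        structures=[[(1, 100), (200, 250), (600, 700)],
                    [(1, 100), (400, 450), (600, 700)]],
        sites=(100, 200, 250, 400, 450, 600), var_len=51, inclusion=0,
    ),
    "AF": dict(
        structures=[[(1, 100), (400, 500)], [(200, 300), (400, 500)]],
        sites=(1, 100, 200, 300, 400), var_len=100, inclusion=0,
    ),
    "AL": dict(
        structures=[[(1, 100), (200, 300)], [(1, 100), (400, 500)]],
        sites=(100, 200, 300, 400, 500), var_len=101, inclusion=1,
    ),
}


def mirror_gene(g: GeneModel, around: int = 10_000) -> GeneModel:
    """Strand-mirrored copy: coordinates reflected, strand flipped."""
    new_strand = "-" if g.strand == "+" else "+"
    structures = []
    for t in g.transcripts:
        structures.append(
            sorted((around - e.end, around - e.start) for e in t.exons)
        )
    return _gene(g.gene_id, g.biotype, new_strand, structures, chrom=g.chrom)


@pytest.fixture(scope="session")
def seven_templates() -> dict[str, GeneModel]:
    return {
        etype: _gene(f"GENE_{etype}", "protein_coding", "+", spec["structures"])
        for etype, spec in SEVEN_TEMPLATES.items()
    }


@pytest.fixture(scope="session")
def planted_cohort():
    """Default study-condition cohort: 1000 two-transcript genes, 60/group,
    planted fold change 3, reciprocal dIF 0.3, RBP drivers at strength 0.8."""
    return simulate_cohort(SimulationConfig(n_genes=1000, seed=5))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects; used for calibration checks."""
    return simulate_cohort(
        SimulationConfig(n_genes=400, seed=3, frac_det=0, frac_switch=0,
                         frac_driven_events=0)
    )
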