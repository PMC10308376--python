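"""Splicing-event inference, PSI quantification and frame annotation."""

import numpy as np
import pandas as pd
import pytest

from adtx.annotation import Exon, GeneModel, TranscriptModel
from adtx.simulate import SimulationConfig, simulate_annotation
from adtx.splicing import (
    compute_psi,
    diff_splice,
    event_summary,
    filter_events,
    infer_all_events,
    infer_events,
    intact_codon,
)
from conftest import SEVEN_TEMPLATES, mirror_gene


class TestInferEvents:
    def test_seven_templates_hand_enumerated(self, seven_templates):
        for etype, spec in SEVEN_TEMPLATES.items():
            g = seven_templates[etype]
            events = infer_events(g)
            assert len(events) == 1, f"{etype}: expected one event, got {events}"
            (e,) = events
            assert e.event_type == etype
            assert e.defining_sites == spec["sites"]
            assert e.variable_region_length == spec["var_len"]
            inc_tid = g.transcripts[spec["inclusion"]].transcript_id
            assert e.inclusion_transcripts == {inc_tid}
            assert e.exclusion_transcripts == {
                t.transcript_id for t in g.transcripts
            } - {inc_tid}

    def test_minus_strand_mirror_preserves_types(self, seven_templates):
        for etype, g in seven_templates.items():
            events = infer_events(mirror_gene(g))
            assert len(events) == 1
            assert events[0].event_type == etype
            assert events[0].variable_region_length == SEVEN_TEMPLATES[etype]["var_len"]

    def test_identical_transcripts_no_events(self):
        exons = [Exon("chr1", 1, 100, "+"), Exon("chr1", 200, 300, "+")]
        g = GeneModel("g", "other", [
            TranscriptModel("t1", "g", "other", list(exons)),
            TranscriptModel("t2", "g", "other", list(exons)),
        ])
        assert infer_events(g) == []

    def test_single_transcript_gene_no_events(self):
        g = GeneModel("g", "other", [
            TranscriptModel("t1", "g", "other", [Exon("chr1", 1, 100, "+")])
        ])
        assert infer_events(g) == []

    def test_invariant_to_transcript_order(self, seven_templates):
        for g in seven_templates.values():
            flipped = GeneModel(g.gene_id, g.biotype, list(reversed(g.transcripts)))
            assert infer_events(flipped) == infer_events(g)

    def test_extra_identical_transcript_joins_inclusion_set(self, seven_templates):
        g = seven_templates["SE"]
        extra = TranscriptModel("GENE_SE.t3", g.gene_id, g.biotype,
                                list(g.transcripts[0].exons))
        g3 = GeneModel(g.gene_id, g.biotype, g.transcripts + [extra])
        (e,) = infer_events(g3)
        assert "GENE_SE.t3" in e.inclusion_transcripts

    def test_simulator_templates_one_event_each_type(self):
        models = simulate_annotation(SimulationConfig(n_genes=7, seed=11))
        events = infer_all_events(models)
        assert len(events) == 7
        assert sorted(e.event_type for e in events) == sorted(
            ["SE", "A5", "A3", "MX", "RI", "AF", "AL"]
        )
        per_gene = {e.gene_id for e in events}
        assert len(per_gene) == 7


class TestPsi:
    def _event(self, seven_templates):
        return infer_events(seven_templates["SE"])[0]

    def test_formula_examples(self, seven_templates):
        e = self._event(seven_templates)
        inc = next(iter(e.inclusion_transcripts))
        exc = next(iter(e.exclusion_transcripts))
        x = pd.DataFrame({"s1": [3.0, 1.0], "s2": [0.0, 2.0], "s3": [0.0, 0.0]},
                         index=[inc, exc])
        psi = compute_psi([e], x)
        assert psi.loc[e.event_id, "s1"] == pytest.approx(0.75)
        assert psi.loc[e.event_id, "s2"] == 0.0
        assert np.isnan(psi.loc[e.event_id, "s3"])

    def test_brute_force_oracle_on_random_events(self):
        """PSI equals an explicit set-membership sum to 1e-12 on a catalog of
        simulated events with random expression."""
        models = simulate_annotation(SimulationConfig(n_genes=100, seed=9))
        events = infer_all_events(models)
        assert len(events) >= 100
        rng = np.random.default_rng(0)
        tx = [t.transcript_id for g in models for t in g.transcripts]
        x = pd.DataFrame(rng.lognormal(size=(len(tx), 12)), index=tx,
                         columns=[f"s{i}" for i in range(12)])
        # zero out some transcripts to exercise the missing-value contract
        x.iloc[rng.choice(len(tx), 40, replace=False), :3] = 0.0
        psi = compute_psi(events, x)
        for e in events[:100]:
            for s in x.columns:
                num = sum(x.loc[t, s] for t in e.inclusion_transcripts)
                den = num + sum(x.loc[t, s] for t in e.exclusion_transcripts)
                if den == 0:
                    assert np.isnan(psi.loc[e.event_id, s])
                else:
                    assert abs(psi.loc[e.event_id, s] - num / den) < 1e-12

    def test_psi_plus_mirrored_event_is_one(self, seven_templates):
        import dataclasses

        e = self._event(seven_templates)
        swapped = dataclasses.replace(
            e,
            inclusion_transcripts=e.exclusion_transcripts,
            exclusion_transcripts=e.inclusion_transcripts,
            event_id=e.event_id + ";swapped",
        )
        rng = np.random.default_rng(2)
        x = pd.DataFrame(
            rng.lognormal(size=(2, 20)),
            index=sorted(e.inclusion_transcripts | e.exclusion_transcripts),
            columns=[f"s{i}" for i in range(20)],
        )
        psi = compute_psi([e, swapped], x)
        total = psi.loc[e.event_id] + psi.loc[swapped.event_id]
        assert np.allclose(total, 1.0)

    def test_missing_transcript_raises(self, seven_templates):
        e = self._event(seven_templates)
        x = pd.DataFrame({"s1": [1.0]}, index=[next(iter(e.inclusion_transcripts))])
        with pytest.raises(KeyError):
            compute_psi([e], x)


class TestFilterEvents:
    def test_low_everywhere_removed(self):
        psi = pd.DataFrame([[0.05] * 20], index=["e"])
        assert len(filter_events(psi)) == 0

    def test_boundary_five_percent_kept(self):
        psi = pd.DataFrame([[0.5] + [0.0] * 19], index=["e"])
        assert len(filter_events(psi)) == 1

    def test_all_missing_removed(self):
        psi = pd.DataFrame([[np.nan] * 10], index=["e"])
        assert len(filter_events(psi)) == 0


class TestDiffSplice:
    @staticmethod
    def _labels(n_a, n_b):
        ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        return pd.Series(["control"] * n_a + ["ad"] * n_b, index=ids), ids

    def test_identical_distributions_not_significant(self):
        labels, ids = self._labels(30, 30)
        rng = np.random.default_rng(0)
        vals = rng.beta(2, 2, 30)
        psi = pd.DataFrame([np.concatenate([vals, vals])], index=["e"], columns=ids)
        res = diff_splice(psi, labels, "control", "ad")
        assert res.loc["e", "delta_psi"] == 0
        assert not res.loc["e", "significant"]

    def test_separated_groups_significant(self):
        labels, ids = self._labels(50, 50)
        rng = np.random.default_rng(1)
        a = np.clip(rng.normal(0.2, 0.03, 50), 0, 1)
        b = np.clip(rng.normal(0.6, 0.03, 50), 0, 1)
        psi = pd.DataFrame([np.concatenate([a, b])], index=["e"], columns=ids)
        res = diff_splice(psi, labels, "control", "ad")
        assert res.loc["e", "significant"]
        assert res.loc["e", "delta_psi"] == pytest.approx(0.4, abs=0.05)

    def test_signed_rank_option(self):
        labels, ids = self._labels(20, 20)
        rng = np.random.default_rng(2)
        a = rng.beta(2, 5, 20)
        b = rng.beta(5, 2, 20)
        psi = pd.DataFrame([np.concatenate([a, b])], index=["e"], columns=ids)
        res = diff_splice(psi, labels, "control", "ad", test="signed_rank")
        assert res.loc["e", "p_value"] < 0.01

    def test_insufficient_data_skipped(self):
        labels, ids = self._labels(3, 3)
        row = [0.5, np.nan, np.nan, 0.4, 0.5, 0.6]
        psi = pd.DataFrame([row, [0.1] * 3 + [0.9] * 3], index=["e1", "e2"],
                           columns=ids)
        res = diff_splice(psi, labels, "control", "ad")
        assert "e1" not in res.index and "e2" in res.index


class TestFrameAndSummary:
    def test_intact_codon_length_sweep(self, seven_templates):
        import dataclasses

        e = infer_events(seven_templates["SE"])[0]
        for length in range(1, 301):
            ev = dataclasses.replace(e, variable_region_length=length)
            assert intact_codon(ev) is (length % 3 == 0)

    def test_non_coding_not_applicable(self, seven_templates):
        import dataclasses

        e = infer_events(seven_templates["SE"])[0]
        assert intact_codon(dataclasses.replace(e, biotype="lncRNA")) is None

    def test_seven_template_summary(self, seven_templates):
        events = [infer_events(g)[0] for g in seven_templates.values()]
        tab = event_summary(events)
        assert (tab["count"] == 1).all()
        assert np.allclose(tab["percent"], 100.0 / 7)

    def test_empty_catalog(self):
        tab = event_summary([])
        assert len(tab) == 0
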