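"""Differential transcript expression and host-gene correlation."""

import numpy as np
import pandas as pd
import pytest

from adtx.diffexpr import (
    det_test,
    expression_fraction,
    host_gene_correlation,
    twenty_percent_sets,
)


def _matrix(rows, n_a, n_b, index=None):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    labels = pd.Series(["control"] * n_a + ["ad"] * n_b, index=ids)
    x = pd.DataFrame(rows, columns=ids,
                     index=index or [f"t{i}" for i in range(len(rows))])
    return x, labels


class TestDetTest:
    def test_identical_groups_fold_change_one(self):
        vals = np.tile(np.arange(1.0, 11), (1, 2))
        x, labels = _matrix(vals.reshape(1, 20), 10, 10)
        res = det_test(x, labels, "control", "ad")
        assert res.iloc[0]["fold_change"] == pytest.approx(1.0)
        assert res.iloc[0]["direction"] == "none"

    def test_doubled_group_called_up(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(1, 0.2, 50)
        row = np.concatenate([base, 2 * base])
        x, labels = _matrix([row], 50, 50)
        res = det_test(x, labels, "control", "ad")
        assert res.iloc[0]["direction"] == "up"
        assert res.iloc[0]["p_value"] < 1e-6

    def test_mirror_symmetry_of_group_order(self):
        rng = np.random.default_rng(3)
        x, labels = _matrix(rng.lognormal(1, 0.5, (50, 40)), 20, 20)
        fwd = det_test(x, labels, "control", "ad")
        rev = det_test(x, labels, "ad", "control")
        assert np.allclose(fwd["p_value"], rev["p_value"])
        eps = 0.01
        ratio = (x[labels.index[labels == "ad"]].mean(axis=1) + eps)
        # reciprocity of the pseudocounted ratio
        assert np.allclose(fwd["fold_change"] * rev["fold_change"],
                           1.0, atol=1e-12)
        swap = {"up": "down", "down": "up", "none": "none"}
        assert (rev["direction"] == fwd["direction"].map(swap)).all()

    def test_planted_fold_change_recovery(self, planted_cohort):
        """Sensitivity for planted fold-3 transcripts at 60/group."""
        from adtx.cohort import filter_low_expression
        from adtx.annotation import transcript_to_gene

        c = planted_cohort
        tx2gene = transcript_to_gene(c.models)
        expr = filter_low_expression(c.expression)
        txs = expr.loc[[t for t in expr.index if t in tx2gene]]
        res = det_test(txs, c.intended_labels, "control", "ad")
        truth = c.truth.det_up | c.truth.det_down
        calls = set(res.index[res["direction"] != "none"])
        assert len(calls & truth) / len(truth) >= 0.9


class TestTwentyPercentSets:
    def test_examples(self):
        ids = ["r0", "a0", "a1", "b0", "b1"]
        labels = pd.Series(["control", "asymad", "asymad", "ad", "ad"], index=ids)
        x = pd.DataFrame(
            [[10, 12.5, 12.5, 7, 7], [10, 11, 11, 11, 11]],
            index=["t_updown", "t_flat"], columns=ids,
        )
        table, crosstab = twenty_percent_sets(x, labels, "control", "asymad", "ad")
        assert table.loc["t_updown", ["class_a", "class_b"]].tolist() == ["up", "down"]
        assert table.loc["t_flat", ["class_a", "class_b"]].tolist() == ["flat", "flat"]
        assert crosstab.loc["up", "down"] == 1
        assert crosstab.to_numpy().sum() == 2

    def test_zero_reference_excluded(self):
        ids = ["r0", "r1", "a0", "a1", "b0", "b1"]
        labels = pd.Series(["control"] * 2 + ["asymad"] * 2 + ["ad"] * 2, index=ids)
        x = pd.DataFrame([[0, 0, 5, 5, 5, 5]], index=["t"], columns=ids)
        table, _ = twenty_percent_sets(x, labels, "control", "asymad", "ad")
        assert "t" not in table.index

    def test_null_simulation_all_flat(self):
        ids = [f"s{i}" for i in range(9)]
        labels = pd.Series(["control"] * 3 + ["asymad"] * 3 + ["ad"] * 3, index=ids)
        x = pd.DataFrame(np.full((5, 9), 7.0), columns=ids,
                         index=[f"t{i}" for i in range(5)])
        _, crosstab = twenty_percent_sets(x, labels, "control", "asymad", "ad")
        assert crosstab.loc["flat", "flat"] == 5
        assert crosstab.to_numpy().sum() == 5


class TestHostGeneCorrelation:
    def test_single_transcript_gene_perfectly_positive(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame([rng.lognormal(0, 1, 30)], index=["t1"],
                         columns=[f"s{i}" for i in range(30)])
        res = host_gene_correlation(x, {"t1": "g1"})
        assert res.loc["t1", "r"] == pytest.approx(1.0)
        assert res.loc["t1", "label"] == "positive"

    def test_orthogonal_transcript_irrelevant(self):
        """A transcript constructed to be uncorrelated with the gene sum."""
        rng = np.random.default_rng(1)
        n = 200
        g_total = rng.lognormal(2, 0.3, n)
        resid = rng.normal(0, 0.05, n)
        resid -= np.polyval(np.polyfit(g_total, resid, 1), g_total)  # orthogonalize
        t1 = 0.5 + resid - resid.min()
        x = pd.DataFrame([t1, g_total - t1], index=["t1", "t2"],
                         columns=[f"s{i}" for i in range(n)])
        res = host_gene_correlation(x, {"t1": "g", "t2": "g"})
        assert abs(res.loc["t1", "r"]) < 0.1
        assert res.loc["t1", "label"] == "irrelevant"

    def test_constant_gene_sum_irrelevant(self):
        rng = np.random.default_rng(2)
        t1 = rng.uniform(1, 2, 20)
        x = pd.DataFrame([t1, 5.0 - t1], index=["t1", "t2"],
                         columns=[f"s{i}" for i in range(20)])
        res = host_gene_correlation(x, {"t1": "g", "t2": "g"})
        assert (res["label"] == "irrelevant").all()

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.lognormal(0, 1, (4, 25)),
                         index=["t1", "t2", "t3", "t4"],
                         columns=[f"s{i}" for i in range(25)])
        tx2gene = {"t1": "g1", "t2": "g1", "t3": "g2", "t4": "g2"}
        res1 = host_gene_correlation(x, tx2gene)
        perm = list(rng.permutation(x.columns))
        res2 = host_gene_correlation(x[perm], tx2gene)
        assert np.allclose(res1["r"], res2["r"])


class TestExpressionFraction:
    def _setup(self, t1_mean, t2_mean, positive):
        x = pd.DataFrame([[t1_mean] * 10, [t2_mean] * 10], index=["t1", "t2"],
                         columns=[f"s{i}" for i in range(10)])
        corr = pd.DataFrame(
            {"gene_id": ["g", "g"],
             "label": ["positive" if "t1" in positive else "irrelevant",
                       "positive" if "t2" in positive else "irrelevant"]},
            index=["t1", "t2"],
        )
        return expression_fraction(x, {"t1": "g", "t2": "g"}, corr)

    def test_all_expression_in_positive_transcript(self):
        res = self._setup(5.0, 0.0, {"t1"})
        assert res.loc["g", "positive_fraction"] == pytest.approx(1.0)

    def test_no_positive_transcripts(self):
        res = self._setup(3.0, 2.0, set())
        assert res.loc["g", "positive_fraction"] == 0.0

    def test_equal_split(self):
        res = self._setup(2.0, 2.0, {"t1"})
        assert res.loc["g", "positive_fraction"] == pytest.approx(0.5)
        assert res.loc["g", "n_transcripts"] == 2
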