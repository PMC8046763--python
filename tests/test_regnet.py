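"""Mutual-information network inference, DPI pruning, master regulators."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sescape.regnet import (
    dpi_prune,
    master_regulator_analysis,
    mi_significance,
    pairwise_mi,
    regulons_from_edges,
    select_regulators,
)
from sescape.targets import SETargetPair


class TestSelectRegulators:
    def setup_method(self):
        self.de = pd.DataFrame(
            {"log2fc": [1.2, 0.8, 1.5], "adj_p": [0.001, 0.001, 0.001]},
            index=["tf_good", "tf_weak", "gene_x"],
        )
        self.fe = pd.DataFrame(
            {"log2fe": [1.4], "adj_p": [0.01]}, index=["chr1:0-8000"]
        )

    def pair(self, gid):
        return SETargetPair("chr1:0-8000", gid, 1000, "A-specific", 1.0)

    def test_qualifying_tf_selected(self):
        out = select_regulators([self.pair("tf_good")], self.de,
                                {"tf_good"}, fe_table=self.fe)
        assert out == ["tf_good"]

    def test_weak_expression_excluded(self):
        with pytest.warns(UserWarning):
            out = select_regulators([self.pair("tf_weak")], self.de,
                                    {"tf_weak"}, fe_table=self.fe)
        assert out == []

    def test_non_tf_excluded(self):
        with pytest.warns(UserWarning):
            out = select_regulators([self.pair("gene_x")], self.de,
                                    {"tf_good"}, fe_table=self.fe)
        assert out == []


class TestPairwiseMI:
    def test_symmetric(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert pairwise_mi(x, y) == pairwise_mi(y, x)
        assert pairwise_mi(x, y, "binned") == pytest.approx(
            pairwise_mi(y, x, "binned"), abs=1e-12
        )

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(4)
        mi = pairwise_mi(rng.normal(size=2000), rng.normal(size=2000))
        assert mi < 0.01

    def test_gaussian_closed_form_limit(self):
        """At rho_g = 0.8 the MI converges to -0.5 ln(1 - 0.64) ~ 0.5108."""
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        y = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(size=n)
        assert pairwise_mi(x, y) == pytest.approx(-0.5 * math.log(0.36), abs=0.05)

    def test_identical_vectors_capped_finite(self):
        x = np.random.default_rng(1).normal(size=50)
        mi = pairwise_mi(x, x)
        assert np.isfinite(mi) and mi > 5

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert pairwise_mi(np.ones(20), np.arange(20.0)) == 0.0


def regulon_matrix(beta, noise_sd, n=40, n_bg=50, regulon=10, seed=0):
    rng = np.random.default_rng(seed)
    tf = rng.normal(size=n)
    z = (tf - tf.mean()) / tf.std()
    rows = {"TF": tf}
    for i in range(regulon):
        rows[f"m{i}"] = beta * z + rng.normal(0, noise_sd, size=n)
    for i in range(n_bg):
        rows[f"bg{i}"] = rng.normal(size=n)
    return pd.DataFrame(rows).T


class TestMISignificance:
    def test_true_edges_kept(self):
        """beta=0.9, noise 0.3, n=40: at least 90% of true edges kept."""
        m = regulon_matrix(0.9, 0.3, seed=5)
        edges = mi_significance(m, ["TF"], n_perm=500, seed=1)
        kept = edges[edges["kept"]]
        true_kept = kept["gene"].str.startswith("m").sum()
        assert true_kept >= 9

    def test_null_type_one_error(self):
        m = regulon_matrix(0.0, 1.0, seed=9)
        edges = mi_significance(m, ["TF"], n_perm=500, alpha=0.05, seed=2)
        assert edges["kept"].mean() <= 0.05

    def test_deterministic_given_seed(self):
        m = regulon_matrix(0.5, 0.5, seed=3)
        e1 = mi_significance(m, ["TF"], n_perm=200, seed=8)
        e2 = mi_significance(m, ["TF"], n_perm=200, seed=8)
        pd.testing.assert_frame_equal(e1, e2)

    def test_stratified_null_absorbs_group_shift(self):
        """A pure subtype mean shift is not evidence for an edge under the
        within-group permutation null."""
        rng = np.random.default_rng(11)
        n = 40
        group = np.array(["A"] * 20 + ["B"] * 20)
        shift = (group == "A") * 1.5
        m = pd.DataFrame(
            {
                "TF": rng.normal(size=n) + shift,
                **{f"de{i}": rng.normal(size=n) + shift for i in range(20)},
                **{f"bg{i}": rng.normal(size=n) for i in range(30)},
            }
        ).T
        groups = {i: g for i, g in zip(m.columns, group)}
        plain = mi_significance(m, ["TF"], n_perm=500, seed=3)
        strat = mi_significance(m, ["TF"], n_perm=500, seed=3, groups=groups)
        de_mask = plain["gene"].str.startswith("de")
        assert plain.loc[de_mask, "p"].median() < 0.01  # confounding bites
        assert strat.loc[de_mask, "p"].median() > 0.1  # null restored

    def test_low_perm_count_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            mi_significance(regulon_matrix(0.5, 0.5), ["TF"], n_perm=50)


def edge_table(rows):
    df = pd.DataFrame(rows, columns=["tf", "gene", "mi"])
    df["p"] = 0.001
    df["adj_p"] = 0.001
    df["kept"] = True
    return df


class TestDPI:
    def chain_matrix(self, seed, n=200, beta=0.9):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = beta * x + math.sqrt(1 - beta**2) * rng.normal(size=n)
        z = beta * y + math.sqrt(1 - beta**2) * rng.normal(size=n)
        return pd.DataFrame({"X": x, "Y": y, "Z": z}).T

    def test_smallest_edge_in_chain_removed(self):
        m = self.chain_matrix(0)
        edges = edge_table([
            ("X", "Z", pairwise_mi(m.loc["X"], m.loc["Z"])),
            ("Y", "Z", pairwise_mi(m.loc["Y"], m.loc["Z"])),
        ])
        out = dpi_prune(edges, m)
        out = out.set_index(["tf", "gene"])
        assert not out.loc[("X", "Z"), "kept_after_dpi"]
        assert out.loc[("Y", "Z"), "kept_after_dpi"]

    def test_exact_tie_keeps_everything(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        m = pd.DataFrame({"X": base, "Y": base, "Z": base}).T
        # all three MIs equal (capped); strict inequality fails -> no removal
        edges = edge_table([
            ("X", "Z", pairwise_mi(base, base)),
            ("Y", "Z", pairwise_mi(base, base)),
        ])
        out = dpi_prune(edges, m)
        assert out["kept_after_dpi"].all()

    def test_edge_outside_any_triplet_untouched(self):
        m = self.chain_matrix(3)
        edges = edge_table([("X", "Z", 0.2)])  # single TF: no triplet exists
        out = dpi_prune(edges, m)
        assert out["kept_after_dpi"].all()

    def test_chain_shortcut_removed_across_seeds(self):
        removed = 0
        for seed in range(20):
            m = self.chain_matrix(seed)
            edges = edge_table([
                ("X", "Z", pairwise_mi(m.loc["X"], m.loc["Z"])),
                ("Y", "Z", pairwise_mi(m.loc["Y"], m.loc["Z"])),
            ])
            out = dpi_prune(edges, m).set_index(["tf", "gene"])
            removed += not out.loc[("X", "Z"), "kept_after_dpi"]
        assert removed >= 19


class TestMRA:
    def test_disjoint_regulon_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        res = master_regulator_analysis(
            {"tf1": {"g1", "g2"}}, {"g50", "g51"}, universe
        )
        assert res.loc[0, "p"] == 1.0

    def test_empty_regulon_flagged(self):
        universe = {f"g{i}" for i in range(10)}
        with pytest.warns(UserWarning, match="empty regulon"):
            res = master_regulator_analysis({"tf1": set()}, {"g1"}, universe)
        assert res.loc[0, "p"] == 1.0

    def test_matches_enumeration_toy_universe(self):
        universe = {f"g{i}" for i in range(12)}
        signature = {"g0", "g1", "g2", "g3"}
        regulon = {"g0", "g1", "g4", "g5", "g6"}
        res = master_regulator_analysis({"tf": regulon}, signature, universe)
        total = math.comb(12, 5)
        count = sum(
            1
            for comb in itertools.combinations(sorted(universe), 5)
            if len(set(comb) & signature) >= 2
        )
        assert res.loc[0, "p"] == pytest.approx(count / total, rel=1e-10)

    def test_enriched_regulon_ranks_first(self):
        universe = {f"g{i}" for i in range(200)}
        signature = {f"g{i}" for i in range(30)}
        regulons = {
            "master": {f"g{i}" for i in range(15)} | {f"g{i}" for i in range(100, 105)},
            "other": {f"g{i}" for i in range(100, 120)},
        }
        res = master_regulator_analysis(regulons, signature, universe)
        assert res.loc[0, "tf"] == "master" and res.loc[0, "adj_p"] < 0.05


class TestFullStageRecovery:
    def test_regulon_edges_recovered(self, small_cohort):
        """9 TFs, regulon size 30, beta=0.8: edge recall and precision
        >= 0.85 after DPI on the planted expression network."""
        import copy

        from sescape.synth import simulate_expression, simulate_genome, simulate_chip_cohort

        annotation, chrom_lengths = simulate_genome(
            1, 5_000_000, 400, 0.1, seed=21
        )
        _, truth = simulate_chip_cohort(annotation, chrom_lengths,
                                        n_per_group=1, seed=21)
        matrix = simulate_expression(annotation, truth, regulon_size=30, seed=21)
        edges = mi_significance(matrix, truth.regulator_tfs, n_perm=500,
                                seed=4, groups=truth.expr_labels)
        edges = dpi_prune(edges, matrix)
        regulons = regulons_from_edges(edges)
        true = {(tf, m) for tf, ms in truth.regulons.items() for m in ms}
        found = {(tf, g) for tf, ms in regulons.items() for g in ms}
        tp = len(true & found)
        assert tp / len(true) >= 0.85
        assert tp / len(found) >= 0.85
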