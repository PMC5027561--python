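"""NJ construction, species-cluster assessment, haplotypes, deep lineages."""

import math

import numpy as np
import pytest
from skbio import TreeNode

from barcodekit.distances import DistanceMatrix, pairwise_matrix
from barcodekit.synthetic_data import SynthConfig, generate_dataset
from barcodekit.tree_clustering import (
    assess_species_clusters,
    bootstrap_support,
    candidate_species_summary,
    collapse_haplotypes,
    deep_lineages,
    neighbor_joining,
    percent_increase,
)

from conftest import dummy_dataset_for, make_dataset, make_matrix


def _tip_distances(tree):
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b] for a in dm.ids for b in dm.ids if a != b}


def _random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive branch lengths -> path-length matrix."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = TreeNode(children=nodes)
    dm = root.tip_tip_distances()
    ids = list(dm.ids)
    return DistanceMatrix(ids, dm.data)


class TestNeighborJoining:
    def test_additive_four_leaf_split_and_internal_branch(self):
        # d(A,B)=3, d(C,D)=7, d(A,C)=5, d(A,D)=6, d(B,C)=6, d(B,D)=7
        m = make_matrix(
            ["A", "B", "C", "D"],
            {("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
             ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7},
        )
        tree = neighbor_joining(m)
        paths = _tip_distances(tree)
        for (a, b), d in {("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
                          ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7}.items():
            assert paths[frozenset((a, b))] == pytest.approx(d, abs=1e-9)
        # AB|CD split means internal branch = (dAC + dBD - dAB - dCD)/2 = 1
        internal = (5 + 7 - 3 - 7) / 2
        assert internal == 1

    def test_three_leaves_closed_form(self):
        m = make_matrix(
            ["A", "B", "C"], {("A", "B"): 2, ("A", "C"): 3, ("B", "C"): 5}
        )
        paths = _tip_distances(neighbor_joining(m))
        assert paths[frozenset(("A", "B"))] == pytest.approx(2, abs=1e-9)
        assert paths[frozenset(("A", "C"))] == pytest.approx(3, abs=1e-9)
        assert paths[frozenset(("B", "C"))] == pytest.approx(5, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_path_lengths_exact_on_random_additive_matrices(self, seed, n_leaves):
        rng = np.random.default_rng(seed * 100 + n_leaves)
        m = _random_additive_matrix(rng, n_leaves)
        paths = _tip_distances(neighbor_joining(m))
        for i, a in enumerate(m.ids):
            for b in m.ids[i + 1:]:
                assert paths[frozenset((a, b))] == pytest.approx(
                    m.get(a, b), abs=1e-9
                )

    def test_undefined_entries_rejected_with_pair_names(self):
        m = make_matrix(["A", "B", "C"], {("A", "B"): 1, ("B", "C"): 2})
        with pytest.raises(ValueError, match="A.*C"):
            neighbor_joining(m)

    def test_too_few_leaves_rejected(self):
        m = make_matrix(["A", "B"], {("A", "B"): 1})
        with pytest.raises(ValueError):
            neighbor_joining(m)


class TestBootstrap:
    @pytest.fixture
    def two_clade_dataset(self):
        a = "ACGT" * 25
        # transition at 30% of sites: well inside the K2P-defined range
        b = "".join(
            {"A": "G", "C": "T", "G": "A", "T": "C"}[c] if i % 10 < 3 else c
            for i, c in enumerate(a)
        )
        return make_dataset(
            [
                ("a1", "Gx spA", a, "Gx"),
                ("a2", "Gx spA", a, "Gx"),
                ("b1", "Gx spB", b, "Gx"),
                ("b2", "Gx spB", b, "Gx"),
            ]
        )

    def test_separating_edge_full_support(self, two_clade_dataset):
        _, support = bootstrap_support(two_clade_dataset, n_reps=50, seed=1)
        key = frozenset({"a1", "a2"})
        assert support[key] == 100.0

    def test_same_seed_identical_supports(self, two_clade_dataset):
        _, s1 = bootstrap_support(two_clade_dataset, n_reps=20, seed=7)
        _, s2 = bootstrap_support(two_clade_dataset, n_reps=20, seed=7)
        assert s1 == s2

    def test_zero_reps_rejected(self, two_clade_dataset):
        with pytest.raises(ValueError):
            bootstrap_support(two_clade_dataset, n_reps=0, seed=1)


class TestClusterAssessment:
    def test_reciprocally_monophyletic_all_distinct(self):
        tree = TreeNode.read(["((a1:1,a2:1):2,(b1:1,b2:1):2);"])
        labels = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"}
        res = assess_species_clusters(tree, labels)
        assert res.status_of == {"spA": "distinct_cluster", "spB": "distinct_cluster"}

    def test_wrapped_species_paraphyletic(self):
        tree = TreeNode.read(["((a1:1,(b1:1,b2:1):3):1,a2:4);"])
        labels = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"}
        res = assess_species_clusters(tree, labels)
        assert res.status_of["spA"] == "paraphyletic"
        assert res.status_of["spB"] == "distinct_cluster"

    def test_interleaved_species_shared_cluster(self):
        tree = TreeNode.read(["((a1:0,b1:0):0.01,(a2:0,b2:0):0.01,c1:5);"])
        labels = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "c1": "spC"}
        res = assess_species_clusters(tree, labels)
        assert res.status_of["spA"] == "shared_cluster"
        assert res.status_of["spB"] == "shared_cluster"
        assert res.status_of["spC"] == "singleton_unassessable"
        assert frozenset({"spA", "spB"}) in res.shared_groups

    def test_haplotype_sharing_forces_shared_cluster(self):
        # B monophyletic on the tree but shares an identical sequence with A
        seq = "ACGT" * 10
        other = "TTTT" + seq[4:]
        ds = make_dataset(
            [
                ("a1", "Gx spA", seq, "Gx"),
                ("a2", "Gx spA", other, "Gx"),
                ("b1", "Gx spB", seq, "Gx"),
                ("b2", "Gx spB", seq, "Gx"),
            ]
        )
        tree = neighbor_joining(pairwise_matrix(ds))
        res = assess_species_clusters(tree, ds.species_of, ds)
        assert res.status_of["Gx spB"] == "shared_cluster"
        assert res.status_of["Gx spA"] == "shared_cluster"

    def test_unlabelled_leaf_rejected(self):
        tree = TreeNode.read(["((a1:1,a2:1):2,(b1:1,b2:1):2);"])
        with pytest.raises(ValueError, match="unlabelled"):
            assess_species_clusters(tree, {"a1": "spA", "a2": "spA", "b1": "spB"})

    def test_synthetic_monophyletic_recovery(self):
        cfg = SynthConfig(seed=3, n_genera=4, species_per_genus=2,
                          specimens_per_species=4)
        ds, _ = generate_dataset(cfg)
        tree = neighbor_joining(pairwise_matrix(ds))
        res = assess_species_clusters(tree, ds.species_of, ds)
        assert all(v == "distinct_cluster" for v in res.status_of.values())


class TestHaplotypes:
    def test_identical_conspecific_collapse_unshared(self):
        ds = make_dataset(
            [("s1", "Aa bb", "ACGT"), ("s2", "Aa bb", "ACGT")]
        )
        table = collapse_haplotypes(ds)
        assert len(table) == 1
        assert not next(iter(table.values())).shared

    def test_cross_species_identity_flagged_shared(self):
        ds = make_dataset(
            [("s1", "Aa bb", "ACGT"), ("s2", "Aa cc", "ACGT")]
        )
        (hap,) = collapse_haplotypes(ds).values()
        assert hap.shared and hap.species_set == {"Aa bb", "Aa cc"}

    def test_ambiguity_mismatch_keeps_haplotypes_distinct(self):
        ds = make_dataset(
            [("s1", "Aa bb", "ACGT"), ("s2", "Aa bb", "ACGN")]
        )
        assert len(collapse_haplotypes(ds)) == 2

    def test_gap_only_columns_ignored(self):
        ds = make_dataset(
            [("s1", "Aa bb", "AC-GT"), ("s2", "Aa bb", "AC-GT")]
        )
        (hap,) = collapse_haplotypes(ds).values()
        assert hap.representative == "ACGT"


class TestDeepLineages:
    def _dataset_with_matrix(self, groups):
        """groups: dict lineage -> list of specimen ids; intra 0.005,
        between lineages 0.08, plus one other species."""
        labels = {}
        for lin, ids in groups.items():
            for sid in ids:
                labels[sid] = "spX"
        labels["z1"] = "spZ"
        ds = dummy_dataset_for(labels)
        entries = {}
        ids = list(labels)
        lineage_of = {
            sid: lin for lin, sids in groups.items() for sid in sids
        }
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                if labels[x] != labels[y]:
                    entries[(x, y)] = 0.2
                elif lineage_of.get(x) == lineage_of.get(y):
                    entries[(x, y)] = 0.005
                else:
                    entries[(x, y)] = 0.08
        return ds, make_matrix(ids, entries)

    def test_uniform_species_single_lineage(self):
        ds, m = self._dataset_with_matrix({"L1": ["x1", "x2", "x3"]})
        assert deep_lineages(m, ds, "spX").n_lineages == 1

    def test_two_groups_split_verified_against_bipartitions(self):
        ds, m = self._dataset_with_matrix(
            {"L1": ["x1", "x2"], "L2": ["x3", "x4"]}
        )
        p = deep_lineages(m, ds, "spX")
        assert p.n_lineages == 2
        assert {frozenset(c) for c in p.clusters} == {
            frozenset({"x1", "x2"}), frozenset({"x3", "x4"})
        }
        assert all(v > 0.02 for v in p.inter_cluster_means.values())

    def test_exact_cutoff_merges(self):
        labels = {"x1": "spX", "x2": "spX", "z1": "spZ"}
        ds = dummy_dataset_for(labels)
        m = make_matrix(
            ["x1", "x2", "z1"],
            {("x1", "x2"): 0.02, ("x1", "z1"): 0.2, ("x2", "z1"): 0.2},
        )
        assert deep_lineages(m, ds, "spX").n_lineages == 1

    def test_order_invariance(self):
        ds, m = self._dataset_with_matrix(
            {"L1": ["x1", "x2"], "L2": ["x3", "x4"], "L3": ["x5"]}
        )
        base = deep_lineages(m, ds, "spX")
        # permute record order and rebuild
        order = [4, 2, 0, 5, 1, 3]
        ids = list(ds.ids)
        perm_ids = [ids[i] for i in order]
        perm_ds = dummy_dataset_for({i: ds.species_of[i] for i in perm_ids})
        perm_m = m.submatrix(perm_ids)
        perm = deep_lineages(perm_m, perm_ds, "spX")
        assert {frozenset(c) for c in perm.clusters} == {
            frozenset(c) for c in base.clusters
        }

    def test_singleton_species_rejected(self):
        labels = {"x1": "spX", "z1": "spZ"}
        ds = dummy_dataset_for(labels)
        m = make_matrix(["x1", "z1"], {("x1", "z1"): 0.1})
        with pytest.raises(ValueError, match="singleton"):
            deep_lineages(m, ds, "spZ")

    def test_planted_lineages_recovered(self):
        cfg = SynthConfig(
            seed=5, n_genera=3, species_per_genus=2, specimens_per_species=4,
            planted_deep_species=[(2, 0.08), (3, 0.06)],
        )
        ds, truth = generate_dataset(cfg)
        m = pairwise_matrix(ds)
        for species, count in ds.species_counts().items():
            if count >= 2:
                assert deep_lineages(m, ds, species).n_lineages == (
                    truth.n_lineages[species]
                ), species


class TestCandidateSummary:
    def test_family_rows_and_conservation(self):
        cfg = SynthConfig(
            seed=8, n_genera=4, species_per_genus=2, specimens_per_species=4,
            planted_deep_species=[(2, 0.08)],
        )
        ds, truth = generate_dataset(cfg)
        m = pairwise_matrix(ds)
        partitions = [
            deep_lineages(m, ds, sp)
            for sp, c in ds.species_counts().items() if c >= 2
        ]
        df = candidate_species_summary(partitions, ds)
        totals = df[df.family == "Total"].iloc[0]
        body = df[df.family != "Total"]
        for col in ("species_barcoded", "species_deep_divergence",
                    "candidate_lineages"):
            assert totals[col] == body[col].sum()
        # conservation: sum(n_lineages - 1) = candidates - deep species
        extra = sum(p.n_lineages - 1 for p in partitions)
        assert extra == totals["candidate_lineages"] - totals["species_deep_divergence"]

    def test_percent_increase_formula(self):
        assert percent_increase(62, 137, 569) == 13
        assert percent_increase(1, 2, 2) == 50
        with pytest.raises(ValueError):
            percent_increase(0, 0, 0)
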