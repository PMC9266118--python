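"""Dendrogram construction, cherries, cell typing and branch extraction."""

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from limbtraj import (
    ClusterProfile,
    Dendrogram,
    assign_cell_types,
    build_joint_dendrogram,
    extract_branches,
    extract_cherries,
)
from limbtraj.fixtures import CHERRY_FIXTURE_NEWICK, example_cherry_dendrogram
from limbtraj.trajectory import DendrogramError, leaf_label

from conftest import random_binary_tree, truth_cluster_mapping

DATA = Path(__file__).parent / "data"


def _profile(cluster_id, condition, means, genes=None, n_cells=10):
    genes = genes or [f"g{i}" for i in range(len(means))]
    return ClusterProfile(
        cluster_id=cluster_id,
        condition=condition,
        n_cells=n_cells,
        mean_expr=pd.Series(np.asarray(means, dtype=float), index=genes),
    )


class TestBuild:
    def test_identical_profiles_merge_at_zero(self):
        a = _profile("A", "unwounded", [1, 5, 2, 8])
        b = _profile("B", "wounded", [1, 5, 2, 8])
        d = build_joint_dendrogram([a, b], [f"g{i}" for i in range(4)])
        assert d.root.height == pytest.approx(0.0, abs=1e-12)
        assert extract_cherries(d) == [("A|unwounded", "B|wounded")]

    def test_three_profiles_match_bruteforce_upgma(self):
        """Exhaustive oracle at n = 3: merge the closest pair, then the root
        height is the size-weighted mean of the two cross distances."""
        rng = np.random.default_rng(2)
        means = rng.uniform(0.1, 10, size=(3, 6))
        profiles = [
            _profile(n, c, m)
            for (n, c), m in zip(
                [("A", "unwounded"), ("B", "unwounded"), ("C", "wounded")], means
            )
        ]
        genes = [f"g{i}" for i in range(6)]

        # oracle: correlation distance on log1p means
        logm = np.log1p(means)
        def corr_dist(i, j):
            return 1 - np.corrcoef(logm[i], logm[j])[0, 1]

        pairs = list(itertools.combinations(range(3), 2))
        dists = {p: corr_dist(*p) for p in pairs}
        (i, j), dmin = min(dists.items(), key=lambda kv: kv[1])
        k = ({0, 1, 2} - {i, j}).pop()
        root_height = (dists[tuple(sorted((i, k)))] + dists[tuple(sorted((j, k)))]) / 2

        d = build_joint_dendrogram(profiles, genes)
        labels = [p.label for p in profiles]
        assert extract_cherries(d) == [tuple(sorted((labels[i], labels[j])))]
        assert d.root.height == pytest.approx(root_height, rel=1e-9)
        cherry_height = [
            n.height for n in d.root.internal_nodes()
            if n.children[0].is_leaf and n.children[1].is_leaf
        ][0]
        assert cherry_height == pytest.approx(dmin, rel=1e-9)

    def test_profile_order_invariance(self):
        rng = np.random.default_rng(4)
        means = rng.uniform(0.1, 20, size=(6, 10))
        genes = [f"g{i}" for i in range(10)]
        conds = ["unwounded"] * 3 + ["wounded"] * 3
        profiles = [
            _profile(f"P{i}", conds[i], means[i], genes) for i in range(6)
        ]
        ref = build_joint_dendrogram(profiles, genes).to_newick()
        for seed in range(3):
            order = np.random.default_rng(seed).permutation(6)
            shuffled = [profiles[i] for i in order]
            assert build_joint_dendrogram(shuffled, genes).to_newick() == ref

    def test_planted_pairs_form_cherries(self, default_run):
        """Each planted cross-condition pair merges as a cherry of the joint
        dendrogram before any cross-type merge."""
        mapping = truth_cluster_mapping(default_run)
        truth = default_run.truth
        cherries = {
            frozenset(mapping[l] for l in pair)
            for pair in extract_cherries(default_run.dendrogram)
        }
        for a, b in truth.pairing.items():
            assert frozenset((a, b)) in cherries

    def test_too_few_profiles_rejected(self):
        with pytest.raises(DendrogramError):
            build_joint_dendrogram([_profile("A", "unwounded", [1, 2])], ["g0"])

    def test_empty_gene_subset_rejected(self):
        a = _profile("A", "unwounded", [1, 2])
        b = _profile("B", "wounded", [2, 1])
        with pytest.raises(DendrogramError):
            build_joint_dendrogram([a, b], [])


class TestCherries:
    def test_two_leaf_tree(self):
        d = Dendrogram.from_newick("(a|unwounded:1,b|wounded:1);")
        assert extract_cherries(d) == [("a|unwounded", "b|wounded")]

    def test_caterpillar_has_one_cherry(self):
        d = Dendrogram.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        assert extract_cherries(d) == [("a", "b")]

    def test_balanced_tree_has_two_cherries(self):
        d = Dendrogram.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert extract_cherries(d) == [("a", "b"), ("c", "d")]

    def test_newick_roundtrip_preserves_cherries(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            d, _leaves = random_binary_tree(rng, int(rng.integers(2, 12)))
            again = Dendrogram.from_newick(d.to_newick())
            assert extract_cherries(again) == extract_cherries(d)


class TestCellTypes:
    def test_reference_cherry_structure(self):
        """16 epithelial leaves with 5 cross-condition cherries yield 11 cell
        types: 5 shared, 3 unwounded-only, 3 wounded-only."""
        d = example_cherry_dendrogram()
        types = assign_cell_types(d, d.leaves())
        assert len(types) == 11
        by_presence = {p: sum(1 for t in types if t.presence == p)
                       for p in ("shared", "unwounded_only", "wounded_only")}
        assert by_presence == {"shared": 5, "unwounded_only": 3,
                               "wounded_only": 3}
        shared_members = {
            frozenset(c for c, _ in t.member_clusters)
            for t in types if t.presence == "shared"
        }
        assert shared_members == {
            frozenset(p) for p in
            [("EC7", "EC15"), ("EC8", "EC16"), ("EC2", "EC9"),
             ("EC3", "EC10"), ("EC4", "EC11")]
        }

    def test_fixture_asset_matches_package_constant(self):
        assert (DATA / "cherry_fixture.nwk").read_text().strip() == \
            CHERRY_FIXTURE_NEWICK

    def test_same_condition_cherry_stays_two_types(self):
        d = Dendrogram.from_newick("(a|unwounded:1,b|unwounded:1);")
        types = assign_cell_types(d, d.leaves())
        assert len(types) == 2
        assert all(t.presence == "unwounded_only" for t in types)

    def test_single_epithelial_leaf(self):
        d = Dendrogram.from_newick("(a|unwounded:1,b|wounded:1);")
        types = assign_cell_types(d, ["a|unwounded"])
        assert len(types) == 1 and types[0].presence == "unwounded_only"

    def test_count_identity_on_random_trees(self):
        """#types = #epithelial leaves - #cross-condition cherries, over
        1000 random trees with random condition labels."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            d, leaves = random_binary_tree(rng, int(rng.integers(2, 16)))
            n_epi = int(rng.integers(1, len(leaves) + 1))
            epi = list(rng.choice(leaves, size=n_epi, replace=False))
            cross = sum(
                1
                for a, b in extract_cherries(d)
                if a in epi and b in epi
                and a.rsplit("|", 1)[1] != b.rsplit("|", 1)[1]
            )
            types = assign_cell_types(d, epi)
            assert len(types) == n_epi - cross
            # every epithelial leaf in exactly one type
            members = [
                leaf_label(c, cond) for t in types for c, cond in t.member_clusters
            ]
            assert sorted(members) == sorted(epi)


class TestBranches:
    def test_k1_single_branch(self):
        d = example_cherry_dendrogram()
        ba = extract_branches(d, d.leaves(), k=1)
        assert ba.k == 1 and ba.branches["B1"] == set(d.leaves())

    def test_k_equals_leaves_singletons(self):
        d = example_cherry_dendrogram()
        ba = extract_branches(d, d.leaves(), k=16)
        assert ba.k == 16
        assert all(len(v) == 1 for v in ba.branches.values())

    def test_three_branch_fixture_recovered(self):
        d = example_cherry_dendrogram()
        ba = extract_branches(d, d.leaves(), k=3)
        groups = {frozenset(v) for v in ba.branches.values()}
        expect = {
            frozenset({"EC1|unwounded", "EC2|unwounded", "EC9|wounded"}),
            frozenset({"EC3|unwounded", "EC10|wounded", "EC4|unwounded",
                       "EC11|wounded", "EC12|wounded", "EC13|wounded"}),
            frozenset({"EC5|unwounded", "EC6|unwounded", "EC7|unwounded",
                       "EC8|unwounded", "EC14|wounded", "EC15|wounded",
                       "EC16|wounded"}),
        }
        assert groups == expect

    def test_k_too_large_rejected(self):
        d = example_cherry_dendrogram()
        with pytest.raises(DendrogramError):
            extract_branches(d, d.leaves(), k=17)

    def test_branches_partition_epithelial_subset(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            d, leaves = random_binary_tree(rng, int(rng.integers(3, 12)))
            epi = list(rng.choice(leaves, size=int(rng.integers(2, len(leaves) + 1)),
                                  replace=False))
            k = int(rng.integers(1, len(epi) + 1))
            ba = extract_branches(d, epi, k=k)
            assert ba.k == k
            combined = sorted(l for v in ba.branches.values() for l in v)
            assert combined == sorted(epi)
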