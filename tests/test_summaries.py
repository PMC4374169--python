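"""Continental aggregation, Ward trees, chromosome bootstrap, consensus."""

import numpy as np
import pandas as pd
import pytest

from haplomix.mixture import DonorBasis
from haplomix.painting import PaintingResult
from haplomix.summaries import (
    ContinentMap,
    bootstrap_populations,
    consensus_tree,
    continental_aggregate,
    relative_composition,
    ward_tree,
)
from haplomix.trees import SupportedTree, TreeNode, tree_from_linkage

from oracles import lance_williams_ward


CMAP = ContinentMap.direct({
    "Yoruba": "Africa", "Mandenka": "Africa", "Spain": "Europe",
    "Britain": "Europe", "China": "Asia/America",
})


def sols(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T.fillna(0.0)


class TestContinentalAggregate:
    def test_single_continent_totals_one(self):
        s = sols({"P1": {"Yoruba": 0.6, "Mandenka": 0.4}})
        agg = continental_aggregate(s, CMAP)
        assert agg.loc["P1", "Africa"] == pytest.approx(1.0)

    def test_additive_across_clusters(self):
        s = sols({"P1": {"Yoruba": 0.3, "Mandenka": 0.2, "Spain": 0.5}})
        agg = continental_aggregate(s, CMAP)
        assert agg.loc["P1", "Africa"] == pytest.approx(0.5)
        assert agg.loc["P1", "Europe"] == pytest.approx(0.5)
        assert agg.sum(axis=1)["P1"] == pytest.approx(1.0)

    def test_unmapped_cluster_with_weight_is_error(self):
        s = sols({"P1": {"Yoruba": 0.5, "Atlantis": 0.5}})
        with pytest.raises(KeyError, match="Atlantis"):
            continental_aggregate(s, CMAP)

    def test_region_to_continent_totality_enforced(self):
        with pytest.raises(ValueError, match="continent"):
            ContinentMap(cluster_region={"x": "regionX"}, region_continent={})


class TestRelativeComposition:
    def test_renormalizes_within_continent(self):
        s = sols({"P1": {"Yoruba": 0.09, "Mandenka": 0.01, "Spain": 0.9}})
        rel = relative_composition(s, CMAP, "Africa", min_total=0.01)
        assert rel.proportions.loc["P1", "Yoruba"] == pytest.approx(0.9)
        assert rel.proportions.loc["P1", "Mandenka"] == pytest.approx(0.1)

    def test_low_total_population_excluded_with_reason(self):
        s = sols({
            "Maya": {"Yoruba": 0.0, "Spain": 0.2, "China": 0.8},
            "Carib": {"Yoruba": 0.5, "Spain": 0.5},
        })
        rel = relative_composition(s, CMAP, "Africa", min_total=0.01)
        assert "Maya" in rel.excluded
        assert list(rel.proportions.index) == ["Carib"]

    def test_min_total_zero_keeps_everyone_with_mass(self):
        s = sols({
            "P1": {"Yoruba": 0.5, "Spain": 0.5},
            "P2": {"Yoruba": 0.2, "Spain": 0.8},
        })
        rel = relative_composition(s, CMAP, "Africa", min_total=0.0)
        assert rel.excluded == {}

    def test_mass_conserved(self):
        s = sols({
            "P1": {"Yoruba": 0.3, "Mandenka": 0.3, "Spain": 0.4},
            "P2": {"Yoruba": 0.1, "Mandenka": 0.5, "Spain": 0.4},
        })
        rel = relative_composition(s, CMAP, "Africa")
        assert np.allclose(rel.proportions.sum(axis=1), 1.0, atol=1e-8)


class TestWardTree:
    def test_two_populations_single_merge(self):
        rel = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}).T
        tree = ward_tree(rel)
        assert set(tree.root.leaves()) == {"a", "b"}
        assert tree.root.children[0].is_leaf

    def test_identical_vectors_merge_first(self):
        rel = pd.DataFrame(
            {"a": [0.5, 0.5], "b": [0.5, 0.5], "c": [0.9, 0.1]}
        ).T
        tree = ward_tree(rel)
        assert frozenset({"a", "b"}) in tree.clades()

    def test_heights_match_lance_williams(self):
        rng = np.random.default_rng(5)
        pts = rng.dirichlet(np.ones(3), size=4)
        rel = pd.DataFrame(pts, index=["p1", "p2", "p3", "p4"])
        tree = ward_tree(rel)

        def heights(node, acc):
            if not node.is_leaf:
                acc.append(node.height)
                for c in node.children:
                    heights(c, acc)
            return acc

        ours = np.sort(heights(tree.root, []))
        ref = np.sort(lance_williams_ward(pts))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            ward_tree(pd.DataFrame({"a": [1.0, 0.0]}).T)


def two_pop_painting(weights_by_pop, n_chroms=3):
    """Painting with one individual per population, fixed per-chrom weights."""
    pops = list(weights_by_pop)
    n = len(pops)
    copied = np.zeros((2 * n, n_chroms, 2))
    for i, p in enumerate(pops):
        w = np.asarray(weights_by_pop[p], dtype=float)
        copied[2 * i] = w / 2
        copied[2 * i + 1] = w / 2
    return PaintingResult(
        targets=[f"{p}_ind" for p in pops], target_populations=pops,
        groups=["A", "B"], chroms=list(range(1, n_chroms + 1)),
        copied_sites=copied, chunk_counts=np.ones_like(copied),
        copied_morgans=copied * 0.01, log_likelihood=np.zeros((2 * n, n_chroms)),
    )


class TestBootstrap:
    def test_single_member_population_is_fixed_point(self):
        res = two_pop_painting({"P": [[0.7, 0.3], [0.6, 0.4], [0.5, 0.5]]})
        reps = bootstrap_populations(res, n_reps=10, seed=1)
        base = res.copying_vectors(level="population").loc["P"]
        for rep in reps:
            assert np.allclose(rep.loc["P"], base, atol=1e-12)

    def test_seed_determinism(self, standard_run):
        _, run = standard_run
        a = bootstrap_populations(run.recipient_paintings, 5, seed=7)
        b = bootstrap_populations(run.recipient_paintings, 5, seed=7)
        for ra, rb in zip(a, b):
            assert ra.equals(rb)

    def test_bootstrap_mean_consistent_with_observed(self, standard_run):
        """Replicate means stay within 3 bootstrap SEs of the observed
        population copying vector, coordinate by coordinate."""
        _, run = standard_run
        reps = bootstrap_populations(run.recipient_paintings, 200, seed=8)
        arr = np.stack([r.loc["ADMIXED"].to_numpy() for r in reps])
        obs = run.recipient_paintings.copying_vectors(
            level="population").loc["ADMIXED"].to_numpy()
        se = arr.std(axis=0, ddof=1) / np.sqrt(len(arr))
        assert (np.abs(arr.mean(axis=0) - obs) <= 3 * se + 1e-12).all()


def chain_tree(*clades_and_leaves):
    """Helper building a rooted tree from nested tuples."""
    def build(x):
        if isinstance(x, str):
            return TreeNode(name=x)
        return TreeNode(children=[build(c) for c in x])
    return SupportedTree(root=build(clades_and_leaves))


class TestConsensus:
    def test_identical_trees_reproduce_themselves(self):
        trees = [chain_tree(("a", "b"), ("c", "d")) for _ in range(1000)]
        cons = consensus_tree(trees, threshold=0.8)
        assert cons.clades() == {frozenset("ab"), frozenset("cd")}
        assert all(v == 1.0 for v in cons.supports().values())

    def test_exact_boundary_support_excluded(self):
        """A clade in exactly 800/1000 trees is dropped at threshold 0.8."""
        with_ab = [chain_tree(("a", "b"), ("c", "d"))] * 800
        without = [chain_tree(("a", "c"), ("b", "d"))] * 200
        cons = consensus_tree(with_ab + without, threshold=0.8)
        assert frozenset("ab") not in cons.clades()
        # at a slightly lower threshold it is kept with support 0.8
        cons2 = consensus_tree(with_ab + without, threshold=0.75)
        assert cons2.supports()[frozenset("ab")] == pytest.approx(0.8)

    def test_five_tree_hand_tally(self):
        """Direct clade count on five 4-leaf trees."""
        trees = [
            chain_tree(("a", "b"), ("c", "d")),
            chain_tree(("a", "b"), ("c", "d")),
            chain_tree(("a", "b"), "c", "d"),
            chain_tree(("a", "c"), ("b", "d")),
            chain_tree((("a", "b"), "c"), "d"),
        ]
        # tallies: {a,b}: 4/5; {c,d}: 2/5; {a,c}: 1/5; {b,d}: 1/5; {a,b,c}: 1/5
        cons = consensus_tree(trees, threshold=0.5)
        assert cons.clades() == {frozenset("ab")}
        assert cons.supports()[frozenset("ab")] == pytest.approx(0.8)

    def test_inconsistent_leaf_sets_rejected(self):
        t1 = chain_tree(("a", "b"), ("c", "d"))
        t2 = chain_tree(("a", "b"), ("c", "e"))
        with pytest.raises(ValueError, match="leaf"):
            consensus_tree([t1, t2])

    def test_majority_clades_nest_into_multifurcation(self):
        trees = (
            [chain_tree((("a", "b"), "c"), "d")] * 7
            + [chain_tree(("a", "b"), ("c", "d"))] * 3
        )
        cons = consensus_tree(trees, threshold=0.5)
        assert frozenset("ab") in cons.clades()
        assert frozenset("abc") in cons.clades()
        assert frozenset("cd") not in cons.clades()

    def test_matches_dendropy_majority_consensus(self):
        import dendropy

        rng = np.random.default_rng(9)
        trees = []
        for _ in range(12):
            leaves = ["a", "b", "c", "d", "e"]
            rng.shuffle(leaves)
            trees.append(chain_tree(
                (leaves[0], leaves[1]), (leaves[2], (leaves[3], leaves[4]))
            ))
        cons = consensus_tree(trees, threshold=0.5)
        tl = dendropy.TreeList.get(
            data="\n".join(t.to_newick() for t in trees), schema="newick",
            rooting="force-rooted",
        )
        ref = tl.consensus(min_freq=0.5001, is_bipartitions_updated=False)
        ref_clades = set()
        for nd in ref.preorder_internal_node_iter():
            c = frozenset(l.taxon.label for l in nd.leaf_iter())
            if 1 < len(c) < 5:
                ref_clades.add(c)
        assert cons.clades() == ref_clades


class TestBlocSeparation:
    def test_observed_relative_composition_separates_blocs(self, bloc_run):
        from haplomix.scenarios import BLOC_CONTINENTS
        from haplomix.summaries import observed_relative_composition

        sc, run = bloc_run
        rel = observed_relative_composition(
            run.recipient_paintings, run.basis, BLOC_CONTINENTS, "Europe"
        )
        p = rel.proportions
        assert p.loc["R1", ["EU1", "EU2"]].sum() > 0.9
        assert p.loc["R3", ["EU3", "EU4"]].sum() > 0.9


def test_newick_support_labels_round_trip():
    import dendropy

    trees = [chain_tree(("a", "b"), ("c", "d"))] * 4
    cons = consensus_tree(trees, threshold=0.5)
    nwk = cons.to_newick()
    t = dendropy.Tree.get(data=nwk, schema="newick")
    labels = {nd.label for nd in t.preorder_internal_node_iter() if nd.label}
    assert "1" in labels
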