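from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from achiasma import (
    METRICS,
    GenomeSpec,
    GenotypeMatrix,
    UnrootedTree,
    build_tree,
    concordance_scan,
    dissimilarity,
    normalize,
    random_pair_means,
    random_topology,
    simulate_population,
    tree_distance,
)


# ---------------------------------------------------------------------------
# independent oracles (naive graph algorithms, no bitmasks)


def oracle_splits(tree: UnrootedTree) -> set[frozenset]:
    """Nontrivial splits via edge removal + flood fill on a networkx graph."""
    import networkx as nx

    g = nx.Graph()
    for u, vs in tree.adjacency.items():
        for v in vs:
            g.add_edge(u, v)
    n = tree.n_leaves
    out = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        side = frozenset(x for x in comp if x < n)
        if 2 <= len(side) <= n - 2:
            out.add(min(side, frozenset(range(n)) - side, key=sorted))
    return out


def oracle_quartet(tree: UnrootedTree, quartet) -> frozenset:
    """Resolution of one quartet: the pair separated from the rest by a split."""
    a, b, c, d = quartet
    qset = {a, b, c, d}
    for side in oracle_splits(tree):
        inter = side & qset
        if len(inter) == 2:
            # canonical: report the pair containing the smallest member
            return inter if min(qset) in inter else qset - inter
    return frozenset()  # unresolved (cannot happen in binary trees)


def oracle_path_lengths(tree: UnrootedTree) -> np.ndarray:
    import networkx as nx

    g = nx.Graph()
    for u, vs in tree.adjacency.items():
        for v in vs:
            g.add_edge(u, v)
    n = tree.n_leaves
    out = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_shortest_path_length(g, i)
        for j in range(n):
            out[i, j] = lengths[j]
    return out


def oracle_rf(t1, t2) -> float:
    return float(len(oracle_splits(t1) ^ oracle_splits(t2)))


def oracle_pd(t1, t2) -> float:
    d1, d2 = oracle_path_lengths(t1), oracle_path_lengths(t2)
    iu = np.triu_indices(t1.n_leaves, k=1)
    return float(np.sqrt(((d1[iu] - d2[iu]) ** 2).sum()))


def oracle_quartet_distance(t1, t2) -> float:
    return float(sum(
        oracle_quartet(t1, q) != oracle_quartet(t2, q)
        for q in combinations(range(t1.n_leaves), 4)
    ))


def oracle_ms(t1, t2) -> float:
    n = t1.n_leaves
    full = frozenset(range(n))
    s1, s2 = sorted(oracle_splits(t1), key=sorted), sorted(oracle_splits(t2), key=sorted)
    while len(s1) < len(s2):
        s1.append(None)
    while len(s2) < len(s1):
        s2.append(None)

    def cost(a, b):
        if a is None and b is None:
            return 0
        if a is None:
            return min(len(b), n - len(b))
        if b is None:
            return min(len(a), n - len(a))
        return min(len(a ^ b), len((full - a) ^ b))

    best = None
    for perm in permutations(range(len(s2))):
        total = sum(cost(s1[i], s2[perm[i]]) for i in range(len(s1)))
        best = total if best is None else min(best, total)
    return float(best)


def oracle_mas(t1, t2) -> float:
    n = t1.n_leaves
    for size in range(n, 2, -1):
        for subset in combinations(range(n), size):
            agree = all(
                oracle_quartet(t1, q) == oracle_quartet(t2, q)
                for q in combinations(subset, 4)
            )
            if agree:
                return float(n - size)
    return float(n - 3)


ORACLES = {"RF": oracle_rf, "PD": oracle_pd, "Q": oracle_quartet_distance,
           "MS": oracle_ms, "MAS": oracle_mas}


# ---------------------------------------------------------------------------


class TestDissimilarity:
    def _gm(self, dosages):
        d = np.asarray(dosages, dtype=np.int8)
        return GenotypeMatrix(
            samples=[f"s{i}" for i in range(d.shape[1])],
            chromosomes=np.array(["c"] * d.shape[0]),
            positions=np.arange(d.shape[0], dtype=np.int64),
            dosages=d,
        )

    def test_identical_rows_distance_zero(self):
        gm = self._gm([[0, 0], [2, 2], [1, 1]])
        assert dissimilarity(gm).iloc[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gm = self._gm([[0, 2], [2, 0], [0, 2]])
        assert dissimilarity(gm).iloc[0, 1] == 1.0

    def test_hom_vs_het_half(self):
        gm = self._gm([[0, 1], [0, 1], [2, 1]])
        assert dissimilarity(gm).iloc[0, 1] == 0.5

    def test_missing_pairwise_deleted(self):
        gm = self._gm([[0, 2], [-1, 2], [0, 0]])
        assert dissimilarity(gm).iloc[0, 1] == 0.5

    def test_no_shared_sites_is_error(self):
        gm = self._gm([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no shared"):
            dissimilarity(gm)


class TestBIONJ:
    def _matrix_from_tree(self, newick):
        tree = UnrootedTree.from_newick(newick)
        import networkx as nx

        g = nx.Graph()
        for u, vs in tree.adjacency.items():
            for v in vs:
                g.add_edge(u, v, weight=tree.lengths[frozenset((u, v))])
        n = tree.n_leaves
        d = np.zeros((n, n))
        for i in range(n):
            lengths = nx.single_source_dijkstra_path_length(g, i)
            for j in range(n):
                d[i, j] = lengths[j]
        return tree, pd.DataFrame(d, index=tree.labels, columns=tree.labels)

    def test_additive_five_taxon_tree_recovered_exactly(self):
        truth, dmat = self._matrix_from_tree("((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);")
        rec = build_tree(dmat)
        assert tree_distance(rec, truth, "RF") == 0.0
        assert sorted(round(v, 9) for v in rec.lengths.values()) == \
            sorted(round(v, 9) for v in truth.lengths.values())

    def test_dominant_split_of_four_taxa(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.9, 0.9],
             [0.1, 0, 0.9, 0.9],
             [0.9, 0.9, 0, 0.1],
             [0.9, 0.9, 0.1, 0]],
            index=list("ABCD"), columns=list("ABCD"))
        tree = build_tree(d)
        assert tree.nontrivial_splits() in ([frozenset("AB")], [frozenset("CD")])

    def test_taxon_order_invariance(self):
        truth, dmat = self._matrix_from_tree("((A:1,B:2):1.5,(C:0.5,D:1):2,(E:1,F:2):1);")
        shuffled = dmat.loc[list("FECDBA"), list("FECDBA")]
        assert tree_distance(build_tree(dmat), build_tree(shuffled), "RF") == 0.0

    def test_incomplete_matrix_rejected(self):
        d = pd.DataFrame(np.full((4, 4), np.nan), index=list("ABCD"), columns=list("ABCD"))
        with pytest.raises(ValueError):
            build_tree(d)


class TestTreeDistances:
    def test_identity_is_zero_for_all_metrics(self, rng):
        t = random_topology([f"x{i}" for i in range(9)], rng)
        for m in METRICS:
            assert tree_distance(t, t, m) == 0.0

    def test_two_four_taxon_topologies(self):
        t1 = UnrootedTree.from_newick("((A,B),(C,D));")
        t2 = UnrootedTree.from_newick("((A,C),(B,D));")
        assert tree_distance(t1, t2, "RF") == 2.0
        assert tree_distance(t1, t2, "Q") == 1.0
        assert tree_distance(t1, t2, "MAS") == 1.0

    @pytest.mark.parametrize("n_taxa", [6, 7])
    def test_all_metrics_match_exhaustive_oracles(self, n_taxa, rng):
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(25):
            t1 = random_topology(labels, rng)
            t2 = random_topology(labels, rng)
            for metric in METRICS:
                got = tree_distance(t1, t2, metric)
                want = ORACLES[metric](t1, t2)
                assert got == pytest.approx(want), metric

    def test_rf_matches_dendropy(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        labels = [f"t{i}" for i in range(10)]
        for _ in range(10):
            t1 = random_topology(labels, rng)
            t2 = random_topology(labels, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert tree_distance(t1, t2, "RF") == treecompare.symmetric_difference(d1, d2)

    def test_metric_axioms_on_sampled_trees(self, rng):
        labels = [f"t{i}" for i in range(7)]
        trees = [random_topology(labels, rng) for _ in range(8)]
        for metric in METRICS:
            for a in trees:
                for b in trees:
                    dab = tree_distance(a, b, metric)
                    assert dab >= 0
                    assert dab == tree_distance(b, a, metric)
                    same_topology = set(a.splits()) == set(b.splits())
                    assert (dab == 0) == same_topology

    def test_leaf_set_mismatch_rejected(self, rng):
        t1 = random_topology(["a", "b", "c", "d"], rng)
        t2 = random_topology(["a", "b", "c", "e"], rng)
        with pytest.raises(ValueError):
            tree_distance(t1, t2, "RF")


class TestRandomTopologies:
    def test_uniform_over_five_taxon_topologies(self):
        # all 15 labeled topologies equally likely (chi-square at alpha 0.01)
        rng = np.random.default_rng(77)
        counts: dict[frozenset, int] = {}
        for _ in range(15_000):
            t = random_topology(list("abcde"), rng)
            key = frozenset(t.nontrivial_splits())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        from scipy import stats

        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 0.01

    def test_newick_round_trip(self, rng):
        t = random_topology([f"s{i}" for i in range(8)], rng)
        back = UnrootedTree.from_newick(t.to_newick())
        assert set(back.splits()) == set(t.splits())


class TestNormalization:
    def test_zero_raw_normalizes_to_zero(self):
        assert normalize(0.0, "RF", n_taxa=8, n_pairs=50, seed=1) == 0.0

    def test_random_pair_normalized_expectation_near_one(self, rng):
        means = random_pair_means(8, ("RF",), n_pairs=400, seed=5)
        draws = [
            tree_distance(random_topology([f"t{i}" for i in range(8)], rng),
                          random_topology([f"t{i}" for i in range(8)], rng), "RF")
            / means["RF"]
            for _ in range(400)
        ]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 1.0) < 3 * se

    def test_rf_random_mean_agrees_with_independent_sampler(self):
        # Monte-Carlo oracle: an independently seeded estimate of the same mean
        a = random_pair_means(11, ("RF",), n_pairs=600, seed=1)["RF"]
        b = random_pair_means(11, ("RF",), n_pairs=600, seed=999)["RF"]
        assert a == pytest.approx(b, rel=0.05)


class TestConcordanceScan:
    def test_shared_history_gives_near_zero_distances(self):
        genome = GenomeSpec(chromosomes=(("c1", 150_000), ("c2", 150_000),
                                         ("c3", 150_000)))
        gm, _ = simulate_population(8, genome, snp_density=3e-3,
                                    n_genealogies=1, seed=101)
        _, chrom_trees, reports = concordance_scan(gm, n_random=100, seed=5)
        assert set(reports) == {"c1", "c2", "c3"}
        for rep in reports.values():
            for m in METRICS:
                assert rep.metrics[m].normalized <= 0.25

    def test_discordant_chromosome_ranks_highest(self):
        genome = GenomeSpec(chromosomes=(("c1", 150_000), ("c2", 150_000),
                                         ("c3", 150_000)))
        gm, _ = simulate_population(
            8, genome, snp_density=3e-3, n_genealogies=2,
            chromosome_genealogy={"c1": 0, "c2": 0, "c3": 1}, seed=103)
        _, _, reports = concordance_scan(gm, n_random=100, seed=5)
        for m in ("RF", "Q", "PD"):
            outlier = reports["c3"].metrics[m].normalized
            assert outlier > reports["c1"].metrics[m].normalized
            assert outlier > reports["c2"].metrics[m].normalized

    def test_sparse_chromosome_skipped(self):
        genome = GenomeSpec(chromosomes=(("c1", 150_000), ("c2", 150_000)))
        gm, _ = simulate_population(8, genome, snp_density=2e-3,
                                    n_genealogies=1, seed=105)
        keep = gm.chromosomes != "c2"
        # leave c2 with a single site: too few informative sites
        drop = np.flatnonzero(~keep)[1:]
        mask = np.ones(gm.n_sites, dtype=bool)
        mask[drop] = False
        gm2 = GenotypeMatrix(gm.samples, gm.chromosomes[mask],
                             gm.positions[mask], gm.dosages[mask])
        _, chrom_trees, reports = concordance_scan(gm2, n_random=50, seed=5)
        assert "c2" not in reports and "c1" in reports
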