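"""SNP-distance trees and unrooted topology-concordance metrics.

Strain relationships are summarized as allele-sharing distances, trees
are built with BIONJ (variance-weighted neighbor joining) and compared
with five unrooted, purely topological metrics:

* RF — Robinson-Foulds: splits present in exactly one tree;
* MS — matching split: minimum-weight perfect matching between split
  sets under the symmetric-difference split weight;
* PD — path difference: Euclidean distance between the vectors of
  topological leaf-pair path lengths;
* Q  — quartet: number of leaf quartets resolved differently;
* MAS — maximum agreement subtree: leaves minus the largest leaf subset
  on which the restricted topologies agree.

Raw distances are normalized by the mean over randomly generated pairs
of uniform unrooted binary topologies, so ~1 means "as different as
random trees".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

METRICS = ("MAS", "MS", "RF", "PD", "Q")


# ---------------------------------------------------------------------------
# genotype container and allele-sharing distance


@dataclass
class GenotypeMatrix:
    """Biallelic sites x strains alt-allele dosages (0/1/2, -1 missing)."""

    samples: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n_sites = len(self.chromosomes)
        if self.dosages.shape != (n_sites, len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")
        if n_sites and not np.isin(self.dosages, (-1, 0, 1, 2)).all():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.chromosomes)

    def for_chromosome(self, chrom: str) -> "GenotypeMatrix":
        mask = self.chromosomes == chrom
        return GenotypeMatrix(self.samples, self.chromosomes[mask],
                              self.positions[mask], self.dosages[mask])

    def informative_sites(self) -> int:
        """Sites with >= 2 distinct non-missing dosages."""
        count = 0
        for row in self.dosages:
            vals = set(int(v) for v in row if v >= 0)
            if len(vals) >= 2:
                count += 1
        return count

    @property
    def chromosome_names(self) -> list[str]:
        return list(dict.fromkeys(self.chromosomes.tolist()))


def dissimilarity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise allele-sharing distance: mean |dosage_i - dosage_j| / 2.

    Identical genotypes score 0, opposite homozygotes 1, hom vs het 0.5;
    sites missing in either strain are pairwise-deleted.  A strain pair
    sharing no called sites is an error (incomplete matrix).
    """
    if len(gm.samples) < 2:
        raise ValueError("need >= 2 strains")
    d = gm.dosages.astype(float)
    d[gm.dosages < 0] = np.nan
    n = len(gm.samples)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
        if not both.any():
            raise ValueError(f"no shared called sites between "
                             f"{gm.samples[i]!r} and {gm.samples[j]!r}")
        out[i, j] = out[j, i] = float(np.mean(np.abs(d[both, i] - d[both, j])) / 2.0)
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


# ---------------------------------------------------------------------------
# unrooted trees


class UnrootedTree:
    """An unrooted leaf-labeled tree: leaves 0..n-1 map to sorted labels.

    Internal nodes are integers >= n; ``lengths`` keys are frozensets of
    adjacent node pairs (branch lengths optional, ignored by all
    metrics).
    """

    def __init__(self, labels, adjacency, lengths=None):
        self.labels = list(labels)
        self.adjacency: dict[int, list[int]] = {u: list(vs) for u, vs in adjacency.items()}
        self.lengths: dict[frozenset, float] = dict(lengths or {})
        n = len(self.labels)
        for leaf in range(n):
            if leaf not in self.adjacency or len(self.adjacency[leaf]) != 1:
                raise ValueError(f"leaf {leaf} must have exactly one neighbor")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    # -- structure ---------------------------------------------------------

    def splits(self) -> list[int]:
        """Nontrivial splits as bitmasks over leaf indices (bit 0 excluded)."""
        n = self.n_leaves
        full = (1 << n) - 1
        masks: dict[tuple[int, int], int] = {}

        def below(child: int, parent: int) -> int:
            if (child, parent) in masks:
                return masks[(child, parent)]
            if child < n:
                m = 1 << child
            else:
                m = 0
                for nb in self.adjacency[child]:
                    if nb != parent:
                        m |= below(nb, child)
            masks[(child, parent)] = m
            return m

        out = set()
        seen_edges = set()
        for u, vs in self.adjacency.items():
            for v in vs:
                if frozenset((u, v)) in seen_edges:
                    continue
                seen_edges.add(frozenset((u, v)))
                if u < n or v < n:
                    continue  # pendant edge: trivial split
                m = below(u, v)
                if m & 1:
                    m = full & ~m
                if 2 <= bin(m).count("1") <= n - 2:
                    out.add(m)
        return sorted(out)

    def nontrivial_splits(self) -> list[frozenset]:
        """Splits as frozensets of labels (side not containing labels[0])."""
        return [frozenset(self.labels[i] for i in range(self.n_leaves) if m >> i & 1)
                for m in self.splits()]

    def leaf_distances(self) -> np.ndarray:
        """Topological (edge-count) distances between all leaf pairs."""
        n = self.n_leaves
        out = np.zeros((n, n), dtype=np.int64)
        for src in range(n):
            dist = {src: 0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        stack.append(v)
            for leaf in range(n):
                out[src, leaf] = dist[leaf]
        return out

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        n = self.n_leaves
        root = max(self.adjacency) if n > 2 else 0

        def render(u: int, parent: int | None) -> str:
            children = [v for v in self.adjacency[u] if v != parent]
            name = self.labels[u] if u < n else ""
            body = name if not children else \
                "(" + ",".join(render(v, u) for v in children) + ")" + name
            if parent is None:
                return body
            length = self.lengths.get(frozenset((u, parent)))
            return body if length is None else f"{body}:{length:.10g}"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")
        tree.deroot()
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        index = {lab: i for i, lab in enumerate(taxa)}
        adjacency: dict[int, list[int]] = {}
        lengths: dict[frozenset, float] = {}
        next_internal = [len(taxa)]
        node_ids: dict = {}

        def nid(node) -> int:
            if node not in node_ids:
                if node.is_leaf():
                    node_ids[node] = index[node.taxon.label]
                else:
                    node_ids[node] = next_internal[0]
                    next_internal[0] += 1
            return node_ids[node]

        for node in tree.preorder_node_iter():
            u = nid(node)
            adjacency.setdefault(u, [])
            for child in node.child_nodes():
                v = nid(child)
                adjacency.setdefault(v, [])
                adjacency[u].append(v)
                adjacency[v].append(u)
                if child.edge.length is not None:
                    lengths[frozenset((u, v))] = float(child.edge.length)
        return cls(taxa, adjacency, lengths)


def random_topology(labels, rng) -> UnrootedTree:
    """Uniform unrooted binary topology by sequential leaf insertion.

    Starting from the 3-leaf star, each next leaf subdivides an edge
    chosen uniformly among the current 2k-5 edges, which yields the
    uniform distribution over labeled topologies.
    """
    labels = sorted(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 labels")
    adjacency: dict[int, list[int]] = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = next_internal
        next_internal += 1
        adjacency[u].remove(v)
        adjacency[v].remove(u)
        adjacency[u].append(w)
        adjacency[v].append(w)
        adjacency[w] = [u, v, leaf]
        adjacency[leaf] = [w]
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (leaf, w)])
    return UnrootedTree(labels, adjacency)


# ---------------------------------------------------------------------------
# BIONJ


def build_tree(dist: "pd.DataFrame | np.ndarray", labels=None) -> UnrootedTree:
    """BIONJ agglomeration of a complete distance matrix.

    Variance-weighted neighbor joining: the reduction step averages the
    two joined rows with a lambda chosen to minimize the variance of the
    new distances.  Additive matrices are recovered exactly (as with
    classical NJ).  Deterministic: ties in the Q criterion resolve to
    the first (row-major) minimum.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            raise ValueError("labels required with a bare matrix")
        labels = list(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.isnan(d).any():
        raise ValueError("incomplete distance matrix")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    if n < 2:
        raise ValueError("need >= 2 taxa")

    order = sorted(range(n), key=lambda i: labels[i])
    sorted_labels = [labels[i] for i in order]
    d = d[np.ix_(order, order)].copy()
    v = d.copy()
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    lengths: dict[frozenset, float] = {}
    active = list(range(n))           # row indices into d/v
    node_id = {i: i for i in range(n)}  # matrix row -> tree node
    next_node = n

    def connect(a: int, b: int, length: float) -> None:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
        lengths[frozenset((a, b))] = float(length)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]
        dij = d[gi, gj]
        bi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        bj = dij - bi
        vij = v[gi, gj]
        others = [a for a in active if a not in (gi, gj)]
        if vij > 0:
            lam = 0.5 + sum(v[gj, k] - v[gi, k] for k in others) / (2.0 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        new_node = next_node
        next_node += 1
        connect(node_id[gi], new_node, bi)
        connect(node_id[gj], new_node, bj)
        new_row = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        v = np.pad(v, ((0, 1), (0, 1)))
        for a in others:
            d[new_row, a] = d[a, new_row] = (
                lam * d[gi, a] + (1 - lam) * d[gj, a] - lam * bi - (1 - lam) * bj
            )
            v[new_row, a] = v[a, new_row] = (
                lam * v[gi, a] + (1 - lam) * v[gj, a] - lam * (1 - lam) * vij
            )
        active = others + [new_row]
        node_id[new_row] = new_node

    if len(active) == 3:
        a, b, c = active
        center = next_node
        next_node += 1
        dab, dac, dbc = d[a, b], d[a, c], d[b, c]
        connect(node_id[a], center, 0.5 * (dab + dac - dbc))
        connect(node_id[b], center, 0.5 * (dab + dbc - dac))
        connect(node_id[c], center, 0.5 * (dac + dbc - dab))
    elif len(active) == 2:
        a, b = active
        connect(node_id[a], node_id[b], d[a, b])
    return UnrootedTree(sorted_labels, adjacency, lengths)


# ---------------------------------------------------------------------------
# tree metrics (topological, unrooted)


def _check_leafsets(t1: UnrootedTree, t2: UnrootedTree) -> None:
    if t1.labels != t2.labels:
        raise ValueError("trees must share an identical leaf set")


def _quartet_resolution(dmat: np.ndarray, a: int, b: int, c: int, e: int) -> int:
    """Which pairing has the strictly smallest distance sum (0: ab|ce, 1: ac|be, 2: ae|bc)."""
    sums = (dmat[a, b] + dmat[c, e], dmat[a, c] + dmat[b, e], dmat[a, e] + dmat[b, c])
    return int(np.argmin(sums))


def _split_match_cost(s1: int, s2: int, full: int) -> int:
    """Symmetric-difference weight of two splits, minimized over orientations."""
    x = s1 ^ s2
    return min(bin(x).count("1"), bin(full & ~x).count("1"))


def _restricted_splits(splits: list[int], subset: int, n: int) -> frozenset:
    """Canonical nontrivial splits after restricting leaves to ``subset``."""
    k = bin(subset).count("1")
    if k < 4:
        return frozenset()
    anchor = subset & -subset  # lowest set bit of the subset
    out = set()
    for s in splits:
        r = s & subset
        c = bin(r).count("1")
        if c < 2 or c > k - 2:
            continue
        if r & anchor:
            r = subset & ~r
        out.add(r)
    return frozenset(out)


def tree_distance(t1: UnrootedTree, t2: UnrootedTree, metric: str) -> float:
    """Raw unrooted topological distance under one of MAS/MS/RF/PD/Q."""
    _check_leafsets(t1, t2)
    n = t1.n_leaves
    full = (1 << n) - 1
    if metric == "RF":
        return float(len(set(t1.splits()) ^ set(t2.splits())))
    if metric == "PD":
        d1, d2 = t1.leaf_distances(), t2.leaf_distances()
        iu = np.triu_indices(n, k=1)
        return float(np.linalg.norm(d1[iu].astype(float) - d2[iu].astype(float)))
    if metric == "Q":
        d1, d2 = t1.leaf_distances(), t2.leaf_distances()
        return float(sum(
            _quartet_resolution(d1, *q) != _quartet_resolution(d2, *q)
            for q in combinations(range(n), 4)
        ))
    if metric == "MS":
        s1, s2 = t1.splits(), t2.splits()
        size = max(len(s1), len(s2))
        if size == 0:
            return 0.0
        cost = np.zeros((size, size))
        for i in range(size):
            for j in range(size):
                if i < len(s1) and j < len(s2):
                    cost[i, j] = _split_match_cost(s1[i], s2[j], full)
                elif i < len(s1):
                    m = s1[i]
                    cost[i, j] = min(bin(m).count("1"), n - bin(m).count("1"))
                elif j < len(s2):
                    m = s2[j]
                    cost[i, j] = min(bin(m).count("1"), n - bin(m).count("1"))
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].sum())
    if metric == "MAS":
        s1, s2 = t1.splits(), t2.splits()
        for size in range(n, 2, -1):
            for subset_leaves in combinations(range(n), size):
                subset = 0
                for leaf in subset_leaves:
                    subset |= 1 << leaf
                if _restricted_splits(s1, subset, n) == _restricted_splits(s2, subset, n):
                    return float(n - size)
        return float(n - 3)
    raise ValueError(f"unknown metric {metric!r}")


def random_pair_means(
    n_taxa: int,
    metrics=METRICS,
    n_pairs: int = 1000,
    seed=None,
) -> dict[str, float]:
    """Mean metric values over random pairs of uniform binary topologies."""
    from .simulate import as_rng

    rng = as_rng(seed)
    labels = [f"t{i:03d}" for i in range(n_taxa)]
    totals = {m: 0.0 for m in metrics}
    for _ in range(n_pairs):
        a = random_topology(labels, rng)
        b = random_topology(labels, rng)
        for m in metrics:
            totals[m] += tree_distance(a, b, m)
    return {m: totals[m] / n_pairs for m in metrics}


def normalize(
    raw: float,
    metric: str,
    n_taxa: int,
    n_pairs: int = 1000,
    seed=None,
    random_mean: float | None = None,
) -> float:
    """raw / mean(metric over random uniform topology pairs)."""
    if random_mean is None:
        random_mean = random_pair_means(n_taxa, (metric,), n_pairs, seed)[metric]
    if random_mean == 0:
        raise ValueError("random-pair mean is zero; cannot normalize")
    return raw / random_mean


@dataclass(frozen=True)
class MetricResult:
    raw: float
    random_mean: float
    normalized: float


@dataclass
class TreeDistanceReport:
    """Raw + normalized distances of one tree against a reference tree."""

    n_taxa: int
    metrics: dict[str, MetricResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            m: {"raw": r.raw, "random_mean": r.random_mean, "normalized": r.normalized}
            for m, r in self.metrics.items()
        }


def concordance_scan(
    gm: GenotypeMatrix,
    n_random: int = 1000,
    seed=None,
    min_informative: int = 4,
) -> tuple[UnrootedTree, dict[str, UnrootedTree], dict[str, TreeDistanceReport]]:
    """Whole-genome tree vs per-chromosome trees, five normalized metrics.

    Chromosomes with fewer than ``min_informative`` informative sites are
    skipped (logged).  Returns (genome tree, per-chromosome trees,
    per-chromosome reports).
    """
    if len(gm.samples) < 4:
        raise ValueError("need >= 4 strains for tree building")
    genome_tree = build_tree(dissimilarity(gm))
    means = random_pair_means(len(gm.samples), METRICS, n_random, seed)
    chrom_trees: dict[str, UnrootedTree] = {}
    reports: dict[str, TreeDistanceReport] = {}
    for chrom in gm.chromosome_names:
        sub = gm.for_chromosome(chrom)
        if sub.informative_sites() < min_informative:
            logger.info("skipping %s: fewer than %d informative sites", chrom, min_informative)
            continue
        tree = build_tree(dissimilarity(sub))
        chrom_trees[chrom] = tree
        report = TreeDistanceReport(n_taxa=len(gm.samples))
        for m in METRICS:
            raw = tree_distance(tree, genome_tree, m)
            report.metrics[m] = MetricResult(
                raw=raw, random_mean=means[m], normalized=raw / means[m])
        reports[chrom] = report
    return genome_tree, chrom_trees, reports
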