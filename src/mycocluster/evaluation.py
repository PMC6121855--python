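"""Benchmark and validation routines with independent oracles.

Each function re-derives one headline property of the pipeline from
scratch: planted-cluster recovery, oracle agreement for co-localization
chaining, MCL, neighbor joining, DTL reconciliation and Fisher tests, HGT
screen error rates, RELL test calibration, PCA consistency, niche-gene
recovery, and I/O round-trips. The oracles here are deliberately naive
(brute force, closed form, exhaustive enumeration) and independent of the
production code paths they check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import io as mio
from .core import Parameters, SupportTree
from .discovery import _chain_positions
from .hgt import screen_genome
from .phylo import DistanceMatrix, nj_tree, poisson_distance, rell_test
from .reconcile import dtl_reconcile, lca_reconcile_dl
from .simulate import (SCREEN_BACKGROUND_TAXA, SCREEN_DONOR_TAXA,
                       SimulationConfig, hgt_screen_scenario,
                       simulate_dataset, substream)
from .workflow import discover_clusters

# ---------------------------------------------------------------------------
# planted-cluster recovery (discovery pipeline end to end)


def planted_cluster_recovery(n_seeds: int = 20, seed: int = 1,
                             n_background: int = 300) -> dict:
    """Run the full discovery pipeline on ``n_seeds`` simulated datasets;
    returns mean precision/recall of the recovered cluster genes against
    the planted truth and the number of exactly recovered datasets."""
    precisions, recalls = [], []
    n_exact = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=seed + k,
                               n_background_families=n_background)
        genomes, truth = simulate_dataset(cfg)
        result = discover_clusters(genomes, seed=seed + k)
        found = result.cluster_gene_set()
        want = truth.cluster_gene_set()
        tp = len(found & want)
        precisions.append(tp / len(found) if found else 0.0)
        recalls.append(tp / len(want))
        n_exact += found == want
    return {"precision": float(np.mean(precisions)),
            "recall": float(np.mean(recalls)),
            "n_exact": n_exact, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# co-localization oracle


def _chain_oracle(positions: Sequence[int], max_intervening: int
                  ) -> list[tuple[int, ...]]:
    """O(n^2) oracle: mark every pair within the gap bound, then take the
    transitive closure (union-find over all-pairs edges)."""
    pos = sorted(positions)
    parent = {p: p for p in pos}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(pos, 2):
        if abs(b - a) - 1 <= max_intervening:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    clusters: dict[int, list[int]] = {}
    for p in pos:
        clusters.setdefault(find(p), []).append(p)
    return sorted(tuple(sorted(c)) for c in clusters.values())


def colocalization_oracle_agreement(n_scaffolds: int = 100, seed: int = 2
                                    ) -> dict:
    """Compare the production chaining with the brute-force oracle on
    random scaffolds for several gap bounds; returns the agreement rate."""
    rng = substream(seed, "coloc_oracle")
    n_ok = n_total = 0
    for _ in range(n_scaffolds):
        n_genes = int(rng.integers(10, 201))
        n_cand = int(rng.integers(2, max(3, n_genes // 3)))
        positions = sorted(rng.choice(n_genes, size=n_cand, replace=False))
        for max_intervening in (0, 3, 6, 10):
            got = sorted(tuple(c) for c in
                         _chain_positions(positions, max_intervening))
            want = _chain_oracle(positions, max_intervening)
            n_total += 1
            n_ok += got == want
    return {"agreement": n_ok / n_total, "n_instances": n_total}


# ---------------------------------------------------------------------------
# MCL reference


def reference_mcl(matrix: np.ndarray, inflation: float = 2.0,
                  n_iter: int = 200) -> list[list[int]]:
    """Textbook dense MCL, written independently of the production code:
    add unit self-loops, column-normalize, iterate expansion/inflation with
    no pruning, read one cluster per attractor row."""
    M = matrix.astype(float).copy()
    np.fill_diagonal(M, np.maximum(M.max(axis=0), 1.0))
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(n_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, 2)
        M = M ** inflation
        M = M / M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < 1e-8:
            break
    clusters = []
    for i in range(M.shape[0]):
        if M[i, i] > 1e-6:
            members = sorted(int(j) for j in np.nonzero(M[i] > 1e-6)[0])
            if members not in clusters:
                clusters.append(members)
    # nodes claimed by several attractors: first (lowest-index) attractor
    seen: set[int] = set()
    out = []
    for c in clusters:
        c2 = [x for x in c if x not in seen]
        if c2:
            out.append(c2)
            seen.update(c2)
    for j in range(M.shape[0]):
        if j not in seen:
            out.append([j])
    return sorted(out)


def mcl_reference_agreement(n_instances: int = 10, seed: int = 3) -> dict:
    """Barbell graphs (two cliques joined by one weak edge): production MCL
    partition must match the reference implementation."""
    import networkx as nx

    from .homology import mcl_cluster

    rng = substream(seed, "mcl_barbell")
    n_ok = 0
    for _ in range(n_instances):
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(3, 7))
        w = float(rng.uniform(5.0, 20.0))
        weak = float(rng.uniform(0.1, 0.5))
        n = n1 + n2
        M = np.zeros((n, n))
        for i, j in itertools.combinations(range(n1), 2):
            M[i, j] = M[j, i] = w
        for i, j in itertools.combinations(range(n1, n), 2):
            M[i, j] = M[j, i] = w
        M[n1 - 1, n1] = M[n1, n1 - 1] = weak

        graph = nx.Graph()
        for i in range(n):
            graph.add_node(i)
        for i, j in zip(*np.nonzero(M)):
            if i < j:
                graph.add_edge(int(i), int(j), weight=float(M[i, j]))
        groups, _ = mcl_cluster(graph, inflation=2.0)
        got = sorted(sorted(g.members) for g in groups)
        want = sorted(sorted(c) for c in reference_mcl(M))
        n_ok += got == want
    return {"agreement": n_ok / n_instances, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# NJ additive recovery


def _random_tree_with_lengths(n_leaves: int, rng: np.random.Generator
                              ) -> SupportTree:
    cfg = SimulationConfig(seed=int(rng.integers(0, 2**31 - 1)),
                           n_taxa=n_leaves)
    from .simulate import simulate_species_tree
    species = simulate_species_tree(cfg)
    tree = species.tree
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


def nj_additive_recovery(n_trees: int = 100, seed: int = 4,
                         n_leaves: int = 8) -> dict:
    """NJ must exactly recover topology and branch lengths (<= 1e-9) from
    additive distances of random trees."""
    rng = substream(seed, "nj_additive")
    n_topo = n_len = 0
    for _ in range(n_trees):
        tree = _random_tree_with_lengths(n_leaves, rng)
        dm_map = tree.leaf_distance_matrix()
        labels = sorted(tree.leaf_labels())
        values = np.array([[dm_map[(a, b)] for b in labels] for a in labels])
        est = nj_tree(DistanceMatrix(labels=labels, values=values))
        topo_ok = est.bipartitions() == tree.bipartitions()
        n_topo += topo_ok
        if topo_ok:
            est_map = est.leaf_distance_matrix()
            err = max(abs(est_map[(a, b)] - dm_map[(a, b)])
                      for a in labels for b in labels)
            n_len += err <= 1e-9
    return {"topology_recovery": n_topo / n_trees,
            "length_recovery": n_len / n_trees, "n_trees": n_trees}


# ---------------------------------------------------------------------------
# DTL oracle


def _all_rooted_topologies(leaves: Sequence[str]):
    """All rooted binary topologies over the leaf set, as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    # recursion: attach the first leaf to every edge of each smaller tree
    if len(leaves) == 2:
        yield (leaves[0], leaves[1])
        return
    for sub in _all_rooted_topologies(leaves[1:]):
        for t in _attach_everywhere(sub, leaves[0]):
            yield t


def _attach_everywhere(tree, leaf):
    yield (leaf, tree)
    if isinstance(tree, tuple):
        a, b = tree
        for t in _attach_everywhere(a, leaf):
            yield (t, b)
        for t in _attach_everywhere(b, leaf):
            yield (a, t)


def _tuple_to_newick(t) -> str:
    def render(x):
        if isinstance(x, tuple):
            return f"({render(x[0])},{render(x[1])})"
        return x
    return render(t) + ";"


@dataclass
class _SpeciesIndex:
    keys: list[str]
    parent: list[int]
    children: list[list[int]]
    dist_down: list[list[int]]
    leaf_index: dict[str, int]

    @classmethod
    def build(cls, species: SupportTree) -> "_SpeciesIndex":
        nodes = list(species.tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        keys = []
        for i, n in enumerate(nodes):
            keys.append(n.taxon.label if n.is_leaf() else f"I{i}")
        parent = [index[id(n.parent_node)] if n.parent_node else -1
                  for n in nodes]
        children = [[index[id(c)] for c in n.child_nodes()] for n in nodes]
        n_s = len(nodes)
        dist_down = [[-1] * n_s for _ in range(n_s)]
        for a in range(n_s):
            dist_down[a][a] = 0
            stack = [(a, 0)]
            while stack:
                x, d = stack.pop()
                for c in children[x]:
                    dist_down[a][c] = d + 1
                    stack.append((c, d + 1))
        leaf_index = {keys[i]: i for i in range(n_s) if not children[i]}
        return cls(keys, parent, children, dist_down, leaf_index)

    def is_ancestor(self, a: int, b: int) -> bool:
        x = self.parent[b]
        while x != -1:
            if x == a:
                return True
            x = self.parent[x]
        return False


def dtl_oracle_cost(gene_tuple, species: SupportTree,
                    dup: float = 1.5, transfer: float = 3.0,
                    loss: float = 1.0) -> float:
    """Exhaustive-enumeration DTL minimum: try every assignment of gene
    nodes to species nodes and charge each internal node its cheapest
    consistent event (speciation with path losses, duplication, or a
    transfer of one child to a non-ancestral node)."""
    sp = _SpeciesIndex.build(species)
    n_s = len(sp.keys)

    nodes: list = []          # postorder of the gene tuple tree
    node_children: list = []

    def collect(t) -> int:
        if isinstance(t, tuple):
            a = collect(t[0])
            b = collect(t[1])
            nodes.append(t)
            node_children.append((a, b))
        else:
            nodes.append(t)
            node_children.append(None)
        return len(nodes) - 1

    collect(gene_tuple)
    internal = [i for i, ch in enumerate(node_children) if ch is not None]
    fixed = {i: sp.leaf_index[nodes[i]] for i, ch in enumerate(node_children)
             if ch is None}

    def node_cost(x: int, ya: int, yb: int) -> float:
        best = math.inf
        # duplication: both children at/below x
        da, db = sp.dist_down[x][ya], sp.dist_down[x][yb]
        if da >= 0 and db >= 0:
            best = min(best, dup + loss * (da + db))
        # speciation: children descend into distinct child subtrees of x
        for c1, c2 in itertools.permutations(sp.children[x], 2) \
                if len(sp.children[x]) == 2 else []:
            d1, d2 = sp.dist_down[c1][ya], sp.dist_down[c2][yb]
            if d1 >= 0 and d2 >= 0:
                best = min(best, loss * (d1 + d2))
        # transfer of one child to a non-ancestral node
        for stay, move in ((ya, yb), (yb, ya)):
            d_stay = sp.dist_down[x][stay]
            if d_stay < 0:
                continue
            if move != x and not sp.is_ancestor(move, x):
                best = min(best, transfer + loss * d_stay)
        return best

    best_total = math.inf
    for assign in itertools.product(range(n_s), repeat=len(internal)):
        gamma = dict(fixed)
        gamma.update({u: x for u, x in zip(internal, assign)})
        total = 0.0
        for u in internal:
            a, b = node_children[u]
            total += node_cost(gamma[u], gamma[a], gamma[b])
            if total == math.inf:
                break
        best_total = min(best_total, total)
    return best_total


def dtl_oracle_sweep(seed: int = 5, n_random: int = 200) -> dict:
    """Systematic ≤5-leaf sweep of DTL DP vs exhaustive enumeration, plus
    DTL <= DL cost on random gene/species pairs."""
    n_ok = n_total = 0
    # systematic: all species topologies on 3 taxa x all gene topologies on
    # up to 4 leaves drawn from those species
    species_sets = [["A", "B", "C"]]
    for sp_leaves in species_sets:
        for sp_t in set(_canon(t) for t in _all_rooted_topologies(sp_leaves)):
            species = SupportTree.from_newick(_tuple_to_newick(sp_t))
            gene_leaf_sets = []
            for size in (2, 3, 4):
                for combo in itertools.combinations_with_replacement(
                        sp_leaves, size):
                    if len(set(combo)) >= 2:
                        gene_leaf_sets.append(list(combo))
            for leaves in gene_leaf_sets:
                labels = [f"{s}|g{i}" for i, s in enumerate(leaves)]
                for gt in set(_canon(t) for t in
                              _all_rooted_topologies(labels)):
                    gene = SupportTree.from_newick(_tuple_to_newick_q(gt))
                    got = dtl_reconcile(gene, species).total_cost
                    want = dtl_oracle_cost(_strip_gene_ids(gt), species)
                    n_total += 1
                    n_ok += abs(got - want) < 1e-9

    # random DTL <= DL
    rng = substream(seed, "dtl_random")
    n_le = 0
    for _ in range(n_random):
        n_sp = int(rng.integers(4, 7))
        sp_leaves = [chr(ord("A") + i) for i in range(n_sp)]
        sp_t = _random_topology(sp_leaves, rng)
        species = SupportTree.from_newick(_tuple_to_newick(sp_t))
        n_g = int(rng.integers(3, 7))
        gl = [sp_leaves[int(rng.integers(n_sp))] for _ in range(n_g)]
        while len(set(gl)) < 2:
            gl = [sp_leaves[int(rng.integers(n_sp))] for _ in range(n_g)]
        labels = [f"{s}|g{i}" for i, s in enumerate(gl)]
        g_t = _random_topology(labels, rng)
        gene = SupportTree.from_newick(_tuple_to_newick_q(g_t))
        dtl = dtl_reconcile(gene, species)
        dl = lca_reconcile_dl(gene, species)
        n_le += dtl.total_cost <= dl.total_cost + 1e-9
    return {"oracle_agreement": n_ok / n_total, "n_systematic": n_total,
            "dtl_le_dl": n_le / n_random, "n_random": n_random}


def _canon(t):
    if isinstance(t, tuple):
        a, b = _canon(t[0]), _canon(t[1])
        return tuple(sorted((a, b), key=str))
    return t


def _strip_gene_ids(t):
    if isinstance(t, tuple):
        return (_strip_gene_ids(t[0]), _strip_gene_ids(t[1]))
    return t.split("|")[0]


def _tuple_to_newick_q(t) -> str:
    def render(x):
        if isinstance(x, tuple):
            return f"({render(x[0])},{render(x[1])})"
        return x
    return render(t) + ";"


def _random_topology(leaves: Sequence[str], rng: np.random.Generator):
    items = list(leaves)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        items.append((a, b))
    return items[0]


# gene leaves carry "species|gene" labels; the oracle wants bare species
def dtl_oracle_cost_from_newick(gene: SupportTree, species: SupportTree,
                                **kw) -> float:
    def to_tuple(node):
        if node.is_leaf():
            return node.taxon.label.split("|")[0]
        a, b = node.child_nodes()
        return (to_tuple(a), to_tuple(b))
    return dtl_oracle_cost(to_tuple(gene.tree.seed_node), species, **kw)


# ---------------------------------------------------------------------------
# HGT screen error rates


def hgt_screen_error_rates(n_vertical: int = 200, n_transfer: int = 50,
                           seed: int = 6, n_families: int = 20) -> dict:
    """Specificity on vertical-only simulations and sensitivity on
    planted-transfer simulations of the screen scenario."""
    params = Parameters()
    n_false = 0
    for k in range(n_vertical):
        cfg = hgt_screen_scenario(seed=seed + k, transfer=False,
                                  n_families=n_families)
        genomes, _ = simulate_dataset(cfg)
        rec = next(g for g in genomes if g.genome_id == "rec")
        rep = screen_genome(rec, genomes, donor_taxa=SCREEN_DONOR_TAXA,
                            recipient_lineage_taxa={"rel1", "rel2"},
                            background_taxa=SCREEN_BACKGROUND_TAXA,
                            params=params, seed=seed + k)
        n_false += len(rep.final_candidates()) > 0

    n_detected = 0
    for k in range(n_transfer):
        cfg = hgt_screen_scenario(seed=seed + 10_000 + k, transfer=True,
                                  n_families=n_families)
        genomes, truth = simulate_dataset(cfg)
        rec = next(g for g in genomes if g.genome_id == "rec")
        rep = screen_genome(rec, genomes, donor_taxa=SCREEN_DONOR_TAXA,
                            recipient_lineage_taxa={"rel1", "rel2"},
                            background_taxa=SCREEN_BACKGROUND_TAXA,
                            params=params, seed=seed + 10_000 + k)
        flagged = {c.query[1] for c in rep.final_candidates()}
        want = {f"rec_{e.family_id}" for e in truth.hgt_events}
        n_detected += want <= flagged and flagged <= want
    return {"specificity": 1.0 - n_false / n_vertical,
            "n_vertical": n_vertical,
            "sensitivity": n_detected / n_transfer,
            "n_transfer": n_transfer}


# ---------------------------------------------------------------------------
# RELL calibration


def rell_type_i_error(n_sims: int = 200, seed: int = 7,
                      n_taxa: int = 6, length: int = 300) -> dict:
    """Type-I error of the RELL test: data simulated vertically, the
    constrained topology IS the generating tree, the 'optimal' tree is the
    NJ fit; rejections are false positives.

    Internal branches of the generating trees are floored at 0.08
    substitutions/site: the type-I property is only well defined when the
    generating topology is identifiable (a near-zero internal branch makes
    the 'true' resolution arbitrary, and any best-vs-prespecified
    comparison is then anticonservative by construction)."""
    from .simulate import evolve_sequences_on_tree, simulate_species_tree

    n_reject = 0
    for k in range(n_sims):
        cfg = SimulationConfig(seed=seed + k, n_taxa=n_taxa)
        species = simulate_species_tree(cfg)
        for edge in species.tree.tree.preorder_edge_iter():
            head = edge.head_node
            if head.parent_node is not None and not head.is_leaf() \
                    and edge.length is not None:
                edge.length = max(edge.length, 0.08)
        aln = evolve_sequences_on_tree(
            species.tree, length, substream(seed + k, "rell_null"))
        dm = poisson_distance(aln)
        # both topologies carry branch lengths fitted to the same data
        from .phylo import fit_branch_lengths_ols
        opt = fit_branch_lengths_ols(nj_tree(dm), dm)
        truth_tree = fit_branch_lengths_ols(species.tree, dm)
        res = rell_test(aln, opt, truth_tree, n_resamples=1000,
                        seed=seed + k)
        n_reject += res.reject
    return {"type_i_error": n_reject / n_sims, "n_sims": n_sims}


# ---------------------------------------------------------------------------
# Fisher oracle


def fisher_hypergeom_oracle(a: int, b: int, c: int, d: int) -> float:
    """Closed-form one-tailed (enrichment) Fisher p: hypergeometric sum
    written from first principles with exact integer arithmetic."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
              / math.comb(n, row1))
    return p


def fisher_oracle_agreement(n_tables: int = 1000, seed: int = 8) -> dict:
    """scipy's one-tailed Fisher test (the production route) vs the
    hypergeometric-sum oracle on random 2x2 tables."""
    from scipy import stats
    rng = substream(seed, "fisher_tables")
    max_err = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        oracle = fisher_hypergeom_oracle(a, b, c, d)
        max_err = max(max_err, abs(p - oracle))
    diag_p = fisher_hypergeom_oracle(10, 0, 0, 10)
    return {"max_abs_error": max_err, "n_tables": n_tables,
            "diag_table_p": diag_p,
            "diag_table_expected": 1.0 / math.comb(20, 10)}


# ---------------------------------------------------------------------------
# PCA consistency


def pca_consistency(n_matrices: int = 50, seed: int = 9) -> dict:
    """Variance fractions must sum to one and scores/loadings must match a
    correlation-matrix eigendecomposition oracle up to sign."""
    from scipy.linalg import eigh

    import pandas as pd

    from .content import pca

    rng = substream(seed, "pca_random")
    worst_var = 0.0
    n_match = 0
    for _ in range(n_matrices):
        n_rows = int(rng.integers(4, 10))
        n_cols = int(rng.integers(5, 25))
        mat = rng.integers(0, 8, size=(n_rows, n_cols)).astype(float)
        # ensure no constant columns
        mat[0] += 1.0
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(n_rows)],
                          columns=[f"c{j}" for j in range(n_cols)])
        df = df.loc[:, df.std(ddof=1) > 0]
        if df.shape[1] < 2:
            continue
        res = pca(df)
        worst_var = max(worst_var,
                        abs(res.variance_fraction.sum() - 1.0))
        # oracle: eigendecomposition of the (unnormalized) correlation matrix
        z = (df - df.mean()) / df.std(ddof=1)
        w, v = eigh((z.T @ z).to_numpy())
        order = np.argsort(w)[::-1]
        w, v = np.clip(w[order], 0.0, None), v[:, order]
        k = len(res.variance_fraction)
        ok = np.allclose(w[:k] / w.sum(), res.variance_fraction, atol=1e-9)
        for j in range(min(3, k)):
            load = res.loadings.iloc[:, j].to_numpy()
            ref = v[:, j]
            ok &= (np.allclose(load, ref, atol=1e-6)
                   or np.allclose(load, -ref, atol=1e-6))
        n_match += bool(ok)
    return {"max_variance_sum_error": worst_var,
            "oracle_match_rate": n_match / n_matrices,
            "n_matrices": n_matrices}


# ---------------------------------------------------------------------------
# niche-gene recovery


CONTENT_ECOLOGY = {}
for i in range(1, 5):
    CONTENT_ECOLOGY[f"G{i:02d}"] = ("dung",)
for i in (5, 6):
    CONTENT_ECOLOGY[f"G{i:02d}"] = ("dung", "wood")
for i in range(7, 13):
    CONTENT_ECOLOGY[f"G{i:02d}"] = ("wood",)
for i in range(13, 17):
    CONTENT_ECOLOGY[f"G{i:02d}"] = ("mycorrhizal",)


def content_scenario(seed: int) -> SimulationConfig:
    """Sixteen genomes with fixed ecologies (6 dung incl. two dual
    dung+wood, 8 wood, 4 mycorrhizal) and 15% ecology-linked families."""
    return SimulationConfig(
        n_taxa=16, seed=seed, n_background_families=150,
        ecology_assignments={k: frozenset(v)
                             for k, v in CONTENT_ECOLOGY.items()},
        ecology_linked_fraction=0.15, plant_cluster=False,
        hgt_events=[])


def niche_recovery(n_seeds: int = 20, seed: int = 10) -> dict:
    """niche_specific_groups on simulated presence matrices must equal the
    truth-log families meeting the niche cutoffs, exactly."""
    from .content import niche_specific_groups
    from .simulate import simulate_gene_content, simulate_species_tree

    cutoffs = Parameters().niche_cutoffs
    niche_label = {"dung": "dung", "wood": "wood", "ecm": "mycorrhizal"}
    n_exact = 0
    for k in range(n_seeds):
        cfg = content_scenario(seed + k)
        species = simulate_species_tree(cfg)
        presence, truth = simulate_gene_content(species, cfg)
        got = niche_specific_groups(presence.T, species.ecology,
                                    species_tree=species.tree,
                                    cutoffs=cutoffs)
        ok = True
        for niche_key, cutoff in cutoffs.items():
            label = niche_label[niche_key]
            in_niche = {g for g, eco in species.ecology.items()
                        if label in eco}
            expected = set()
            for fam, pres in truth.family_presence.items():
                pres = set(pres)
                if len(pres & in_niche) >= cutoff and not (pres - in_niche):
                    expected.add(fam)
            ok &= set(got[niche_key].groups) == expected
        n_exact += ok
    return {"n_exact": n_exact, "n_seeds": n_seeds,
            "exact_rate": n_exact / n_seeds}


# ---------------------------------------------------------------------------
# I/O round trips


def io_roundtrip_check(seed: int = 11, tmp_dir=None) -> dict:
    """write -> read identity for the genome bundle and Newick trees on a
    simulated dataset."""
    import tempfile
    from pathlib import Path

    genomes, truth = simulate_dataset(SimulationConfig(seed=seed))
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        td = Path(td)
        mio.write_genome_bundle(genomes, td / "bundle")
        back = mio.read_bundle_dir(td / "bundle")
        bundle_ok = _bundles_equal(genomes, back)
        n_tree_ok = 0
        trees = list(truth.family_trees.values())[:50] + [truth.species_newick]
        for nwk in trees:
            t = SupportTree.from_newick(nwk)
            t.write(td / "t.nwk")
            t2 = SupportTree.read(td / "t.nwk")
            same_topo = t.bipartitions() == t2.bipartitions()
            d1, d2 = t.leaf_distance_matrix(), t2.leaf_distance_matrix()
            same_len = all(abs(d1[k] - d2[k]) <= 1e-9 for k in d1)
            n_tree_ok += same_topo and same_len
        return {"bundle_roundtrip": float(bundle_ok),
                "tree_roundtrips": n_tree_ok / len(trees),
                "n_trees": len(trees)}


def _bundles_equal(a, b) -> bool:
    if len(a) != len(b):
        return False
    for ga, gb in zip(sorted(a, key=lambda g: g.genome_id),
                      sorted(b, key=lambda g: g.genome_id)):
        if (ga.genome_id != gb.genome_id or ga.phenotype != gb.phenotype
                or ga.ecology != gb.ecology):
            return False
        ka = sorted((g.scaffold_id, g.order_index, g.gene_id, g.protein_seq,
                     g.function_label) for g in ga.genes)
        kb = sorted((g.scaffold_id, g.order_index, g.gene_id, g.protein_seq,
                     g.function_label) for g in gb.genes)
        if ka != kb:
            return False
    return True
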