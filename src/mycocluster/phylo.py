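"""Tree building and tree statistics.

Distance-based inference stands in for full ML tree search: Poisson-corrected
p-distances feed Saitou-Nei neighbor joining, bootstrap supports come from
column resampling, and the species tree is the greedy (extended
majority-rule) consensus of single-copy-family bootstrap trees. Site
log-likelihoods under the package's fixed empirical amino-acid model are
computed exactly by Felsenstein pruning, and competing topologies are
compared with a one-sided RELL bootstrap of per-site log-likelihoods.

Alignments are ordered ``{label: sequence}`` mappings of equal-length
sequences; ``-`` (or ``X``) positions are treated as missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from . import seqmodel
from .core import Parameters, SupportTree
from .simulate import substream

Alignment = Mapping[str, str]

_GAP_CHARS = {"-", ".", "X", "?"}

#: p-distances are capped here before the -ln(1-p) correction (saturation)
MAX_P_DISTANCE = 0.95


def _check_alignment(alignment: Alignment) -> int:
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop()


def pad_alignment(seqs: Mapping[str, str]) -> dict[str, str]:
    """Pad unequal-length sequences with trailing gaps (missing data)."""
    width = max(len(s) for s in seqs.values())
    return {k: s + "-" * (width - len(s)) for k, s in seqs.items()}


def trim_columns(alignment: Alignment, max_gap_fraction: float = 0.5
                 ) -> dict[str, str]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``."""
    ncol = _check_alignment(alignment)
    labels = list(alignment)
    keep = []
    for j in range(ncol):
        gaps = sum(alignment[l][j] in _GAP_CHARS for l in labels)
        if gaps / len(labels) <= max_gap_fraction:
            keep.append(j)
    return {l: "".join(alignment[l][j] for j in keep) for l in labels}


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, nonnegative, "
                             "zero-diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def poisson_distance(alignment: Alignment) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared non-gap
    columns; p is capped at 0.95 before correction."""
    _check_alignment(alignment)
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    n = len(labels)
    values = np.zeros((n, n))
    arrays = {l: np.array(list(alignment[l])) for l in labels}
    gap = {l: np.isin(arrays[l], list(_GAP_CHARS)) for l in labels}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            shared = ~(gap[a] | gap[b])
            if not shared.any():
                raise ValueError(
                    f"no shared non-gap columns between {a} and {b}")
            p = float(np.mean(arrays[a][shared] != arrays[b][shared]))
            p = min(p, MAX_P_DISTANCE)
            values[i, j] = values[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root node).

    Ties in the Q criterion are broken on the lexicographically smallest
    (label, label) pair, so output is deterministic. Negative branch length
    estimates are clamped to zero.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    ns = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=label)
        ns.add_taxon(node.taxon)
        nodes[label] = node

    labels = sorted(dm.labels)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            dist[(a, b)] = float(dm.values[i, j])

    joined = 0
    while len(labels) > 3:
        n = len(labels)
        r = {a: sum(dist[(a, b)] for b in labels if b != a) for a in labels}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = labels[i], labels[j]
                q = (n - 2) * dist[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        d_ab = dist[(a, b)]
        la = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d_ab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_label = f"\x00join{joined}"
        joined += 1
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        nodes[new_label] = parent
        for c in labels:
            if c in (a, b):
                continue
            dist[(new_label, c)] = dist[(c, new_label)] = max(
                (dist[(a, c)] + dist[(b, c)] - d_ab) / 2.0, 0.0)
        labels = sorted(set(labels) - {a, b} | {new_label})

    # join the final three at an unrooted central node
    a, b, c = labels
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = (dist[(x, y)] + dist[(x, z)] - dist[(y, z)]) / 2.0
        root.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return SupportTree(tree)


def nj_tree_constrained(dm: DistanceMatrix, clade: Iterable[str]
                        ) -> SupportTree:
    """NJ with one leaf set constrained to be a clade.

    The constrained leaves are joined first (NJ among themselves, midpoint
    rooted), then treated as a single composite taxon whose distance to any
    other leaf is the mean over members; the composite leaf in the outer NJ
    tree is finally replaced by the subtree.
    """
    clade = sorted(set(clade))
    missing = set(clade) - set(dm.labels)
    if missing:
        raise ValueError(f"constraint labels not in matrix: {sorted(missing)}")
    rest = [l for l in dm.labels if l not in clade]
    if len(clade) < 2:
        return nj_tree(dm)
    if len(rest) < 2:
        raise ValueError("constraint covers nearly the whole leaf set")

    # subtree over the constrained leaves
    idx = [dm.labels.index(l) for l in clade]
    sub_dm = DistanceMatrix(labels=clade,
                            values=dm.values[np.ix_(idx, idx)])
    if len(clade) == 2:
        sub_root = dendropy.Node()
        half = sub_dm.values[0, 1] / 2.0
        taxa = []
        for l in clade:
            leaf = dendropy.Node()
            leaf.taxon = dendropy.Taxon(label=l)
            taxa.append(leaf.taxon)
            sub_root.add_child(leaf)
            leaf.edge.length = half
        sub_tree = dendropy.Tree()
        sub_tree.seed_node = sub_root
        for t in taxa:
            sub_tree.taxon_namespace.add_taxon(t)
    else:
        sub = nj_tree(sub_dm)
        sub.tree.reroot_at_midpoint()
        sub_tree = sub.tree
    sub_tree.is_rooted = True

    composite = "\x00clade"
    outer_labels = rest + [composite]
    n_out = len(outer_labels)
    outer = np.zeros((n_out, n_out))
    ridx = [dm.labels.index(l) for l in rest]
    for i, a in enumerate(rest):
        for j, b in enumerate(rest):
            outer[i, j] = dm.values[ridx[i], ridx[j]]
    for i, a in enumerate(rest):
        mean_d = float(np.mean([dm.get(a, m) for m in clade]))
        outer[i, -1] = outer[-1, i] = mean_d
    outer_tree = nj_tree(DistanceMatrix(labels=outer_labels, values=outer))

    # replace the composite leaf with the subtree
    target = outer_tree.leaf(composite)
    edge_len = target.edge.length or 0.0
    parent = target.parent_node
    parent.remove_child(target)
    graft = sub_tree.seed_node
    parent.add_child(graft)
    graft.edge.length = edge_len
    for taxon in sub_tree.taxon_namespace:
        outer_tree.tree.taxon_namespace.add_taxon(taxon)
    outer_tree.tree.taxon_namespace.remove_taxon(target.taxon)
    outer_tree.tree.is_rooted = False
    return SupportTree.from_newick(outer_tree.as_newick())


def fit_branch_lengths_ols(tree: SupportTree, dm: DistanceMatrix
                           ) -> SupportTree:
    """Refit all branch lengths of a fixed topology to a distance matrix by
    nonnegative least squares over the path-edge incidence system.

    Used so that two competing topologies carry lengths estimated from the
    same data before their likelihoods are compared.
    """
    from scipy.optimize import nnls

    work = tree.copy()
    leaves = {lf.taxon.label: lf for lf in work.tree.leaf_node_iter()}
    missing = set(dm.labels) - set(leaves)
    if missing:
        raise ValueError(f"distance labels not in tree: {sorted(missing)}")
    edges = [e for e in work.tree.preorder_edge_iter()
             if e.head_node.parent_node is not None]
    eindex = {id(e): i for i, e in enumerate(edges)}

    def root_path(node):
        out = []
        while node.parent_node is not None:
            out.append(id(node.edge))
            node = node.parent_node
        return set(out)

    paths = {label: root_path(node) for label, node in leaves.items()}
    rows, d = [], []
    labels = dm.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            onpath = paths[labels[i]] ^ paths[labels[j]]
            row = np.zeros(len(edges))
            for eid in onpath:
                row[eindex[eid]] = 1.0
            rows.append(row)
            d.append(dm.values[i, j])
    lengths, _ = nnls(np.array(rows), np.array(d))
    for e, ln in zip(edges, lengths):
        e.length = float(ln)
    return work


# ---------------------------------------------------------------------------
# bootstrap

def _resample_columns(alignment: Alignment, rng: np.random.Generator
                      ) -> dict[str, str]:
    ncol = _check_alignment(alignment)
    idx = rng.integers(0, ncol, size=ncol)
    return {l: "".join(s[j] for j in idx) for l, s in alignment.items()}


def bootstrap_tree(alignment: Alignment, n: int, seed: int) -> SupportTree:
    """NJ tree from the full alignment with bootstrap supports mapped onto
    its internal edges (percent of ``n`` column-resampled replicates
    containing each bipartition)."""
    if n <= 0:
        raise ValueError("number of bootstrap replicates must be positive")
    point = nj_tree(poisson_distance(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    rng = substream(seed, "bootstrap")
    for _ in range(n):
        rep = _resample_columns(alignment, rng)
        try:
            rep_tree = nj_tree(poisson_distance(rep))
        except ValueError:
            continue  # resampled columns may erase all shared signal
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    labels = sorted(point.leaf_labels())
    anchor = labels[0]
    full = frozenset(labels)
    for node in point.tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            node.label = str(int(round(100.0 * counts[side] / n)))
    return point


def mean_internal_support(tree: SupportTree) -> float:
    sups = [s for s in tree.supports().values()]
    return float(np.mean(sups)) if sups else 0.0


# ---------------------------------------------------------------------------
# rooting

def root_at_most_distant(tree: SupportTree, query_leaf: str) -> SupportTree:
    """Root on the terminal edge of the leaf farthest (by path length) from
    the query; ties break to the lexicographically smaller label."""
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    work = tree.copy()
    support_map = _support_by_split(work)
    pdm = work.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in work.tree.taxon_namespace}
    if query_leaf not in taxa:
        raise KeyError(f"query leaf {query_leaf} not in tree")
    qt = taxa[query_leaf]
    best = None
    for label, taxon in taxa.items():
        if label == query_leaf:
            continue
        d = pdm.distance(qt, taxon)
        key = (-d, label)
        if best is None or key < best:
            best = key
    outgroup = work.leaf(best[1])
    edge_len = outgroup.edge.length or 0.0
    work.tree.reroot_at_edge(outgroup.edge,
                             length1=edge_len / 2.0, length2=edge_len / 2.0,
                             update_bipartitions=False)
    work.tree.is_rooted = True
    _reassign_supports(work, support_map)
    return work


def _support_by_split(tree: SupportTree) -> dict[frozenset, int]:
    out = {}
    for node, sup in tree.supports().items():
        labels = sorted(tree.leaf_labels())
        anchor = labels[0]
        full = frozenset(labels)
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = full - side
        out[side] = sup
    return out


def _reassign_supports(tree: SupportTree, support_map: dict[frozenset, int]
                       ) -> None:
    labels = sorted(tree.leaf_labels())
    anchor = labels[0]
    full = frozenset(labels)
    for node in tree.tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = full - side
        node.label = (str(support_map[side]) if side in support_map else None)


# ---------------------------------------------------------------------------
# species tree

def _consensus_tree(trees: Sequence[SupportTree]) -> SupportTree:
    """Greedy (extended majority-rule) consensus: majority bipartitions
    first, then remaining bipartitions by frequency if compatible."""
    if not trees:
        raise ValueError("no input trees")
    labels = sorted(trees[0].leaf_labels())
    full = frozenset(labels)
    counts: dict[frozenset, int] = {}
    for t in trees:
        if sorted(t.leaf_labels()) != labels:
            raise ValueError("consensus input trees disagree on leaf set")
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    def compatible(c: frozenset, accepted: list[frozenset]) -> bool:
        return all(c <= o or o <= c or not (c & o) for o in accepted)

    order = sorted(counts.items(),
                   key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))))
    accepted: list[tuple[frozenset, int]] = []
    for cset, cnt in order:
        if compatible(cset, [a for a, _ in accepted]):
            accepted.append((cset, cnt))

    # build the rooted-at-anchor tree from the laminar clade family
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: dict[frozenset, dendropy.Node] = {full: tree.seed_node}
    n_trees = len(trees)
    for cset, cnt in sorted(accepted, key=lambda kv: -len(kv[0])):
        parent = min((s for s in nodes if cset < s), key=len)
        node = dendropy.Node()
        node.label = str(int(round(100.0 * cnt / n_trees)))
        nodes[parent].add_child(node)
        nodes[cset] = node
    for label in labels:
        parent = min((s for s in nodes if label in s), key=len)
        leaf = dendropy.Node()
        leaf.taxon = dendropy.Taxon(label=label)
        ns.add_taxon(leaf.taxon)
        nodes[parent].add_child(leaf)
    tree.is_rooted = False
    return SupportTree(tree)


@dataclass
class SpeciesTreeResult:
    tree: SupportTree
    n_gene_trees: int
    quota_met: bool
    groups_used: list[str] = field(default_factory=list)


def build_species_tree(genomes, groups, params: Optional[Parameters] = None,
                       seed: int = 0, quota: int = 100) -> SpeciesTreeResult:
    """Species tree from single-copy homolog groups.

    Randomly ordered 1:1 groups (exactly one member in every genome) are
    turned into bootstrap NJ trees; trees whose mean internal support
    exceeds ``params.support_threshold`` accumulate until ``quota`` is met,
    and their greedy majority-rule consensus is returned. If the quota is
    unreachable the consensus of whatever passed is returned, flagged.
    """
    params = params or Parameters()
    genome_ids = sorted(g.genome_id for g in genomes)
    by_id = {g.genome_id: g for g in genomes}
    single_copy = [grp for grp in groups
                   if sorted(grp.genomes) == genome_ids
                   and all(c == 1 for c in grp.presence.values())]
    order_rng = substream(seed, "species_tree_sampling")
    single_copy = sorted(single_copy, key=lambda g: g.group_id)
    order_rng.shuffle(single_copy)

    kept: list[SupportTree] = []
    used: list[str] = []
    for grp in single_copy:
        if len(kept) >= quota:
            break
        seqs = {}
        for genome_id, gene_id in sorted(grp.members):
            seqs[genome_id] = by_id[genome_id].gene(gene_id).protein_seq
        alignment = pad_alignment(seqs)
        gtree = bootstrap_tree(alignment, params.n_bootstraps,
                               seed=seed + len(kept) + 1)
        if mean_internal_support(gtree) > params.support_threshold:
            kept.append(gtree)
            used.append(grp.group_id)
    if not kept:
        raise ValueError("no gene tree passed the support threshold")
    consensus = _consensus_tree(kept)
    return SpeciesTreeResult(tree=consensus, n_gene_trees=len(kept),
                             quota_met=len(kept) >= quota, groups_used=used)


# ---------------------------------------------------------------------------
# likelihoods

def site_loglik(tree: SupportTree, alignment: Alignment) -> np.ndarray:
    """Per-site log-likelihood by Felsenstein pruning under the package's
    fixed empirical model. Gaps are missing data. Requires branch lengths."""
    ncol = _check_alignment(alignment)
    leaf_labels = set(tree.leaf_labels())
    missing = leaf_labels - set(alignment)
    if missing:
        raise ValueError(f"no sequence for leaves {sorted(missing)}")

    pi = seqmodel.stationary_frequencies()
    partials: dict[int, np.ndarray] = {}
    scale = np.zeros(ncol)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            states = seqmodel.encode(alignment[node.taxon.label])
            part = np.ones((ncol, seqmodel.N_STATES))
            known = states >= 0
            part[known] = 0.0
            part[known, states[known]] = 1.0
        else:
            part = np.ones((ncol, seqmodel.N_STATES))
            for child in node.child_nodes():
                t = child.edge.length
                if t is None:
                    raise ValueError("tree has missing branch lengths")
                P = seqmodel.transition_matrix(t)
                part = part * (partials[id(child)] @ P.T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            part = part / mx[:, None]
            scale += np.log(mx)
        partials[id(node)] = part
    root = partials[id(tree.tree.seed_node)]
    return np.log(root @ pi) + scale


@dataclass
class RellResult:
    p_value: float
    delta_ll: float
    reject: bool
    n_resamples: int
    warning: bool = False


def rell_test(alignment: Alignment, tree_optimal: SupportTree,
              tree_constrained: SupportTree, n_resamples: int = 1000,
              seed: int = 0, alpha: float = 0.05) -> RellResult:
    """One-sided RELL bootstrap comparison of two topologies.

    Per-site log-likelihood vectors for both trees are resampled (sites with
    replacement); the p-value is the fraction of resamples in which the
    constrained tree's total log-likelihood is at least the optimal tree's.
    The constrained topology is rejected when p < alpha.
    """
    if set(tree_optimal.leaf_labels()) != set(tree_constrained.leaf_labels()):
        raise ValueError("trees must share one leaf set")
    warning = n_resamples < 100
    ll_opt = site_loglik(tree_optimal, alignment)
    ll_con = site_loglik(tree_constrained, alignment)
    delta = ll_opt - ll_con
    rng = substream(seed, "rell")
    ncol = len(delta)
    wins = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, ncol, size=ncol)
        if delta[idx].sum() <= 0:
            wins += 1
    p = wins / n_resamples
    return RellResult(p_value=p, delta_ll=float(delta.sum()),
                      reject=p < alpha, n_resamples=n_resamples,
                      warning=warning)


# ---------------------------------------------------------------------------
# clade reduction

def reduce_to_supported_clade(tree: SupportTree, query_leaves: Sequence[str],
                              params: Optional[Parameters] = None
                              ) -> tuple[list[str], bool]:
    """Largest clade containing all queries with support >= threshold and at
    most ``max_clade_leaves`` leaves.

    The whole tree qualifies whenever it fits the size bound. Returns
    ``(leaf subset, qualified)``; if no clade qualifies the smallest clade
    containing the queries is returned with ``qualified=False``.
    """
    params = params or Parameters()
    queries = set(query_leaves)
    missing = queries - set(tree.leaf_labels())
    if missing:
        raise ValueError(f"query leaves not in tree: {sorted(missing)}")
    all_leaves = sorted(tree.leaf_labels())
    if len(all_leaves) <= params.max_clade_leaves:
        return all_leaves, True

    best: Optional[list[str]] = None
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if not queries <= set(leaves):
            continue
        sup = SupportTree.node_support(node)
        if sup is None or sup < params.support_threshold:
            continue
        if len(leaves) > params.max_clade_leaves:
            continue
        if best is None or len(leaves) > len(best):
            best = leaves
    if best is not None:
        return best, True

    # fall back: smallest containing clade
    smallest = all_leaves
    for node in tree.tree.preorder_internal_node_iter():
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if queries <= set(leaves) and len(leaves) < len(smallest):
            smallest = leaves
    return smallest, False
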