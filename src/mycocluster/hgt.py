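"""Genome-wide screen for horizontally transferred genes.

Three filtering stages plus a constrained-topology test, mirroring a
donor-targeted HGT search:

1. *Best hit*: keep recipient queries whose best-scoring database hit
   (self and same-genome hits excluded) comes from a donor taxon.
2. *Preliminary topology*: on a quick unrooted NJ tree rooted at the leaf
   most distant from the query, keep queries that share an immediate common
   ancestor with a donor sequence and are separated from any background
   taxon by at least ``min_separating_nodes`` internal nodes.
3. *Supported nesting*: on a bootstrap tree, keep queries nested inside a
   clade of surrounding-group sequences through more than two internal
   nodes, each with support above the threshold.
4. *Vertical-inheritance constraint*: reject the constrained topology that
   forces the query back into its own lineage when its log-likelihood is
   significantly worse (one-sided RELL, p < alpha) than the optimal tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy

from .core import (GenomeRecord, Parameters, SupportTree, leaf_label,
                   split_leaf_label)
from .homology import SimilarityEdge, pairwise_similarity
from .phylo import (RellResult, bootstrap_tree, fit_branch_lengths_ols,
                    nj_tree, nj_tree_constrained, pad_alignment,
                    poisson_distance, reduce_to_supported_clade, rell_test,
                    root_at_most_distant)

STAGES = ("best_hit", "prefilter", "supported", "constraint_rejected_vertical")


@dataclass
class HGTCandidate:
    query: tuple[str, str]
    donor_taxa: frozenset[str]
    stage_passed: str
    p_value: Optional[float] = None
    preliminary_tree: Optional[SupportTree] = None
    final_tree: Optional[SupportTree] = None

    def stage_index(self) -> int:
        return STAGES.index(self.stage_passed)


# ---------------------------------------------------------------------------
# stage 1

def best_hit_filter(query_keys: Sequence[tuple[str, str]],
                    edges: Sequence[SimilarityEdge],
                    donor_taxa: Iterable[str]
                    ) -> tuple[list[tuple[str, str]], dict]:
    """Retain queries whose top-scoring non-self, non-same-genome hit is in
    a donor taxon. Ties break to higher raw score then lexicographic hit id.

    Returns (retained query keys, counts report). Queries with no eligible
    hits are dropped silently but counted.
    """
    donor_taxa = set(donor_taxa)
    hits_of: dict[tuple[str, str], list[SimilarityEdge]] = {}
    for e in edges:
        if e.hit == e.query or e.hit[0] == e.query[0]:
            continue  # self or same-genome paralog: excluded from ranking
        hits_of.setdefault(e.query, []).append(e)

    retained = []
    n_no_hits = 0
    for q in query_keys:
        hits = hits_of.get(q)
        if not hits:
            n_no_hits += 1
            continue
        best = min(hits, key=lambda e: (-e.raw_score, e.hit))
        if best.hit[0] in donor_taxa:
            retained.append(q)
    report = {"queries": len(query_keys), "no_hits": n_no_hits,
              "best_hit": len(retained)}
    return retained, report


# ---------------------------------------------------------------------------
# stage 2

def _query_node(tree: SupportTree, query_leaf: str) -> dendropy.Node:
    try:
        return tree.leaf(query_leaf)
    except KeyError:
        raise ValueError(f"query {query_leaf} absent from tree")


def _genome_of_leaf(label: str) -> str:
    return split_leaf_label(label)[0]


def topology_prefilter(tree: SupportTree, query_leaf: str,
                       donor_taxa: Iterable[str],
                       background_taxa: Iterable[str],
                       params: Optional[Parameters] = None,
                       mode: str = "path") -> bool:
    """Preliminary-tree filter on a rooted tree.

    True iff (a) the query's parent clade contains a donor-taxon leaf, and
    (b) at least ``min_separating_nodes`` consecutive rootward ancestors of
    the query add no background-taxon leaf before the first one that does.
    ``mode='distance'`` instead counts internal nodes on the path from the
    query to its nearest background leaf.
    """
    params = params or Parameters()
    donor_taxa = set(donor_taxa)
    background_taxa = set(background_taxa)
    node = _query_node(tree, query_leaf)

    parent = node.parent_node
    if parent is None:
        return False
    sibling_leaves = {lf.taxon.label for lf in parent.leaf_iter()} - {query_leaf}
    if not any(_genome_of_leaf(l) in donor_taxa for l in sibling_leaves):
        return False

    if mode == "distance":
        best = None
        for leaf in tree.tree.leaf_node_iter():
            if _genome_of_leaf(leaf.taxon.label) not in background_taxa:
                continue
            # internal nodes strictly between query and this leaf
            n_between = _path_internal_nodes(node, leaf)
            best = n_between if best is None else min(best, n_between)
        return best is None or best >= params.min_separating_nodes

    # 'path' mode: consecutive ancestors adding no background leaf
    n_sep = 0
    seen = {query_leaf}
    current = parent
    while current is not None:
        added = {lf.taxon.label for lf in current.leaf_iter()} - seen
        if any(_genome_of_leaf(l) in background_taxa for l in added):
            break
        n_sep += 1
        seen |= added
        current = current.parent_node
    return n_sep >= params.min_separating_nodes


def _path_internal_nodes(a: dendropy.Node, b: dendropy.Node) -> int:
    ancestors_a = []
    x = a
    while x is not None:
        ancestors_a.append(x)
        x = x.parent_node
    seen = {id(n): i for i, n in enumerate(ancestors_a)}
    path_b = 0
    x = b
    while id(x) not in seen:
        path_b += 1
        x = x.parent_node
    mrca_idx = seen[id(x)]
    # internal nodes strictly between the two leaves
    return (mrca_idx - 1) + (path_b - 1) + 1


# ---------------------------------------------------------------------------
# stage 3

def supported_nesting_filter(tree: SupportTree, query_leaf: str,
                             donor_taxa: Iterable[str],
                             surrounding_taxa: Iterable[str],
                             params: Optional[Parameters] = None) -> bool:
    """Bootstrap-tree filter: the query shares an immediate ancestor with a
    donor sequence and sits inside a chain of more than two internal nodes,
    each supported above the threshold, whose subtrees contain only
    surrounding-group leaves (besides the query)."""
    params = params or Parameters()
    donor_taxa = set(donor_taxa)
    surrounding = set(surrounding_taxa)
    node = _query_node(tree, query_leaf)
    if not tree.supports():
        raise ValueError("tree carries no bootstrap supports")

    parent = node.parent_node
    if parent is None:
        return False
    sibling_leaves = {lf.taxon.label for lf in parent.leaf_iter()} - {query_leaf}
    if not any(_genome_of_leaf(l) in donor_taxa for l in sibling_leaves):
        return False

    n_supported = 0
    current = parent
    while current is not None and current.parent_node is not None:
        leaves = {lf.taxon.label for lf in current.leaf_iter()} - {query_leaf}
        if not all(_genome_of_leaf(l) in surrounding for l in leaves):
            break
        sup = SupportTree.node_support(current)
        if sup is not None and sup > params.support_threshold:
            n_supported += 1
        current = current.parent_node
    return n_supported > 2


# ---------------------------------------------------------------------------
# stage 4

def vertical_constraint_test(alignment, optimal_tree: SupportTree,
                             recipient_lineage_taxa: Iterable[str],
                             params: Optional[Parameters] = None,
                             seed: int = 0) -> RellResult:
    """Test the vertical-inheritance hypothesis for a query gene.

    The constrained topology forces all leaves from the recipient's own
    lineage into one clade (constrained NJ on the alignment distances); the
    constraint is rejected when its likelihood is significantly worse than
    the optimal tree's under the one-sided RELL bootstrap.
    """
    params = params or Parameters()
    lineage = set(recipient_lineage_taxa)
    clade_leaves = [l for l in optimal_tree.leaf_labels()
                    if _genome_of_leaf(l) in lineage]
    if len(clade_leaves) < 2:
        raise ValueError(
            "vertical constraint needs the query plus at least one "
            "own-lineage relative in the tree")
    dm = poisson_distance(alignment)
    constrained = nj_tree_constrained(dm, clade_leaves)
    # both topologies get branch lengths fitted to the same distances, so
    # the comparison is not biased by how each tree was built
    optimal = fit_branch_lengths_ols(optimal_tree, dm)
    constrained = fit_branch_lengths_ols(constrained, dm)
    return rell_test(alignment, optimal, constrained,
                     seed=seed, alpha=params.alpha)


# ---------------------------------------------------------------------------
# full screen

@dataclass
class ScreenReport:
    counts: dict = field(default_factory=dict)
    candidates: list[HGTCandidate] = field(default_factory=list)

    def final_candidates(self) -> list[HGTCandidate]:
        return [c for c in self.candidates
                if c.stage_passed == "constraint_rejected_vertical"]


def screen_genome(recipient: GenomeRecord,
                  database: Sequence[GenomeRecord],
                  donor_taxa: Iterable[str],
                  recipient_lineage_taxa: Iterable[str],
                  background_taxa: Optional[Iterable[str]] = None,
                  surrounding_taxa: Optional[Iterable[str]] = None,
                  params: Optional[Parameters] = None,
                  seed: int = 0,
                  edges: Optional[Sequence[SimilarityEdge]] = None
                  ) -> ScreenReport:
    """Run the full HGT screen for every gene of the recipient genome.

    ``donor_taxa`` selects the lineage transfers are sought from;
    ``background_taxa`` (default: every non-donor, non-recipient genome)
    feeds the separation rule; ``surrounding_taxa`` (default: the donor
    taxa) defines the clade the query must be nested in at stage 3.
    """
    params = params or Parameters()
    donor_taxa = frozenset(donor_taxa)
    lineage = frozenset(recipient_lineage_taxa)
    all_ids = {g.genome_id for g in database} | {recipient.genome_id}
    background = (frozenset(background_taxa) if background_taxa is not None
                  else frozenset(all_ids - donor_taxa - {recipient.genome_id}))
    surrounding = (frozenset(surrounding_taxa) if surrounding_taxa is not None
                   else donor_taxa)

    report = ScreenReport()
    if not recipient.genes:
        report.counts = {"queries": 0, "no_hits": 0, "best_hit": 0,
                         "prefilter": 0, "supported": 0,
                         "constraint_rejected_vertical": 0}
        return report

    db_genes = [g for genome in database for g in genome.genes
                if genome.genome_id != recipient.genome_id]
    pool = db_genes + list(recipient.genes)
    if edges is None:
        edges = pairwise_similarity(pool, params, queries=list(recipient.genes))

    query_keys = [g.key for g in recipient.genes]
    retained, counts = best_hit_filter(query_keys, edges, donor_taxa)
    counts.update({"prefilter": 0, "supported": 0,
                   "constraint_rejected_vertical": 0})

    seqs_by_key = {g.key: g.protein_seq for g in pool}
    genes_by_key = {g.key: g for g in pool}
    hits_of: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for e in edges:
        if e.evalue <= params.evalue_homology:
            hits_of.setdefault(e.query, set()).add(e.hit)
    best_of: dict[tuple[str, str], tuple[str, str]] = {}
    for e in edges:
        if e.hit[0] == e.query[0]:
            continue
        cur = best_of.get(e.query)
        if cur is None or (e.raw_score, e.hit) > (cur[0], cur[1]):
            best_of[e.query] = (e.raw_score, e.hit)

    for q in retained:
        cand = HGTCandidate(query=q, donor_taxa=donor_taxa,
                            stage_passed="best_hit")
        report.candidates.append(cand)
        members = set(hits_of.get(q, set())) | {q}
        # a distant transfer's query may fail to retrieve its own-lineage
        # relatives directly; hits of its (vertically inherited) best hit
        # complete the family
        best = best_of.get(q)
        if best is not None:
            hub_edges = pairwise_similarity(
                pool, params, queries=[genes_by_key[best[1]]])
            members |= {e.hit for e in hub_edges
                        if e.evalue <= params.evalue_homology}
            members.discard(best[1])
            members.add(best[1])
        members = sorted(members)
        if len(members) < 4:
            continue
        q_label = leaf_label(*q)
        seqs = {leaf_label(*m): seqs_by_key[m] for m in members}
        alignment = pad_alignment(seqs)

        # stage 2: preliminary tree
        prelim = nj_tree(poisson_distance(alignment))
        rooted = root_at_most_distant(prelim, q_label)
        cand.preliminary_tree = rooted
        if not topology_prefilter(rooted, q_label, donor_taxa, background,
                                  params):
            continue
        cand.stage_passed = "prefilter"
        counts["prefilter"] += 1

        # stage 3: bootstrap tree (reduced when oversized)
        btree = bootstrap_tree(alignment, params.n_bootstraps,
                               seed=seed + 17)
        brooted = root_at_most_distant(btree, q_label)
        if len(alignment) > params.max_clade_leaves:
            keep, _ = reduce_to_supported_clade(brooted, [q_label], params)
            alignment = {l: alignment[l] for l in keep}
            btree = bootstrap_tree(alignment, params.n_bootstraps,
                                   seed=seed + 17)
            brooted = root_at_most_distant(btree, q_label)
        cand.final_tree = brooted
        if not supported_nesting_filter(brooted, q_label, donor_taxa,
                                        surrounding, params):
            continue
        cand.stage_passed = "supported"
        counts["supported"] += 1

        # stage 4: constrained-topology test
        unrooted = nj_tree(poisson_distance(alignment))
        try:
            result = vertical_constraint_test(
                alignment, unrooted, lineage | {recipient.genome_id},
                params, seed=seed)
        except ValueError:
            continue
        cand.p_value = result.p_value
        if result.reject:
            cand.stage_passed = "constraint_rejected_vertical"
            counts["constraint_rejected_vertical"] += 1

    report.counts = counts
    return report
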