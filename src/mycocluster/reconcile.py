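"""Gene-tree / species-tree reconciliation under event parsimony.

Two models are provided: DL (duplication-loss, the classical LCA mapping,
provably minimal) and DTL (duplication-transfer-loss, a dynamic program
over gene-node x species-node placements). Default event costs are
duplication 1.5, transfer 3.0, loss 1.0; under DL only the first and last
apply. Transfers may land on any species node that is not an ancestor of
the donor position (the standard undated-parsimony relaxation: global time
consistency of transfers is not enforced). Gene-tree edges with bootstrap
support below the edge-weight threshold are collapsed first and the
resulting polytomies re-resolved to follow the species tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy

from .core import Parameters, SupportTree, split_leaf_label

INF = math.inf


@dataclass
class ReconciliationSummary:
    model: str  # 'DL' | 'DTL'
    n_dup: int
    n_transfer: int
    n_loss: int
    total_cost: float
    mapping: dict = field(default_factory=dict)  # gene clade -> species node

    def validate(self) -> None:
        if self.model == "DL" and self.n_transfer:
            raise ValueError("DL reconciliation cannot contain transfers")
        if min(self.n_dup, self.n_transfer, self.n_loss) < 0:
            raise ValueError("negative event counts")


def _species_of(leaf_label_: str, leaf_map: Optional[dict]) -> str:
    if leaf_map is not None:
        return leaf_map[leaf_label_]
    return split_leaf_label(leaf_label_)[0]


def _check_binary_rooted(tree: SupportTree, name: str) -> None:
    for node in tree.tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError(f"{name} tree must be rooted and binary")


def _label_species_nodes(species: SupportTree) -> None:
    i = 0
    for node in species.tree.preorder_internal_node_iter():
        if not node.label:
            i += 1
            node.label = f"S{i}"


def _node_key(node: dendropy.Node) -> str:
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


# ---------------------------------------------------------------------------
# gene-tree preprocessing

def collapse_weak_edges(gene_tree: SupportTree, threshold: float
                        ) -> SupportTree:
    """Collapse internal gene-tree edges whose support is below the
    threshold (on the 0-100 scale); unsupported edges are kept."""
    work = gene_tree.copy()
    to_collapse = []
    for node in work.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        sup = SupportTree.node_support(node)
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return work


def resolve_polytomies_with_species(gene_tree: SupportTree,
                                    species: SupportTree,
                                    leaf_map: Optional[dict] = None
                                    ) -> SupportTree:
    """Binarize polytomies by repeatedly joining the two children whose
    species LCA is deepest (follows the species tree, greedily minimizing
    implied duplications and losses); ties break lexicographically."""
    work = gene_tree.copy()
    species = species.copy()
    _label_species_nodes(species)
    depth: dict[str, int] = {}
    snodes: dict[str, dendropy.Node] = {}
    for node in species.tree.preorder_node_iter():
        key = node.taxon.label if node.is_leaf() else node.label
        snodes[key] = node
        depth[key] = 0 if node.parent_node is None else \
            depth[_species_node_key(node.parent_node)] + 1

    def gene_species(node: dendropy.Node) -> dendropy.Node:
        labels = {_species_of(lf.taxon.label, leaf_map)
                  for lf in node.leaf_iter()}
        return _species_mrca(species, labels)

    for node in list(work.tree.preorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            children = sorted(node.child_nodes(), key=_node_key)
            best = None
            for i in range(len(children)):
                for j in range(i + 1, len(children)):
                    lca = _species_mrca(
                        species,
                        {_species_of(lf.taxon.label, leaf_map)
                         for lf in children[i].leaf_iter()} |
                        {_species_of(lf.taxon.label, leaf_map)
                         for lf in children[j].leaf_iter()})
                    d = depth[_species_node_key(lca)]
                    key = (-d, _node_key(children[i]), _node_key(children[j]))
                    if best is None or key < best[0]:
                        best = (key, children[i], children[j])
            _, ci, cj = best
            node.remove_child(ci)
            node.remove_child(cj)
            joint = node.new_child(edge_length=0.0)
            joint.add_child(ci)
            joint.add_child(cj)
    return work


def _species_node_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _species_mrca(species: SupportTree, labels: set[str]) -> dendropy.Node:
    nodes = [species.leaf(l) for l in labels]
    if len(nodes) == 1:
        return nodes[0]
    ancestors = []
    x = nodes[0]
    while x is not None:
        ancestors.append(x)
        x = x.parent_node
    order = {id(n): i for i, n in enumerate(ancestors)}
    best = 0
    for n in nodes[1:]:
        x = n
        while id(x) not in order:
            x = x.parent_node
        best = max(best, order[id(x)])
    return ancestors[best]


# ---------------------------------------------------------------------------
# DL (LCA) reconciliation

def lca_reconcile_dl(gene_tree: SupportTree, species_tree: SupportTree,
                     params: Optional[Parameters] = None,
                     leaf_map: Optional[dict] = None
                     ) -> ReconciliationSummary:
    """Classical LCA-mapping duplication-loss reconciliation (minimal DL
    event count). Gene leaves map to species via the ``genome|gene`` label
    convention unless an explicit ``leaf_map`` is given."""
    params = params or Parameters()
    _check_binary_rooted(gene_tree, "gene")
    _check_binary_rooted(species_tree, "species")
    species = species_tree.copy()
    _label_species_nodes(species)
    sp_leaves = set(species.leaf_labels())
    for lf in gene_tree.tree.leaf_node_iter():
        sp = _species_of(lf.taxon.label, leaf_map)
        if sp not in sp_leaves:
            raise ValueError(f"gene leaf {lf.taxon.label} maps to unknown "
                             f"species {sp}")

    depth: dict[int, int] = {}
    for node in species.tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else \
            depth[id(node.parent_node)] + 1

    mapping: dict[int, dendropy.Node] = {}
    n_dup = 0
    n_loss = 0
    out_map: dict[str, str] = {}
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            mapping[id(node)] = species.leaf(
                _species_of(node.taxon.label, leaf_map))
        else:
            kids = node.child_nodes()
            labels = {_species_node_key(mapping[id(k)]) for k in kids}
            leaf_set = set()
            for k in kids:
                m = mapping[id(k)]
                leaf_set |= ({m.taxon.label} if m.is_leaf() else
                             {lf.taxon.label for lf in m.leaf_iter()})
            mapping[id(node)] = _species_mrca(species, leaf_set)
            # duplication iff the node maps to the same species node as
            # one of its children
            is_dup = any(mapping[id(k)] is mapping[id(node)] for k in kids)
            if is_dup:
                n_dup += 1
            for k in kids:
                d = depth[id(mapping[id(k)])] - depth[id(mapping[id(node)])]
                n_loss += d if is_dup else max(d - 1, 0)
        out_map[_node_key(node)] = _species_node_key(mapping[id(node)])

    cost = params.dup_cost * n_dup + params.loss_cost * n_loss
    summary = ReconciliationSummary(
        model="DL", n_dup=n_dup, n_transfer=0, n_loss=n_loss,
        total_cost=cost, mapping=out_map)
    summary.validate()
    return summary


def _is_ancestor(node: dendropy.Node, other: dendropy.Node) -> bool:
    x = other.parent_node
    while x is not None:
        if x is node:
            return True
        x = x.parent_node
    return False


# ---------------------------------------------------------------------------
# DTL reconciliation

#: deterministic preference among equal-cost events
_EVENT_PREF = {"speciation": 0, "loss": 1, "duplication": 2, "transfer": 3}


def dtl_reconcile(gene_tree: SupportTree, species_tree: SupportTree,
                  params: Optional[Parameters] = None,
                  leaf_map: Optional[dict] = None,
                  allow_transfers: bool = True) -> ReconciliationSummary:
    """Minimum-cost duplication-transfer-loss reconciliation.

    Dynamic program over (gene node, species node) placements. A transfer
    sends one child lineage to any species node that is not an ancestor of
    (nor equal to) the donor position; losses are charged along descent
    paths; transfers carry no path losses. With ``allow_transfers=False``
    (or an infinite transfer cost) the model degenerates to DL.
    """
    params = params or Parameters()
    _check_binary_rooted(gene_tree, "gene")
    _check_binary_rooted(species_tree, "species")
    species = species_tree.copy()
    _label_species_nodes(species)

    snodes = list(species.tree.preorder_node_iter())
    sindex = {id(n): i for i, n in enumerate(snodes)}
    skeys = [_species_node_key(n) for n in snodes]
    n_s = len(snodes)

    # ancestor/descendant tables
    parent = [sindex[id(n.parent_node)] if n.parent_node else -1
              for n in snodes]
    is_anc = [[False] * n_s for _ in range(n_s)]  # is_anc[a][b]: a ancestor of b
    for b in range(n_s):
        x = parent[b]
        while x != -1:
            is_anc[x][b] = True
            x = parent[x]
    children = [[sindex[id(c)] for c in n.child_nodes()] for n in snodes]
    dist_down = [[-1] * n_s for _ in range(n_s)]  # edges from a down to b
    for a in range(n_s):
        dist_down[a][a] = 0
        stack = [(a, 0)]
        while stack:
            x, d = stack.pop()
            for c in children[x]:
                dist_down[a][c] = d + 1
                stack.append((c, d + 1))

    gnodes = list(gene_tree.tree.postorder_node_iter())
    gindex = {id(n): i for i, n in enumerate(gnodes)}
    sp_leaf_index = {skeys[i]: i for i in range(n_s) if snodes[i].is_leaf()}

    t_cost = params.transfer_cost if allow_transfers else INF
    d_cost, l_cost = params.dup_cost, params.loss_cost

    # DP tables: cost[u][x]; choice[u][x] for backtracking
    cost = [[INF] * n_s for _ in gnodes]
    choice: list[list] = [[None] * n_s for _ in gnodes]

    def in_cost(u: int, x: int) -> tuple[float, int]:
        """min over y descendant-or-equal of x of cost[u][y] + losses."""
        best = (INF, -1)
        for y in range(n_s):
            if dist_down[x][y] < 0:
                continue
            c = cost[u][y] + l_cost * dist_down[x][y]
            if c < best[0] or (c == best[0] and best[1] >= 0
                               and skeys[y] < skeys[best[1]]):
                best = (c, y)
        return best

    def out_cost(u: int, x: int) -> tuple[float, int]:
        """min over y neither x nor an ancestor of x of cost[u][y]."""
        best = (INF, -1)
        for y in range(n_s):
            if y == x or is_anc[y][x]:
                continue
            c = cost[u][y]
            if c < best[0] or (c == best[0] and best[1] >= 0
                               and skeys[y] < skeys[best[1]]):
                best = (c, y)
        return best

    for u, gnode in enumerate(gnodes):
        if gnode.is_leaf():
            sp = _species_of(gnode.taxon.label, leaf_map)
            if sp not in sp_leaf_index:
                raise ValueError(f"gene leaf {gnode.taxon.label} maps to "
                                 f"unknown species {sp}")
            cost[u][sp_leaf_index[sp]] = 0.0
            choice[u][sp_leaf_index[sp]] = ("leaf",)
            continue
        v, w = (gindex[id(c)] for c in gnode.child_nodes())
        for x in range(n_s):
            options = []
            if children[x]:
                x1, x2 = children[x]
                for a, b in ((x1, x2), (x2, x1)):
                    cv, yv = in_cost(v, a)
                    cw, yw = in_cost(w, b)
                    options.append((cv + cw, _EVENT_PREF["speciation"],
                                    ("speciation", (v, yv, a), (w, yw, b))))
            cv_in, yv_in = in_cost(v, x)
            cw_in, yw_in = in_cost(w, x)
            options.append((d_cost + cv_in + cw_in, _EVENT_PREF["duplication"],
                            ("duplication", (v, yv_in, x), (w, yw_in, x))))
            if allow_transfers and t_cost < INF:
                cv_out, yv_out = out_cost(v, x)
                cw_out, yw_out = out_cost(w, x)
                options.append((t_cost + cw_in + cv_out,
                                _EVENT_PREF["transfer"],
                                ("transfer", (v, yv_out, None), (w, yw_in, x))))
                options.append((t_cost + cv_in + cw_out,
                                _EVENT_PREF["transfer"],
                                ("transfer", (w, yw_out, None), (v, yv_in, x))))
            best = min(options, key=lambda o: (o[0], o[1]))
            cost[u][x] = best[0]
            choice[u][x] = best[2]

    root = len(gnodes) - 1
    best_x = min(range(n_s), key=lambda x: (cost[root][x], skeys[x]))
    if cost[root][best_x] == INF:
        raise ValueError("no finite-cost reconciliation exists")

    # backtrack event counts
    n_dup = n_transfer = n_loss = 0
    mapping: dict[str, str] = {}
    stack = [(root, best_x)]
    while stack:
        u, x = stack.pop()
        mapping[_node_key(gnodes[u])] = skeys[x]
        ch = choice[u][x]
        if ch is None or ch[0] == "leaf":
            continue
        kind = ch[0]
        if kind == "duplication":
            n_dup += 1
        elif kind == "transfer":
            n_transfer += 1
        for (u2, y, from_x) in (ch[1], ch[2]):
            if from_x is not None:
                n_loss += dist_down[from_x][y]
            stack.append((u2, y))
        if kind == "speciation":
            # a lost copy along each child descent is already counted; no
            # extra charge, but descents below x's children start one edge in
            pass
    total = d_cost * n_dup + (params.transfer_cost * n_transfer
                              if n_transfer else 0.0) + l_cost * n_loss
    summary = ReconciliationSummary(
        model="DTL", n_dup=n_dup, n_transfer=n_transfer, n_loss=n_loss,
        total_cost=cost[root][best_x], mapping=mapping)
    if abs(total - summary.total_cost) > 1e-9:
        raise AssertionError("event counts inconsistent with DP cost")
    summary.validate()
    return summary


# ---------------------------------------------------------------------------
# model comparison

def compare_models(gene_tree: SupportTree, species_tree: SupportTree,
                   params: Optional[Parameters] = None,
                   leaf_map: Optional[dict] = None
                   ) -> tuple[ReconciliationSummary, ReconciliationSummary, str]:
    """Run DL and DTL; the cheaper model is preferred, ties go to DL."""
    params = params or Parameters()
    dl = lca_reconcile_dl(gene_tree, species_tree, params, leaf_map)
    dtl = dtl_reconcile(gene_tree, species_tree, params, leaf_map)
    preferred = "DL" if dl.total_cost <= dtl.total_cost else "DTL"
    return dl, dtl, preferred


def reconcile_with_support_collapse(gene_tree: SupportTree,
                                    species_tree: SupportTree,
                                    params: Optional[Parameters] = None,
                                    leaf_map: Optional[dict] = None
                                    ) -> tuple[ReconciliationSummary,
                                               ReconciliationSummary, str]:
    """Collapse weakly supported gene-tree edges, re-resolve polytomies to
    follow the species tree, then compare DL and DTL models."""
    params = params or Parameters()
    collapsed = collapse_weak_edges(gene_tree, params.edge_weight_threshold)
    resolved = resolve_polytomies_with_species(collapsed, species_tree,
                                               leaf_map)
    return compare_models(resolved, species_tree, params, leaf_map)
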