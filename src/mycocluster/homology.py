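"""Protein similarity graph and Markov clustering into homolog groups.

Candidate pairs passing a shared-k-mer prefilter are aligned with
Smith-Waterman (BLOSUM62, affine gaps 11/1); e-values come from the
Karlin-Altschul formula with fixed gapped-BLOSUM62 constants and a
database-size correction. "Amino-acid similarity" is the fraction of aligned
columns with a positive substitution score. The resulting graph (edge weight
-log10 e-value, reciprocal hits averaged) is partitioned by Markov
Clustering (MCL): alternate expansion (matrix squaring) and inflation
(entrywise power + column renormalization) until the flow stabilizes, then
read clusters off the attractor structure.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import GeneRecord, HomologGroup, Parameters, _AA_SET

# Karlin-Altschul constants for gapped BLOSUM62 (open 11, extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041
#: -log10(evalue) weight cap used for evalue == 0
MAX_EDGE_WEIGHT = 200.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_POSITIVE_PAIRS = {(a, b)
                   for a in _BLOSUM62.alphabet for b in _BLOSUM62.alphabet
                   if _BLOSUM62[a][b] > 0}


@dataclass
class SimilarityEdge:
    """A directed similarity hit between two genes."""
    query: tuple[str, str]
    hit: tuple[str, str]
    raw_score: float
    evalue: float
    similarity: float  # fraction of aligned columns with positive BLOSUM62 score

    def validate(self) -> None:
        if self.query == self.hit:
            raise ValueError("self-edges are not allowed")
        if self.evalue < 0 or not 0 <= self.similarity <= 1:
            raise ValueError("invalid edge statistics")


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = _BLOSUM62
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def smith_waterman(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Local alignment of two proteins.

    Returns ``(score, similarity)`` where similarity is the fraction of
    aligned (ungapped) columns whose BLOSUM62 score is positive.
    """
    for seq in (seq_a, seq_b):
        bad = set(seq) - _AA_SET
        if bad:
            raise ValueError(f"non-amino-acid characters {sorted(bad)}")
    aln = _aligner()
    alignment = aln.align(seq_a, seq_b)[0]
    score = float(alignment.score)
    positives = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            columns += 1
            if (seq_a[i], seq_b[j]) in _POSITIVE_PAIRS:
                positives += 1
    similarity = positives / columns if columns else 0.0
    return score, similarity


def evalue_from_score(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul e-value: E = K * m * n * exp(-lambda * S), with the
    search space taken as query length x total database residues."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def _kmer_candidates(genes: Sequence[GeneRecord], k: int,
                     min_shared: int) -> set[tuple[int, int]]:
    """Index genes by k-mers; candidate pairs share >= min_shared k-mers."""
    buckets: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genes):
        seq = g.protein_seq
        for kmer in {seq[j:j + k] for j in range(len(seq) - k + 1)}:
            buckets[kmer].append(i)
    shared: Counter = Counter()
    for members in buckets.values():
        if len(members) < 2 or len(members) > 200:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                shared[(members[a], members[b])] += 1
    return {pair for pair, count in shared.items() if count >= min_shared}


def pairwise_similarity(genes: Sequence[GeneRecord],
                        params: Optional[Parameters] = None,
                        queries: Optional[Sequence[GeneRecord]] = None,
                        evalue_cutoff: Optional[float] = None,
                        kmer_size: int = 4,
                        min_shared_kmers: int = 3) -> list[SimilarityEdge]:
    """All-vs-all (or queries-vs-database) similarity search.

    Smith-Waterman is run for every candidate pair passing the k-mer
    prefilter; an edge is emitted (in both directions for all-vs-all runs)
    when its e-value passes the cutoff. ``queries`` restricts the search to
    hits of the given genes against the full ``genes`` database.
    """
    params = params or Parameters()
    cutoff = evalue_cutoff if evalue_cutoff is not None else params.evalue_homology
    if not genes:
        raise ValueError("empty protein set")
    for g in genes:
        bad = set(g.protein_seq) - _AA_SET
        if bad:
            raise ValueError(
                f"gene {g.gene_id}: non-amino-acid characters {sorted(bad)}")
    db_len = sum(len(g.protein_seq) for g in genes)
    aln = _aligner()

    if queries is None:
        pool = list(genes)
        pairs = _kmer_candidates(pool, kmer_size, min_shared_kmers)
        directed = False
    else:
        # queries-vs-database: prefilter within the union, keep pairs with
        # one query member
        qkeys = {g.key for g in queries}
        pool = list(queries) + [g for g in genes if g.key not in qkeys]
        nq = len(queries)
        pairs = {(a, b) for a, b in
                 _kmer_candidates(pool, kmer_size, min_shared_kmers)
                 if a < nq or b < nq}
        directed = True

    edges: list[SimilarityEdge] = []
    for a, b in sorted(pairs):
        ga, gb = pool[a], pool[b]
        if ga.key == gb.key:
            continue
        score = float(aln.score(ga.protein_seq, gb.protein_seq))
        ev_ab = evalue_from_score(score, len(ga.protein_seq), db_len)
        ev_ba = evalue_from_score(score, len(gb.protein_seq), db_len)
        if min(ev_ab, ev_ba) > cutoff:
            continue
        _, similarity = smith_waterman(ga.protein_seq, gb.protein_seq)
        edges.append(SimilarityEdge(query=ga.key, hit=gb.key,
                                    raw_score=score, evalue=ev_ab,
                                    similarity=similarity))
        edges.append(SimilarityEdge(query=gb.key, hit=ga.key,
                                    raw_score=score, evalue=ev_ba,
                                    similarity=similarity))
    if queries is not None:
        qkeys = {g.key for g in queries}
        edges = [e for e in edges if e.query in qkeys]
    return edges


def build_graph(edges: Iterable[SimilarityEdge],
                params: Optional[Parameters] = None) -> nx.Graph:
    """Weighted undirected homology graph.

    Edge weight is -log10(evalue) capped at :data:`MAX_EDGE_WEIGHT`;
    reciprocal hits are averaged. Nodes are (genome, gene) keys; isolated
    genes stay isolated nodes when added via ``add_genes``.
    """
    graph = nx.Graph()
    sums: dict[tuple, list] = {}
    for e in edges:
        e.validate()
        weight = MAX_EDGE_WEIGHT if e.evalue <= 0 else min(
            -math.log10(e.evalue), MAX_EDGE_WEIGHT)
        key = tuple(sorted((e.query, e.hit)))
        entry = sums.setdefault(key, [0.0, 0])
        entry[0] += max(weight, 0.0)
        entry[1] += 1
        graph.add_node(e.query)
        graph.add_node(e.hit)
    for (u, v), (total, n) in sums.items():
        graph.add_edge(u, v, weight=total / n)
    return graph


def add_genes(graph: nx.Graph, genes: Iterable[GeneRecord]) -> nx.Graph:
    for g in genes:
        graph.add_node(g.key)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering

def _mcl_component(nodes: list, graph: nx.Graph, inflation: float,
                   prune: float = 1e-5, tol: float = 1e-6,
                   max_iter: int = 200) -> tuple[list[list], bool]:
    """Run MCL on one connected component. Returns (clusters, converged)."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(nodes, data=True):
        if u in index and v in index:
            w = float(data.get("weight", 1.0))
            M[index[u], index[v]] = w
            M[index[v], index[u]] = w
    # self-loops (standard MCL regularization): per-node max incident weight
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                       # expansion
        np.power(M, inflation, out=M)   # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break

    # attractors: rows with nonzero diagonal; cluster = columns flowing there
    attractors = [i for i in range(n) if M[i, i] > tol]
    if not attractors:
        attractors = list(range(n))
    owner: dict[int, int] = {}
    for j in range(n):
        cands = [(M[i, j], -i) for i in attractors if M[i, j] > 0]
        if cands:
            weight, neg_i = max(cands)
            owner[j] = -neg_i
        else:
            owner[j] = j
    # merge attractors that share members (overlapping attractor systems)
    clusters: dict[int, list] = defaultdict(list)
    for j, att in sorted(owner.items()):
        clusters[att].append(nodes[j])
    return list(clusters.values()), converged


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0,
                group_prefix: str = "HG") -> tuple[list[HomologGroup], bool]:
    """Partition the homology graph into homolog groups with MCL.

    Returns ``(groups, converged)``. Every gene lands in exactly one group;
    disconnected components are clustered independently (MCL flow cannot
    cross a gap in the graph), and isolated nodes become singletons.
    """
    if any(d.get("weight", 0) < 0 for _, _, d in graph.edges(data=True)):
        raise ValueError("MCL requires nonnegative edge weights")
    all_clusters: list[list] = []
    all_converged = True
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            all_clusters.append(nodes)
            continue
        clusters, converged = _mcl_component(nodes, graph, inflation)
        all_converged &= converged
        all_clusters.extend(clusters)
    all_clusters.sort(key=lambda c: sorted(c))
    groups = [
        HomologGroup(group_id=f"{group_prefix}{i:05d}",
                     members=frozenset(cluster))
        for i, cluster in enumerate(all_clusters)
    ]
    return groups, all_converged


def homolog_groups(genes: Sequence[GeneRecord],
                   params: Optional[Parameters] = None
                   ) -> tuple[list[HomologGroup], list[SimilarityEdge]]:
    """End-to-end: similarity search, graph build, MCL partition."""
    params = params or Parameters()
    edges = pairwise_similarity(genes, params)
    graph = build_graph(edges, params)
    add_genes(graph, genes)
    groups, _ = mcl_cluster(graph, params.mcl_inflation)
    return groups, edges
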