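"""Targeted gene-cluster discovery.

The discovery logic mirrors a phenotype-guided screen: homolog groups are
first filtered by taxon distribution (present in every producer genome, and
in at most ``max_negative`` non-producer genomes), surviving candidate genes
are chained into loci wherever two candidates on the same scaffold are
separated by no more than ``max_intervening`` genes, locus boundaries are
refined by admitting flanking genes whose groups satisfy the same
phenotype distribution *and* whose position is syntenic with a sibling
locus, and finally each locus is screened against the other genomes for
conserved local synteny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import (PS_MINUS, PS_PLUS, GenomeRecord, HomologGroup,
                   Parameters)
from .homology import SimilarityEdge, pairwise_similarity


@dataclass
class ClusterLocus:
    """A contiguous run of candidate genes on one scaffold."""
    genome_id: str
    scaffold_id: str
    members: list[tuple[str, str]]  # (gene_id, group_id), sorted by position
    start_index: int
    end_index: int
    n_intervening_max: int

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def group_ids(self) -> set[str]:
        return {grp for _, grp in self.members}

    def validate(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("locus start after end")


@dataclass
class SyntenyBlock:
    """Conserved local gene order between a query locus and a target genome."""
    genome_a: str
    genome_b: str
    anchor_pairs: list[tuple[str, str]]  # (gene_a, gene_b) homolog anchors
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    scaffold_b: str = ""


# ---------------------------------------------------------------------------
# taxon filtering

def _phenotype_sets(genomes: Sequence[GenomeRecord]
                    ) -> tuple[set[str], set[str]]:
    producers = {g.genome_id for g in genomes if g.phenotype == PS_PLUS}
    negatives = {g.genome_id for g in genomes if g.phenotype == PS_MINUS}
    return producers, negatives


def taxon_filter_groups(groups: Iterable[HomologGroup],
                        genomes: Sequence[GenomeRecord],
                        max_negative: int = 1,
                        params: Optional[Parameters] = None
                        ) -> list[HomologGroup]:
    """Retain groups present in ALL producer genomes and in at most
    ``max_negative`` non-producer genomes.

    With three producers and ``max_negative=1`` this is the "three to four
    genomes total" candidate rule; the total-genome ceiling from
    ``params.candidate_max_genomes`` is applied as well.
    """
    producers, _ = _phenotype_sets(genomes)
    if not producers:
        raise ValueError("no producer (PS+) genomes declared")
    params = params or Parameters()
    out = []
    for grp in groups:
        present = grp.genomes
        if not producers <= present:
            continue
        n_neg = len(present - producers)
        if n_neg > max_negative:
            continue
        if len(present) > params.candidate_max_genomes:
            continue
        out.append(grp)
    return sorted(out, key=lambda g: g.group_id)


@dataclass
class FilterCountsReport:
    """Audit trail of the staged taxon filtering."""
    total_groups: int
    in_all_producers: int
    in_all_genomes: int
    remaining_after_universal: int
    candidates: int


def filter_counts_report(groups: Sequence[HomologGroup],
                         genomes: Sequence[GenomeRecord],
                         max_negative: int = 1,
                         params: Optional[Parameters] = None
                         ) -> FilterCountsReport:
    """Staged counts: total groups, groups found in every producer genome,
    universal groups, non-universal producer groups, and final candidates."""
    producers, _ = _phenotype_sets(genomes)
    if not producers:
        raise ValueError("no producer (PS+) genomes declared")
    all_ids = {g.genome_id for g in genomes}
    in_all_ps = [g for g in groups if producers <= g.genomes]
    in_all = [g for g in groups if all_ids <= g.genomes]
    candidates = taxon_filter_groups(groups, genomes, max_negative, params)
    return FilterCountsReport(
        total_groups=len(groups),
        in_all_producers=len(in_all_ps),
        in_all_genomes=len(in_all),
        remaining_after_universal=len(in_all_ps) - len(in_all),
        candidates=len(candidates),
    )


# ---------------------------------------------------------------------------
# co-localization

def _chain_positions(positions: Sequence[int], max_intervening: int
                     ) -> list[list[int]]:
    """Single-linkage chaining of sorted positions: consecutive candidates
    separated by <= max_intervening intervening genes join one chain."""
    chains: list[list[int]] = []
    for pos in sorted(positions):
        if chains and pos - chains[-1][-1] - 1 <= max_intervening:
            chains[-1].append(pos)
        else:
            chains.append([pos])
    return chains


def find_colocalized(candidate_groups: Sequence[HomologGroup],
                     genomes: Sequence[GenomeRecord],
                     params: Optional[Parameters] = None
                     ) -> list[ClusterLocus]:
    """Chain candidate genes into loci per genome/scaffold.

    Consecutive candidates separated by at most ``params.max_intervening``
    non-candidate genes merge into one locus (single linkage); a locus is
    reported when it has >= 2 member genes drawn from >= 2 distinct groups.
    """
    params = params or Parameters()
    group_of: dict[tuple[str, str], str] = {}
    for grp in candidate_groups:
        for member in grp.members:
            group_of[member] = grp.group_id

    loci: list[ClusterLocus] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for scaffold_id, genes in sorted(genome.scaffolds().items()):
            by_pos = {g.order_index: g for g in genes}
            cand_pos = [g.order_index for g in genes
                        if (genome.genome_id, g.gene_id) in group_of]
            for chain in _chain_positions(cand_pos, params.max_intervening):
                members = [
                    (by_pos[p].gene_id,
                     group_of[(genome.genome_id, by_pos[p].gene_id)])
                    for p in chain]
                if len(members) < 2 or len({grp for _, grp in members}) < 2:
                    continue
                loci.append(ClusterLocus(
                    genome_id=genome.genome_id, scaffold_id=scaffold_id,
                    members=members, start_index=chain[0],
                    end_index=chain[-1],
                    n_intervening_max=params.max_intervening))
    return loci


# ---------------------------------------------------------------------------
# boundary refinement

def refine_boundaries(locus: ClusterLocus,
                      genomes: Sequence[GenomeRecord],
                      groups: Sequence[HomologGroup],
                      max_negative: int = 1,
                      params: Optional[Parameters] = None,
                      sibling_loci: Optional[Sequence[ClusterLocus]] = None
                      ) -> ClusterLocus:
    """Widen a locus by admitting flanking genes consistent with the
    producer phenotype and with cross-genome synteny.

    Each iteration scans up to ``params.boundary_window`` genes on either
    side of the current boundaries; a flank is admitted iff (a) its homolog
    group passes the same taxon filter as the seed candidates and (b) when
    sibling loci (the same cluster in other genomes) are supplied, the
    flank's group also has a member within the window of at least one
    sibling locus. Iterations repeat until nothing new is admitted.
    """
    params = params or Parameters()
    genome = next(g for g in genomes if g.genome_id == locus.genome_id)
    genes = genome.scaffolds()[locus.scaffold_id]
    by_pos = {g.order_index: g for g in genes}
    passing = {g.group_id
               for g in taxon_filter_groups(groups, genomes, max_negative,
                                            params)}
    group_of: dict[tuple[str, str], str] = {}
    for grp in groups:
        for member in grp.members:
            group_of[member] = grp.group_id

    # groups lying within the window of each sibling locus
    syntenic_groups: Optional[set[str]] = None
    if sibling_loci is not None:
        syntenic_groups = set()
        for sib in sibling_loci:
            if sib.genome_id == locus.genome_id:
                continue
            sib_genome = next(g for g in genomes if g.genome_id == sib.genome_id)
            sib_genes = sib_genome.scaffolds()[sib.scaffold_id]
            lo = sib.start_index - params.boundary_window
            hi = sib.end_index + params.boundary_window
            for g in sib_genes:
                if lo <= g.order_index <= hi:
                    grp = group_of.get((sib.genome_id, g.gene_id))
                    if grp is not None:
                        syntenic_groups.add(grp)

    members = dict(locus.members)  # gene_id -> group_id
    start, end = locus.start_index, locus.end_index
    changed = True
    while changed:
        changed = False
        window = (list(range(start - params.boundary_window, start)) +
                  list(range(end + 1, end + params.boundary_window + 1)))
        for pos in window:
            gene = by_pos.get(pos)
            if gene is None or gene.gene_id in members:
                continue
            grp = group_of.get((locus.genome_id, gene.gene_id))
            if grp is None or grp not in passing:
                continue
            if syntenic_groups is not None and grp not in syntenic_groups:
                continue
            members[gene.gene_id] = grp
            start = min(start, pos)
            end = max(end, pos)
            changed = True

    ordered = sorted(members.items(),
                     key=lambda kv: genome.gene(kv[0]).order_index)
    refined = ClusterLocus(
        genome_id=locus.genome_id, scaffold_id=locus.scaffold_id,
        members=ordered,
        start_index=min(genome.gene(g).order_index for g in members),
        end_index=max(genome.gene(g).order_index for g in members),
        n_intervening_max=locus.n_intervening_max)
    refined.validate()
    return refined


# ---------------------------------------------------------------------------
# synteny screen

def detect_synteny(locus: ClusterLocus,
                   genomes: Sequence[GenomeRecord],
                   params: Optional[Parameters] = None,
                   edges: Optional[Sequence[SimilarityEdge]] = None
                   ) -> list[SyntenyBlock]:
    """Screen other genomes for conserved local synteny with a locus.

    Homologs of the locus proteins are retrieved at the screening thresholds
    (e-value <= ``params.evalue_screen``, similarity >=
    ``params.min_sim_synteny``); a block is reported wherever homologs of
    >= 2 distinct locus genes co-localize within ``params.max_intervening``
    intervening genes in the target genome. The locus genome itself yields
    its own locus back (self-synteny). Precomputed similarity ``edges`` may
    be supplied to skip the search.
    """
    params = params or Parameters()
    query_genome = next(g for g in genomes if g.genome_id == locus.genome_id)
    query_genes = [query_genome.gene(gid) for gid in locus.gene_ids]
    query_keys = {g.key for g in query_genes}

    if edges is None:
        database = [g for genome in genomes for g in genome.genes]
        edges = pairwise_similarity(
            database, params, queries=query_genes,
            evalue_cutoff=params.evalue_screen)

    # hits of each query gene, grouped by target genome
    hit_map: dict[str, dict[tuple[str, str], set[str]]] = {}
    for e in edges:
        if e.query not in query_keys:
            continue
        if e.evalue > params.evalue_screen or e.similarity < params.min_sim_synteny:
            continue
        tgt_genome = e.hit[0]
        hit_map.setdefault(tgt_genome, {}).setdefault(e.hit, set()).add(
            e.query[1])
    # every query gene is trivially its own homolog
    for g in query_genes:
        hit_map.setdefault(locus.genome_id, {}).setdefault(g.key, set()).add(
            g.gene_id)

    blocks: list[SyntenyBlock] = []
    for tgt_id in sorted(hit_map):
        target = next(g for g in genomes if g.genome_id == tgt_id)
        hits = hit_map[tgt_id]
        for scaffold_id, genes in sorted(target.scaffolds().items()):
            positions = [g.order_index for g in genes if g.key in hits]
            by_pos = {g.order_index: g for g in genes}
            for chain in _chain_positions(positions, params.max_intervening):
                chain_genes = [by_pos[p] for p in chain]
                covered_queries = set()
                for g in chain_genes:
                    covered_queries |= hits[g.key]
                if len(chain) < 2 or len(covered_queries) < 2:
                    continue
                anchors = []
                for g in chain_genes:
                    for q in sorted(hits[g.key]):
                        anchors.append((q, g.gene_id))
                qpos = [query_genome.gene(q).order_index
                        for q, _ in anchors]
                blocks.append(SyntenyBlock(
                    genome_a=locus.genome_id, genome_b=tgt_id,
                    anchor_pairs=anchors,
                    span_a=(min(qpos), max(qpos)),
                    span_b=(chain[0], chain[-1]),
                    scaffold_b=scaffold_id))
    return blocks
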