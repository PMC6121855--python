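"""End-to-end orchestration: configuration, staged pipelines, artifacts.

Two pipelines are exposed. *Discovery* runs homology -> taxon filters ->
co-localization -> boundary refinement -> cross-genome synteny and reports
the clusters found; a locus is reported only when the same combination of
homolog groups is clustered in at least one other genome (chance
co-localizations in a single genome are not reproducible across genomes).
*HGT* runs the staged transfer screen against a configured donor lineage
and reconciles candidate gene trees against the species tree.

Configuration is a YAML file (or an equivalent dict) with sections
``simulate`` (generator settings), ``params`` (Parameters overrides),
``discovery`` and ``hgt``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as mio
from .core import GenomeRecord, HomologGroup, Parameters
from .discovery import (ClusterLocus, detect_synteny, filter_counts_report,
                        find_colocalized, refine_boundaries,
                        taxon_filter_groups)
from .hgt import ScreenReport, screen_genome
from .homology import SimilarityEdge, homolog_groups
from .reconcile import reconcile_with_support_collapse
from .phylo import bootstrap_tree, pad_alignment
from .core import leaf_label
from .simulate import HGTEvent, SimulationConfig, simulate_dataset


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class PipelineReport:
    stages: list[StageRecord] = field(default_factory=list)
    seed: int = 0
    parameters: Optional[Parameters] = None
    artifacts: dict = field(default_factory=dict)

    def add(self, name: str, n_in: int, n_out: int, t0: float) -> None:
        self.stages.append(StageRecord(name, n_in, n_out, time.time() - t0))

    def counts(self) -> dict[str, int]:
        return {s.name: s.n_out for s in self.stages}

    def to_text(self) -> str:
        lines = [f"seed\t{self.seed}"]
        for s in self.stages:
            lines.append(f"{s.name}\tin={s.n_in}\tout={s.n_out}\t"
                         f"sec={s.seconds:.2f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# configuration

def load_config(source) -> dict:
    """Read a YAML config file, or pass a dict through."""
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh) or {}


def parameters_from_config(config: dict) -> Parameters:
    overrides = dict(config.get("params") or {})
    return Parameters(**overrides)


def simulation_from_config(config: dict, seed: Optional[int] = None
                           ) -> SimulationConfig:
    section = dict(config.get("simulate") or {})
    events = section.pop("hgt_events", None)
    if events is not None:
        events = [HGTEvent(**e) for e in events]
    if seed is not None:
        section["seed"] = seed
    return SimulationConfig(hgt_events=events, **section)


def load_or_simulate_genomes(config: dict, seed: Optional[int] = None):
    """Genomes from explicit input paths, or from the simulator section."""
    inputs = config.get("inputs")
    if inputs:
        genomes = mio.read_genome_bundle(
            inputs["fasta"], inputs["gene_table"], inputs["metadata"])
        return genomes, None
    sim = simulation_from_config(config, seed)
    return simulate_dataset(sim)


# ---------------------------------------------------------------------------
# discovery pipeline

@dataclass
class DiscoveryResult:
    groups: list[HomologGroup]
    edges: list[SimilarityEdge]
    candidates: list[HomologGroup]
    raw_loci: list[ClusterLocus]
    refined_loci: list[ClusterLocus]
    final_loci: list[ClusterLocus]
    counts_report: object
    report: PipelineReport

    def cluster_gene_set(self) -> set[tuple[str, str]]:
        return {(locus.genome_id, gid)
                for locus in self.final_loci for gid in locus.gene_ids}


def _shares_groups(a: ClusterLocus, b: ClusterLocus, k: int) -> bool:
    return a.genome_id != b.genome_id and len(a.group_ids & b.group_ids) >= k


def discover_clusters(genomes: Sequence[GenomeRecord],
                      params: Optional[Parameters] = None,
                      max_negative: int = 1,
                      groups: Optional[Sequence[HomologGroup]] = None,
                      edges: Optional[Sequence[SimilarityEdge]] = None,
                      seed: int = 0) -> DiscoveryResult:
    """The full in-memory discovery pipeline."""
    params = params or Parameters()
    report = PipelineReport(seed=seed, parameters=params)
    genes = [g for genome in genomes for g in genome.genes]

    t0 = time.time()
    if groups is None:
        groups, edges = homolog_groups(genes, params)
    groups = list(groups)
    report.add("homology", len(genes), len(groups), t0)

    t0 = time.time()
    counts = filter_counts_report(groups, genomes, max_negative, params)
    candidates = taxon_filter_groups(groups, genomes, max_negative, params)
    report.add("taxon_filter", len(groups), len(candidates), t0)

    t0 = time.time()
    raw_loci = find_colocalized(candidates, genomes, params)
    report.add("colocalization", len(candidates), len(raw_loci), t0)

    t0 = time.time()
    refined = []
    for locus in raw_loci:
        siblings = [m for m in raw_loci if _shares_groups(locus, m, 1)]
        refined.append(refine_boundaries(
            locus, genomes, groups, max_negative, params,
            sibling_loci=siblings))
    report.add("boundary_refinement", len(raw_loci), len(refined), t0)

    t0 = time.time()
    final = [l for l in refined
             if any(_shares_groups(l, m, 2) for m in refined)]
    final = _prune_unsupported_members(final, genomes, params)
    report.add("cross_genome_support", len(refined), len(final), t0)

    return DiscoveryResult(
        groups=groups, edges=list(edges or []), candidates=candidates,
        raw_loci=raw_loci, refined_loci=refined, final_loci=final,
        counts_report=counts, report=report)


def _prune_unsupported_members(loci: list[ClusterLocus],
                               genomes: Sequence[GenomeRecord],
                               params: Parameters) -> list[ClusterLocus]:
    """Drop locus members whose homolog group is not clustered in at least
    two genomes (synteny convergence applied member-wise): a chance
    candidate adjacent to a real cluster in one genome is not reproduced
    near the sibling loci."""
    by_id = {g.genome_id: g for g in genomes}
    # groups found within the window of each locus, per genome
    window_groups: dict[str, set[str]] = {}
    for locus in loci:
        genome = by_id[locus.genome_id]
        near = set()
        lo = locus.start_index - params.boundary_window
        hi = locus.end_index + params.boundary_window
        member_groups = dict(locus.members)
        for gene in genome.scaffolds()[locus.scaffold_id]:
            if lo <= gene.order_index <= hi and gene.gene_id in member_groups:
                near.add(member_groups[gene.gene_id])
        window_groups.setdefault(locus.genome_id, set()).update(near)

    support: dict[str, int] = {}
    for grp_set in window_groups.values():
        for grp in grp_set:
            support[grp] = support.get(grp, 0) + 1

    pruned: list[ClusterLocus] = []
    for locus in loci:
        genome = by_id[locus.genome_id]
        kept = [(gid, grp) for gid, grp in locus.members
                if support.get(grp, 0) >= 2]
        if len(kept) < 2 or len({grp for _, grp in kept}) < 2:
            continue
        positions = [genome.gene(gid).order_index for gid, _ in kept]
        pruned.append(ClusterLocus(
            genome_id=locus.genome_id, scaffold_id=locus.scaffold_id,
            members=kept, start_index=min(positions),
            end_index=max(positions),
            n_intervening_max=locus.n_intervening_max))
    return pruned


def run_discovery(config, out_dir=None, seed: Optional[int] = None
                  ) -> tuple[DiscoveryResult, PipelineReport]:
    """Discovery pipeline from a config file/dict; optionally writes
    artifacts (groups, loci, synteny, staged report) to ``out_dir``."""
    config = load_config(config)
    params = parameters_from_config(config)
    genomes, truth = load_or_simulate_genomes(config, seed)
    max_negative = int((config.get("discovery") or {}).get("max_negative", 1))
    result = discover_clusters(genomes, params, max_negative,
                               seed=seed if seed is not None else 0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mio.write_genome_bundle(genomes, out_dir / "bundle")
        if truth is not None:
            truth.write(out_dir / "truth.json")
        mio.write_groups(result.groups, out_dir / "groups.tsv")
        _write_loci(result.final_loci, out_dir / "loci.tsv")
        _write_edges(result.edges, out_dir / "edges.tsv")
        synteny_rows = []
        for locus in result.final_loci:
            for block in detect_synteny(locus, genomes, params,
                                        edges=result.edges):
                synteny_rows.append({
                    "genome_a": block.genome_a, "genome_b": block.genome_b,
                    "scaffold_b": block.scaffold_b,
                    "span_a": f"{block.span_a[0]}-{block.span_a[1]}",
                    "span_b": f"{block.span_b[0]}-{block.span_b[1]}",
                    "n_anchors": len(block.anchor_pairs)})
        pd.DataFrame(synteny_rows).to_csv(out_dir / "synteny.tsv",
                                          sep="\t", index=False)
        (out_dir / "report.txt").write_text(result.report.to_text())
        result.report.artifacts = {
            "groups": str(out_dir / "groups.tsv"),
            "loci": str(out_dir / "loci.tsv"),
            "synteny": str(out_dir / "synteny.tsv"),
            "report": str(out_dir / "report.txt")}
    return result, result.report


def _write_loci(loci: Sequence[ClusterLocus], path) -> None:
    rows = []
    for l in loci:
        rows.append({
            "genome_id": l.genome_id, "scaffold_id": l.scaffold_id,
            "start_index": l.start_index, "end_index": l.end_index,
            "genes": ",".join(l.gene_ids),
            "groups": ",".join(sorted(l.group_ids))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_edges(edges: Sequence[SimilarityEdge], path) -> None:
    rows = [{"query_genome": e.query[0], "query_gene": e.query[1],
             "hit_genome": e.hit[0], "hit_gene": e.hit[1],
             "raw_score": e.raw_score, "evalue": e.evalue,
             "similarity": round(e.similarity, 4)} for e in edges]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HGT pipeline

def run_hgt(config, out_dir=None, seed: Optional[int] = None
            ) -> tuple[ScreenReport, PipelineReport]:
    """HGT screen from a config file/dict.

    The ``hgt`` section must name the recipient genome and the donor taxa;
    optional keys: ``lineage_taxa`` (the recipient's vertical relatives),
    ``background_taxa``, ``surrounding_taxa``, ``reconcile`` (bool).
    """
    config = load_config(config)
    params = parameters_from_config(config)
    genomes, truth = load_or_simulate_genomes(config, seed)
    section = config.get("hgt") or {}
    recipient_id = section["recipient"]
    donor_taxa = set(section["donor_taxa"])
    lineage = set(section.get("lineage_taxa") or [])
    background = section.get("background_taxa")
    surrounding = section.get("surrounding_taxa")
    use_seed = seed if seed is not None else 0

    report = PipelineReport(seed=use_seed, parameters=params)
    recipient = next(g for g in genomes if g.genome_id == recipient_id)

    t0 = time.time()
    screen = screen_genome(
        recipient, genomes, donor_taxa=donor_taxa,
        recipient_lineage_taxa=lineage,
        background_taxa=set(background) if background else None,
        surrounding_taxa=set(surrounding) if surrounding else None,
        params=params, seed=use_seed)
    report.add("hgt_screen", screen.counts.get("queries", 0),
               len(screen.final_candidates()), t0)

    reconciliations = []
    if section.get("reconcile") and truth is not None:
        t0 = time.time()
        species_tree = truth.species_tree
        by_id = {g.genome_id: g for g in genomes}
        fams = {}
        for cand in screen.final_candidates():
            fam = truth.gene_to_family.get(cand.query)
            if fam is not None:
                fams[fam] = cand
        for fam in sorted(fams):
            members = [(g, gid) for (g, gid), f in
                       truth.gene_to_family.items() if f == fam]
            seqs = {leaf_label(g, gid): by_id[g].gene(gid).protein_seq
                    for g, gid in members}
            gtree = bootstrap_tree(pad_alignment(seqs), params.n_bootstraps,
                                   seed=use_seed + 31)
            rooted = gtree.copy()
            rooted.tree.reroot_at_midpoint()
            rooted.tree.is_rooted = True
            dl, dtl, preferred = reconcile_with_support_collapse(
                rooted, species_tree, params)
            reconciliations.append((fam, dl, dtl, preferred))
        report.add("reconciliation", len(fams), len(reconciliations), t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [{"query_genome": c.query[0], "query_gene": c.query[1],
                 "stage": c.stage_passed,
                 "p_value": "" if c.p_value is None else c.p_value}
                for c in screen.candidates]
        pd.DataFrame(rows).to_csv(out_dir / "hgt_candidates.tsv",
                                  sep="\t", index=False)
        rec_rows = [{"family": fam, "model_preferred": pref,
                     "dl_dup": dl.n_dup, "dl_loss": dl.n_loss,
                     "dl_cost": dl.total_cost,
                     "dtl_dup": dtl.n_dup, "dtl_transfer": dtl.n_transfer,
                     "dtl_loss": dtl.n_loss, "dtl_cost": dtl.total_cost}
                    for fam, dl, dtl, pref in reconciliations]
        pd.DataFrame(rec_rows).to_csv(out_dir / "reconciliation.tsv",
                                      sep="\t", index=False)
        (out_dir / "report.txt").write_text(report.to_text())
    report.artifacts["reconciliations"] = reconciliations
    return screen, report
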