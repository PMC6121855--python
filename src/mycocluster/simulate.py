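"""Synthetic genome simulator.

Generates the statistical structure the discovery and HGT analyses assume:
a species tree over related mushroom genomes, background gene families whose
presence/absence evolves by a two-state gain/loss Markov process (with an
optional ecology-linked subset), protein sequences evolved site-wise under a
fixed empirical amino-acid model (indel-free, so families are natively
aligned), a 5-gene biosynthetic cluster planted contiguously in producer
genomes only, and explicit horizontal transfer events whose recipient
sequences descend from the donor lineage. Every run is reproducible from a
single seed, and a ground-truth log records everything that was planted.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import seqmodel
from .core import (ECOLOGIES, PS_MINUS, PS_PLUS, GeneRecord, GenomeRecord,
                   SupportTree, leaf_label)

#: Functional roles of the planted cluster, mirroring a tryptophan-derived
#: alkaloid pathway: decarboxylase, P450 monooxygenase, kinase
#: (phosphotransferase), methyltransferase, MFS transporter.
DEFAULT_CLUSTER_SPEC = [
    "decarboxylase", "monooxygenase", "methyltransferase",
    "phosphotransferase", "MFS_transporter",
]


@dataclass
class HGTEvent:
    """A horizontal transfer to simulate. ``kind='cluster'`` moves the whole
    planted cluster; ``kind='family'`` re-routes one background family."""
    donor: str
    recipient: str
    kind: str = "cluster"  # 'cluster' | 'family'
    family_id: Optional[str] = None


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions the
    rest of the package is exercised under (six genomes, three scattered
    producers, 300 background families, one cluster transfer between the two
    most distant producers)."""

    n_taxa: int = 6
    seed: int = 0
    n_background_families: int = 300
    gain_rate: float = 0.05
    loss_rate: float = 0.20
    root_presence: float = 0.90
    min_family_length: int = 100
    max_family_length: int = 180
    subs_per_unit: float = 1.0       # global branch-length multiplier
    tree_depth: float = 0.45          # mean root-to-tip path after rescaling
    cluster_spec: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_CLUSTER_SPEC))
    cluster_seq_length: int = 250
    cluster_rate_scale: float = 0.4  # cluster genes evolve slower (conserved enzymes)
    producer_taxa: Optional[Sequence[str]] = None
    n_producers: int = 3
    hgt_events: Optional[Sequence[HGTEvent]] = None  # None -> one default cluster HGT
    ecology_probs: dict = field(default_factory=lambda: {
        "dung": 0.30, "wood": 0.45, "mycorrhizal": 0.25})
    dual_ecology_prob: float = 0.10
    ecology_assignments: Optional[dict] = None  # genome -> iterable of labels
    ecology_linked_fraction: float = 0.0
    genes_per_scaffold: int = 50
    plant_cluster: bool = True
    species_newick: Optional[str] = None  # fixed topology/lengths if given

    def validate(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("gain/loss rates must be nonnegative")
        if self.min_family_length < 1:
            raise ValueError("family length must be positive")
        if not 0 <= self.ecology_linked_fraction <= 1:
            raise ValueError("ecology_linked_fraction in [0,1]")


@dataclass
class RealizedHGT:
    donor: str
    recipient: str
    family_id: str
    kind: str


@dataclass
class TruthLog:
    """Ground truth for a simulated dataset."""
    species_newick: str = ""
    phenotype: dict = field(default_factory=dict)
    ecology: dict = field(default_factory=dict)
    producers: list = field(default_factory=list)
    family_presence: dict = field(default_factory=dict)   # family -> set(genomes)
    gene_to_family: dict = field(default_factory=dict)    # (genome, gene) -> family
    cluster_families: list = field(default_factory=list)
    cluster_genes: dict = field(default_factory=dict)     # genome -> ordered gene ids
    hgt_events: list = field(default_factory=list)        # RealizedHGT
    ecology_linked: dict = field(default_factory=dict)    # family -> niche
    family_trees: dict = field(default_factory=dict)      # family -> newick
    node_states: dict = field(default_factory=dict)       # node label -> bool array

    @property
    def species_tree(self) -> SupportTree:
        return SupportTree.from_newick(self.species_newick)

    def families_in_all_producers(self) -> set[str]:
        prod = set(self.producers)
        return {f for f, pres in self.family_presence.items()
                if prod <= set(pres)}

    def cluster_gene_set(self) -> set[tuple[str, str]]:
        return {(genome, gid) for genome, gids in self.cluster_genes.items()
                for gid in gids}

    def write(self, path) -> None:
        doc = {
            "species_newick": self.species_newick,
            "phenotype": self.phenotype,
            "ecology": {k: sorted(v) for k, v in self.ecology.items()},
            "producers": list(self.producers),
            "family_presence": {k: sorted(v) for k, v in self.family_presence.items()},
            "gene_to_family": [
                {"genome": g, "gene": i, "family": f}
                for (g, i), f in sorted(self.gene_to_family.items())],
            "cluster_families": list(self.cluster_families),
            "cluster_genes": self.cluster_genes,
            "hgt_events": [vars(e) for e in self.hgt_events],
            "ecology_linked": self.ecology_linked,
            "family_trees": self.family_trees,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def read(cls, path) -> "TruthLog":
        doc = json.loads(Path(path).read_text())
        log = cls(
            species_newick=doc["species_newick"],
            phenotype=doc["phenotype"],
            ecology={k: frozenset(v) for k, v in doc["ecology"].items()},
            producers=doc["producers"],
            family_presence={k: frozenset(v)
                             for k, v in doc["family_presence"].items()},
            gene_to_family={(r["genome"], r["gene"]): r["family"]
                            for r in doc["gene_to_family"]},
            cluster_families=doc["cluster_families"],
            cluster_genes=doc["cluster_genes"],
            hgt_events=[RealizedHGT(**e) for e in doc["hgt_events"]],
            ecology_linked=doc["ecology_linked"],
            family_trees=doc["family_trees"],
        )
        return log


# ---------------------------------------------------------------------------
# seeded substreams

def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# species tree

@dataclass
class SpeciesSim:
    tree: SupportTree
    phenotype: dict
    ecology: dict
    producers: list


def _scattered_leaves(tree: SupportTree, k: int) -> list[str]:
    """Pick k leaves spread across the tree (greedy max-min path length)."""
    dm = tree.leaf_distance_matrix()
    labels = sorted(tree.leaf_labels())
    best_pair = max(
        ((a, b) for a in labels for b in labels if a < b),
        key=lambda p: (dm[p], p))
    chosen = [best_pair[0], best_pair[1]]
    while len(chosen) < k:
        cand = max((l for l in labels if l not in chosen),
                   key=lambda l: (min(dm[(l, c)] for c in chosen), l))
        chosen.append(cand)
    return sorted(chosen)


def simulate_species_tree(config: SimulationConfig) -> SpeciesSim:
    """Simulate (or load) the species tree and assign phenotype/ecology."""
    config.validate()
    if config.species_newick is not None:
        tree = SupportTree.from_newick(config.species_newick)
    else:
        rnd = random.Random(int(substream(config.seed, "species_tree")
                                .integers(0, 2**31 - 1)))
        dtree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0,
            num_extant_tips=config.n_taxa, rng=rnd)
        # relabel leaves deterministically and rescale depth
        leaves = sorted(dtree.leaf_node_iter(),
                        key=lambda n: n.taxon.label)
        for i, leaf in enumerate(leaves):
            leaf.taxon.label = f"G{i + 1:02d}"
        depths = dtree.calc_node_root_distances(return_leaf_distances_only=True)
        mean_depth = float(np.mean(depths))
        scale = config.tree_depth / mean_depth if mean_depth > 0 else 1.0
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = max(edge.length * scale, 0.02)
        dtree.is_rooted = True
        tree = SupportTree(dtree)
    # name internal nodes for the truth log
    for i, node in enumerate(tree.tree.preorder_internal_node_iter()):
        node.label = node.label or f"N{i + 1}"

    labels = sorted(tree.leaf_labels())
    if config.producer_taxa is not None:
        producers = sorted(config.producer_taxa)
        missing = set(producers) - set(labels)
        if missing:
            raise ValueError(f"producer taxa not in tree: {sorted(missing)}")
    else:
        producers = _scattered_leaves(tree, config.n_producers)

    phenotype = {l: (PS_PLUS if l in producers else PS_MINUS) for l in labels}

    ecology: dict[str, frozenset] = {}
    if config.ecology_assignments is not None:
        for l in labels:
            ecology[l] = frozenset(config.ecology_assignments[l])
    else:
        rng = substream(config.seed, "ecology")
        names = list(config.ecology_probs)
        probs = np.array([config.ecology_probs[n] for n in names], dtype=float)
        probs /= probs.sum()
        for l in labels:
            primary = names[int(rng.choice(len(names), p=probs))]
            labels_set = {primary}
            if rng.random() < config.dual_ecology_prob:
                others = [n for n in names if n != primary]
                labels_set.add(others[int(rng.integers(len(others)))])
            ecology[l] = frozenset(labels_set)

    return SpeciesSim(tree=tree, phenotype=phenotype,
                      ecology=ecology, producers=producers)


# ---------------------------------------------------------------------------
# gene content

def _two_state_transition(present: bool, t: float, gain: float, loss: float,
                          u: float) -> bool:
    """One draw of the two-state gain/loss chain along a branch of length t."""
    tot = gain + loss
    if tot == 0:
        return present
    stay_frac = np.exp(-tot * t)
    p1 = gain / tot * (1 - stay_frac)  # P(0 -> 1)
    if present:
        p_present = 1 - loss / tot * (1 - stay_frac)
    else:
        p_present = p1
    return u < p_present


def simulate_gene_content(species: SpeciesSim, config: SimulationConfig
                          ) -> tuple[pd.DataFrame, TruthLog]:
    """Evolve background-family presence/absence along the species tree.

    Returns a boolean family x genome presence frame and a truth log seeded
    with the species assignments and per-node presence states. A configurable
    fraction of families is ecology-linked: their presence is forced to the
    set of genomes carrying one niche label.
    """
    config.validate()
    rng = substream(config.seed, "gene_content")
    n_fam = config.n_background_families
    families = [f"fam{i:04d}" for i in range(n_fam)]
    tree = species.tree.tree

    node_states: dict[str, np.ndarray] = {}
    root_state = rng.random(n_fam) < config.root_presence
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = root_state.copy()
        else:
            parent_key = (node.parent_node.taxon.label
                          if node.parent_node.is_leaf()
                          else node.parent_node.label)
            parent_state = node_states[parent_key]
            t = (node.edge.length or 0.0)
            u = rng.random(n_fam)
            state = np.array([
                _two_state_transition(bool(parent_state[i]), t,
                                      config.gain_rate, config.loss_rate, u[i])
                for i in range(n_fam)])
        key = node.taxon.label if node.is_leaf() else node.label
        node_states[key] = state

    genomes = sorted(species.tree.leaf_labels())
    presence = pd.DataFrame(
        {g: node_states[g] for g in genomes}, index=families)

    # ecology-linked families: presence forced to the niche's genome set
    linked: dict[str, str] = {}
    if config.ecology_linked_fraction > 0:
        n_linked = int(round(config.ecology_linked_fraction * n_fam))
        link_rng = substream(config.seed, "ecology_linked")
        chosen = sorted(link_rng.choice(n_fam, size=n_linked, replace=False))
        niches = sorted(ECOLOGIES)
        for idx in chosen:
            niche = niches[int(link_rng.integers(len(niches)))]
            fam = families[idx]
            linked[fam] = niche
            presence.loc[fam] = [niche in species.ecology[g] for g in genomes]

    truth = TruthLog(
        species_newick=species.tree.as_newick().strip(),
        phenotype=dict(species.phenotype),
        ecology=dict(species.ecology),
        producers=list(species.producers),
        family_presence={
            fam: frozenset(presence.columns[presence.loc[fam]])
            for fam in families},
        ecology_linked=linked,
        node_states=node_states,
    )
    return presence, truth


# ---------------------------------------------------------------------------
# sequences

def _sample_child_states(parent: np.ndarray, t: float,
                         rng: np.random.Generator) -> np.ndarray:
    P = seqmodel.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    r = rng.random(parent.shape[0])
    rows = cum[parent]
    return (rows < r[:, None]).sum(axis=1).astype(np.int64)


def evolve_sequences_on_tree(tree: SupportTree, length: int,
                             rng: np.random.Generator,
                             rate_scale: float = 1.0) -> dict[str, str]:
    """Evolve one protein family along ``tree``; returns leaf label -> seq.

    The root sequence is drawn from the model's stationary distribution and
    substituted site-wise along each branch (branch length x ``rate_scale``
    expected substitutions per site).
    """
    if length < 1:
        raise ValueError("sequence length must be positive")
    pi = seqmodel.stationary_frequencies()
    root_states = rng.choice(seqmodel.N_STATES, size=length, p=pi)
    states: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            s = root_states
        else:
            t = (node.edge.length or 0.0) * rate_scale
            s = _sample_child_states(states[id(node.parent_node)], t, rng)
        states[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = seqmodel.decode(s)
    return out


def evolve_family_sequences(tree: SupportTree, present_taxa: Sequence[str],
                            length: int, rng: np.random.Generator,
                            rate_scale: float = 1.0) -> dict[str, str]:
    """Evolve a family restricted to ``present_taxa`` (the family's gene tree
    is the species tree pruned to its presence set)."""
    present = sorted(present_taxa)
    if not present:
        raise ValueError("family present in no taxon")
    sub = _pruned_tree(tree, present)
    return evolve_sequences_on_tree(sub, length, rng, rate_scale)


def _pruned_tree(tree: SupportTree, keep: Sequence[str]) -> SupportTree:
    keep_set = set(keep)
    if len(keep_set) == 1:
        # degenerate single-leaf "tree"
        only = next(iter(keep_set))
        leaf = tree.leaf(only)
        depth = leaf.distance_from_root()
        t = dendropy.Tree()
        t.seed_node.taxon = dendropy.Taxon(label=only)
        t.taxon_namespace.add_taxon(t.seed_node.taxon)
        t.seed_node.edge.length = depth
        return SupportTree(t)
    # fresh parse: fully independent tree + taxon namespace
    sub = dendropy.Tree.get(data=tree.as_newick(), schema="newick",
                            suppress_internal_node_taxa=True,
                            preserve_underscores=True)
    sub.retain_taxa_with_labels(keep_set)
    sub.suppress_unifurcations()
    sub.is_rooted = True
    return SupportTree(sub)


def transferred_gene_tree(species_tree: SupportTree, present: Sequence[str],
                          donor: str, recipient: str) -> SupportTree:
    """Gene tree of a horizontally transferred family: the species tree
    restricted to the presence set, with the recipient's leaf detached and
    re-grafted halfway along the donor's terminal branch (the transferred
    copy descends from the donor lineage, not the recipient's)."""
    present = sorted(set(present) | {donor, recipient})
    sub = _pruned_tree(species_tree, present).tree
    ns = sub.taxon_namespace
    rec_leaf = None
    don_leaf = None
    for leaf in sub.leaf_node_iter():
        if leaf.taxon.label == recipient:
            rec_leaf = leaf
        elif leaf.taxon.label == donor:
            don_leaf = leaf
    if rec_leaf is None or don_leaf is None:
        raise ValueError("donor or recipient missing from family presence set")
    # detach recipient
    parent = rec_leaf.parent_node
    parent.remove_child(rec_leaf)
    sub.suppress_unifurcations()
    # graft onto the donor's terminal edge at its midpoint
    don_parent = don_leaf.parent_node
    t_don = don_leaf.edge.length or 0.1
    don_parent.remove_child(don_leaf)
    joint = don_parent.new_child(edge_length=t_don / 2.0)
    joint.add_child(don_leaf)
    don_leaf.edge.length = t_don / 2.0
    joint.add_child(rec_leaf)
    rec_leaf.edge.length = t_don / 2.0
    sub.is_rooted = True
    return SupportTree(sub)


# ---------------------------------------------------------------------------
# whole-dataset orchestration

def _relabel_gene_tree(tree: SupportTree, genome_to_gene: dict[str, str]
                       ) -> SupportTree:
    t = tree.copy()
    for leaf in t.tree.leaf_node_iter():
        genome = leaf.taxon.label
        leaf.taxon.label = leaf_label(genome, genome_to_gene[genome])
    return t


def plant_cluster_and_hgt(species: SpeciesSim, config: SimulationConfig,
                          truth: TruthLog) -> dict[str, dict[str, str]]:
    """Evolve the cluster families (producer-only presence) and apply HGT
    events; returns family -> (genome -> sequence) and updates the truth log.

    Cluster gene trees are the species tree restricted to producers; for each
    cluster HGT event the recipient's sequences are instead evolved on a tree
    where the recipient is nested inside the donor's terminal branch.
    """
    producers = list(species.producers)
    if not producers:
        raise ValueError("no producer taxa")
    events = list(config.hgt_events) if config.hgt_events is not None else None
    if events is None:
        # default condition: one cluster transfer between the two most
        # distant producers (donor = lexicographically smaller of the pair)
        dm = species.tree.leaf_distance_matrix()
        pair = max(((a, b) for a in producers for b in producers if a < b),
                   key=lambda p: (dm[p], p))
        events = [HGTEvent(donor=pair[0], recipient=pair[1], kind="cluster")]
    for ev in events:
        if ev.kind == "cluster" and ev.recipient not in producers:
            raise ValueError(
                f"cluster HGT recipient {ev.recipient} is not a producer")

    cluster_events = [e for e in events if e.kind == "cluster"]
    fam_seqs: dict[str, dict[str, str]] = {}
    for k, role in enumerate(config.cluster_spec):
        fam = f"clu_{role}"
        truth.cluster_families.append(fam)
        truth.family_presence[fam] = frozenset(producers)
        if cluster_events:
            ev = cluster_events[0]
            gtree = transferred_gene_tree(
                species.tree, producers, ev.donor, ev.recipient)
            truth.hgt_events.append(RealizedHGT(
                donor=ev.donor, recipient=ev.recipient,
                family_id=fam, kind="cluster"))
        else:
            gtree = _pruned_tree(species.tree, producers)
        rng = substream(config.seed, f"cluster_seq:{fam}")
        seqs = evolve_sequences_on_tree(
            gtree, config.cluster_seq_length, rng,
            rate_scale=config.subs_per_unit * config.cluster_rate_scale)
        fam_seqs[fam] = seqs
        truth.family_trees[fam] = _relabel_gene_tree(
            gtree, {g: f"{g}_{fam}" for g in seqs}).as_newick().strip()
    return fam_seqs


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[list[GenomeRecord], TruthLog]:
    """Run the full generator: species tree, content, sequences, cluster
    planting, HGT, and genome assembly into scaffolds."""
    config.validate()
    species = simulate_species_tree(config)
    presence, truth = simulate_gene_content(species, config)

    events = list(config.hgt_events) if config.hgt_events is not None else None
    family_transfer: dict[str, HGTEvent] = {}
    if events:
        for ev in events:
            if ev.kind == "family":
                if ev.family_id is None:
                    raise ValueError("family HGT event needs family_id")
                family_transfer[ev.family_id] = ev

    # background family sequences
    len_rng = substream(config.seed, "family_lengths")
    fam_seqs: dict[str, dict[str, str]] = {}
    for fam in presence.index:
        present = sorted(presence.columns[presence.loc[fam]])
        if fam in family_transfer:
            ev = family_transfer[fam]
            present = sorted(set(present) | {ev.donor, ev.recipient})
            presence.loc[fam] = [g in present for g in presence.columns]
            truth.family_presence[fam] = frozenset(present)
            truth.hgt_events.append(RealizedHGT(
                donor=ev.donor, recipient=ev.recipient,
                family_id=fam, kind="family"))
        if not present:
            continue
        length = int(len_rng.integers(config.min_family_length,
                                      config.max_family_length + 1))
        rng = substream(config.seed, f"family_seq:{fam}")
        if fam in family_transfer:
            ev = family_transfer[fam]
            gtree = transferred_gene_tree(
                species.tree, present, ev.donor, ev.recipient)
        else:
            gtree = _pruned_tree(species.tree, present)
        seqs = evolve_sequences_on_tree(gtree, length, rng,
                                        rate_scale=config.subs_per_unit)
        fam_seqs[fam] = seqs
        truth.family_trees[fam] = _relabel_gene_tree(
            gtree, {g: f"{g}_{fam}" for g in seqs}).as_newick().strip()

    # cluster families (+ cluster HGT)
    cluster_seqs: dict[str, dict[str, str]] = {}
    if config.plant_cluster:
        cluster_seqs = plant_cluster_and_hgt(species, config, truth)

    # assemble genomes: shuffle background genes onto scaffolds, then insert
    # the cluster contiguously (member order shuffled within the locus)
    genomes: list[GenomeRecord] = []
    role_of = {f"clu_{role}": role for role in config.cluster_spec}
    for genome_id in sorted(species.tree.leaf_labels()):
        grng = substream(config.seed, f"layout:{genome_id}")
        background = sorted(f for f, seqs in fam_seqs.items()
                            if genome_id in seqs)
        order = list(background)
        grng.shuffle(order)
        is_producer = config.plant_cluster and genome_id in species.producers
        cluster_order: list[str] = []
        insert_at = None
        if is_producer:
            cluster_order = [f"clu_{r}" for r in config.cluster_spec]
            grng.shuffle(cluster_order)
            insert_at = int(grng.integers(0, len(order) + 1))
            order[insert_at:insert_at] = cluster_order

        genes: list[GeneRecord] = []
        scaffold_sizes: list[int] = []
        n = len(order)
        pos = 0
        while pos < n:
            scaffold_sizes.append(min(config.genes_per_scaffold, n - pos))
            pos += scaffold_sizes[-1]
        # keep the cluster on one scaffold: grow the containing scaffold
        pos = 0
        idx = 0
        for s, size in enumerate(scaffold_sizes):
            lo, hi = pos, pos + size
            if insert_at is not None and lo < insert_at + len(cluster_order) \
                    and insert_at < hi:
                # ensure whole cluster inside [lo, hi)
                hi = max(hi, insert_at + len(cluster_order))
                if s + 1 < len(scaffold_sizes):
                    shift = hi - (pos + size)
                    scaffold_sizes[s + 1] -= shift
            for oi, fam in enumerate(order[lo:hi]):
                gene_id = f"{genome_id}_{fam}"
                seq_map = cluster_seqs.get(fam) or fam_seqs[fam]
                genes.append(GeneRecord(
                    gene_id=gene_id, genome_id=genome_id,
                    scaffold_id=f"scf{s + 1:03d}", order_index=oi,
                    protein_seq=seq_map[genome_id],
                    function_label=role_of.get(fam),
                ))
                truth.gene_to_family[(genome_id, gene_id)] = fam
            pos = hi
        if is_producer:
            truth.cluster_genes[genome_id] = [
                f"{genome_id}_{fam}" for fam in cluster_order]
        rec = GenomeRecord(
            genome_id=genome_id, genes=genes,
            phenotype=species.phenotype[genome_id],
            ecology=species.ecology[genome_id])
        rec.validate()
        genomes.append(rec)

    return genomes, truth


# ---------------------------------------------------------------------------
# named scenarios

def hgt_screen_scenario(seed: int, transfer: bool,
                        n_families: int = 20,
                        n_transferred: int = 5,
                        seq_length: tuple[int, int] = (150, 200),
                        ) -> SimulationConfig:
    """Study conditions for the genome-wide HGT screen: a fixed 10-taxon
    species tree where the recipient (``rec``) has two close relatives and
    the donor group is a 4-taxon ladder (``don1``..``don4``); transfers move
    background families from ``don4`` (the most nested donor) to ``rec``."""
    newick = ("((rec:0.15,(rel1:0.10,rel2:0.10):0.08):0.22,"
              "((don1:0.10,(don2:0.08,(don3:0.07,don4:0.07):0.05):0.05):0.16,"
              "(out1:0.12,(out2:0.10,out3:0.10):0.06):0.14):0.10):0.0;")
    events: list[HGTEvent] = []
    if transfer:
        events = [HGTEvent(donor="don4", recipient="rec", kind="family",
                           family_id=f"fam{i:04d}")
                  for i in range(n_transferred)]
    return SimulationConfig(
        n_taxa=10, seed=seed, species_newick=newick,
        n_background_families=n_families,
        gain_rate=0.0, loss_rate=0.0, root_presence=1.0,
        min_family_length=seq_length[0], max_family_length=seq_length[1],
        producer_taxa=["rec", "don4", "don1"],  # phenotype unused by the screen
        plant_cluster=False,
        hgt_events=events or [],
        genes_per_scaffold=50,
    )


SCREEN_DONOR_TAXA = frozenset({"don1", "don2", "don3", "don4"})
SCREEN_BACKGROUND_TAXA = frozenset({"rel1", "rel2", "out1", "out2", "out3"})
SCREEN_SURROUNDING_TAXA = SCREEN_DONOR_TAXA
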