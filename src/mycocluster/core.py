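"""Shared data model for comparative-genomics cluster discovery.

The pipeline reasons about genomes as ordered lists of protein-coding genes
on scaffolds (gene position is an integer rank, not a base-pair coordinate),
about homolog groups as cross-genome sets of genes, and about trees whose
leaves are either genomes or ``genome|gene`` pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy

logger = logging.getLogger("mycocluster")

#: Phenotype labels: producer, non-producer, unscored.
PS_PLUS = "PS+"
PS_MINUS = "PS-"
UNKNOWN = "unknown"
PHENOTYPES = (PS_PLUS, PS_MINUS, UNKNOWN)

#: Ecology labels. A genome may carry more than one (e.g. litter fungi that
#: decay both dung and wood).
ECOLOGIES = ("dung", "wood", "mycorrhizal")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Separator joining genome and gene ids in tree leaf labels. Reserved:
#: neither id may contain it.
LEAF_SEP = "|"


def leaf_label(genome_id: str, gene_id: str) -> str:
    """Join a genome id and gene id into a tree leaf label."""
    return f"{genome_id}{LEAF_SEP}{gene_id}"


def split_leaf_label(label: str) -> tuple[str, str]:
    """Split a ``genome|gene`` leaf label. Species-tree leaves (no separator)
    return ``(label, "")``."""
    if LEAF_SEP in label:
        genome, gene = label.split(LEAF_SEP, 1)
        return genome, gene
    return label, ""


@dataclass
class GeneRecord:
    """One protein-coding gene: its identity, position, and translation."""

    gene_id: str
    genome_id: str
    scaffold_id: str
    order_index: int
    protein_seq: str
    function_label: Optional[str] = None

    def validate(self) -> None:
        if self.order_index < 0:
            raise ValueError(f"gene {self.gene_id}: order_index must be >= 0")
        if not self.protein_seq:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq) - _AA_SET
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-amino-acid characters {sorted(bad)}"
            )
        if LEAF_SEP in self.gene_id or LEAF_SEP in self.genome_id:
            raise ValueError(f"'{LEAF_SEP}' is reserved in gene/genome ids")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class GenomeRecord:
    """One taxon: its ordered genes plus phenotype and ecology metadata."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    phenotype: str = UNKNOWN
    ecology: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.ecology = frozenset(self.ecology)

    def validate(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"{self.genome_id}: unknown phenotype {self.phenotype}")
        bad_eco = self.ecology - set(ECOLOGIES)
        if bad_eco:
            raise ValueError(f"{self.genome_id}: unknown ecology {sorted(bad_eco)}")
        seen: dict[tuple[str, int], str] = {}
        ids = set()
        for g in self.genes:
            g.validate()
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} carries genome {g.genome_id}, "
                    f"expected {self.genome_id}"
                )
            if g.gene_id in ids:
                raise ValueError(f"{self.genome_id}: duplicate gene id {g.gene_id}")
            ids.add(g.gene_id)
            key = (g.scaffold_id, g.order_index)
            if key in seen:
                raise ValueError(
                    f"{self.genome_id}/{g.scaffold_id}: duplicate order_index "
                    f"{g.order_index} ({seen[key]}, {g.gene_id})"
                )
            seen[key] = g.gene_id
        # order indices consecutive from 0 per scaffold
        by_scaffold: dict[str, list[int]] = {}
        for g in self.genes:
            by_scaffold.setdefault(g.scaffold_id, []).append(g.order_index)
        for scaf, idx in by_scaffold.items():
            if sorted(idx) != list(range(len(idx))):
                raise ValueError(
                    f"{self.genome_id}/{scaf}: order_index not consecutive from 0"
                )

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.scaffold_id, g.order_index))

    def scaffolds(self) -> dict[str, list[GeneRecord]]:
        """Genes grouped by scaffold, sorted by order index."""
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.scaffold_id, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: g.order_index)
        return out

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.genome_id}: no gene {gene_id}")


@dataclass
class HomologGroup:
    """A set of putatively homologous genes across genomes."""

    group_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, gene_id)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    @property
    def presence(self) -> dict[str, int]:
        """Member count per genome."""
        counts: dict[str, int] = {}
        for genome_id, _ in self.members:
            counts[genome_id] = counts.get(genome_id, 0) + 1
        return counts

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Parameters:
    """Registry of every tunable threshold in the pipeline.

    Defaults are the operating points of the published workflow this package
    re-implements: homolog retrieval at e-value 1e-4 and 45% amino-acid
    similarity, synteny screening at 1e-5 and 0.40 similarity, cluster
    chaining at up to six intervening genes, boundary refinement over a
    10-gene window, MCL inflation 2.0, 100 bootstrap replicates with a 70%
    support threshold, tree reduction to <=250 leaves, a two-ancestral-node
    separation rule, duplication/transfer/loss costs 1.5/3.0/1.0, an
    edge-weight (support) collapse threshold of 1.0, the 95th loading
    percentile, niche cutoffs of 3 (dung) / 4 (wood) / 2 (ectomycorrhizal),
    alpha 0.05, and a candidate ceiling of 4 genomes.
    """

    evalue_homology: float = 1e-4
    evalue_screen: float = 1e-5
    min_sim_cluster: float = 0.45
    min_sim_synteny: float = 0.40
    max_intervening: int = 6
    boundary_window: int = 10
    mcl_inflation: float = 2.0
    n_bootstraps: int = 100
    support_threshold: int = 70  # percent
    max_clade_leaves: int = 250
    min_separating_nodes: int = 2
    dup_cost: float = 1.5
    transfer_cost: float = 3.0
    loss_cost: float = 1.0
    edge_weight_threshold: float = 1.0
    loading_percentile: float = 95.0
    niche_cutoffs: Mapping[str, int] = field(
        default_factory=lambda: {"dung": 3, "wood": 4, "ecm": 2}
    )
    alpha: float = 0.05
    candidate_max_genomes: int = 4

    def __post_init__(self) -> None:
        positive = [
            "evalue_homology", "evalue_screen", "min_sim_cluster",
            "min_sim_synteny", "mcl_inflation", "n_bootstraps",
            "support_threshold", "max_clade_leaves", "edge_weight_threshold",
            "alpha", "candidate_max_genomes",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("dup_cost", "transfer_cost", "loss_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if not 0 < self.loading_percentile < 100:
            raise ValueError("loading_percentile must lie in (0, 100)")
        if self.max_intervening < 0 or self.boundary_window < 0:
            raise ValueError("window parameters must be >= 0")
        for f_ in dataclasses.fields(self):
            default = (
                f_.default_factory() if f_.default_factory is not dataclasses.MISSING
                else f_.default
            )
            value = getattr(self, f_.name)
            if value != default:
                logger.info("non-default parameter %s=%r (default %r)",
                            f_.name, value, default)


class SupportTree:
    """A phylogenetic tree with branch lengths and integer percent supports.

    Thin wrapper over :class:`dendropy.Tree`. Supports live on internal
    nodes (``node.label``, parsed to int on demand); absence of a support is
    distinct from a support of 0. Leaf labels are ``genome|gene`` for gene
    trees and bare genome ids for species trees.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "SupportTree":
        """Parse a Newick string."""
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"Newick parse error: {exc}") from exc
        tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
        st = cls(tree)
        st._check_supports()
        return st

    @classmethod
    def read(cls, path) -> "SupportTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _check_supports(self) -> None:
        labels = set()
        for leaf in self.tree.leaf_node_iter():
            lab = leaf.taxon.label
            if lab in labels:
                raise ValueError(f"duplicate leaf label {lab}")
            labels.add(lab)
        for node, sup in self.supports().items():
            if not 0 <= sup <= 100:
                raise ValueError(f"support {sup} outside [0, 100]")

    # -- serialization -----------------------------------------------------

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True, real_value_format_specifier="",
        )
        return s.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    # -- accessors ---------------------------------------------------------

    def copy(self) -> "SupportTree":
        # newick round-trip: independent topology *and* taxon namespace
        return SupportTree.from_newick(self.as_newick())

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def leaf(self, label: str) -> dendropy.Node:
        for node in self.tree.leaf_node_iter():
            if node.taxon.label == label:
                return node
        raise KeyError(f"no leaf labelled {label}")

    @staticmethod
    def node_support(node: dendropy.Node) -> Optional[int]:
        """Integer support of an internal node, or None when absent."""
        if node.is_leaf() or node.label in (None, ""):
            return None
        try:
            return int(round(float(node.label)))
        except ValueError:
            return None

    def supports(self) -> dict[dendropy.Node, int]:
        out = {}
        for node in self.tree.preorder_internal_node_iter():
            sup = self.node_support(node)
            if sup is not None:
                out[node] = sup
        return out

    def leaf_distance_matrix(self) -> dict[tuple[str, str], float]:
        """All-pairs leaf path lengths keyed by (label_a, label_b)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        out: dict[tuple[str, str], float] = {}
        for t1 in pdm.taxon_iter():
            for t2 in pdm.taxon_iter():
                out[(t1.label, t2.label)] = pdm.distance(t1, t2)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each encoded as the leaf-label
        set on the side not containing the lexicographically first leaf."""
        labels = sorted(self.leaf_labels())
        anchor = labels[0]
        full = frozenset(labels)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_internal_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if anchor in side:
                side = full - side
            if 1 < len(side) < len(full) - 1:
                out.add(side)
        return out

    def __str__(self) -> str:
        return self.as_newick().strip()
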