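"""Genome-content ordination and niche-specific gene detection.

Works on a genome x homolog-group count matrix: groups found in a single
genome or in every genome are uninformative and dropped, the rest are
zero-centered, scaled to unit variance, and ordinated by PCA. Groups with
extreme loadings on the leading components (95th percentile of the positive,
and of the negative, loadings) are picked out and tested for functional-
category enrichment (one-tailed Fisher's exact test, Bonferroni-corrected).
Separately, groups restricted to an ecological niche (dung / wood /
ectomycorrhizal, with minimum counts of 3 / 4 / 2 genomes and zero presence
outside the niche) are extracted, and their phylogenetic distribution is
flagged when polyphyletic on the species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeRecord, HomologGroup, Parameters, SupportTree

#: ecology label used for mycorrhizal genomes in niche cutoffs
_NICHE_KEYS = {"dung": "dung", "wood": "wood", "ecm": "mycorrhizal"}


# ---------------------------------------------------------------------------
# count matrix

def build_count_matrix(groups: Sequence[HomologGroup],
                       genome_ids: Sequence[str]) -> pd.DataFrame:
    """Genome x group matrix of member counts (rows: genomes)."""
    genome_ids = sorted(genome_ids)
    data = {}
    for grp in sorted(groups, key=lambda g: g.group_id):
        presence = grp.presence
        data[grp.group_id] = [presence.get(g, 0) for g in genome_ids]
    matrix = pd.DataFrame(data, index=genome_ids, dtype=int)
    if (matrix.values < 0).any():
        raise ValueError("negative counts")
    return matrix


def build_and_filter_matrix(groups: Sequence[HomologGroup],
                            genomes: Sequence[GenomeRecord] | Sequence[str]
                            ) -> pd.DataFrame:
    """Count matrix with single-genome and universal groups removed."""
    genome_ids = [g.genome_id if isinstance(g, GenomeRecord) else g
                  for g in genomes]
    matrix = build_count_matrix(groups, genome_ids)
    n_genomes = len(genome_ids)
    present_in = (matrix > 0).sum(axis=0)
    keep = (present_in > 1) & (present_in < n_genomes)
    filtered = matrix.loc[:, keep]
    if filtered.shape[1] == 0:
        raise ValueError("no informative groups remain after filtering")
    return filtered


# ---------------------------------------------------------------------------
# ordination

@dataclass
class OrdinationResult:
    scores: pd.DataFrame        # genomes x PCs
    loadings: pd.DataFrame      # groups x PCs
    variance_fraction: np.ndarray
    dropped_constant: list[str] = field(default_factory=list)


def pca(matrix: pd.DataFrame) -> OrdinationResult:
    """PCA of the count matrix with zero-centered, unit-variance columns.

    Computed by SVD of the standardized matrix. Constant columns (unit
    variance undefined) are dropped. Sign convention: the largest-magnitude
    entry of each loading vector is positive.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genomes")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = list(matrix.columns[constant])
    values = values[:, ~constant]
    cols = matrix.columns[~constant]
    if values.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant columns")
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_pc = min(z.shape[0] - 1, z.shape[1])
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    # sign convention
    for k in range(n_pc):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s ** 2
    var_frac = var / var.sum()
    pc_names = [f"PC{k + 1}" for k in range(n_pc)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pc_names),
        loadings=pd.DataFrame(vt.T, index=cols, columns=pc_names),
        variance_fraction=var_frac,
        dropped_constant=dropped,
    )


def select_loading_groups(loadings: pd.DataFrame, pc: str | int = "PC1",
                          percentile: float = 95.0
                          ) -> tuple[list[str], list[str]]:
    """Groups with extreme loadings on one PC.

    The positive set holds groups whose loading is at or above the given
    percentile of all positive loadings; the negative set is the analogue on
    the magnitudes of negative loadings. Either set may be empty.
    """
    if isinstance(pc, int):
        pc = f"PC{pc}"
    vec = loadings[pc]
    pos = vec[vec > 0]
    neg = -vec[vec < 0]
    positive_set: list[str] = []
    negative_set: list[str] = []
    if len(pos):
        cut = np.percentile(pos.to_numpy(), percentile)
        positive_set = sorted(pos[pos >= cut].index)
    if len(neg):
        cut = np.percentile(neg.to_numpy(), percentile)
        negative_set = sorted(neg[neg >= cut].index)
    return positive_set, negative_set


# ---------------------------------------------------------------------------
# enrichment

@dataclass
class EnrichmentResult:
    category: str
    n_selected_in: int
    n_selected_out: int
    n_background_in: int
    n_background_out: int
    p_value: float
    p_bonferroni: float
    significant: bool


def category_enrichment(selected_groups: Iterable[str],
                        annotations: Mapping[str, str],
                        background_groups: Iterable[str],
                        alpha: float = 0.05,
                        n_tests: int = 4) -> list[EnrichmentResult]:
    """One-tailed Fisher enrichment of functional categories.

    For each category, the 2x2 table (selected vs not) x (in category vs
    not) is tested for over-representation; p-values are Bonferroni-scaled
    by ``n_tests`` (the number of loading sets examined; 4 by default:
    +PC1, -PC1, +PC2, -PC2).
    """
    background = sorted(set(background_groups))
    selected = set(selected_groups) & set(background)
    annotated = {g: annotations[g] for g in background if g in annotations}
    categories = sorted(set(annotated.values()))
    results = []
    for cat in categories:
        in_cat = {g for g, c in annotated.items() if c == cat}
        a = len(selected & in_cat)
        b = len(selected - in_cat)
        c = len(in_cat - selected)
        d = len(set(background)) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        p_adj = min(p * n_tests, 1.0)
        results.append(EnrichmentResult(
            category=cat, n_selected_in=a, n_selected_out=b,
            n_background_in=c, n_background_out=d,
            p_value=float(p), p_bonferroni=float(p_adj),
            significant=p_adj < alpha))
    return results


# ---------------------------------------------------------------------------
# niche-specific groups

@dataclass
class NicheGroups:
    niche: str
    groups: list[str]
    polyphyletic: dict = field(default_factory=dict)  # group -> bool


def niche_specific_groups(presence: pd.DataFrame,
                          ecology: Mapping[str, frozenset | set],
                          species_tree: Optional[SupportTree] = None,
                          cutoffs: Optional[Mapping[str, int]] = None,
                          ) -> dict[str, NicheGroups]:
    """Groups restricted to one ecological niche.

    ``presence`` is a genome x group boolean/count frame. For each niche a
    group qualifies when present in at least the cutoff number of genomes
    carrying the niche label and absent from every genome *not* carrying
    it. Genomes with two ecology labels count toward both of their niches
    and never disqualify a group for either. When a species tree is given,
    each qualifying group is flagged polyphyletic if its presence set is
    not a clade.
    """
    cutoffs = dict(cutoffs or Parameters().niche_cutoffs)
    genomes = list(presence.index)
    missing = [g for g in genomes if g not in ecology]
    if missing:
        raise ValueError(f"genomes without ecology labels: {missing}")
    ecology = {g: frozenset(v) for g, v in ecology.items()}

    clades: Optional[set[frozenset]] = None
    if species_tree is not None:
        clades = {
            frozenset(lf.taxon.label for lf in node.leaf_iter())
            for node in species_tree.tree.preorder_node_iter()}

    out: dict[str, NicheGroups] = {}
    boolean = presence.astype(bool)
    for niche_key, cutoff in sorted(cutoffs.items()):
        label = _NICHE_KEYS.get(niche_key, niche_key)
        in_niche = [g for g in genomes if label in ecology[g]]
        outside = [g for g in genomes if label not in ecology[g]]
        result = NicheGroups(niche=niche_key, groups=[])
        for grp in boolean.columns:
            col = boolean[grp]
            n_in = int(col.loc[in_niche].sum()) if in_niche else 0
            n_out = int(col.loc[outside].sum()) if outside else 0
            if n_in >= cutoff and n_out == 0:
                result.groups.append(grp)
                if clades is not None:
                    present_set = frozenset(presence.index[col])
                    result.polyphyletic[grp] = present_set not in clades
        result.groups.sort()
        out[niche_key] = result
    return out
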