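"""Phenotype filtering, co-localization chaining, boundary refinement,
and synteny detection."""

import pytest
from hypothesis import given, strategies as st

from mycocluster.core import (GeneRecord, GenomeRecord, HomologGroup,
                              Parameters, PS_MINUS, PS_PLUS)
from mycocluster.discovery import (ClusterLocus, _chain_positions,
                                   detect_synteny, filter_counts_report,
                                   find_colocalized, refine_boundaries,
                                   taxon_filter_groups)
from mycocluster.evaluation import _chain_oracle
from conftest import make_genome


def _group(gid, genome_ids):
    return HomologGroup(group_id=gid, members=frozenset(
        (g, f"{g}_{gid}") for g in genome_ids))


@pytest.fixture
def six_genomes():
    producers = [f"P{i}" for i in range(1, 4)]
    negatives = [f"N{i}" for i in range(1, 4)]
    out = []
    for gid in producers:
        out.append(GenomeRecord(genome_id=gid, phenotype=PS_PLUS))
    for gid in negatives:
        out.append(GenomeRecord(genome_id=gid, phenotype=PS_MINUS))
    return out


class TestTaxonFilter:
    def test_group_in_all_producers_only_is_retained_at_every_level(
            self, six_genomes):
        grp = _group("g", ["P1", "P2", "P3"])
        for max_neg in (0, 1, 2, 3):
            assert taxon_filter_groups([grp], six_genomes, max_neg) == [grp]

    def test_group_missing_one_producer_is_always_discarded(self, six_genomes):
        grp = _group("g", ["P1", "P2", "N1", "N2"])
        for max_neg in (0, 1, 2, 3):
            assert taxon_filter_groups([grp], six_genomes, max_neg) == []

    def test_two_negatives_fail_the_candidate_level(self, six_genomes):
        grp = _group("g", ["P1", "P2", "P3", "N1", "N2"])
        assert taxon_filter_groups([grp], six_genomes, max_negative=1) == []
        # at looser levels the genome-count ceiling (4) still applies
        assert taxon_filter_groups(
            [grp], six_genomes, max_negative=2,
            params=Parameters(candidate_max_genomes=6)) == [grp]

    def test_no_producers_declared_is_an_error(self):
        genomes = [GenomeRecord(genome_id="N1", phenotype=PS_MINUS)]
        with pytest.raises(ValueError, match="PS\\+"):
            taxon_filter_groups([_group("g", ["N1"])], genomes)

    def test_filter_monotone_in_max_negative(self, six_genomes):
        groups = [
            _group("a", ["P1", "P2", "P3"]),
            _group("b", ["P1", "P2", "P3", "N1"]),
            _group("c", ["P1", "P2", "P3", "N1", "N2"]),
        ]
        params = Parameters(candidate_max_genomes=6)
        sizes = [len(taxon_filter_groups(groups, six_genomes, k, params))
                 for k in (0, 1, 2, 3)]
        assert sizes == sorted(sizes)


class TestFilterCounts:
    def test_bookkeeping_identity(self, six_genomes):
        groups = [
            _group("a", ["P1", "P2", "P3"]),
            _group("b", ["P1", "P2", "P3", "N1", "N2", "N3"]),  # universal
            _group("c", ["P1", "N1"]),
        ]
        rep = filter_counts_report(groups, six_genomes)
        assert rep.total_groups == 3
        assert rep.in_all_producers == 2
        assert rep.in_all_genomes == 1
        assert rep.remaining_after_universal == 1
        assert rep.candidates == 1

    def test_all_universal_leaves_nothing(self, six_genomes):
        groups = [_group("a", ["P1", "P2", "P3", "N1", "N2", "N3"])]
        rep = filter_counts_report(groups, six_genomes)
        assert rep.remaining_after_universal == 0

    def test_disjoint_singletons_have_no_producer_groups(self, six_genomes):
        groups = [_group(f"s{i}", [g.genome_id])
                  for i, g in enumerate(six_genomes)]
        rep = filter_counts_report(groups, six_genomes)
        assert rep.in_all_producers == 0


def _positions_genome(positions, n_genes=40, genome_id="P1"):
    specs = [("s1", i, f"{genome_id}_x{i}") for i in range(n_genes)]
    genome = make_genome(genome_id, PS_PLUS, specs)
    groups = [HomologGroup(group_id=f"cand{k}", members=frozenset(
        {(genome_id, f"{genome_id}_x{p}"), ("P2", f"P2_y{k}")}))
        for k, p in enumerate(positions)]
    return genome, groups


class TestColocalization:
    def test_six_intervening_genes_form_one_locus(self):
        genome, groups = _positions_genome([10, 17])
        loci = find_colocalized(groups, [genome])
        assert len(loci) == 1
        assert (loci[0].start_index, loci[0].end_index) == (10, 17)

    def test_seven_intervening_genes_do_not(self):
        genome, groups = _positions_genome([10, 18])
        assert find_colocalized(groups, [genome]) == []

    def test_transitive_chaining_merges_three_candidates(self):
        genome, groups = _positions_genome([3, 8, 14])
        loci = find_colocalized(groups, [genome])
        assert len(loci) == 1
        assert len(loci[0].members) == 3

    def test_single_group_runs_do_not_count(self):
        # two genes of the SAME group within range: not a reportable locus
        genome, _ = _positions_genome([10, 12])
        grp = HomologGroup(group_id="dup", members=frozenset(
            {("P1", "P1_x10"), ("P1", "P1_x12")}))
        assert find_colocalized([grp], [genome]) == []

    @given(st.lists(st.integers(0, 199), min_size=2, max_size=30,
                    unique=True),
           st.sampled_from([0, 3, 6, 10]))
    def test_chaining_equals_brute_force_oracle(self, positions, gap):
        got = sorted(tuple(c) for c in _chain_positions(positions, gap))
        assert got == _chain_oracle(positions, gap)

    def test_loci_invariant_under_scaffold_reversal(self):
        positions = [3, 8, 14, 30, 33]
        n = 40
        genome, groups = _positions_genome(positions, n_genes=n)
        loci_fwd = find_colocalized(groups, [genome])
        rev_genome, _ = _positions_genome([n - 1 - p for p in positions],
                                          n_genes=n)
        rev_groups = [HomologGroup(
            group_id=f"cand{k}",
            members=frozenset({("P1", f"P1_x{n - 1 - p}"), ("P2", f"P2_y{k}")}))
            for k, p in enumerate(positions)]
        loci_rev = find_colocalized(rev_groups, [genome] if False else [rev_genome])
        spans_fwd = sorted((l.end_index - l.start_index, len(l.members))
                           for l in loci_fwd)
        spans_rev = sorted((l.end_index - l.start_index, len(l.members))
                           for l in loci_rev)
        assert spans_fwd == spans_rev


def _refinement_setup():
    """Three producers, one negative; a 2-gene seed locus in P1 with one
    admissible flank (PS+-only group, 4 genes away, syntenic in P2) and one
    inadmissible flank (universal group)."""
    genomes = []
    groups = []
    # P1 layout: [flankU]=idx2, seed=idx6, seed=idx7, [flankA]=idx11
    specs = [("s1", i, f"P1_x{i}") for i in range(20)]
    genomes.append(make_genome("P1", PS_PLUS, specs))
    genomes.append(make_genome("P2", PS_PLUS,
                               [("s1", i, f"P2_x{i}") for i in range(20)]))
    genomes.append(make_genome("P3", PS_PLUS,
                               [("s1", i, f"P3_x{i}") for i in range(20)]))
    for neg in ("N1", "N2", "N3"):
        genomes.append(make_genome(neg, PS_MINUS,
                                   [("s1", i, f"{neg}_x{i}")
                                    for i in range(20)]))

    def grp(gid, members):
        return HomologGroup(group_id=gid, members=frozenset(members))

    groups.append(grp("seedA", {("P1", "P1_x6"), ("P2", "P2_x5"),
                                ("P3", "P3_x5")}))
    groups.append(grp("seedB", {("P1", "P1_x7"), ("P2", "P2_x6"),
                                ("P3", "P3_x6")}))
    # admissible flank: producers only, 4 genes from the seed, near the
    # sibling locus in P2
    groups.append(grp("flankA", {("P1", "P1_x11"), ("P2", "P2_x8"),
                                 ("P3", "P3_x15")}))
    # inadmissible: present in every genome
    groups.append(grp("flankU", {("P1", "P1_x2"), ("P2", "P2_x2"),
                                 ("P3", "P3_x2"), ("N1", "N1_x2"),
                                 ("N2", "N2_x2"), ("N3", "N3_x2")}))
    locus = ClusterLocus(genome_id="P1", scaffold_id="s1",
                         members=[("P1_x6", "seedA"), ("P1_x7", "seedB")],
                         start_index=6, end_index=7, n_intervening_max=6)
    sibling = ClusterLocus(genome_id="P2", scaffold_id="s1",
                           members=[("P2_x5", "seedA"), ("P2_x6", "seedB")],
                           start_index=5, end_index=6, n_intervening_max=6)
    return genomes, groups, locus, sibling


class TestBoundaryRefinement:
    def test_universal_flank_not_admitted(self):
        genomes, groups, locus, sib = _refinement_setup()
        refined = refine_boundaries(locus, genomes, groups,
                                    sibling_loci=[sib])
        assert "P1_x2" not in refined.gene_ids

    def test_producer_flank_within_window_admitted(self):
        genomes, groups, locus, sib = _refinement_setup()
        refined = refine_boundaries(locus, genomes, groups,
                                    sibling_loci=[sib])
        assert "P1_x11" in refined.gene_ids
        assert refined.end_index == 11

    def test_no_candidate_flanks_is_a_fixpoint(self):
        genomes, groups, locus, sib = _refinement_setup()
        groups = [g for g in groups if g.group_id in ("seedA", "seedB")]
        refined = refine_boundaries(locus, genomes, groups,
                                    sibling_loci=[sib])
        assert refined.members == locus.members

    def test_without_sibling_loci_phenotype_filter_alone_admits(self):
        genomes, groups, locus, _ = _refinement_setup()
        refined = refine_boundaries(locus, genomes, groups, sibling_loci=None)
        assert "P1_x11" in refined.gene_ids


class TestSynteny:
    def test_locus_against_own_genome_returns_itself(self):
        genomes, groups, locus, sib = _refinement_setup()
        blocks = detect_synteny(locus, [genomes[0]])
        own = [b for b in blocks if b.genome_b == "P1"]
        assert len(own) == 1
        assert own[0].span_b == (6, 7)

    def test_homologs_eight_genes_apart_form_no_block(self):
        # target genome carries homologs of both locus genes but 8 apart
        genomes, groups, locus, _ = _refinement_setup()
        target = make_genome("T1", PS_MINUS,
                             [("s1", i, f"T1_x{i}") for i in range(20)])
        g1 = genomes[0].gene("P1_x6")
        g2 = genomes[0].gene("P1_x7")
        target.genes[2] = GeneRecord("T1_x2", "T1", "s1", 2, g1.protein_seq)
        target.genes[11] = GeneRecord("T1_x11", "T1", "s1", 11,
                                      g2.protein_seq)
        blocks = detect_synteny(locus, [genomes[0], target])
        assert [b for b in blocks if b.genome_b == "T1"] == []

    def test_planted_clusters_recovered_as_blocks(self, default_dataset):
        from mycocluster.workflow import discover_clusters
        genomes, truth = default_dataset
        result = discover_clusters(genomes)
        locus = result.final_loci[0]
        blocks = detect_synteny(locus, genomes, edges=result.edges)
        found = {b.genome_b for b in blocks
                 if len({q for q, _ in b.anchor_pairs}) >= 2}
        assert set(truth.producers) <= found
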