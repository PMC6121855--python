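"""Generator behavior: determinism, limit cases, and the statistical
properties the downstream analyses rely on."""

import numpy as np
import pytest

from mycocluster.core import SupportTree
from mycocluster.simulate import (SimulationConfig, HGTEvent,
                                  evolve_sequences_on_tree,
                                  simulate_dataset, simulate_gene_content,
                                  simulate_species_tree, substream)


class TestSpeciesTree:
    def test_deterministic_given_seed(self):
        a = simulate_species_tree(SimulationConfig(seed=1))
        b = simulate_species_tree(SimulationConfig(seed=1))
        assert a.tree.as_newick() == b.tree.as_newick()
        assert a.producers == b.producers

    def test_leaf_and_internal_node_counts(self):
        sp = simulate_species_tree(SimulationConfig(seed=3, n_taxa=6))
        assert len(sp.tree.leaf_labels()) == 6
        internal = list(sp.tree.tree.preorder_internal_node_iter())
        assert len(internal) == 5  # rooted binary: n-1 internal nodes

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            simulate_species_tree(SimulationConfig(seed=1, n_taxa=3))

    def test_pure_dung_probabilities_label_every_taxon_dung(self):
        cfg = SimulationConfig(
            seed=5, ecology_probs={"dung": 1.0, "wood": 0.0,
                                   "mycorrhizal": 0.0},
            dual_ecology_prob=0.0)
        sp = simulate_species_tree(cfg)
        assert all(eco == frozenset({"dung"}) for eco in sp.ecology.values())


class TestGeneContent:
    def test_zero_loss_root_present_family_everywhere(self):
        cfg = SimulationConfig(seed=7, gain_rate=0.0, loss_rate=0.0,
                               root_presence=1.0, n_background_families=50)
        sp = simulate_species_tree(cfg)
        presence, _ = simulate_gene_content(sp, cfg)
        assert presence.values.all()

    def test_zero_rates_root_absent_family_nowhere(self):
        cfg = SimulationConfig(seed=7, gain_rate=0.0, loss_rate=0.0,
                               root_presence=0.0, n_background_families=50)
        sp = simulate_species_tree(cfg)
        presence, _ = simulate_gene_content(sp, cfg)
        assert not presence.values.any()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, gain_rate=-0.1).validate()

    def test_branch_change_frequency_matches_markov_expectation(self):
        """Empirical per-branch loss frequency across 2000 families agrees
        with the closed-form two-state transition probability to 3 s.e."""
        cfg = SimulationConfig(seed=11, n_background_families=2000,
                               gain_rate=0.1, loss_rate=0.4,
                               root_presence=1.0)
        sp = simulate_species_tree(cfg)
        _, truth = simulate_gene_content(sp, cfg)
        tree = sp.tree.tree
        checked = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            pkey = (node.parent_node.taxon.label
                    if node.parent_node.is_leaf() else node.parent_node.label)
            key = node.taxon.label if node.is_leaf() else node.label
            parent_state = truth.node_states[pkey]
            child_state = truth.node_states[key]
            t = node.edge.length
            tot = cfg.gain_rate + cfg.loss_rate
            p_loss = cfg.loss_rate / tot * (1 - np.exp(-tot * t))
            among_present = parent_state.nonzero()[0]
            n = len(among_present)
            if n < 300:
                continue
            emp = float(np.mean(~child_state[among_present]))
            se = np.sqrt(p_loss * (1 - p_loss) / n)
            assert abs(emp - p_loss) <= 3 * se + 1e-12
            checked += 1
        assert checked >= 3


class TestSequences:
    def test_zero_branch_lengths_give_identical_sequences(self):
        t = SupportTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        seqs = evolve_sequences_on_tree(t, 80, substream(1, "x"))
        assert len(set(seqs.values())) == 1

    def test_divergence_increases_with_path_length(self):
        """Mean p-distance over replicates is smaller at path length 0.1
        than at 1.0 (Monte-Carlo check of the substitution process)."""
        short = SupportTree.from_newick("(A:0.05,B:0.05);")
        long = SupportTree.from_newick("(A:0.5,B:0.5);")
        def mean_p(tree, tag):
            ps = []
            for r in range(100):
                seqs = evolve_sequences_on_tree(
                    tree, 120, substream(r, tag))
                a, b = seqs["A"], seqs["B"]
                ps.append(sum(x != y for x, y in zip(a, b)) / len(a))
            return np.mean(ps)
        p_short = mean_p(short, "short")
        p_long = mean_p(long, "long")
        assert p_short < p_long
        # closed-form sanity: expected p at t is 1 - sum_i pi_i P_ii(t)
        from mycocluster import seqmodel
        pi = seqmodel.stationary_frequencies()
        for t, emp in ((0.1, p_short), (1.0, p_long)):
            P = seqmodel.transition_matrix(t)
            expected = 1.0 - float(pi @ np.diag(P))
            assert abs(emp - expected) < 0.05

    def test_seed_determinism(self):
        t = SupportTree.from_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        s1 = evolve_sequences_on_tree(t, 50, substream(9, "d"))
        s2 = evolve_sequences_on_tree(t, 50, substream(9, "d"))
        assert s1 == s2


class TestClusterPlanting:
    def test_cluster_contiguous_in_every_producer(self, default_dataset):
        genomes, truth = default_dataset
        by_id = {g.genome_id: g for g in genomes}
        assert sorted(truth.cluster_genes) == sorted(truth.producers)
        for genome_id, gene_ids in truth.cluster_genes.items():
            genome = by_id[genome_id]
            members = [genome.gene(gid) for gid in gene_ids]
            scaffolds = {m.scaffold_id for m in members}
            assert len(scaffolds) == 1
            idx = sorted(m.order_index for m in members)
            assert idx == list(range(idx[0], idx[0] + len(members)))

    def test_cluster_absent_from_nonproducers(self, default_dataset):
        genomes, truth = default_dataset
        producers = set(truth.producers)
        for genome in genomes:
            has_cluster = any("clu_" in g.gene_id for g in genome.genes)
            assert has_cluster == (genome.genome_id in producers)

    def test_no_hgt_gene_trees_congruent_with_species_tree(self):
        cfg = SimulationConfig(seed=21, hgt_events=[])
        genomes, truth = simulate_dataset(cfg)
        species = truth.species_tree
        prod = set(truth.producers)
        for fam in truth.cluster_families:
            gtree = SupportTree.from_newick(truth.family_trees[fam])
            species_side = {l.split("|")[0] for l in gtree.leaf_labels()}
            assert species_side == prod
            # compare restricted species-tree splits with gene-tree splits
            restricted = {frozenset(s.split("|")[0] for s in bp)
                          for bp in gtree.bipartitions()}
            species_bps = set()
            for node in species.tree.preorder_internal_node_iter():
                side = frozenset(lf.taxon.label
                                 for lf in node.leaf_iter()) & prod
                if 1 < len(side) < len(prod):
                    species_bps.add(side)
            assert all(bp in species_bps or (prod - bp) in species_bps
                       for bp in restricted)

    def test_hgt_recipient_nests_inside_donor_lineage(self, default_dataset):
        _, truth = default_dataset
        ev = truth.hgt_events[0]
        fam_tree = SupportTree.from_newick(truth.family_trees[ev.family_id])
        donor_leaf = f"{ev.donor}|{ev.donor}_{ev.family_id}"
        rec_leaf = f"{ev.recipient}|{ev.recipient}_{ev.family_id}"
        dm = fam_tree.leaf_distance_matrix()
        others = [l for l in fam_tree.leaf_labels()
                  if l not in (donor_leaf, rec_leaf)]
        assert all(dm[(rec_leaf, donor_leaf)] < dm[(rec_leaf, o)]
                   for o in others)

    def test_cluster_hgt_to_nonproducer_rejected(self):
        cfg = SimulationConfig(
            seed=1, producer_taxa=["G01", "G02", "G03"],
            hgt_events=[HGTEvent(donor="G01", recipient="G06",
                                 kind="cluster")])
        with pytest.raises(ValueError, match="not a producer"):
            simulate_dataset(cfg)


class TestConservation:
    def test_gene_counts_equal_family_presence(self, small_dataset):
        genomes, truth = small_dataset
        for genome in genomes:
            expected = sum(1 for fam, pres in truth.family_presence.items()
                           if genome.genome_id in pres)
            assert len(genome.genes) == expected

    def test_bitwise_reproducibility(self, small_dataset):
        genomes, truth = small_dataset
        cfg = SimulationConfig(seed=2, n_background_families=60)
        genomes2, truth2 = simulate_dataset(cfg)
        assert truth.species_newick == truth2.species_newick
        a = [(g.genome_id, g.gene_id, g.protein_seq)
             for gen in genomes for g in gen.genes]
        b = [(g.genome_id, g.gene_id, g.protein_seq)
             for gen in genomes2 for g in gen.genes]
        assert a == b


class TestTruthLogIO:
    def test_truth_log_roundtrip(self, small_dataset, tmp_path):
        _, truth = small_dataset
        truth.write(tmp_path / "truth.json")
        back = type(truth).read(tmp_path / "truth.json")
        assert back.species_newick == truth.species_newick
        assert back.family_presence == truth.family_presence
        assert back.cluster_genes == truth.cluster_genes
        assert [vars(e) for e in back.hgt_events] == \
            [vars(e) for e in truth.hgt_events]
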