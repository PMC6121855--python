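"""Distances, neighbor joining, bootstrap, rooting, consensus, likelihoods
and the RELL topology test."""

import math

import numpy as np
import pytest

from mycocluster import seqmodel
from mycocluster.core import Parameters, SupportTree
from mycocluster.phylo import (DistanceMatrix, _consensus_tree,
                               bootstrap_tree, build_species_tree,
                               fit_branch_lengths_ols, mean_internal_support,
                               nj_tree, nj_tree_constrained, pad_alignment,
                               poisson_distance, reduce_to_supported_clade,
                               rell_test, root_at_most_distant, site_loglik,
                               trim_columns)
from mycocluster.simulate import (SimulationConfig, evolve_sequences_on_tree,
                                  simulate_species_tree, substream)


class TestTrim:
    def test_gapless_alignment_unchanged(self):
        aln = {"A": "MKLV", "B": "MKIV"}
        assert trim_columns(aln) == aln

    def test_all_gap_column_removed(self):
        aln = {"A": "M-LV", "B": "M-IV"}
        assert trim_columns(aln) == {"A": "MLV", "B": "MIV"}

    def test_mixed_columns_against_hand_count(self):
        # column gap fractions: 0, 1/3, 1/3, 2/3 -> drop only the last
        aln = {"A": "M-KV", "B": "MLK-", "C": "ML--"}
        assert trim_columns(aln, 0.5) == {"A": "M-K", "B": "MLK", "C": "ML-"}

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_columns({"A": "MKL", "B": "MK"})


class TestPoissonDistance:
    def test_identical_pair_has_zero_distance(self):
        dm = poisson_distance({"A": "MKLV", "B": "MKLV"})
        assert dm.get("A", "B") == 0.0

    def test_half_different_gives_ln2(self):
        dm = poisson_distance({"A": "AAAA", "B": "AACC"})
        assert dm.get("A", "B") == pytest.approx(math.log(2.0))

    def test_saturation_capped(self):
        dm = poisson_distance({"A": "AAAA", "B": "CCCC"})
        assert dm.get("A", "B") == pytest.approx(-math.log(0.05))

    def test_no_shared_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="A and B"):
            poisson_distance({"A": "MK--", "B": "--LV"})

    def test_symmetry_on_random_input(self):
        rng = substream(1, "pdist")
        aas = "ACDEFGHIKLMNPQRSTVWY"
        aln = {f"T{i}": "".join(aas[j] for j in rng.integers(0, 20, 60))
               for i in range(5)}
        dm = poisson_distance(aln)
        assert np.allclose(dm.values, dm.values.T)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> lA=1, lB=2, lC=3
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.]]))
        t = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in t.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> unique additive topology
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                      [5, 6, 0, 4], [3, 4, 4, 0.]]))
        t = nj_tree(dm)
        assert t.bipartitions() == {frozenset({"C", "D"})}
        est = t.leaf_distance_matrix()
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                assert abs(est[(a, b)] - dm.values[i, j]) < 1e-9

    def test_deterministic_under_ties(self):
        # perfectly symmetric distances: output fixed by lexicographic rule
        n = 5
        vals = np.full((n, n), 2.0)
        np.fill_diagonal(vals, 0.0)
        labels = ["E", "D", "C", "B", "A"]
        t1 = nj_tree(DistanceMatrix(labels, vals))
        t2 = nj_tree(DistanceMatrix(labels, vals))
        assert t1.as_newick() == t2.as_newick()

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))

    def test_constrained_clade_is_enforced(self):
        rng = substream(3, "cnj")
        cfg = SimulationConfig(seed=8, n_taxa=7)
        species = simulate_species_tree(cfg)
        aln = evolve_sequences_on_tree(species.tree, 200, rng)
        labels = sorted(aln)
        clade = labels[:3]
        t = nj_tree_constrained(poisson_distance(aln), clade)
        full = frozenset(labels)
        enc = frozenset(clade)
        if labels[0] in enc:
            enc = full - enc
        assert enc in t.bipartitions()


class TestBootstrap:
    def test_supports_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=4, n_taxa=6)
        species = simulate_species_tree(cfg)
        aln = evolve_sequences_on_tree(species.tree, 200,
                                       substream(4, "boot"))
        t1 = bootstrap_tree(aln, 50, seed=99)
        t2 = bootstrap_tree(aln, 50, seed=99)
        assert t1.as_newick() == t2.as_newick()

    def test_strong_signal_gives_high_supports(self):
        cfg = SimulationConfig(seed=5, n_taxa=6)
        species = simulate_species_tree(cfg)
        for edge in species.tree.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = max(edge.length, 0.15)
        aln = evolve_sequences_on_tree(species.tree, 2000,
                                       substream(5, "boot_strong"))
        t = bootstrap_tree(aln, 50, seed=1)
        assert min(t.supports().values()) >= 95

    def test_star_data_gives_low_internal_supports(self):
        # zero internal branches: splits are noise, supports low
        t_star = SupportTree.from_newick(
            "((A:0.3,B:0.3):0.0,(C:0.3,D:0.3):0.0,(E:0.3,F:0.3):0.0);")
        aln = evolve_sequences_on_tree(t_star, 300,
                                       substream(6, "boot_star"))
        t = bootstrap_tree(aln, 100, seed=2)
        assert min(t.supports().values()) < 70

    def test_nonpositive_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_tree({"A": "MK", "B": "MK", "C": "MK"}, 0, seed=1)


class TestRooting:
    def test_root_on_most_distant_leaf(self):
        t = SupportTree.from_newick("(q:1,(a:0.5,b:4.0):0.5);")
        rooted = root_at_most_distant(t, "q")
        root_kids = rooted.tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in root_kids]
        assert {"b"} in sides

    def test_tie_breaks_to_lexicographically_smaller(self):
        t = SupportTree.from_newick("(q:1,(a:2.0,b:2.0):1);")
        rooted = root_at_most_distant(t, "q")
        sides = [{lf.taxon.label for lf in k.leaf_iter()}
                 for k in rooted.tree.seed_node.child_nodes()]
        assert {"a"} in sides

    def test_root_leaf_attains_max_path_length(self):
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_taxa=7)
            species = simulate_species_tree(cfg)
            tree = species.tree
            q = sorted(tree.leaf_labels())[0]
            rooted = root_at_most_distant(tree, q)
            dm = tree.leaf_distance_matrix()
            best = max(d for (a, b), d in dm.items() if a == q)
            sides = [{lf.taxon.label for lf in k.leaf_iter()}
                     for k in rooted.tree.seed_node.child_nodes()]
            single = [s for s in sides if len(s) == 1]
            assert single and dm[(q, next(iter(single[0])))] == \
                pytest.approx(best)

    def test_missing_lengths_rejected(self):
        t = SupportTree.from_newick("(q,(a,b));")
        with pytest.raises(ValueError, match="lengths"):
            root_at_most_distant(t, "q")

    def test_supports_preserved_across_rooting(self):
        t = SupportTree.from_newick(
            "((A:1,B:1)90:1,(C:1,D:1)75:1,E:3);")
        rooted = root_at_most_distant(t, "A")
        by_split = {}
        for node, sup in rooted.supports().items():
            by_split[frozenset(lf.taxon.label
                               for lf in node.leaf_iter())] = sup
        assert by_split.get(frozenset({"C", "D"})) == 75


class TestConsensus:
    def test_identical_trees_yield_that_topology_at_full_support(self):
        t = SupportTree.from_newick("((A,B),(C,D),E);")
        cons = _consensus_tree([t, t, t])
        assert cons.bipartitions() == t.bipartitions()
        assert set(cons.supports().values()) == {100}

    def test_majority_bipartition_retained_in_60_40_split(self):
        a = SupportTree.from_newick("((A,B),(C,D),E);")
        b = SupportTree.from_newick("((A,C),(B,D),E);")
        cons = _consensus_tree([a, a, a, b, b])
        assert frozenset({"C", "D"}) in cons.bipartitions() or \
            frozenset({"A", "B"}) in {s for s in cons.bipartitions()} or \
            frozenset({"B", "C", "D", "E"}) in cons.bipartitions()
        # the 60% splits win; the 40% splits must be absent
        assert frozenset({"B", "D"}) not in cons.bipartitions()


class TestSpeciesTree:
    def test_consensus_recovers_generating_topology(self, small_dataset):
        from mycocluster.homology import homolog_groups
        genomes, truth = small_dataset
        genes = [g for gen in genomes for g in gen.genes]
        groups, _ = homolog_groups(genes, Parameters())
        res = build_species_tree(genomes, groups,
                                 Parameters(n_bootstraps=50),
                                 seed=2, quota=20)
        assert res.quota_met
        assert res.tree.bipartitions() == truth.species_tree.bipartitions()


class TestSiteLoglik:
    def test_zero_branch_identical_sequences_give_log_pi(self):
        t = SupportTree.from_newick("(A:0,B:0);")
        pi = seqmodel.stationary_frequencies()
        ll = site_loglik(t, {"A": "AC", "B": "AC"})
        idx = [seqmodel.AA_INDEX["A"], seqmodel.AA_INDEX["C"]]
        assert np.allclose(ll, np.log(pi[idx]))

    def test_two_leaf_tree_matches_matrix_exponential_oracle(self):
        from scipy.linalg import expm
        t = SupportTree.from_newick("(A:0.2,B:0.3);")
        aln = {"A": "MKWV", "B": "MRWI"}
        ll = site_loglik(t, aln)
        Q = seqmodel.rate_matrix()
        pi = seqmodel.stationary_frequencies()
        P = expm(Q * 0.5)  # total path length
        for k, (ca, cb) in enumerate(zip(aln["A"], aln["B"])):
            i, j = seqmodel.AA_INDEX[ca], seqmodel.AA_INDEX[cb]
            assert ll[k] == pytest.approx(math.log(pi[i] * P[i, j]))

    def test_total_invariant_to_root_placement(self):
        cfg = SimulationConfig(seed=9, n_taxa=6)
        species = simulate_species_tree(cfg)
        aln = evolve_sequences_on_tree(species.tree, 150,
                                       substream(9, "ll"))
        t = bootstrap_tree(aln, 10, seed=3)
        rooted = root_at_most_distant(t, sorted(aln)[0])
        assert site_loglik(t, aln).sum() == pytest.approx(
            site_loglik(rooted, aln).sum())

    def test_leaf_without_sequence_rejected(self):
        t = SupportTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="no sequence"):
            site_loglik(t, {"A": "MK"})

    def test_site_logliks_are_log_probabilities(self):
        cfg = SimulationConfig(seed=10, n_taxa=5)
        species = simulate_species_tree(cfg)
        aln = evolve_sequences_on_tree(species.tree, 100,
                                       substream(10, "llp"))
        ll = site_loglik(nj_tree(poisson_distance(aln)), aln)
        assert np.all(np.isfinite(ll)) and np.all(ll <= 0)


class TestRell:
    def test_identical_topologies_never_rejected(self):
        cfg = SimulationConfig(seed=12, n_taxa=6)
        species = simulate_species_tree(cfg)
        aln = evolve_sequences_on_tree(species.tree, 200,
                                       substream(12, "rell"))
        t = nj_tree(poisson_distance(aln))
        res = rell_test(aln, t, t, n_resamples=300, seed=1)
        assert res.delta_ll == 0.0
        assert not res.reject

    def test_strongly_contradicted_constraint_rejected(self):
        t_true = SupportTree.from_newick(
            "((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);")
        aln = evolve_sequences_on_tree(t_true, 800, substream(13, "power"))
        dm = poisson_distance(aln)
        opt = fit_branch_lengths_ols(nj_tree(dm), dm)
        wrong = fit_branch_lengths_ols(SupportTree.from_newick(
            "((A:0.1,C:0.1):0.3,(B:0.1,D:0.1):0.3);"), dm)
        res = rell_test(aln, opt, wrong, n_resamples=500, seed=2)
        assert res.reject and res.p_value < 0.05

    def test_few_resamples_flagged(self):
        t = SupportTree.from_newick("(A:0.1,B:0.1);")
        aln = {"A": "MKWVMKWV", "B": "MKWIMKWV"}
        res = rell_test(aln, t, t, n_resamples=50, seed=1)
        assert res.warning


class TestBranchLengthFit:
    def test_ols_recovers_additive_lengths(self):
        cfg = SimulationConfig(seed=14, n_taxa=6)
        species = simulate_species_tree(cfg)
        dm_map = species.tree.leaf_distance_matrix()
        labels = sorted(species.tree.leaf_labels())
        dm = DistanceMatrix(labels, np.array(
            [[dm_map[(a, b)] for b in labels] for a in labels]))
        refit = fit_branch_lengths_ols(species.tree, dm)
        refit_map = refit.leaf_distance_matrix()
        assert all(abs(refit_map[k] - dm_map[k]) < 1e-6 for k in dm_map)


class TestCladeReduction:
    def test_small_tree_qualifies_whole(self):
        t = SupportTree.from_newick("((A:1,B:1)100:1,(C:1,D:1)100:1);")
        leaves, ok = reduce_to_supported_clade(t, ["A"])
        assert ok and leaves == ["A", "B", "C", "D"]

    def test_supported_subclade_extracted_from_large_tree(self):
        # 300 leaves; the query sits in a 40-leaf clade with support 90
        inner = "(" + ",".join(f"q{i}:1" for i in range(40)) + ")90"
        outer = ",".join(f"x{i}:1" for i in range(260))
        t = SupportTree.from_newick(f"({inner}:1,{outer});")
        leaves, ok = reduce_to_supported_clade(t, ["q0"])
        assert ok and len(leaves) == 40
        assert set(leaves) == {f"q{i}" for i in range(40)}

    def test_unsupported_query_falls_back_to_smallest_clade(self):
        inner = "(" + ",".join(f"q{i}:1" for i in range(40)) + ")50"
        outer = ",".join(f"x{i}:1" for i in range(260))
        t = SupportTree.from_newick(f"({inner}:1,{outer});")
        leaves, ok = reduce_to_supported_clade(t, ["q0"])
        assert not ok and len(leaves) == 40

    def test_two_queries_use_their_mrca_clade(self):
        inner1 = "(" + ",".join(f"q{i}:1" for i in range(20)) + ")95"
        inner2 = "(" + ",".join(f"r{i}:1" for i in range(20)) + ")95"
        outer = ",".join(f"x{i}:1" for i in range(260))
        t = SupportTree.from_newick(
            f"(({inner1}:1,{inner2}:1)88:1,{outer});")
        leaves, ok = reduce_to_supported_clade(t, ["q0", "r0"])
        assert ok and len(leaves) == 40
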