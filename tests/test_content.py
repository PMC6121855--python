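"""Count-matrix filtering, PCA ordination, loading selection, enrichment,
and niche-specific group detection."""

import math

import numpy as np
import pandas as pd
import pytest

from mycocluster.content import (build_and_filter_matrix, build_count_matrix,
                                 category_enrichment, niche_specific_groups,
                                 pca, select_loading_groups)
from mycocluster.core import HomologGroup, SupportTree
from mycocluster.simulate import substream


def _group(gid, genome_ids):
    return HomologGroup(group_id=gid, members=frozenset(
        (g, f"{g}_{gid}") for g in genome_ids))


GENOMES = [f"G{i}" for i in range(1, 7)]


class TestMatrix:
    def test_single_genome_group_dropped(self):
        groups = [_group("solo", ["G1"]), _group("pair", ["G1", "G2"])]
        m = build_and_filter_matrix(groups, GENOMES)
        assert list(m.columns) == ["pair"]

    def test_universal_group_dropped(self):
        groups = [_group("uni", GENOMES), _group("pair", ["G1", "G2"])]
        m = build_and_filter_matrix(groups, GENOMES)
        assert list(m.columns) == ["pair"]

    def test_two_genome_group_kept(self):
        groups = [_group("pair", ["G1", "G6"])]
        m = build_and_filter_matrix(groups, GENOMES)
        assert m["pair"].sum() == 2

    def test_counts_are_member_tallies(self):
        grp = HomologGroup(group_id="multi", members=frozenset(
            {("G1", "a"), ("G1", "b"), ("G2", "c")}))
        m = build_count_matrix([grp], ["G1", "G2"])
        assert m.loc["G1", "multi"] == 2
        assert m.loc["G2", "multi"] == 1

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="no informative"):
            build_and_filter_matrix([_group("uni", GENOMES)], GENOMES)


class TestPCA:
    def test_two_distinct_duplicated_genomes_put_everything_on_pc1(self):
        rows = [[5, 0, 3, 1]] * 3 + [[0, 4, 1, 3]] * 3
        df = pd.DataFrame(rows, index=GENOMES,
                          columns=["c1", "c2", "c3", "c4"], dtype=float)
        res = pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = substream(1, "pca_unit")
        df = pd.DataFrame(rng.integers(0, 6, size=(6, 12)).astype(float),
                          index=GENOMES,
                          columns=[f"c{j}" for j in range(12)])
        df.iloc[0] += 1
        df = df.loc[:, df.std(ddof=1) > 0]
        res = pca(df)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_row_permutation_permutes_scores(self):
        rng = substream(2, "pca_perm")
        df = pd.DataFrame(rng.integers(0, 6, size=(6, 10)).astype(float),
                          index=GENOMES,
                          columns=[f"c{j}" for j in range(10)])
        df.iloc[0] += 1
        df = df.loc[:, df.std(ddof=1) > 0]
        res1 = pca(df)
        perm = list(reversed(GENOMES))
        res2 = pca(df.loc[perm])
        assert np.allclose(res1.scores.loc[perm].to_numpy(),
                           res2.scores.to_numpy())

    def test_constant_columns_dropped_with_note(self):
        df = pd.DataFrame({"c1": [1., 1, 1, 1], "c2": [0., 1, 2, 3],
                           "c3": [3., 1, 0, 2]},
                          index=["a", "b", "c", "d"])
        res = pca(df)
        assert res.dropped_constant == ["c1"]
        assert "c1" not in res.loadings.index

    def test_sign_convention_largest_loading_positive(self):
        rng = substream(3, "pca_sign")
        df = pd.DataFrame(rng.integers(0, 9, size=(5, 8)).astype(float),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"c{j}" for j in range(8)])
        df = df.loc[:, df.std(ddof=1) > 0]
        res = pca(df)
        for pc in res.loadings.columns:
            v = res.loadings[pc].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestLoadingSelection:
    def test_uniform_positive_loadings_select_about_five_percent(self):
        rng = substream(4, "sel")
        loadings = pd.DataFrame(
            {"PC1": rng.uniform(0.001, 1.0, size=100)},
            index=[f"grp{i}" for i in range(100)])
        pos, neg = select_loading_groups(loadings, "PC1", 95.0)
        assert neg == []
        assert 5 <= len(pos) <= 6

    def test_all_negative_loadings_leave_positive_set_empty(self):
        loadings = pd.DataFrame({"PC1": [-0.5, -0.1, -0.9]},
                                index=["a", "b", "c"])
        pos, neg = select_loading_groups(loadings, "PC1")
        assert pos == []
        assert "c" in neg  # the largest-magnitude negative loading

    def test_single_positive_loading_is_selected(self):
        loadings = pd.DataFrame({"PC1": [0.7, -0.2, -0.3]},
                                index=["a", "b", "c"])
        pos, _ = select_loading_groups(loadings, "PC1")
        assert pos == ["a"]


class TestEnrichment:
    def test_diagonal_table_closed_form(self):
        selected = [f"s{i}" for i in range(10)]
        background = selected + [f"b{i}" for i in range(10)]
        annotations = {g: ("X" if g.startswith("s") else "Y")
                       for g in background}
        results = category_enrichment(selected, annotations, background,
                                      n_tests=1)
        x = next(r for r in results if r.category == "X")
        assert x.p_value == pytest.approx(1.0 / math.comb(20, 10))

    def test_no_overlap_gives_p_one(self):
        selected = ["s1", "s2"]
        background = selected + ["b1", "b2", "b3"]
        annotations = {"b1": "X", "b2": "X", "b3": "X",
                       "s1": "Y", "s2": "Y"}
        results = category_enrichment(selected, annotations, background)
        x = next(r for r in results if r.category == "X")
        assert x.p_value == pytest.approx(1.0)

    def test_bonferroni_scaling(self):
        selected = [f"s{i}" for i in range(10)]
        background = selected + [f"b{i}" for i in range(10)]
        annotations = {g: ("X" if g.startswith("s") else "Y")
                       for g in background}
        r1 = category_enrichment(selected, annotations, background,
                                 n_tests=1)[0]
        r4 = category_enrichment(selected, annotations, background,
                                 n_tests=4)[0]
        assert r4.p_bonferroni == pytest.approx(min(4 * r1.p_value, 1.0))

    def test_null_type_i_rate_controlled(self):
        """Random labels: Bonferroni-corrected rejections stay below
        alpha across simulations."""
        rng = substream(5, "enrich_null")
        n_sig = 0
        n_sims = 400
        for _ in range(n_sims):
            background = [f"g{i}" for i in range(40)]
            selected = [background[i]
                        for i in rng.choice(40, size=8, replace=False)]
            annotations = {g: ("X" if rng.random() < 0.3 else "Y")
                           for g in background}
            results = category_enrichment(selected, annotations, background,
                                          alpha=0.05, n_tests=4)
            n_sig += any(r.significant for r in results)
        assert n_sig / n_sims <= 0.05


def _presence(data, genomes):
    return pd.DataFrame(data, index=genomes).astype(bool)


class TestNicheGroups:
    ECO = {"D1": {"dung"}, "D2": {"dung"}, "D3": {"dung"},
           "W1": {"wood"}, "W2": {"wood"}, "W3": {"wood"}, "W4": {"wood"},
           "M1": {"mycorrhizal"}, "M2": {"mycorrhizal"},
           "B1": {"dung", "wood"}}
    GENOMES = list(ECO)

    def _frame(self, present):
        data = {"grp": [g in present for g in self.GENOMES]}
        return pd.DataFrame(data, index=self.GENOMES)

    def test_three_dung_only_qualifies(self):
        got = niche_specific_groups(self._frame({"D1", "D2", "D3"}),
                                    self.ECO)
        assert got["dung"].groups == ["grp"]

    def test_dung_plus_wood_contamination_excluded(self):
        got = niche_specific_groups(
            self._frame({"D1", "D2", "D3", "W1"}), self.ECO)
        assert got["dung"].groups == []

    def test_two_dung_below_cutoff(self):
        got = niche_specific_groups(self._frame({"D1", "D2"}), self.ECO)
        assert got["dung"].groups == []

    def test_dual_label_genome_counts_for_both_niches(self):
        # B1 is dung+wood: it completes a dung trio without disqualifying
        got = niche_specific_groups(self._frame({"D1", "D2", "B1"}),
                                    self.ECO)
        assert got["dung"].groups == ["grp"]
        # and completes the wood quota the same way
        got2 = niche_specific_groups(
            self._frame({"W1", "W2", "W3", "B1"}), self.ECO)
        assert got2["wood"].groups == ["grp"]

    def test_ecm_cutoff_is_two(self):
        got = niche_specific_groups(self._frame({"M1", "M2"}), self.ECO)
        assert got["ecm"].groups == ["grp"]

    def test_missing_ecology_is_an_error(self):
        eco = dict(self.ECO)
        del eco["M2"]
        with pytest.raises(ValueError, match="without ecology"):
            niche_specific_groups(self._frame({"D1"}), eco)

    def test_polyphyly_flag_false_for_clades(self):
        tree = SupportTree.from_newick(
            "(((D1,D2),(D3,B1)),((W1,(W2,(W3,W4))),(M1,M2)));")
        clade = niche_specific_groups(self._frame({"D1", "D2", "D3"}),
                                      self.ECO, species_tree=tree)
        # D1,D2,D3 is not a clade here (B1 interrupts): flagged polyphyletic
        assert clade["dung"].polyphyletic["grp"] is True
        clade2 = niche_specific_groups(
            self._frame({"D1", "D2", "D3", "B1"}), self.ECO,
            species_tree=tree)
        assert clade2["dung"].polyphyletic["grp"] is False
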