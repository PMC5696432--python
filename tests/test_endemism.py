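"""WPE, AED and IAC: hand examples, oracles and conservation identities."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from conftest import random_tree, random_abundances
from phylodistricts import (
    CommunityMatrix,
    aed,
    clade_ranges,
    endemism_table,
    faith_pd,
    iac,
    read_newick,
    weighted_phylogenetic_endemism,
)
from phylodistricts.spatial import GridSpec


def _cm(rows, plots, species):
    return CommunityMatrix(pd.DataFrame(rows, index=plots, columns=species))


class TestCladeRanges:
    def test_plot_unit_hand_example(self, quartet_tree):
        # p1 = {A,B}, p2 = {B,C} on ((A:1,B:1):1,(C:1,D:1):1)
        cm = _cm([[1, 1, 0, 0], [0, 1, 1, 0]], ["p1", "p2"], list("ABCD"))
        ranges = clade_ranges(quartet_tree, cm)
        node_of = {quartet_tree.labels[v]: v for v in range(quartet_tree.n_nodes)
                   if quartet_tree.is_tip[v]}
        assert ranges[node_of["A"]] == 1
        assert ranges[node_of["B"]] == 2
        assert ranges[node_of["C"]] == 1
        assert ranges[node_of["D"]] == 0
        # clade {A,B} occupies both plots; clade {C,D} only p2
        ab = quartet_tree.mrca({"A", "B"})
        cd = quartet_tree.mrca({"C", "D"})
        assert ranges[ab] == 2
        assert ranges[cd] == 1

    def test_grid_cells_merge_colocated_plots(self, quartet_tree):
        """Two plots in the same 0.5-degree cell count as one range unit."""
        cm = _cm(
            [[1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]],
            ["p1", "p2", "p3"],
            list("ABCD"),
        )
        coords = pd.DataFrame(
            {"lon": [-76.1, -76.2, -75.1], "lat": [-0.1, -0.2, -0.1]},
            index=pd.Index(["p1", "p2", "p3"], name="plot_id"),
        )
        node_a = quartet_tree.tip_node("A")
        r_plots = clade_ranges(quartet_tree, cm, unit="plots")
        r_cells = clade_ranges(
            quartet_tree, cm, unit="grid-cells", coords=coords,
            grid=GridSpec.from_points(
                coords["lon"].to_numpy(), coords["lat"].to_numpy()
            ),
        )
        assert r_plots[node_a] == 3
        assert r_cells[node_a] == 2

    def test_grid_cells_require_coords(self, quartet_tree):
        cm = _cm([[1, 1, 1, 1]], ["p1"], list("ABCD"))
        with pytest.raises(ValueError, match="coordinates"):
            clade_ranges(quartet_tree, cm, unit="grid-cells")

    def test_monotone_rootward(self):
        """A clade's range includes every subclade's range, so R_e never
        decreases toward the root."""
        tree = random_tree(20, seed=8)
        rng = np.random.default_rng(8)
        counts = (rng.random((10, 20)) < 0.3).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        cm = _cm(counts, [f"p{i}" for i in range(10)], tree.tip_names)
        ranges = clade_ranges(tree, cm)
        # the root itself carries no edge, so compare only edge-bearing nodes
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0 and p != tree.root:
                assert ranges[p] >= ranges[v]


class TestWPE:
    def test_hand_example(self, quartet_tree):
        cm = _cm([[1, 1, 0, 0], [0, 1, 1, 0]], ["p1", "p2"], list("ABCD"))
        wpe = weighted_phylogenetic_endemism(quartet_tree, cm)
        # p1 spans A (r=1), B (r=2), stem AB (r=2): 1 + 0.5 + 0.5 = 2.0
        assert wpe["p1"] == pytest.approx(2.0)
        # p2 spans B (2), stem AB (2), C (1), stem CD (1): 0.5+0.5+1+1 = 3.0
        assert wpe["p2"] == pytest.approx(3.0)

    def test_single_plot_equals_pd(self, cherry_tree):
        cm = _cm([[2, 1, 4]], ["solo"], ["A", "B", "C"])
        wpe = weighted_phylogenetic_endemism(cherry_tree, cm)
        assert wpe["solo"] == pytest.approx(faith_pd(cherry_tree, {"A", "B", "C"}))

    def test_bounded_by_pd(self, small_landscape):
        tree, cm = small_landscape
        wpe = weighted_phylogenetic_endemism(tree, cm)
        for p in cm.plot_ids:
            assert wpe[p] <= faith_pd(tree, set(cm.plot_species(p))) + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        tree = random_tree(12, seed=seed + 40)
        rng = np.random.default_rng(seed)
        counts = (rng.random((6, 12)) < 0.4).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        cm = _cm(counts, [f"p{i}" for i in range(6)], tree.tip_names)
        wpe = weighted_phylogenetic_endemism(tree, cm)
        dt = orc.parse(tree.to_newick())
        plot_sets = {p: set(cm.plot_species(p)) for p in cm.plot_ids}
        for p in cm.plot_ids:
            assert wpe[p] == pytest.approx(
                orc.wpe_oracle(dt, plot_sets, p), abs=1e-9
            )


class TestAED:
    def test_hand_example(self, cherry_tree):
        # plot {A:2, B:1} on ((A:1,B:1):1,C:2)
        cm = _cm([[2, 1, 0]], ["p1"], ["A", "B", "C"])
        s = aed(cherry_tree, cm, "p1")
        # AED_A = 1/2 (own edge over 2) + 1/3 (stem over 3) = 5/6
        assert s["A"] == pytest.approx(5 / 6)
        # AED_B = 1/1 + 1/3 = 4/3
        assert s["B"] == pytest.approx(4 / 3)
        # conservation: 2*(5/6) + 1*(4/3) = 3 = Faith PD of {A,B}
        assert 2 * s["A"] + 1 * s["B"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_identity(self, seed):
        """Sum of abundance x AED over a plot equals its Faith PD exactly."""
        tree = random_tree(6 + seed * 2, seed=seed + 90)
        abund = random_abundances(tree, seed=seed)
        # zero out some species so the plot is a strict subset
        names = list(abund)
        for name in names[:: 3]:
            abund[name] = 0
        present = {s: n for s, n in abund.items() if n > 0}
        if len(present) < 1:
            present = {names[1]: 2}
        cm = _cm([list(present.values())], ["p"], list(present))
        s = aed(tree, cm, "p")
        total = sum(present[sp] * s[sp] for sp in present)
        assert total == pytest.approx(faith_pd(tree, set(present)), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle(self, seed):
        tree = random_tree(10, seed=seed + 77)
        abund = random_abundances(tree, seed=seed)
        cm = _cm([list(abund.values())], ["p"], list(abund))
        s = aed(tree, cm, "p")
        want = orc.aed_oracle(orc.parse(tree.to_newick()), abund)
        for sp, v in want.items():
            assert s[sp] == pytest.approx(v, abs=1e-9)


class TestIAC:
    def test_even_split_is_zero(self, quartet_tree):
        cm = _cm([[2, 2, 0, 0]], ["p1"], list("ABCD"))
        assert iac(quartet_tree, cm, "p1") == pytest.approx(0.0)

    def test_hand_example(self, quartet_tree):
        # {A:3, B:1}: expected 2,2 at the single retained split
        cm = _cm([[3, 1, 0, 0]], ["p1"], list("ABCD"))
        assert iac(quartet_tree, cm, "p1") == pytest.approx(2.0)

    def test_two_split_example(self, quartet_tree):
        # {A:4, B:2, C:2}: root split halves N=8 into 4/4; clade AB splits
        # 4 into 2/2.  Expected A=2, B=2, C=4; deviations 2+0+2 over v=2.
        cm = _cm([[4, 2, 2, 0]], ["p1"], list("ABCD"))
        assert iac(quartet_tree, cm, "p1") == pytest.approx(2.0)

    def test_single_species_plot_is_zero(self, quartet_tree):
        cm = _cm([[7, 0, 0, 0]], ["p1"], list("ABCD"))
        assert iac(quartet_tree, cm, "p1") == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_recursive_oracle(self, seed):
        tree = random_tree(9, seed=seed + 33)
        abund = random_abundances(tree, seed=seed + 5)
        names = list(abund)
        for name in names[:: 2]:
            abund[name] = 0
        if sum(v > 0 for v in abund.values()) < 2:
            abund[names[1]] = 2
            abund[names[3]] = 1
        present = {s: n for s, n in abund.items() if n > 0}
        cm = _cm([list(present.values())], ["p"], list(present))
        got = iac(tree, cm, "p")
        want = orc.iac_oracle(orc.parse(tree.to_newick()), abund)
        assert got == pytest.approx(want, abs=1e-9)


class TestEndemismTable:
    def test_shapes_and_consistency(self, small_landscape):
        tree, cm = small_landscape
        tables = endemism_table(tree, cm)
        assert list(tables.per_plot.columns) == ["WPE", "IAC"]
        assert set(tables.per_plot.index) == set(cm.plot_ids)
        assert set(tables.per_species.columns) == {
            "plot_id", "species", "abundance", "AED"
        }
        # per-species rows cover exactly the nonzero cells of the matrix
        assert len(tables.per_species) == int((cm.counts > 0).sum())
        # conservation holds plot-wise inside the assembled table
        for p, grp in tables.per_species.groupby("plot_id"):
            total = (grp["abundance"] * grp["AED"]).sum()
            assert total == pytest.approx(
                faith_pd(tree, set(grp["species"])), rel=1e-9
            )
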