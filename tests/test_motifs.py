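import numpy as np
import pandas as pd
import pytest

from vg3plexus.arbor import geodesic_distances
from vg3plexus.motifs import (
    dyad_census,
    ei_balance,
    find_triads,
    proximity_candidates,
    shared_input_fraction,
    type_adjacency,
)

from conftest import make_chain, synapse_row


def input_table(counts):
    """counts: {cell: (n_bc, n_amc)}."""
    rows = []
    for cell, (n_bc, n_amc) in counts.items():
        for i in range(n_bc):
            rows.append(synapse_row(f"{cell}-b{i}", 0, partner=f"BC-{i}",
                                    host=cell))
        for i in range(n_amc):
            rows.append(synapse_row(f"{cell}-a{i}", 0, partner=f"AMC-{i}",
                                    pclass="AMC", tlabel="amc", pol="none",
                                    ribbon=False, host=cell))
    return pd.DataFrame(rows)


class TestEiBalance:
    def test_equal_counts_ratio_one(self):
        res = ei_balance(input_table({"c0": (10, 10)}))
        assert res["per_cell"]["ei_ratio"].iloc[0] == 1.0

    def test_observed_26_74_split_gives_ratio_0p35(self):
        res = ei_balance(input_table({"c0": (261, 739)}))
        assert res["ei_ratio_mean"] == pytest.approx(0.353, abs=0.001)
        assert res["bc_fraction_mean"] == pytest.approx(0.261)

    def test_three_cell_se_matches_hand_formula(self):
        res = ei_balance(input_table({"a": (2, 8), "b": (3, 7), "c": (4, 6)}))
        fracs = np.array([0.2, 0.3, 0.4])
        assert res["bc_fraction_mean"] == pytest.approx(fracs.mean())
        assert res["bc_fraction_se"] == pytest.approx(
            fracs.std(ddof=1) / np.sqrt(3))

    def test_no_amc_inputs_flagged_infinite(self):
        res = ei_balance(input_table({"c0": (5, 0)}))
        assert np.isinf(res["per_cell"]["ei_ratio"].iloc[0])


class TestTypeAdjacency:
    def test_single_synapse_single_entry(self):
        syn = pd.DataFrame([synapse_row("s0", 0)])
        res = type_adjacency(syn)
        assert res["matrix"].to_numpy().sum() == 1

    def test_column_normalization(self):
        syn = pd.DataFrame([
            synapse_row("s0", 0, tlabel="3a"),
            synapse_row("s1", 0, tlabel="5o"),
            synapse_row("s2", 0, tlabel="3a"),
        ])
        res = type_adjacency(syn, normalize="columns")
        assert res["matrix"].sum(axis=0).iloc[0] == pytest.approx(1.0)

    def test_missing_labels_become_unidentified(self):
        syn = pd.DataFrame([synapse_row("s0", 0, tlabel="")])
        res = type_adjacency(syn)
        assert "unidentified" in res["matrix"].index

    def test_marginals_reconcile_with_table(self):
        rng = np.random.default_rng(0)
        syn = pd.DataFrame([
            synapse_row(f"s{i}", 0, tlabel=rng.choice(["3a", "5o", "4"]),
                        host=rng.choice(["c0", "c1"]))
            for i in range(30)
        ])
        res = type_adjacency(syn)
        assert res["row_totals"].sum() == len(syn)
        assert res["col_totals"].sum() == len(syn)


class TestSharedInput:
    def make_inputs(self, shared, total, rgc="R0"):
        rows = []
        for i in range(total):
            bc = f"BCshared-{i}" if i < shared else f"BCother-{i}"
            rows.append({"bc_cell_id": bc, "rgc_cell_id": rgc})
        return pd.DataFrame(rows)

    def test_published_style_count(self):
        df = self.make_inputs(42, 61)
        vg3_bcs = {f"BCshared-{i}" for i in range(42)}
        res = shared_input_fraction(df, vg3_bcs, "R0")
        assert res["fraction"] * 100 == pytest.approx(68.9, abs=0.1)
        assert (res["shared"], res["total"]) == (42, 61)

    def test_none_and_all_shared(self):
        df = self.make_inputs(0, 10)
        assert shared_input_fraction(df, set(), "R0")["fraction"] == 0.0
        df = self.make_inputs(10, 10)
        vg3 = set(df["bc_cell_id"])
        assert shared_input_fraction(df, vg3, "R0")["fraction"] == 1.0

    def test_zero_inputs_undefined(self):
        df = pd.DataFrame(columns=["bc_cell_id", "rgc_cell_id"])
        assert np.isnan(shared_input_fraction(df, set(), "R0")["fraction"])


class TestDyadCensus:
    def make_targets(self, one, two, rgc_frac=0.5):
        rows = []
        rid = 0
        for _ in range(one):
            cls = "RGC" if rid % 2 == 0 else "AMC"
            rows.append({"ribbon_synapse_id": f"rib{rid}",
                         "partner_cell_id": f"p{rid}", "partner_class": cls})
            rid += 1
        for _ in range(two):
            for k in range(2):
                rows.append({"ribbon_synapse_id": f"rib{rid}",
                             "partner_cell_id": f"p{rid}-{k}",
                             "partner_class": "AMC"})
            rid += 1
        return pd.DataFrame(rows)

    def test_counts_conserved(self):
        res = dyad_census(self.make_targets(20, 5))
        assert res["n_ribbons"] == 25
        assert res["n_one_partner"] == 20
        assert res["n_two_partner"] == 5

    def test_all_single_partner(self):
        res = dyad_census(self.make_targets(10, 0))
        assert res["n_two_partner"] == 0

    def test_vg3_innervated_fraction(self):
        df = pd.DataFrame([
            {"ribbon_synapse_id": f"rib{i}", "partner_cell_id": f"R{i}",
             "partner_class": "RGC"}
            for i in range(133)
        ])
        innervated = {f"R{i}" for i in range(119)}
        res = dyad_census(df, vg3_innervated_rgcs=innervated)
        assert res["vg3_innervated_fraction"] * 100 == pytest.approx(89.5,
                                                                     abs=0.1)
        assert (res["n_rgc_vg3_innervated"], res["n_rgc_ribbons"]) == (119, 133)


class TestFindTriads:
    def setup_tables(self):
        skel = make_chain(200, spacing=0.1)
        bc = pd.DataFrame([
            synapse_row("b0", 50, partner="BC-0"),
            synapse_row("b1", 150, partner="BC-1"),
        ])
        out = pd.DataFrame([
            synapse_row("o0", 50, direction="output", partner="RGC-0",
                        pclass="RGC", tlabel="4ow", pol="none", ribbon=False),
            synapse_row("o1", 100, direction="output", partner="RGC-1",
                        pclass="RGC", tlabel="5ti", pol="none", ribbon=False),
        ])
        return skel, bc, out

    def test_same_node_motif_has_zero_leg(self):
        skel, bc, out = self.setup_tables()
        pairs = pd.DataFrame([{"bc_cell_id": "BC-0", "rgc_cell_id": "RGC-0",
                               "ribbon_synapse_id": "b0"}])
        res = find_triads(bc, out, pairs, skel)
        assert len(res["motifs"]) == 1
        assert res["motifs"]["leg_distance_um"].iloc[0] == 0.0
        assert res["fraction_under_1um"] == 1.0
        assert bool(res["motifs"]["shared_ribbon"].iloc[0])

    def test_no_shared_pairs_empty(self):
        skel, bc, out = self.setup_tables()
        pairs = pd.DataFrame(columns=["bc_cell_id", "rgc_cell_id"])
        res = find_triads(bc, out, pairs, skel)
        assert len(res["motifs"]) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        skel = make_chain(300, spacing=0.1)
        bc = pd.DataFrame([
            synapse_row(f"b{i}", int(rng.integers(300)),
                        partner=f"BC-{i % 4}") for i in range(10)
        ])
        out = pd.DataFrame([
            synapse_row(f"o{i}", int(rng.integers(300)), direction="output",
                        partner=f"RGC-{i % 3}", pclass="RGC", tlabel="4ow",
                        pol="none", ribbon=False) for i in range(10)
        ])
        pairs = pd.DataFrame([
            {"bc_cell_id": f"BC-{b}", "rgc_cell_id": f"RGC-{r}"}
            for b, r in [(0, 0), (1, 2), (3, 1)]
        ])
        res = find_triads(bc, out, pairs, skel)
        # brute force oracle
        valid = set(zip(pairs["bc_cell_id"], pairs["rgc_cell_id"]))
        d = geodesic_distances(skel, bc["host_node_id"].to_numpy(),
                               out["host_node_id"].to_numpy())
        expected = []
        for i in range(len(bc)):
            for j in range(len(out)):
                if (bc["partner_cell_id"][i], out["partner_cell_id"][j]) in valid:
                    expected.append((bc["synapse_id"][i], out["synapse_id"][j],
                                     round(float(d[i, j]), 9)))
        got = sorted(
            (r.bc_vg3_synapse, r.vg3_rgc_synapse, round(r.leg_distance_um, 9))
            for r in res["motifs"].itertuples())
        assert got == sorted(expected)

    def test_relabeling_invariance(self):
        skel, bc, out = self.setup_tables()
        pairs = pd.DataFrame([{"bc_cell_id": "BC-0", "rgc_cell_id": "RGC-1"}])
        res1 = find_triads(bc, out, pairs, skel)
        relabel = {"BC-0": "X", "BC-1": "Y", "RGC-0": "P", "RGC-1": "Q"}
        bc2 = bc.assign(partner_cell_id=bc["partner_cell_id"].map(relabel))
        out2 = out.assign(partner_cell_id=out["partner_cell_id"].map(relabel))
        pairs2 = pd.DataFrame([{"bc_cell_id": "X", "rgc_cell_id": "Q"}])
        res2 = find_triads(bc2, out2, pairs2, skel)
        assert np.allclose(res1["motifs"]["leg_distance_um"],
                           res2["motifs"]["leg_distance_um"])


class TestProximity:
    def test_identical_points_pair_at_zero(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        res = proximity_candidates(pts, pts, 0.1)
        assert len(res) == 1
        assert res["distance_um"].iloc[0] == 0.0

    def test_radius_zero_only_coincidences(self):
        a = np.array([[0, 0, 0], [1, 1, 1]], dtype=float)
        b = np.array([[0, 0, 0], [2, 2, 2]], dtype=float)
        res = proximity_candidates(a, b, 0.0)
        assert len(res) == 1

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 5, size=(200, 3))
        b = rng.uniform(0, 5, size=(200, 3))
        r = 0.3
        res = proximity_candidates(a, b, r)
        got = set(zip(res["index_a"], res["index_b"]))
        expected = {
            (i, j) for i in range(200) for j in range(200)
            if np.linalg.norm(a[i] - b[j]) <= r
        }
        assert got == expected
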