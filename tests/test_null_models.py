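import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vg3plexus.arbor import StratProfile, depth_histogram
from vg3plexus.influence import InfluenceParams, predict_polarity
from vg3plexus.null_models import (
    depth_preserving_shuffle,
    overlap_weights,
    prune_same_pair,
    ranked_ci,
    relocation_null,
    type_assignment_null,
)

from conftest import make_chain, synapse_row


class TestRankedCI:
    def test_rank_rule_on_1_to_100(self):
        assert ranked_ci(np.arange(1, 101), 0.95) == (3.0, 98.0)

    def test_constant_values(self):
        assert ranked_ci([4.2] * 50, 0.95) == (4.2, 4.2)

    def test_uniform_order_statistics(self):
        rng = np.random.default_rng(0)
        lo, hi = ranked_ci(rng.uniform(size=10000), 0.95)
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranked_ci([], 0.95)


def delta_profile(label, center, width=0.02):
    grid = np.linspace(0, 1, 501)
    dens = ((grid >= center - width) & (grid <= center + width)).astype(float)
    return StratProfile(label, grid, dens)


class TestOverlapWeights:
    def arbor_hist(self):
        skel = make_chain(201, spacing=0.1)
        skel.nodes["z"] = np.linspace(10, 14, 201)
        from vg3plexus.arbor import normalize_ipl_depth
        skel = normalize_ipl_depth(skel, 0.0, 40.0)
        return depth_histogram(skel, None, 0.02, lo=0.0, hi=1.0)

    def test_direct_normalization_of_3_to_1_overlap(self):
        # arbor cable sits at depths 0.25-0.35; profile a is uniform over
        # exactly that band (density 10), profile b uniform over a 3x wider
        # band (density 10/3 inside the arbor) -> overlaps 3:1 -> 0.75/0.25
        hist = self.arbor_hist()
        g = np.linspace(0, 1, 2001)
        p_a = StratProfile("a", g, ((g >= 0.25) & (g <= 0.35)).astype(float))
        p_b = StratProfile("b", g, ((g >= 0.25) & (g <= 0.55)).astype(float))
        w = overlap_weights(hist, {"a": p_a, "b": p_b})
        assert w.sum() == pytest.approx(1.0)
        assert w["a"] == pytest.approx(0.75, abs=0.02)
        assert w["b"] == pytest.approx(0.25, abs=0.02)

    def test_disjoint_support_gets_zero(self):
        hist = self.arbor_hist()  # arbor at depth 0.25-0.35
        w = overlap_weights(hist, {"in": delta_profile("in", 0.30),
                                   "out": delta_profile("out", 0.80)})
        assert w["out"] == 0.0
        assert w["in"] == pytest.approx(1.0)

    def test_matched_profile_beats_shifted_copies(self):
        hist = self.arbor_hist()
        profiles = {
            "match": StratProfile.gaussian("match", 0.30, 0.03),
            "shift1": StratProfile.gaussian("shift1", 0.40, 0.03),
            "shift2": StratProfile.gaussian("shift2", 0.20, 0.03),
        }
        w = overlap_weights(hist, profiles)
        assert w.idxmax() == "match"

    def test_all_zero_overlap_rejected(self):
        hist = self.arbor_hist()
        with pytest.raises(ValueError):
            overlap_weights(hist, {"out": delta_profile("out", 0.9)})


class TestTypeAssignmentNull:
    def test_single_type_always_one(self):
        res = type_assignment_null(100, {"only": 1.0}, n_reps=50, seed=0)
        assert (res.per_rep["only"] == 1.0).all()

    def test_matches_multinomial_moments(self):
        w = {"a": 0.5, "b": 0.3, "c": 0.2}
        n, reps = 424, 4000
        res = type_assignment_null(n, w, n_reps=reps, seed=1)
        for t, p in w.items():
            mean = res.per_rep[t].mean()
            se = np.sqrt(p * (1 - p) / n / reps)
            assert abs(mean - p) < 3 * se * np.sqrt(reps)  # 3 MC SEs of mean
            var = res.per_rep[t].var()
            assert var == pytest.approx(p * (1 - p) / n, rel=0.2)

    def test_ci_matches_exact_binomial(self):
        res = type_assignment_null(424, {"a": 0.5, "b": 0.5}, n_reps=10000,
                                   seed=2)
        lo, hi = res.ci["a"]
        blo = sps.binom.ppf(0.025, 424, 0.5) / 424
        bhi = sps.binom.ppf(0.975, 424, 0.5) / 424
        assert abs(lo - blo) < 0.005
        assert abs(hi - bhi) < 0.005

    def test_reproducible_under_seed(self):
        a = type_assignment_null(50, {"a": 0.6, "b": 0.4}, 100, seed=9)
        b = type_assignment_null(50, {"a": 0.6, "b": 0.4}, 100, seed=9)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)


class TestPruneSamePair:
    def chain_synapses(self, nodes, partners):
        return pd.DataFrame([
            synapse_row(f"s{i}", n, direction="output", partner=p,
                        pclass="RGC", tlabel="4ow", pol="none", ribbon=False)
            for i, (n, p) in enumerate(zip(nodes, partners))
        ])

    def test_close_same_pair_thinned(self):
        skel = make_chain(200, spacing=0.1)
        syn = self.chain_synapses([0, 50], ["R0", "R0"])  # 5 µm apart
        out = prune_same_pair(syn, skel, 10.0)
        assert len(out) == 1

    def test_distinct_pairs_untouched(self):
        skel = make_chain(200, spacing=0.1)
        syn = self.chain_synapses([0, 50], ["R0", "R1"])
        out = prune_same_pair(syn, skel, 10.0)
        assert len(out) == 2

    def test_greedy_chain_keeps_first_and_third(self):
        skel = make_chain(200, spacing=0.1)
        # A at 0, B at 6 µm, C at 12 µm: greedy keeps A, drops B, keeps C
        syn = self.chain_synapses([0, 60, 120], ["R0"] * 3)
        out = prune_same_pair(syn, skel, 10.0)
        assert list(out["synapse_id"]) == ["s0", "s2"]


def stratified_chain():
    """Vertical chain spanning the IPL with OFF inputs shallow, ON deep."""
    from vg3plexus.arbor import normalize_ipl_depth
    skel = make_chain(401, spacing=0.1)
    skel.nodes["z"] = np.linspace(8, 24, 401)  # depths 0.2 - 0.6 of 40 µm
    skel = normalize_ipl_depth(skel, 0.0, 40.0)
    bc = pd.DataFrame(
        [synapse_row(f"off{i}", 20 + 10 * i, partner=f"BCoff-{i}",
                     tlabel="3a", pol="OFF") for i in range(6)]
        + [synapse_row(f"on{i}", 320 + 10 * i, partner=f"BCon-{i}",
                       tlabel="5o", pol="ON") for i in range(6)]
    )
    return skel, bc


class TestRelocationNull:
    def test_delta_profile_confines_relocation(self):
        skel, bc = stratified_chain()
        out = pd.DataFrame([
            synapse_row("o0", 200, direction="output", partner="R0",
                        pclass="RGC", tlabel="4ow", pol="none", ribbon=False)])
        prof = {"4ow": delta_profile("4ow", 0.25, 0.01)}
        res = relocation_null(skel, out, prof, bc, InfluenceParams(16.0),
                              n_reps=200, seed=0)
        # all relocated positions sit in the OFF stratum -> polarity < 0
        assert (res.per_rep["4ow"] < 0).all()

    def test_observed_matches_influence_model(self):
        skel, bc = stratified_chain()
        out = pd.DataFrame([
            synapse_row("o0", 40, direction="output", partner="R0",
                        pclass="RGC", tlabel="4ow", pol="none", ribbon=False)])
        prof = {"4ow": delta_profile("4ow", 0.25, 0.05)}
        res = relocation_null(skel, out, prof, bc, InfluenceParams(16.0),
                              n_reps=10, seed=0)
        field = predict_polarity(skel, bc, [40], InfluenceParams(16.0))
        assert res.observed["4ow"] == pytest.approx(
            field["polarity"].iloc[0])

    def test_unknown_type_raises_with_name(self):
        skel, bc = stratified_chain()
        out = pd.DataFrame([
            synapse_row("o0", 40, direction="output", partner="R0",
                        pclass="RGC", tlabel="mystery", pol="none",
                        ribbon=False)])
        with pytest.raises(ValueError, match="mystery"):
            relocation_null(skel, out, {}, bc, InfluenceParams(16.0), 10, 0)

    def test_flat_profile_equals_uniform_shuffle(self):
        skel, bc = stratified_chain()
        rng = np.random.default_rng(3)
        out = pd.DataFrame([
            synapse_row(f"o{i}", int(rng.integers(400)), direction="output",
                        partner="R0", pclass="RGC", tlabel="4ow", pol="none",
                        ribbon=False) for i in range(10)])
        flat = StratProfile("4ow", np.linspace(0, 1, 11), np.ones(11))
        res = relocation_null(skel, out, {"4ow": flat}, bc,
                              InfluenceParams(16.0), n_reps=2000, seed=4)
        # uniform-node shuffle oracle (node shares are equal on a chain)
        field = predict_polarity(skel, bc, None, InfluenceParams(16.0))
        on = field["on_sum"].to_numpy()
        off = field["off_sum"].to_numpy()
        rng2 = np.random.default_rng(5)
        picks = rng2.integers(0, skel.n_nodes, size=(2000, 10))
        pol = ((on[picks].sum(1) - off[picks].sum(1))
               / (on[picks].sum(1) + off[picks].sum(1)))
        ks = sps.ks_2samp(res.per_rep["4ow"], pol)
        assert ks.pvalue > 0.01

    def test_on_off_pooled_difference(self):
        skel, bc = stratified_chain()
        out = pd.DataFrame([
            synapse_row("o0", 350, direction="output", partner="R0",
                        pclass="RGC", tlabel="6sw", pol="none", ribbon=False),
            synapse_row("o1", 50, direction="output", partner="R1",
                        pclass="RGC", tlabel="4ow", pol="none", ribbon=False)])
        prof = {"6sw": delta_profile("6sw", 0.55, 0.03),
                "4ow": delta_profile("4ow", 0.25, 0.03)}
        res = relocation_null(skel, out, prof, bc, InfluenceParams(16.0),
                              n_reps=500, seed=1, on_types=("6sw",),
                              off_types=("4ow",))
        assert "on_minus_off" in res.per_rep
        lo, hi = res.ci["on_minus_off"]
        assert lo <= res.observed["on_minus_off"] <= hi
        assert res.per_rep["on_minus_off"].mean() > 0


class TestDepthPreservingShuffle:
    def test_uniform_polarity_gives_zero_shift(self):
        skel, _ = stratified_chain()
        bc = pd.DataFrame([synapse_row("on0", 200, pol="ON")])
        syn = pd.DataFrame([synapse_row(f"x{i}", 50 + i, pol="ON")
                            for i in range(5)])
        res = depth_preserving_shuffle(skel, syn, bc, 0.5, 50,
                                       InfluenceParams(16.0), seed=0)
        assert res.observed["mean_abs_dev_from_cell_mean"] == pytest.approx(0.0)
        assert np.allclose(res.per_rep.to_numpy(), 0.0)

    def test_zero_tolerance_with_unique_depths_is_identity(self):
        skel, bc = stratified_chain()
        syn = pd.DataFrame([synapse_row(f"x{i}", 100 + 40 * i, pol="ON")
                            for i in range(4)])
        res = depth_preserving_shuffle(skel, syn, bc, 1e-9, 20,
                                       InfluenceParams(16.0), seed=0)
        obs = res.observed["mean_abs_dev_from_cell_mean"]
        assert np.allclose(res.per_rep.to_numpy(), obs)

    def test_extreme_placement_shifts_toward_mean(self):
        skel, bc = stratified_chain()
        # synapses at the polarity extremes (the two chain ends)
        syn = pd.DataFrame([
            synapse_row("e0", 0, pol="ON"), synapse_row("e1", 400, pol="ON")])
        res = depth_preserving_shuffle(skel, syn, bc, 8.0, 200,
                                       InfluenceParams(16.0), seed=2)
        obs = res.observed["mean_abs_dev_from_cell_mean"]
        assert res.per_rep["mean_abs_dev_from_cell_mean"].mean() < obs

    def test_missing_candidates_reported(self):
        skel, bc = stratified_chain()
        syn = pd.DataFrame([synapse_row("x0", 0, pol="ON")])
        # impossible tolerance cannot occur on a dense chain; use a sparse one
        sparse = make_chain(5, spacing=10.0)
        sparse.nodes["z"] = [0, 10, 20, 30, 40]
        from vg3plexus.arbor import normalize_ipl_depth
        sparse = normalize_ipl_depth(sparse, 0.0, 40.0)
        syn_sparse = pd.DataFrame([synapse_row("x0", 0, pol="ON")])
        bc_sparse = pd.DataFrame([synapse_row("on0", 2, pol="ON")])
        res = depth_preserving_shuffle(sparse, syn_sparse, bc_sparse, 0.5, 5,
                                       InfluenceParams(16.0), seed=0)
        assert res is not None  # own node is always a candidate
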