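import numpy as np
import pandas as pd
import pytest

from vg3plexus.influence import InfluenceParams, depth_polarity_curve, predict_polarity
from vg3plexus.length_constant import (
    FitConfig,
    RoiSet,
    consensus_lambda,
    fit_correlation,
    fit_depth_polarity,
    fit_roi_polarity,
    neighbor_consistency,
    qc_filter,
)

from conftest import make_chain


def roi_set(skel, node_ids, polarities, planes=None, traces=None, trials=None):
    frame = pd.DataFrame({
        "roi_id": [f"r{i}" for i in range(len(node_ids))],
        "plane_id": planes or ["p0"] * len(node_ids),
        "cell_id": skel.cell_id,
        "node_id": node_ids,
        "polarity_measured": polarities,
    })
    return RoiSet(frame=frame, traces=traces, trial_polarities=trials)


class TestNeighborConsistency:
    def test_identical_polarities_give_zero_median(self):
        skel = make_chain(50, spacing=0.1)
        rois = roi_set(skel, [0, 5, 10, 40], [0.3] * 4)
        res = neighbor_consistency(rois, {skel.cell_id: skel}, 3.0)
        assert res["median_abs_dpolarity"] == 0.0

    def test_pairs_restricted_to_threshold(self):
        skel = make_chain(101, spacing=0.1)
        rois = roi_set(skel, [0, 10, 100], [0.0, 0.5, 1.0])
        res = neighbor_consistency(rois, {skel.cell_id: skel}, 3.0)
        # only (0, 10) are within 3 µm (1 µm apart); node 100 is 10 µm away
        assert len(res["pairs"]) == 1
        assert res["pairs"]["abs_dpolarity"].iloc[0] == pytest.approx(0.5)

    def test_no_pairs_warns_and_returns_empty(self):
        skel = make_chain(101, spacing=0.1)
        rois = roi_set(skel, [0, 100], [0.0, 1.0])
        res = neighbor_consistency(rois, {skel.cell_id: skel}, 3.0)
        assert np.isnan(res["median_abs_dpolarity"])

    def test_noisy_plane_has_maximal_contribution(self):
        rng = np.random.default_rng(0)
        skel = make_chain(400, spacing=0.1)
        nodes, planes, pols = [], [], []
        for p, base in zip("abcd", [0, 100, 200, 300]):
            for k in range(8):
                nodes.append(base + 2 * k)
                planes.append(f"plane_{p}")
                pol = 0.2 if p != "d" else float(rng.uniform(-1, 1))
                pols.append(pol)
        rois = roi_set(skel, nodes, pols, planes)
        res = neighbor_consistency(rois, {skel.cell_id: skel}, 3.0)
        contrib = res["plane_contributions"].set_index("plane_id")["contribution"]
        assert contrib.idxmax() == "plane_d"


class TestQcFilter:
    def test_identity_when_nothing_to_fix(self):
        skel = make_chain(200, spacing=0.1)
        rois = roi_set(skel, [0, 20, 40, 60], [0.1, 0.2, 0.3, 0.4])
        out = qc_filter(rois, {skel.cell_id: skel})
        assert len(out) == 4
        assert np.allclose(out.frame["polarity_measured"],
                           rois.frame["polarity_measured"])

    def test_sub_micron_rois_merge_to_mean(self):
        skel = make_chain(100, spacing=0.1)
        rois = roi_set(skel, [10, 15, 80], [0.2, 0.4, 0.9])  # 0.5 µm apart
        out = qc_filter(rois, {skel.cell_id: skel})
        assert len(out) == 2
        merged = sorted(out.frame["polarity_measured"])
        assert merged[0] == pytest.approx(0.3)
        assert merged[1] == pytest.approx(0.9)

    def test_merge_is_idempotent(self):
        skel = make_chain(100, spacing=0.1)
        rois = roi_set(skel, [10, 15, 80], [0.2, 0.4, 0.9])
        once = qc_filter(rois, {skel.cell_id: skel})
        twice = qc_filter(once, {skel.cell_id: skel})
        assert np.allclose(once.frame["polarity_measured"],
                           twice.frame["polarity_measured"])

    def test_injected_bad_plane_removed(self):
        rng = np.random.default_rng(1)
        skel = make_chain(400, spacing=0.1)
        nodes, planes, pols = [], [], []
        for p, base in zip("abc", [0, 120, 240]):
            for k in range(10):
                nodes.append(base + 2 * k)
                planes.append(f"plane_{p}")
                pols.append(0.2 if p != "c" else float(rng.uniform(-1, 1)))
        rois = roi_set(skel, nodes, pols, planes)
        out = qc_filter(rois, {skel.cell_id: skel})
        assert "plane_c" not in set(out.frame["plane_id"])
        assert {"plane_a", "plane_b"} <= set(out.frame["plane_id"])

    def test_trial_variation_filter(self):
        skel = make_chain(200, spacing=0.1)
        trials = np.array([[0.2, 0.2, 0.2], [0.9, -0.9, 0.5]])
        rois = roi_set(skel, [0, 100], [0.2, 0.2], trials=trials)
        out = qc_filter(rois, {skel.cell_id: skel}, drop_trial_variable=True)
        assert len(out) == 1

    def test_everything_filtered_raises(self):
        skel = make_chain(200, spacing=0.1)
        trials = np.array([[0.9, -0.9, 0.5]])
        rois = roi_set(skel, [0], [0.2], trials=trials)
        with pytest.raises(ValueError):
            qc_filter(rois, {skel.cell_id: skel}, drop_trial_variable=True)


class TestFitDepthPolarity:
    def test_self_fit_recovers_lambda_19(self, small_plexus):
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        # targets = the λ=19 predictions themselves -> zero-error self fit
        target_depths = np.linspace(0.2, 0.55, 6)
        cell_id, skel = next(iter(skels.items()))
        syn = bc[bc["host_cell_id"] == cell_id]
        field = predict_polarity(skel, syn, None, InfluenceParams(19.0))
        curve = depth_polarity_curve(field, skel, target_depths, 0.25)
        ok = curve["n_nodes"] > 0
        fit = fit_depth_polarity(
            {cell_id: skel}, syn, target_depths[ok.to_numpy()],
            curve.loc[ok, "mean_polarity"].to_numpy(), FitConfig())
        assert fit.best_lambda == 19.0
        assert fit.errors.min() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self, small_plexus):
        with pytest.raises(ValueError):
            fit_depth_polarity(small_plexus["skels"], small_plexus["bc"],
                               [0.3, 0.4], [0.1])


class TestFitRoiPolarity:
    def test_exact_recovery_of_generating_parameters(self, small_plexus):
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        cell_id, skel = next(iter(skels.items()))
        syn = bc[bc["host_cell_id"] == cell_id]
        nodes = skel.nodes["node_id"].to_numpy()[:: max(1, skel.n_nodes // 25)]
        field = predict_polarity(skel, syn, nodes, InfluenceParams(16.0))
        rois = roi_set(skel, nodes, field["polarity"].to_numpy())
        fit = fit_roi_polarity({cell_id: skel}, syn, rois, FitConfig())
        assert fit.best_params["lambda_um"] == 16.0
        assert fit.best_params["noise_offset"] == 0.0
        assert fit.best_params["on_scale"] == 1.0
        assert fit.best_params["error"] == pytest.approx(0.0, abs=1e-12)
        lo, hi = fit.level_set
        assert lo <= 16.0 <= hi

    def test_scrambled_polarities_fit_much_worse(self, small_plexus):
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        cell_id, skel = next(iter(skels.items()))
        syn = bc[bc["host_cell_id"] == cell_id]
        nodes = skel.nodes["node_id"].to_numpy()[:: max(1, skel.n_nodes // 30)]
        field = predict_polarity(skel, syn, nodes, InfluenceParams(16.0))
        rois = roi_set(skel, nodes, field["polarity"].to_numpy())
        fit = fit_roi_polarity({cell_id: skel}, syn, rois, FitConfig())
        rng = np.random.default_rng(0)
        scrambled = roi_set(skel, nodes,
                            rng.permutation(field["polarity"].to_numpy()))
        fit_s = fit_roi_polarity({cell_id: skel}, syn, scrambled, FitConfig())
        assert fit_s.best_params["error"] > fit.best_params["error"] + 0.05


class TestFitCorrelation:
    def test_degenerate_traces_raise(self, small_plexus):
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        cell_id, skel = next(iter(skels.items()))
        nodes = skel.nodes["node_id"].to_numpy()[:40:4]
        traces = np.tile(np.sin(np.arange(100)), (len(nodes), 1))
        rois = roi_set(skel, nodes, [0.1] * len(nodes), traces=traces)
        with pytest.raises(ValueError):
            fit_correlation({cell_id: skel},
                            bc[bc["host_cell_id"] == cell_id], rois)

    def test_too_few_pairs_raise(self, small_plexus):
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        cell_id, skel = next(iter(skels.items()))
        rois = roi_set(skel, [0, 1], [0.1, 0.1],
                       traces=np.random.default_rng(0).normal(size=(2, 50)))
        with pytest.raises(ValueError):
            fit_correlation({cell_id: skel},
                            bc[bc["host_cell_id"] == cell_id], rois)

    def test_lands_in_short_lambda_regime(self, small_plexus):
        # at this small sample size the estimator is coarse; it must still
        # land in the short-λ regime rather than the flat large-λ tail
        # (precise recovery is checked at full plexus scale elsewhere)
        skels, bc = small_plexus["skels"], small_plexus["bc"]
        rois = RoiSet.concat([c["rois"] for c in small_plexus["cells"]])
        fit = fit_correlation(skels, bc, rois, FitConfig())
        assert 4 <= fit.best_lambda <= 48


class TestConsensus:
    @pytest.mark.parametrize("vals,expected", [
        ((10.2, 18, 19), 16),
        ((16,), 16),
        ((12, 20), 16),
    ])
    def test_mean_rounded(self, vals, expected):
        assert consensus_lambda(vals)["consensus_um"] == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_lambda([])
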