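"""Length-constant estimation from functional recordings.

Three independent estimators of the functional length constant λ of signal
spread in the arbor:

1. :func:`fit_depth_polarity` — match the influence model's polarity-vs-IPL-
   depth curve to target polarities at a set of depths, minimizing the
   summed absolute difference over a λ grid.
2. :func:`fit_roi_polarity` — match predicted polarity at functionally
   imaged, skeleton-matched ROIs, grid-searching λ × noise-offset ×
   ON-scale and minimizing the mean absolute polarity error.
3. :func:`fit_correlation` — polarity-free: compare pairwise correlation
   coefficients of raw calcium traces with correlations of the pairs'
   per-BC-cell influence vectors, maximizing their agreement over λ.

ROI quality control mirrors the recording workflow: imaging planes whose
removal strongly reduces the close-neighbor polarity disagreement are
dropped, ROIs closer than 1 µm (geodesic) are merged, and ROIs with large
inter-trial polarity scatter can be excluded.  The consensus λ is the
rounded mean of the available estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arbor import Skeleton, geodesic_distances
from .influence import InfluenceParams, depth_polarity_curve, predict_polarity
from .stats import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "RoiSet",
    "FitConfig",
    "FitResult",
    "PUBLISHED_TARGET_DEPTHS",
    "PUBLISHED_TARGET_POLARITIES",
    "neighbor_consistency",
    "qc_filter",
    "fit_depth_polarity",
    "fit_roi_polarity",
    "fit_correlation",
    "consensus_lambda",
]

# Previously published calcium polarities of the VG3 plexus by IPL depth,
# used as the default target curve for the depth-polarity estimator.
PUBLISHED_TARGET_DEPTHS = np.array([0.0, 0.21, 0.29, 0.37, 0.44, 0.51, 0.60])
PUBLISHED_TARGET_POLARITIES = np.array([-0.18, -0.44, -0.45, -0.325, 0.02, 0.225, 0.23])


@dataclass
class RoiSet:
    """Functionally imaged points matched to skeleton nodes.

    ``frame`` columns: roi_id, plane_id, cell_id, node_id,
    polarity_measured (and optionally polarity_true).  ``traces`` is a
    (n_rois, n_frames) array aligned with ``frame`` rows;
    ``trial_polarities`` is (n_rois, n_trials).
    """

    frame: pd.DataFrame
    traces: np.ndarray | None = None
    trial_polarities: np.ndarray | None = None
    protocol: StimulusProtocol | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "RoiSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            frame=self.frame.iloc[idx].reset_index(drop=True),
            traces=None if self.traces is None else self.traces[idx],
            trial_polarities=(None if self.trial_polarities is None
                              else self.trial_polarities[idx]),
        )

    @staticmethod
    def concat(sets: list["RoiSet"]) -> "RoiSet":
        frames = pd.concat([s.frame for s in sets], ignore_index=True)
        traces = (np.concatenate([s.traces for s in sets])
                  if all(s.traces is not None for s in sets) else None)
        trials = (np.concatenate([s.trial_polarities for s in sets])
                  if all(s.trial_polarities is not None for s in sets) else None)
        return RoiSet(frame=frames, traces=traces, trial_polarities=trials,
                      protocol=sets[0].protocol, seed=sets[0].seed)


@dataclass
class FitConfig:
    """Grids and thresholds for λ fitting and ROI QC."""

    lambda_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 151.0))
    noise_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 0.0051, 0.001))
    on_scale_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.5, 2.01, 0.25))
    neighbor_um: float = 3.0
    merge_um: float = 1.0
    plane_drop_fraction: float = 1 / 3
    trial_sd_cut: float = 0.3
    window_um: float = 0.25
    polarity_match_cut: float = 0.25

    def __post_init__(self) -> None:
        for name in ("lambda_grid", "noise_grid", "on_scale_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0 or np.any(np.diff(g) < 0):
                raise ValueError(f"{name} must be non-empty and ascending")
            setattr(self, name, g)


@dataclass
class FitResult:
    """Outcome of a grid fit: the chosen λ plus the full error curve."""

    best_lambda: float
    lambdas: np.ndarray
    errors: np.ndarray           # error (or score) per λ, minimized over other axes
    best_params: dict | None = None
    error_cube: np.ndarray | None = None
    level_set: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "best_lambda": self.best_lambda,
            "lambdas": self.lambdas.tolist(),
            "errors": self.errors.tolist(),
            "best_params": self.best_params,
            "level_set": self.level_set,
        }

    def plot(self, ax=None, ylabel: str = "error"):
        """Error (or score) vs λ with the chosen λ marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.plot(self.lambdas, self.errors, color="k", lw=1)
        ax.axvline(self.best_lambda, color="crimson", ls="--", lw=1,
                   label=f"best λ = {self.best_lambda:g} µm")
        if self.level_set is not None:
            ax.axvspan(*self.level_set, color="crimson", alpha=0.12)
        ax.set_xlabel("length constant λ (µm)")
        ax.set_ylabel(ylabel)
        ax.legend(frameon=False, fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# Neighbor consistency & QC
# ---------------------------------------------------------------------------

def _neighbor_pairs(rois: RoiSet, skels: dict[str, Skeleton],
                    threshold_um: float) -> pd.DataFrame:
    """All within-cell ROI pairs at geodesic distance < threshold."""
    rows = []
    for cell_id, grp in rois.frame.groupby("cell_id"):
        if len(grp) < 2 or cell_id not in skels:
            continue
        d = geodesic_distances(skels[cell_id], grp["node_id"].to_numpy(),
                               grp["node_id"].to_numpy())
        i, j = np.triu_indices(len(grp), k=1)
        close = d[i, j] < threshold_um
        pol = grp["polarity_measured"].to_numpy()
        for a, b in zip(i[close], j[close]):
            rows.append({
                "roi_a": grp["roi_id"].iloc[a], "roi_b": grp["roi_id"].iloc[b],
                "plane_a": grp["plane_id"].iloc[a],
                "plane_b": grp["plane_id"].iloc[b],
                "distance_um": d[a, b],
                "abs_dpolarity": abs(pol[a] - pol[b]),
            })
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "plane_a", "plane_b",
                                       "distance_um", "abs_dpolarity"])


def neighbor_consistency(
    rois: RoiSet, skels: dict[str, Skeleton], threshold_um: float = 3.0
) -> dict:
    """Close-neighbor polarity disagreement and per-plane contributions.

    Returns the qualifying pairs, the median |Δpolarity|, and for each
    imaging plane the mean neighbor error with and without pairs touching
    that plane (leave-one-plane-out).
    """
    pairs = _neighbor_pairs(rois, skels, threshold_um)
    if pairs.empty:
        logger.warning("neighbor_consistency: no qualifying pairs")
        return {"pairs": pairs, "median_abs_dpolarity": np.nan,
                "plane_contributions": pd.DataFrame()}
    planes = sorted(set(pairs["plane_a"]) | set(pairs["plane_b"]))
    overall = pairs["abs_dpolarity"].mean()
    rows = []
    for p in planes:
        keep = (pairs["plane_a"] != p) & (pairs["plane_b"] != p)
        without = pairs.loc[keep, "abs_dpolarity"].mean() if keep.any() else np.nan
        rows.append({"plane_id": p, "mean_error_with": overall,
                     "mean_error_without": without,
                     "contribution": overall - without})
    return {
        "pairs": pairs,
        "median_abs_dpolarity": float(pairs["abs_dpolarity"].median()),
        "plane_contributions": pd.DataFrame(rows),
    }


def qc_filter(rois: RoiSet, skels: dict[str, Skeleton],
              fitcfg: FitConfig | None = None,
              drop_trial_variable: bool = False) -> RoiSet:
    """Filter and merge ROIs before fitting.

    1. Repeatedly drop the imaging plane whose removal reduces the mean
       close-neighbor error by at least ``plane_drop_fraction`` (relative),
       worst plane first.
    2. Optionally drop ROIs whose inter-trial polarity SD exceeds
       ``trial_sd_cut``.
    3. Merge surviving ROIs within ``merge_um`` geodesic distance of each
       other (single-linkage clusters): polarities, traces and trial
       polarities are averaged.
    """
    cfg = fitcfg or FitConfig()
    out = rois

    while True:
        res = neighbor_consistency(out, skels, cfg.neighbor_um)
        contrib = res["plane_contributions"]
        if contrib.empty:
            break
        overall = res["pairs"]["abs_dpolarity"].mean()
        if overall <= 0:
            break
        contrib = contrib.dropna(subset=["mean_error_without"])
        rel = (overall - contrib["mean_error_without"]) / overall
        if rel.empty or rel.max() < cfg.plane_drop_fraction:
            break
        worst = contrib.loc[rel.idxmax(), "plane_id"]
        logger.info("qc_filter: dropping plane %s (relative reduction %.2f)",
                    worst, rel.max())
        out = out.subset((out.frame["plane_id"] != worst).to_numpy())

    if drop_trial_variable and out.trial_polarities is not None:
        sd = out.trial_polarities.std(axis=1, ddof=1)
        out = out.subset(sd <= cfg.trial_sd_cut)

    merged = _merge_close(out, skels, cfg.merge_um)
    if len(merged) == 0:
        raise ValueError("qc_filter removed every ROI")
    return merged


def _merge_close(rois: RoiSet, skels: dict[str, Skeleton],
                 merge_um: float) -> RoiSet:
    frame = rois.frame
    cluster = -np.ones(len(frame), dtype=int)
    next_cluster = 0
    for cell_id, grp in frame.groupby("cell_id"):
        idx = grp.index.to_numpy()
        if cell_id not in skels or len(grp) == 1:
            for k in idx:
                cluster[k] = next_cluster
                next_cluster += 1
            continue
        d = geodesic_distances(skels[cell_id], grp["node_id"].to_numpy(),
                               grp["node_id"].to_numpy())
        # union-find single linkage under merge_um
        parent = list(range(len(idx)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ii, jj = np.nonzero(d < merge_um)
        for a, b in zip(ii, jj):
            if a < b:
                parent[find(a)] = find(b)
        roots = {}
        for k, orig in enumerate(idx):
            r = find(k)
            if r not in roots:
                roots[r] = next_cluster
                next_cluster += 1
            cluster[orig] = roots[r]

    rows, traces, trials = [], [], []
    for c in sorted(set(cluster)):
        members = np.flatnonzero(cluster == c)
        sub = frame.iloc[members]
        row = sub.iloc[0].copy()
        row["polarity_measured"] = sub["polarity_measured"].mean()
        if "polarity_true" in sub:
            row["polarity_true"] = sub["polarity_true"].mean()
        rows.append(row)
        if rois.traces is not None:
            traces.append(rois.traces[members].mean(axis=0))
        if rois.trial_polarities is not None:
            trials.append(rois.trial_polarities[members].mean(axis=0))
    return RoiSet(
        frame=pd.DataFrame(rows).reset_index(drop=True),
        traces=np.asarray(traces) if traces else None,
        trial_polarities=np.asarray(trials) if trials else None,
        protocol=rois.protocol, seed=rois.seed,
    )


# ---------------------------------------------------------------------------
# Estimator 1: depth-polarity curve fit
# ---------------------------------------------------------------------------

def fit_depth_polarity(
    skels: dict[str, Skeleton],
    bc_synapses: pd.DataFrame,
    target_depths=PUBLISHED_TARGET_DEPTHS,
    target_polarities=PUBLISHED_TARGET_POLARITIES,
    fitcfg: FitConfig | None = None,
) -> FitResult:
    """Best λ matching predicted polarity-by-depth to target polarities.

    For each λ on the grid, node polarities are predicted on every cell,
    pooled, averaged in ±``window_um`` windows around the target depths,
    and scored by the summed absolute difference to the targets (depths
    whose windows contain no nodes on any cell are skipped).  Ties take the
    smallest λ.
    """
    cfg = fitcfg or FitConfig()
    targets = np.asarray(target_polarities, dtype=float)
    depths = np.asarray(target_depths, dtype=float)
    if len(targets) != len(depths):
        raise ValueError("targets and depths must have equal length")

    # precompute per-cell geodesic distance matrices, restricted to nodes
    # that fall inside at least one target-depth window
    cell_data = []
    for cell_id, skel in skels.items():
        syn = bc_synapses[bc_synapses["host_cell_id"] == cell_id]
        if len(syn) == 0:
            continue
        from .arbor import ipl_span_um
        span = ipl_span_um(skel)
        node_depth = skel.nodes["ipl_depth"].to_numpy()
        in_window = np.zeros(skel.n_nodes, dtype=bool)
        for td in depths:
            in_window |= np.abs(node_depth - td) * span <= cfg.window_um
        if not in_window.any():
            continue
        query = skel.nodes["node_id"].to_numpy()[in_window]
        d = geodesic_distances(skel, syn["host_node_id"].to_numpy(), query)
        cell_data.append((skel, syn, query, d))
    if not cell_data:
        raise ValueError("no cells with BC synapses and occupied depth windows")

    errors = np.empty(len(cfg.lambda_grid))
    for k, lam in enumerate(cfg.lambda_grid):
        preds = np.full((len(cell_data), len(depths)), np.nan)
        ns = np.zeros((len(cell_data), len(depths)))
        for c, (skel, syn, query, d) in enumerate(cell_data):
            field = predict_polarity(skel, syn, query, InfluenceParams(lam),
                                     distances=d)
            curve = depth_polarity_curve(field, skel, depths, cfg.window_um)
            preds[c] = curve["mean_polarity"].to_numpy()
            ns[c] = curve["n_nodes"].to_numpy()
        with np.errstate(invalid="ignore"):
            pooled = np.nansum(np.where(ns > 0, preds, 0) * ns, axis=0)
        tot = ns.sum(axis=0)
        ok = tot > 0
        if not ok.any():
            raise ValueError("every depth window is empty")
        pooled = pooled[ok] / tot[ok]
        errors[k] = np.abs(pooled - targets[ok]).sum()
    best = int(np.argmin(errors))  # argmin takes the first (smallest λ) on ties
    return FitResult(float(cfg.lambda_grid[best]), cfg.lambda_grid, errors)


# ---------------------------------------------------------------------------
# Estimator 2: ROI polarity fit
# ---------------------------------------------------------------------------

def fit_roi_polarity(
    skels: dict[str, Skeleton],
    bc_synapses: pd.DataFrame,
    rois: RoiSet,
    fitcfg: FitConfig | None = None,
    error_ceiling: float | None = None,
) -> FitResult:
    """Grid search (λ, noise offset, ON scale) minimizing the mean absolute
    difference between predicted and measured ROI polarity.

    Also reports the λ level set: the range of length constants whose best
    error (over the other two axes) stays at or below ``error_ceiling``
    (default: best error + 0.018, mirroring how a slightly relaxed error
    level widens the admissible λ range).
    """
    cfg = fitcfg or FitConfig()
    measured, cells, d_by_cell, on_by_cell = _prepare_roi_fit(
        skels, bc_synapses, rois)

    n_lam, n_noise, n_scale = (len(cfg.lambda_grid), len(cfg.noise_grid),
                               len(cfg.on_scale_grid))
    cube = np.empty((n_lam, n_noise, n_scale))
    for k, lam in enumerate(cfg.lambda_grid):
        on_base = np.empty(len(measured))
        off_base = np.empty(len(measured))
        n_on = np.empty(len(measured))
        n_off = np.empty(len(measured))
        for cell_id, (d, is_on, cols) in d_by_cell.items():
            w_syn = np.exp(-d / lam)
            w_cell = on_by_cell[cell_id] @ w_syn  # (n_cells, n_rois_of_cell)
            on_base[cols] = w_cell[is_on].sum(axis=0)
            off_base[cols] = w_cell[~is_on].sum(axis=0)
            n_on[cols] = is_on.sum()
            n_off[cols] = (~is_on).sum()
        for i, noise in enumerate(cfg.noise_grid):
            on_n = on_base + noise * n_on
            off_n = off_base + noise * n_off
            for j, scale in enumerate(cfg.on_scale_grid):
                on = scale * on_n
                tot = on + off_n
                with np.errstate(invalid="ignore", divide="ignore"):
                    pred = np.where(tot > 0, (on - off_n) / np.where(tot > 0, tot, 1),
                                    np.nan)
                cube[k, i, j] = np.nanmean(np.abs(pred - measured))

    per_lambda = cube.min(axis=(1, 2))
    k, i, j = np.unravel_index(np.argmin(cube), cube.shape)
    best = {
        "lambda_um": float(cfg.lambda_grid[k]),
        "noise_offset": float(cfg.noise_grid[i]),
        "on_scale": float(cfg.on_scale_grid[j]),
        "error": float(cube[k, i, j]),
    }
    ceiling = (cube[k, i, j] + 0.018) if error_ceiling is None else error_ceiling
    ok = np.flatnonzero(per_lambda <= ceiling)
    level = (float(cfg.lambda_grid[ok[0]]), float(cfg.lambda_grid[ok[-1]]))
    return FitResult(best["lambda_um"], cfg.lambda_grid, per_lambda,
                     best_params=best, error_cube=cube, level_set=level)


def _prepare_roi_fit(skels, bc_synapses, rois):
    """Distance matrices and BC-cell groupings per cell for ROI fitting."""
    measured = rois.frame["polarity_measured"].to_numpy(dtype=float)
    d_by_cell: dict = {}
    on_by_cell: dict = {}
    for cell_id, grp in rois.frame.groupby("cell_id"):
        skel = skels[cell_id]
        syn = bc_synapses[bc_synapses["host_cell_id"] == cell_id]
        if len(syn) == 0:
            raise ValueError(f"cell {cell_id} has no BC synapses")
        d = geodesic_distances(skel, syn["host_node_id"].to_numpy(),
                               grp["node_id"].to_numpy())
        bc_cells = pd.Index(syn["partner_cell_id"].unique())
        member = np.zeros((len(bc_cells), len(syn)))
        member[bc_cells.get_indexer(syn["partner_cell_id"]),
               np.arange(len(syn))] = 1.0
        first = syn.groupby("partner_cell_id", sort=False)["polarity_class"].first()
        is_on = (first.reindex(bc_cells) == "ON").to_numpy()
        d_by_cell[cell_id] = (d, is_on, grp.index.to_numpy())
        on_by_cell[cell_id] = member
    return measured, list(d_by_cell), d_by_cell, on_by_cell


# ---------------------------------------------------------------------------
# Estimator 3: trace-correlation fit
# ---------------------------------------------------------------------------

def fit_correlation(
    skels: dict[str, Skeleton],
    bc_synapses: pd.DataFrame,
    rois: RoiSet,
    fitcfg: FitConfig | None = None,
    same_plane_only: bool = True,
) -> FitResult:
    """Best λ matching functional trace correlations to influence-vector
    correlations of ROI pairs (stimulus timing is ignored).

    Eligible pairs share a cell (and, by default, an imaging plane) and have
    similar measured polarity (|Δ| < ``polarity_match_cut``).  For each λ,
    the anatomical coefficient of a pair is the Pearson correlation of the
    two per-BC-cell influence vectors; the fit score is the correlation
    between anatomical and functional coefficients across pairs, maximized
    over λ.
    """
    cfg = fitcfg or FitConfig()
    if rois.traces is None:
        raise ValueError("fit_correlation requires raw traces")

    pairs = []  # (cell_id, row_a, row_b)
    frame = rois.frame
    for cell_id, grp in frame.groupby("cell_id"):
        idx = grp.index.to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ra, rb = grp.iloc[a], grp.iloc[b]
                if same_plane_only and ra["plane_id"] != rb["plane_id"]:
                    continue
                if abs(ra["polarity_measured"] - rb["polarity_measured"]) \
                        >= cfg.polarity_match_cut:
                    continue
                pairs.append((cell_id, idx[a], idx[b]))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} eligible ROI pairs (<3)")

    func = np.array([
        _pearson(rois.traces[a], rois.traces[b]) for _, a, b in pairs
    ])
    if np.nanstd(func) == 0:
        raise ValueError("functional coefficients are degenerate (zero variance)")

    # per-cell distance matrices BC synapses -> ROI nodes used in pairs
    by_cell: dict = {}
    for cell_id, grp in frame.groupby("cell_id"):
        syn = bc_synapses[bc_synapses["host_cell_id"] == cell_id]
        if len(syn) == 0:
            continue
        d = geodesic_distances(skels[cell_id], syn["host_node_id"].to_numpy(),
                               grp["node_id"].to_numpy())
        bc_cells = pd.Index(syn["partner_cell_id"].unique())
        member = np.zeros((len(bc_cells), len(syn)))
        member[bc_cells.get_indexer(syn["partner_cell_id"]),
               np.arange(len(syn))] = 1.0
        col_of = {orig: c for c, orig in enumerate(grp.index)}
        by_cell[cell_id] = (d, member, col_of)

    scores = np.empty(len(cfg.lambda_grid))
    for k, lam in enumerate(cfg.lambda_grid):
        vec_by_cell = {
            cid: member @ np.exp(-d / lam) for cid, (d, member, _) in by_cell.items()
        }
        anat = np.empty(len(pairs))
        for q, (cid, a, b) in enumerate(pairs):
            col_of = by_cell[cid][2]
            v = vec_by_cell[cid]
            anat[q] = _pearson(v[:, col_of[a]], v[:, col_of[b]])
        ok = ~(np.isnan(anat) | np.isnan(func))
        scores[k] = _pearson(anat[ok], func[ok]) if ok.sum() >= 3 else np.nan
    if np.all(np.isnan(scores)) or np.nanstd(scores) == 0:
        raise ValueError("anatomical coefficients are degenerate; no fit")
    best = int(np.nanargmax(scores))
    return FitResult(float(cfg.lambda_grid[best]), cfg.lambda_grid, scores,
                     best_params={"n_pairs": len(pairs)})


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def consensus_lambda(estimates) -> dict:
    """Arithmetic mean of the available λ estimates, rounded to the nearest µm."""
    vals = [float(v) for v in np.atleast_1d(estimates) if np.isfinite(v)]
    if not vals:
        raise ValueError("no finite estimates")
    return {"consensus_um": int(round(float(np.mean(vals)))), "inputs": vals}
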