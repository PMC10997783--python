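"""Exponential-decay influence model.

A bipolar-cell (BC) input synapse at geodesic distance ``d`` from a point on
the arbor contributes an influence ``W = exp(-d / λ)`` (each ribbon input
carries unit weight).  Summing ON-type and OFF-type BC influences at a point
gives a predicted calcium response polarity

    polarity = (ON - OFF) / (ON + OFF)  ∈ [-1, 1],

undefined (NaN, never 0) where both sums vanish.  Two optional parameters
mirror the fitting procedure: a small ``noise_offset`` added once per
BC-cell–point pair (compensating the pull of pixel noise toward polarity 0)
and an ``on_scale`` multiplying the summed ON influence only (ON/OFF input
asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arbor import Skeleton, geodesic_distances, ipl_span_um

__all__ = [
    "InfluenceParams",
    "influence_weight",
    "predict_polarity",
    "depth_polarity_curve",
    "influence_vector",
    "cumulative_drive",
    "bc_to_rgc_matrix",
]


@dataclass(frozen=True)
class InfluenceParams:
    """Parameters of the decay model.

    lambda_um : length constant λ in µm (> 0).
    noise_offset : additive constant per BC-cell–point influence (≥ 0).
    on_scale : multiplicative factor on the summed ON influence (> 0).
    """

    lambda_um: float = 16.0
    noise_offset: float = 0.0
    on_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_um <= 0:
            raise ValueError("lambda must be positive")
        if self.noise_offset < 0:
            raise ValueError("noise_offset must be non-negative")
        if self.on_scale <= 0:
            raise ValueError("on_scale must be positive")


def influence_weight(d_um, params: InfluenceParams) -> np.ndarray | float:
    """W = exp(-d/λ) + noise_offset for geodesic distance(s) ``d_um``."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = np.exp(-d / params.lambda_um) + params.noise_offset
    return w if w.ndim else float(w)


def _bc_cell_weights(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    query_nodes,
    params: InfluenceParams,
    distances: np.ndarray | None = None,
) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Per-BC-cell summed synapse weights at each query node.

    Returns (cell index, weights[n_cells, n_query], cell_is_on).  The
    noise offset is added once per cell–point pair, after summing that
    cell's synapses.  ``distances`` may carry a precomputed
    (n_synapses, n_query) geodesic distance matrix.
    """
    if not bc_synapses["polarity_class"].isin(["ON", "OFF"]).all():
        raise ValueError("every BC synapse must be labelled ON or OFF")
    if distances is None:
        distances = geodesic_distances(
            skel, from_nodes=bc_synapses["host_node_id"].to_numpy(),
            to_nodes=query_nodes,
        )
    w_syn = np.exp(-distances / params.lambda_um)  # (n_syn, n_query)
    cells = pd.Index(bc_synapses["partner_cell_id"].unique())
    row = cells.get_indexer(bc_synapses["partner_cell_id"])
    w_cell = np.zeros((len(cells), w_syn.shape[1]))
    np.add.at(w_cell, row, w_syn)
    w_cell += params.noise_offset
    first = bc_synapses.groupby("partner_cell_id", sort=False)["polarity_class"].first()
    cell_is_on = (first.reindex(cells) == "ON").to_numpy()
    return cells, w_cell, cell_is_on


def predict_polarity(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    query_nodes=None,
    params: InfluenceParams = InfluenceParams(),
    distances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted ON/OFF polarity at ``query_nodes`` (default: every node).

    Returns a frame with ``node_id``, ``on_sum``, ``off_sum`` and
    ``polarity`` = (on − off)/(on + off); NaN where no influence reaches.
    """
    if query_nodes is None:
        query_nodes = skel.nodes["node_id"].to_numpy()
    query_nodes = np.atleast_1d(query_nodes)
    cells, w_cell, is_on = _bc_cell_weights(skel, bc_synapses, query_nodes, params,
                                            distances)
    on = params.on_scale * w_cell[is_on].sum(axis=0)
    off = w_cell[~is_on].sum(axis=0)
    tot = on + off
    with np.errstate(invalid="ignore", divide="ignore"):
        pol = np.where(tot > 0, (on - off) / np.where(tot > 0, tot, 1), np.nan)
    return pd.DataFrame(
        {"node_id": query_nodes, "on_sum": on, "off_sum": off, "polarity": pol}
    )


def depth_polarity_curve(
    field: pd.DataFrame,
    skel: Skeleton,
    target_depths,
    window_um: float = 0.25,
    ipl_span: float | None = None,
) -> pd.DataFrame:
    """Mean node polarity within ±``window_um`` (along the IPL axis) of each
    target depth (IPL fraction).

    Windows may overlap; an empty window yields NaN.  ``ipl_span`` (µm)
    converts the µm window into depth fraction; by default it is taken from
    the skeleton's stored IPL borders.
    """
    span = ipl_span_um(skel) if ipl_span is None else ipl_span
    depths = skel.nodes.set_index("node_id").loc[field["node_id"], "ipl_depth"]
    depths = depths.to_numpy(dtype=float)
    pol = field["polarity"].to_numpy(dtype=float)
    rows = []
    for td in np.atleast_1d(target_depths):
        sel = np.abs(depths - td) * span <= window_um
        vals = pol[sel]
        vals = vals[~np.isnan(vals)]
        rows.append({"depth": float(td), "n_nodes": int(len(vals)),
                     "mean_polarity": float(vals.mean()) if len(vals) else np.nan})
    return pd.DataFrame(rows)


def influence_vector(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    query_node,
    params: InfluenceParams = InfluenceParams(),
) -> pd.Series:
    """Per-presynaptic-BC-cell influence at a single query node.

    One entry per BC cell: the sum of that cell's synapse weights to the
    query node (plus the per-cell noise offset).
    """
    cells, w_cell, _ = _bc_cell_weights(skel, bc_synapses, [query_node], params)
    return pd.Series(w_cell[:, 0], index=cells, name="influence")


def cumulative_drive(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    output_synapse_node,
    params: InfluenceParams = InfluenceParams(),
) -> tuple[pd.DataFrame, int]:
    """Cumulative BC influence on an output synapse as a function of distance,
    and the minimum number of (strongest) BC inputs supplying ≥50% of drive.

    The fraction curve accumulates synapse influence in order of increasing
    geodesic distance; the minimum count adds synapses in decreasing
    influence order (ties broken by ``synapse_id``).
    """
    if len(bc_synapses) == 0:
        raise ValueError("no BC inputs")
    d = geodesic_distances(
        skel, from_nodes=bc_synapses["host_node_id"].to_numpy(),
        to_nodes=[output_synapse_node],
    )[:, 0]
    w = np.exp(-d / params.lambda_um)
    total = w.sum()
    order = np.lexsort((bc_synapses["synapse_id"].to_numpy(), d))
    curve = pd.DataFrame(
        {
            "synapse_id": bc_synapses["synapse_id"].to_numpy()[order],
            "distance_um": d[order],
            "cum_fraction": np.cumsum(w[order]) / total,
        }
    )
    order_w = np.lexsort((bc_synapses["synapse_id"].to_numpy(), -w))
    cum = np.cumsum(w[order_w]) / total
    min_count = int(np.searchsorted(cum, 0.5 - 1e-12) + 1)
    return curve, min_count


def bc_to_rgc_matrix(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    vg3_rgc_synapses: pd.DataFrame,
    params: InfluenceParams = InfluenceParams(),
) -> dict:
    """Influence of each BC type on each RGC type routed through one arbor.

    Every BC→VG3 synapse's influence (exp decay at λ) on every VG3→RGC
    synapse is summed by (BC type, RGC type).  Returns the raw matrix, the
    column-normalized matrix (each RGC-type column sums to 1; all-zero
    columns become NaN), and the un-normalized row/column totals.
    """
    d = geodesic_distances(
        skel,
        from_nodes=bc_synapses["host_node_id"].to_numpy(),
        to_nodes=vg3_rgc_synapses["host_node_id"].to_numpy(),
    )
    w = np.exp(-d / params.lambda_um)
    bc_types = pd.Index(sorted(bc_synapses["partner_type_label"].unique()))
    rgc_types = pd.Index(sorted(vg3_rgc_synapses["partner_type_label"].unique()))
    rows = bc_types.get_indexer(bc_synapses["partner_type_label"])
    cols = rgc_types.get_indexer(vg3_rgc_synapses["partner_type_label"])
    raw = np.zeros((len(bc_types), len(rgc_types)))
    for j_syn, j_type in enumerate(cols):
        np.add.at(raw[:, j_type], rows, w[:, j_syn])
    col_tot = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(col_tot > 0, raw / np.where(col_tot > 0, col_tot, 1), np.nan)
    return {
        "raw": pd.DataFrame(raw, index=bc_types, columns=rgc_types),
        "normalized": pd.DataFrame(normed, index=bc_types, columns=rgc_types),
        "bc_totals": pd.Series(raw.sum(axis=1), index=bc_types),
        "rgc_totals": pd.Series(col_tot, index=rgc_types),
    }
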