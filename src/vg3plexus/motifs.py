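"""Connectivity census: E/I balance, adjacency matrices, dyads and triads.

A triad motif is a bipolar cell (BC) that synapses onto a VG3 amacrine cell
which in turn synapses onto a retinal ganglion cell (RGC) also directly
innervated by that BC.  The motif's leg distance is the geodesic distance —
along the VG3 arbor — between the BC→VG3 input and the VG3→RGC output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .arbor import Skeleton, geodesic_distances

logger = logging.getLogger(__name__)

__all__ = [
    "ei_balance",
    "type_adjacency",
    "shared_input_fraction",
    "dyad_census",
    "find_triads",
    "proximity_candidates",
]


def ei_balance(synapses: pd.DataFrame) -> dict:
    """Per-cell and mean excitatory/inhibitory input composition.

    For each host cell: the fraction of input synapses from BCs
    (excitatory ribbons) and from AMCs (inhibitory), and their ratio
    BC/AMC (inf if a cell has no AMC inputs).  The summary reports the
    mean ± SE over cells.
    """
    inputs = synapses[synapses["direction"] == "input"]
    rows = []
    for cell, grp in inputs.groupby("host_cell_id"):
        n_bc = int((grp["partner_class"] == "BC").sum())
        n_amc = int((grp["partner_class"] == "AMC").sum())
        tot = n_bc + n_amc
        rows.append({
            "host_cell_id": cell, "n_bc": n_bc, "n_amc": n_amc,
            "bc_fraction": n_bc / tot if tot else np.nan,
            "amc_fraction": n_amc / tot if tot else np.nan,
            "ei_ratio": n_bc / n_amc if n_amc else np.inf,
        })
    per_cell = pd.DataFrame(rows)

    def mean_se(col):
        v = per_cell[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return np.nan, np.nan
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        return float(v.mean()), float(se)

    bc_m, bc_se = mean_se("bc_fraction")
    amc_m, amc_se = mean_se("amc_fraction")
    r_m, r_se = mean_se("ei_ratio")
    return {
        "per_cell": per_cell,
        "bc_fraction_mean": bc_m, "bc_fraction_se": bc_se,
        "amc_fraction_mean": amc_m, "amc_fraction_se": amc_se,
        "ei_ratio_mean": r_m, "ei_ratio_se": r_se,
    }


def type_adjacency(
    synapses: pd.DataFrame,
    row_field: str = "partner_type_label",
    col_field: str = "host_cell_id",
    normalize: str | None = None,
) -> dict:
    """Count matrix of synapses by (row type, column type).

    Missing/empty labels aggregate under ``"unidentified"``.
    ``normalize="columns"`` divides each column by its total.  Returns the
    matrix plus row/column marginal totals.
    """
    df = synapses.copy()
    for f in (row_field, col_field):
        df[f] = df[f].fillna("unidentified").replace("", "unidentified")
    counts = pd.crosstab(df[row_field], df[col_field])
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if normalize == "columns":
        with np.errstate(invalid="ignore", divide="ignore"):
            counts = counts / col_tot
    elif normalize is not None:
        raise ValueError(f"unknown normalize {normalize!r}")
    return {"matrix": counts, "row_totals": row_tot, "col_totals": col_tot}


def shared_input_fraction(
    bc_rgc_synapses: pd.DataFrame, vg3_connected_bcs, rgc_cell_id
) -> dict:
    """Fraction of an RGC's BC inputs that come from VG3-connected BCs.

    ``bc_rgc_synapses`` needs columns ``bc_cell_id`` and ``rgc_cell_id``;
    ``vg3_connected_bcs`` is the set of BC cell ids with ≥1 ribbon synapse
    onto any VG3 in the dataset (a lower bound, since not all VG3s are
    reconstructed).
    """
    vg3_set = set(vg3_connected_bcs)
    inputs = bc_rgc_synapses[bc_rgc_synapses["rgc_cell_id"] == rgc_cell_id]
    total = len(inputs)
    if total == 0:
        return {"rgc_cell_id": rgc_cell_id, "shared": 0, "total": 0,
                "fraction": np.nan}
    shared = int(inputs["bc_cell_id"].isin(vg3_set).sum())
    return {"rgc_cell_id": rgc_cell_id, "shared": shared, "total": total,
            "fraction": shared / total}


def dyad_census(
    ribbon_targets: pd.DataFrame, vg3_innervated_rgcs=None
) -> dict:
    """Census of the non-VG3 partners of VG3-innervating ribbon synapses.

    ``ribbon_targets`` has one row per (ribbon synapse, non-VG3 partner)
    with columns ``ribbon_synapse_id``, ``partner_cell_id``,
    ``partner_class``.  Counts ribbons contacting one or two non-VG3
    partners, the fraction whose partner is an RGC (reported against both
    the all-ribbons and the single-partner denominators), and — when
    ``vg3_innervated_rgcs`` is given — the fraction of RGC-innervating
    ribbons whose RGC is itself a known VG3 target.
    """
    per_ribbon = ribbon_targets.groupby("ribbon_synapse_id").agg(
        n_partners=("partner_cell_id", "nunique"),
        any_rgc=("partner_class", lambda s: (s == "RGC").any()),
    )
    zero = per_ribbon[per_ribbon["n_partners"] == 0]
    if len(zero):
        logger.warning("dyad_census: %d ribbons with zero partners", len(zero))
    n_total = len(per_ribbon)
    n_one = int((per_ribbon["n_partners"] == 1).sum())
    n_two = int((per_ribbon["n_partners"] == 2).sum())
    n_rgc = int(per_ribbon["any_rgc"].sum())
    single = per_ribbon[per_ribbon["n_partners"] == 1]
    out = {
        "n_ribbons": n_total,
        "n_one_partner": n_one,
        "n_two_partner": n_two,
        "n_rgc_partner": n_rgc,
        "rgc_fraction_all": n_rgc / n_total if n_total else np.nan,
        "rgc_fraction_single": (float(single["any_rgc"].mean())
                                if len(single) else np.nan),
    }
    if vg3_innervated_rgcs is not None:
        targets = set(vg3_innervated_rgcs)
        rgc_rows = ribbon_targets[ribbon_targets["partner_class"] == "RGC"]
        per = rgc_rows.groupby("ribbon_synapse_id")["partner_cell_id"].agg(
            lambda s: s.isin(targets).any())
        out["n_rgc_ribbons"] = int(len(per))
        out["n_rgc_vg3_innervated"] = int(per.sum())
        out["vg3_innervated_fraction"] = (float(per.mean()) if len(per)
                                          else np.nan)
    return out


def find_triads(
    bc_vg3_synapses: pd.DataFrame,
    vg3_rgc_synapses: pd.DataFrame,
    bc_rgc_synapses: pd.DataFrame,
    skel_vg3: Skeleton,
) -> dict:
    """Enumerate BC→VG3→RGC triad motifs on one VG3 arbor.

    One motif per (BC→VG3 synapse, VG3→RGC synapse) pair such that the
    BC cell also directly innervates that RGC (per ``bc_rgc_synapses``
    with columns ``bc_cell_id``, ``rgc_cell_id`` and optionally
    ``ribbon_synapse_id`` marking shared-ribbon contacts).  Returns the
    motif table with per-motif leg distance (geodesic on the VG3 arbor),
    the distance histogram, the median, and the fraction under 1 µm.
    """
    pairs = set(zip(bc_rgc_synapses["bc_cell_id"], bc_rgc_synapses["rgc_cell_id"]))
    shared_ribbons = set(
        bc_rgc_synapses.loc[bc_rgc_synapses.get("ribbon_synapse_id").notna(),
                            "ribbon_synapse_id"]
        if "ribbon_synapse_id" in bc_rgc_synapses else []
    )
    if not pairs:
        empty = pd.DataFrame(columns=[
            "bc_cell_id", "vg3_cell_id", "rgc_cell_id", "bc_vg3_synapse",
            "vg3_rgc_synapse", "leg_distance_um", "shared_ribbon"])
        return {"motifs": empty, "median_um": np.nan, "fraction_under_1um": np.nan}

    d = geodesic_distances(
        skel_vg3,
        bc_vg3_synapses["host_node_id"].to_numpy(),
        vg3_rgc_synapses["host_node_id"].to_numpy(),
    )
    rows = []
    for i, bc in enumerate(bc_vg3_synapses.itertuples(index=False)):
        for j, out in enumerate(vg3_rgc_synapses.itertuples(index=False)):
            if (bc.partner_cell_id, out.partner_cell_id) not in pairs:
                continue
            rows.append({
                "bc_cell_id": bc.partner_cell_id,
                "vg3_cell_id": bc.host_cell_id,
                "rgc_cell_id": out.partner_cell_id,
                "bc_vg3_synapse": bc.synapse_id,
                "vg3_rgc_synapse": out.synapse_id,
                "leg_distance_um": float(d[i, j]),
                "shared_ribbon": bc.synapse_id in shared_ribbons,
            })
    motifs = pd.DataFrame(rows)
    if motifs.empty:
        return {"motifs": motifs, "median_um": np.nan,
                "fraction_under_1um": np.nan}
    dist = motifs["leg_distance_um"].to_numpy()
    hist, edges = np.histogram(dist, bins=np.arange(0, dist.max() + 2.0, 1.0))
    return {
        "motifs": motifs,
        "histogram": pd.DataFrame({"lo": edges[:-1], "hi": edges[1:],
                                   "count": hist}),
        "median_um": float(np.median(dist)),
        "fraction_under_1um": float((dist < 1.0).mean()),
    }


def proximity_candidates(
    points_a: np.ndarray, points_b: np.ndarray, radius_um: float = 0.1
) -> pd.DataFrame:
    """All (a, b) point pairs within a Euclidean radius (candidate contacts).

    A spatial-index replacement for mesh-based apposition detection;
    intended to produce lists for manual review.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=["index_a", "index_b", "distance_um"])
    tree = cKDTree(b)
    rows = []
    for i, neighbors in enumerate(tree.query_ball_point(a, r=radius_um)):
        for j in neighbors:
            rows.append({"index_a": i, "index_b": int(j),
                         "distance_um": float(np.linalg.norm(a[i] - b[j]))})
    return pd.DataFrame(rows, columns=["index_a", "index_b", "distance_um"])
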