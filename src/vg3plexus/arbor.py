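"""Skeletons, synapses, and stratification profiles.

The substrate for everything else in the package is a rooted node-edge
skeleton of a neuronal arbor: 3-D node positions in µm, per-node diameters,
parent links forming a tree, and (after normalization) a position along the
inner plexiform layer (IPL) axis expressed as a fraction of the IPL span
(0 = INL/IPL border, 1 = IPL/GCL border).  All distances in the package are
geodesic along the skeleton, never Euclidean.

Synapses are rows of a plain :class:`pandas.DataFrame` with a fixed column
set (see :data:`SYNAPSE_COLUMNS`); each synapse attaches to exactly one
skeleton node.  Stratification profiles are per-cell-type density curves
over IPL depth, normalized to integrate to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "Skeleton",
    "StratProfile",
    "SYNAPSE_COLUMNS",
    "SkeletonError",
    "read_swc",
    "write_swc",
    "resample_skeleton",
    "geodesic_distances",
    "normalize_ipl_depth",
    "depth_histogram",
    "tip_zone_profile",
    "read_synapse_csv",
    "write_synapse_csv",
    "validate_synapses",
    "read_strat_profiles",
    "write_strat_profiles",
]

SYNAPSE_COLUMNS = [
    "synapse_id",
    "host_cell_id",
    "host_node_id",
    "direction",
    "partner_cell_id",
    "partner_class",
    "partner_type_label",
    "polarity_class",
    "ribbon",
]


class SkeletonError(ValueError):
    """Structural problem in a skeleton (cycles, multiple roots, missing nodes)."""


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

@dataclass
class Skeleton:
    """A rooted tree of 3-D nodes with diameters.

    Parameters
    ----------
    cell_id
        Identifier of the cell the arbor belongs to.
    nodes
        DataFrame with columns ``node_id`` (int), ``x``, ``y``, ``z`` (µm),
        ``diameter`` (µm), ``parent_id`` (int, ``-1`` for the root) and
        optionally ``ipl_depth``.  ``z`` increases from the INL toward the
        GCL.
    cell_type
        Free-text type label (e.g. ``"VG3"``).
    ipl_borders
        ``(inl_border_z, gcl_border_z)`` once depth has been normalized.
    """

    cell_id: str
    nodes: pd.DataFrame
    cell_type: str = "VG3"
    ipl_borders: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        req = {"node_id", "x", "y", "z", "diameter", "parent_id"}
        missing = req - set(self.nodes.columns)
        if missing:
            raise SkeletonError(f"node table missing columns: {sorted(missing)}")
        ids = self.nodes["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise SkeletonError("duplicate node ids")
        self._index = pd.Index(ids)
        parents = self.nodes["parent_id"].to_numpy()
        roots = np.flatnonzero(parents == -1)
        if len(roots) != 1:
            raise SkeletonError(f"expected exactly one root, found {len(roots)}")
        self._root_pos = int(roots[0])
        known = set(ids)
        bad = [p for p in parents if p != -1 and p not in known]
        if bad:
            raise SkeletonError(f"parent ids not in node table: {bad[:5]}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        pos = {nid: i for i, nid in enumerate(self._index)}
        parents = self.nodes["parent_id"].to_numpy()
        state = np.zeros(len(parents), dtype=np.int8)  # 0 new, 1 active, 2 done
        for start in range(len(parents)):
            path = []
            i = start
            while state[i] == 0:
                state[i] = 1
                path.append(i)
                p = parents[i]
                if p == -1:
                    break
                i = pos[p]
                if state[i] == 1:
                    raise SkeletonError("cyclic parent links")
            for j in path:
                state[j] = 2

    # -- basic geometry ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root_id(self) -> int:
        return int(self.nodes["node_id"].iloc[self._root_pos])

    def node_positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def index_of(self, node_ids) -> np.ndarray:
        """Positional indices of ``node_ids`` in the node table."""
        idx = self._index.get_indexer(np.atleast_1d(node_ids))
        if (idx < 0).any():
            missing = np.atleast_1d(node_ids)[idx < 0]
            raise SkeletonError(f"unknown node ids: {missing[:5].tolist()}")
        return idx

    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (child_pos, parent_pos, length_µm) for every non-root node."""
        parents = self.nodes["parent_id"].to_numpy()
        child = np.flatnonzero(parents != -1)
        parent = self._index.get_indexer(parents[child])
        xyz = self.node_positions()
        lengths = np.linalg.norm(xyz[child] - xyz[parent], axis=1)
        return child, parent, lengths

    @property
    def total_length(self) -> float:
        """Total cable length in µm."""
        return float(self.edges()[2].sum())

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse adjacency weighted by edge length (µm)."""
        child, parent, w = self.edges()
        n = self.n_nodes
        return csr_matrix(
            (np.r_[w, w], (np.r_[child, parent], np.r_[parent, child])), shape=(n, n)
        )

    def leaf_ids(self, exclude_root: bool = True) -> np.ndarray:
        """Node ids of tips (degree-1 nodes; the root end is not a tip)."""
        parents = self.nodes["parent_id"].to_numpy()
        has_child = np.isin(self.nodes["node_id"].to_numpy(), parents)
        leaves = ~has_child
        if not exclude_root:
            leaves = leaves.copy()
            leaves[self._root_pos] = True
        else:
            leaves[self._root_pos] = False
        return self.nodes["node_id"].to_numpy()[leaves]

    def node_share_lengths(self) -> np.ndarray:
        """Cable length (µm) attributed to each node: half of each incident edge."""
        child, parent, w = self.edges()
        share = np.zeros(self.n_nodes)
        np.add.at(share, child, w / 2)
        np.add.at(share, parent, w / 2)
        return share

    def copy(self) -> "Skeleton":
        return replace(self, nodes=self.nodes.copy())


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path, cell_id: str | None = None, cell_type: str = "VG3") -> Skeleton:
    """Read a 7-column SWC file into a :class:`Skeleton`.

    The type column is ignored for analysis, coordinates are taken as µm and
    the radius column is doubled into a diameter (the most permissive common
    SWC dialect).  Cyclic parent links or multiple roots raise
    :class:`SkeletonError`.
    """
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["node_id", "type", "x", "y", "z", "radius", "parent_id"],
    )
    nodes = pd.DataFrame(
        {
            "node_id": df["node_id"].astype(int),
            "x": df["x"].astype(float),
            "y": df["y"].astype(float),
            "z": df["z"].astype(float),
            "diameter": 2.0 * df["radius"].astype(float),
            "parent_id": df["parent_id"].astype(int),
        }
    )
    skel = Skeleton(cell_id=cell_id or str(path), nodes=nodes, cell_type=cell_type)
    logger.info("read_swc: %s -> %d nodes", path, skel.n_nodes)
    return skel


def write_swc(skel: Skeleton, path) -> None:
    """Write a skeleton as 7-column SWC (radius = diameter / 2)."""
    out = pd.DataFrame(
        {
            "node_id": skel.nodes["node_id"].astype(int),
            "type": 0,
            "x": skel.nodes["x"],
            "y": skel.nodes["y"],
            "z": skel.nodes["z"],
            "radius": skel.nodes["diameter"] / 2.0,
            "parent_id": skel.nodes["parent_id"].astype(int),
        }
    )
    out.to_csv(path, sep=" ", header=False, index=False, float_format="%.6f")
    logger.info("write_swc: %s <- %d nodes", path, skel.n_nodes)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_skeleton(
    skel: Skeleton, spacing_um: float = 0.1, min_diameter_um: float = 0.1
) -> Skeleton:
    """Subdivide every edge so no internode distance exceeds ``spacing_um``.

    Each parent→child edge is split into equal pieces along the straight
    segment, so total cable length is preserved exactly; diameters are
    linearly interpolated and then floored at ``min_diameter_um`` (enforcing
    a minimum node diameter guards the downstream cable model against
    segmentation artifacts).  Node ids are renumbered 0..n-1.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    child, parent, lengths = skel.edges()
    if len(child) == 0 or lengths.sum() == 0:
        raise SkeletonError("cannot resample a zero-length skeleton")

    xyz = skel.node_positions()
    diam = skel.nodes["diameter"].to_numpy(dtype=float)

    new_xyz = [xyz[skel._root_pos]]
    new_diam = [diam[skel._root_pos]]
    new_parent = [-1]
    # map original node position -> new id
    new_id_of = {skel._root_pos: 0}

    # walk edges in topological (parent-before-child) order
    order = _topological_edge_order(skel, child, parent)
    for e in order:
        c, p, L = child[e], parent[e], lengths[e]
        n_seg = max(1, int(np.ceil(L / spacing_um - 1e-9)))
        prev = new_id_of[p]
        for k in range(1, n_seg + 1):
            t = k / n_seg
            new_xyz.append(xyz[p] * (1 - t) + xyz[c] * t)
            new_diam.append(diam[p] * (1 - t) + diam[c] * t)
            new_parent.append(prev)
            prev = len(new_xyz) - 1
        new_id_of[c] = prev

    new_xyz = np.asarray(new_xyz)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(len(new_xyz)),
            "x": new_xyz[:, 0],
            "y": new_xyz[:, 1],
            "z": new_xyz[:, 2],
            "diameter": np.maximum(new_diam, min_diameter_um),
            "parent_id": new_parent,
        }
    )
    out = Skeleton(cell_id=skel.cell_id, nodes=nodes, cell_type=skel.cell_type,
                   ipl_borders=skel.ipl_borders)
    if skel.ipl_borders is not None:
        out = normalize_ipl_depth(out, *skel.ipl_borders)
    return out


def _topological_edge_order(skel: Skeleton, child: np.ndarray, parent: np.ndarray):
    """Edge indices ordered so that a parent's edge precedes its children's."""
    kids: dict[int, list[int]] = {}
    for e, p in enumerate(parent):
        kids.setdefault(int(p), []).append(e)
    order: list[int] = []
    stack = list(reversed(kids.get(skel._root_pos, [])))
    while stack:
        e = stack.pop()
        order.append(e)
        stack.extend(reversed(kids.get(int(child[e]), [])))
    if len(order) != len(child):
        raise SkeletonError("tree walk did not reach all edges")
    return order


# ---------------------------------------------------------------------------
# Geodesics & depth
# ---------------------------------------------------------------------------

def geodesic_distances(skel: Skeleton, from_nodes=None, to_nodes=None) -> np.ndarray:
    """Geodesic (along-the-arbor) distances in µm.

    Returns an ``(len(from_nodes), len(to_nodes))`` array.  ``None`` means
    all nodes, in node-table order.  Unreachable pairs raise
    :class:`SkeletonError`.
    """
    adj = skel.adjacency()
    if from_nodes is None:
        src = np.arange(skel.n_nodes)
    else:
        src = skel.index_of(from_nodes)
    dist = dijkstra(adj, directed=False, indices=src)
    if to_nodes is None:
        out = dist
    else:
        out = dist[:, skel.index_of(to_nodes)]
    if not np.all(np.isfinite(out)):
        raise SkeletonError("unreachable node pair (disconnected skeleton)")
    return out


def normalize_ipl_depth(
    skel: Skeleton, inl_border_z: float, gcl_border_z: float
) -> Skeleton:
    """Fill ``ipl_depth`` = (z − inl) / (gcl − inl).

    Values outside [0, 1] are retained: dendrites do stray beyond the
    nominal borders and those nodes remain part of the arbor.
    """
    if inl_border_z == gcl_border_z:
        raise ValueError("IPL borders must be distinct")
    out = skel.copy()
    out.nodes["ipl_depth"] = (out.nodes["z"] - inl_border_z) / (
        gcl_border_z - inl_border_z
    )
    out.ipl_borders = (inl_border_z, gcl_border_z)
    return out


def ipl_span_um(skel: Skeleton) -> float:
    """Physical IPL thickness in µm implied by the stored borders."""
    if skel.ipl_borders is None:
        raise ValueError("skeleton has no IPL borders; call normalize_ipl_depth")
    return abs(skel.ipl_borders[1] - skel.ipl_borders[0])


def depth_histogram(
    skel: Skeleton,
    item_depths=None,
    bin_width: float = 0.05,
    lo: float | None = None,
    hi: float | None = None,
) -> pd.DataFrame:
    """Histogram of items (e.g. synapses) and cable over IPL depth.

    Bins are half-open ``[lo, hi)``.  Returns per-bin item ``count``, cable
    length ``cable_um`` (edge midpoints binned by depth), and ``density`` =
    count / cable; bins containing no arbor get a NaN density rather than
    zero, so "no arbor here" is distinguishable from "arbor but no synapses".
    """
    depths = skel.nodes["ipl_depth"].to_numpy(dtype=float)
    child, parent, lengths = skel.edges()
    edge_depth = (depths[child] + depths[parent]) / 2
    items = np.asarray([] if item_depths is None else item_depths, dtype=float)
    all_vals = np.r_[edge_depth, items]
    if lo is None:
        lo = np.floor(all_vals.min() / bin_width) * bin_width
    if hi is None:
        hi = np.ceil((all_vals.max() + 1e-12) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(items, bins=edges)
    cable, _ = np.histogram(edge_depth, bins=edges, weights=lengths)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(cable > 0, counts / np.where(cable > 0, cable, 1), np.nan)
    return pd.DataFrame(
        {
            "depth_lo": edges[:-1],
            "depth_hi": edges[1:],
            "count": counts,
            "cable_um": cable,
            "density": density,
        }
    )


# ---------------------------------------------------------------------------
# Tip-zone profile
# ---------------------------------------------------------------------------

_COMBO_CLASSES = ("bc_input", "amc_input", "output")


def tip_zone_profile(
    skel: Skeleton, synapses: pd.DataFrame, zone_edges_um
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synapse density and synapse-combination frequencies near dendrite tips.

    Every node is assigned the geodesic distance to its nearest tip (leaf of
    the tree, excluding the root end).  Zones are the half-open bands
    ``[edge_k, edge_{k+1})`` of that distance.  The first returned frame has
    per-zone cable length and density of BC inputs, AMC inputs, and outputs.
    The second has, per zone, the frequency of the 8 presence/absence
    combinations of {BC input, AMC input, output} over tips: each synapse is
    assigned to its nearest tip, and a tip's combination in a zone reflects
    which classes occur among its synapses in that distance band.
    """
    zone_edges = np.asarray(zone_edges_um, dtype=float)
    tips = skel.leaf_ids()
    if len(tips) == 0:
        raise SkeletonError("skeleton has no tips")
    dist_from_tips = geodesic_distances(skel, from_nodes=tips)  # (n_tips, n_nodes)
    nearest_tip = np.argmin(dist_from_tips, axis=0)
    tip_dist = dist_from_tips[nearest_tip, np.arange(skel.n_nodes)]

    share = skel.node_share_lengths()
    cable_per_zone, _ = np.histogram(tip_dist, bins=zone_edges, weights=share)

    syn_pos = skel.index_of(synapses["host_node_id"].to_numpy())
    syn_tipdist = tip_dist[syn_pos]
    syn_tip = nearest_tip[syn_pos]
    is_bc = (synapses["direction"] == "input") & (synapses["partner_class"] == "BC")
    is_amc = (synapses["direction"] == "input") & (synapses["partner_class"] == "AMC")
    is_out = synapses["direction"] == "output"

    dens_rows = []
    for k in range(len(zone_edges) - 1):
        in_zone = (syn_tipdist >= zone_edges[k]) & (syn_tipdist < zone_edges[k + 1])
        cable = cable_per_zone[k]
        row = {"zone_lo": zone_edges[k], "zone_hi": zone_edges[k + 1],
               "cable_um": cable}
        for name, mask in zip(_COMBO_CLASSES, (is_bc, is_amc, is_out)):
            n = int((in_zone & mask.to_numpy()).sum())
            row[f"n_{name}"] = n
            row[f"density_{name}"] = n / cable if cable > 0 else np.nan
        dens_rows.append(row)

    combo_rows = []
    zone_idx = np.digitize(syn_tipdist, zone_edges) - 1
    for k in range(len(zone_edges) - 1):
        present: dict[int, set[str]] = {}
        sel = zone_idx == k
        for t, b, a, o in zip(syn_tip[sel], is_bc[sel], is_amc[sel], is_out[sel]):
            s = present.setdefault(int(t), set())
            if b:
                s.add("bc_input")
            if a:
                s.add("amc_input")
            if o:
                s.add("output")
        counts: dict[str, int] = {}
        for t in range(len(tips)):
            combo = "+".join(c for c in _COMBO_CLASSES if c in present.get(t, set()))
            combo = combo or "none"
            counts[combo] = counts.get(combo, 0) + 1
        total = len(tips)
        for combo, n in sorted(counts.items()):
            combo_rows.append(
                {"zone_lo": zone_edges[k], "zone_hi": zone_edges[k + 1],
                 "combination": combo, "count": n, "frequency": n / total}
            )
    return pd.DataFrame(dens_rows), pd.DataFrame(combo_rows)


# ---------------------------------------------------------------------------
# Synapse & profile I/O
# ---------------------------------------------------------------------------

def validate_synapses(df: pd.DataFrame) -> pd.DataFrame:
    """Check the synapse-table invariants and return the frame unchanged.

    Ribbon synapses must be bipolar-cell inputs, and only bipolar-cell
    partners may carry an ON/OFF polarity class.
    """
    missing = set(SYNAPSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"synapse table missing columns: {sorted(missing)}")
    rib = df["ribbon"].astype(bool)
    bad = rib & ~((df["direction"] == "input") & (df["partner_class"] == "BC"))
    if bad.any():
        raise ValueError(f"{bad.sum()} ribbon synapses are not BC inputs")
    bad_pol = (df["polarity_class"].isin(["ON", "OFF"])) & (df["partner_class"] != "BC")
    if bad_pol.any():
        raise ValueError(f"{bad_pol.sum()} non-BC synapses carry an ON/OFF polarity")
    return df


def read_synapse_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["ribbon"] = df["ribbon"].astype(bool)
    validate_synapses(df)
    logger.info("read_synapse_csv: %s -> %d synapses", path, len(df))
    return df


def write_synapse_csv(df: pd.DataFrame, path) -> None:
    validate_synapses(df)[SYNAPSE_COLUMNS].to_csv(path, index=False)
    logger.info("write_synapse_csv: %s <- %d synapses", path, len(df))


@dataclass
class StratProfile:
    """A cell type's arbor-density curve over IPL depth.

    ``density`` is normalized so its trapezoidal integral over
    ``depth_grid`` equals one.
    """

    type_label: str
    depth_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.depth_grid) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        area = np.trapezoid(self.density, self.depth_grid)
        if area <= 0:
            raise ValueError("profile has zero mass")
        self.density = self.density / area

    @classmethod
    def gaussian(cls, type_label: str, center: float, sd: float = 0.05,
                 grid=None) -> "StratProfile":
        grid = np.linspace(0, 1, 201) if grid is None else np.asarray(grid)
        dens = np.exp(-0.5 * ((grid - center) / sd) ** 2)
        return cls(type_label, grid, dens)

    def at(self, depths) -> np.ndarray:
        """Density interpolated at ``depths`` (zero outside the grid)."""
        return np.interp(depths, self.depth_grid, self.density, left=0.0, right=0.0)


def read_strat_profiles(path) -> dict[str, StratProfile]:
    df = pd.read_csv(path)
    out = {}
    for label, grp in df.groupby("type_label"):
        grp = grp.sort_values("depth")
        out[str(label)] = StratProfile(str(label), grp["depth"].to_numpy(),
                                       grp["density"].to_numpy())
    logger.info("read_strat_profiles: %s -> %d types", path, len(out))
    return out


def write_strat_profiles(profiles: dict[str, StratProfile], path) -> None:
    rows = []
    for label, p in profiles.items():
        for d, v in zip(p.depth_grid, p.density):
            rows.append({"type_label": label, "depth": d, "density": v})
    pd.DataFrame(rows).to_csv(path, index=False)
    logger.info("write_strat_profiles: %s <- %d types", path, len(profiles))
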