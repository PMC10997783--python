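"""Stratification-overlap Monte Carlo null models.

The nulls test whether observed connectivity exceeds what co-stratification
alone predicts: partner types are reassigned (or synapses relocated) with
probabilities given by the depth overlap between the host arbor and each
candidate type's stratification profile.  Confidence intervals are read off
the ranked per-repetition results, centered at the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arbor import Skeleton, StratProfile, depth_histogram, geodesic_distances
from .influence import InfluenceParams, predict_polarity

logger = logging.getLogger(__name__)

__all__ = [
    "NullResult",
    "overlap_weights",
    "type_assignment_null",
    "prune_same_pair",
    "relocation_null",
    "depth_preserving_shuffle",
    "ranked_ci",
]

RELOCATION_QUANTILES = (0.001, 0.25, 0.5, 0.75, 0.999)


@dataclass
class NullResult:
    """Per-repetition Monte Carlo statistics with ranked CIs.

    ``per_rep`` has one row per repetition and one column per statistic;
    ``ci`` maps statistic name to (lo, hi) ranked bounds; ``observed`` holds
    the statistic computed from the real configuration where applicable.
    """

    per_rep: pd.DataFrame
    ci: dict
    ci_fraction: float
    seed: int | None = None
    observed: dict | None = None
    extras: dict | None = None


def ranked_ci(per_rep_values, ci_fraction: float = 0.95) -> tuple[float, float]:
    """CI bounds from ranked Monte Carlo results, centered at the median.

    With n sorted values (1-based ranks), the bounds sit at ranks
    (n+1)/2 ± ci·n/2, linearly interpolated between neighboring values.
    """
    vals = np.sort(np.asarray(per_rep_values, dtype=float))
    n = len(vals)
    if n == 0:
        raise ValueError("no values")
    recommended = 2.0 / max(1e-12, 1 - ci_fraction)
    if n < recommended:
        logger.warning("ranked_ci: %d reps is few for ci=%.3f (recommend >= %d)",
                       n, ci_fraction, int(recommended))
    m = (n + 1) / 2
    half = ci_fraction * n / 2
    lo_rank = max(1.0, m - half)
    hi_rank = min(float(n), m + half)
    ranks = np.arange(1, n + 1, dtype=float)
    lo = float(np.interp(lo_rank, ranks, vals))
    hi = float(np.interp(hi_rank, ranks, vals))
    return lo, hi


def overlap_weights(
    vg3_hist: pd.DataFrame, strat_profiles: dict[str, StratProfile]
) -> pd.Series:
    """Per-type connection weights from depth overlap with the host arbor.

    ``vg3_hist`` is a depth histogram of the host arbor (as produced by
    :func:`vg3plexus.arbor.depth_histogram`); the weight of a type is the
    sum over depth bins of arbor cable density × profile density,
    normalized to sum to one over the candidate types.
    """
    centers = (vg3_hist["depth_lo"] + vg3_hist["depth_hi"]).to_numpy() / 2
    cable = vg3_hist["cable_um"].to_numpy(dtype=float)
    raw = {}
    for label, prof in strat_profiles.items():
        raw[label] = float(np.sum(cable * prof.at(centers)))
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("all-zero depth overlap between arbor and profiles")
    return pd.Series({k: v / total for k, v in raw.items()}, name="weight")


def type_assignment_null(
    n_synapses: int,
    weights: pd.Series | dict,
    n_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
    ci_fraction: float = 0.95,
) -> NullResult:
    """Null distribution of per-type synapse fractions under overlap weights.

    Each repetition multinomially reassigns the observed number of synapses
    to types with the overlap probabilities.
    """
    if n_synapses <= 0:
        raise ValueError("n_synapses must be positive")
    w = pd.Series(weights, dtype=float)
    p = (w / w.sum()).to_numpy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multinomial(n_synapses, p, size=n_reps)
    fracs = pd.DataFrame(draws / n_synapses, columns=w.index)
    ci = {t: ranked_ci(fracs[t].to_numpy(), ci_fraction) for t in w.index}
    return NullResult(per_rep=fracs, ci=ci, ci_fraction=ci_fraction,
                      seed=None if isinstance(seed, np.random.Generator) else seed)


def prune_same_pair(
    synapses: pd.DataFrame, skel: Skeleton, min_separation_um: float = 10.0
) -> pd.DataFrame:
    """Thin same-(host, partner)-pair synapses to ≥ ``min_separation_um`` apart.

    Greedy retention in ascending ``synapse_id`` order: a synapse is kept if
    it is at least the minimum geodesic distance from every already-kept
    synapse of the same cell pair.  Counteracts the clustering bias of
    multiple synapses forming near an existing contact.
    """
    keep_mask = np.ones(len(synapses), dtype=bool)
    for _, grp in synapses.groupby(["host_cell_id", "partner_cell_id"]):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("synapse_id")
        d = geodesic_distances(skel, grp["host_node_id"].to_numpy(),
                               grp["host_node_id"].to_numpy())
        kept: list[int] = []
        for i in range(len(grp)):
            if all(d[i, j] >= min_separation_um for j in kept):
                kept.append(i)
        drop = [k for i, k in enumerate(grp.index) if i not in kept]
        keep_mask[synapses.index.get_indexer(drop)] = False
    return synapses[keep_mask]


def relocation_null(
    skel: Skeleton,
    vg3_rgc_synapses: pd.DataFrame,
    overlap_profiles: dict[str, StratProfile],
    bc_synapses: pd.DataFrame,
    params: InfluenceParams = InfluenceParams(16.0),
    n_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
    ci_fraction: float = 0.95,
    on_types: tuple = (),
    off_types: tuple = (),
) -> NullResult:
    """Relocate output synapses by depth-overlap weights; polarity per type.

    Per repetition, each VG3→RGC synapse of a type is moved to a node
    sampled with probability ∝ cable share × that type's overlap-profile
    density at the node's depth (sampling nodes, not depths, guarantees
    on-arbor placement).  The ON/OFF bipolar influence at relocated synapse
    positions is summed per type and turned into a polarity; quantile
    whiskers at 0.001/0.25/0.5/0.75/0.999 are reported per type, along with
    the pooled ON-type-vs-OFF-type polarity difference distribution when
    ``on_types``/``off_types`` are given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = skel.nodes["node_id"].to_numpy()
    share = skel.node_share_lengths()
    depths = skel.nodes["ipl_depth"].to_numpy()

    # on/off influence precomputed for every node
    field = predict_polarity(skel, bc_synapses, None, params)
    on = field["on_sum"].to_numpy()
    off = field["off_sum"].to_numpy()

    types = sorted(vg3_rgc_synapses["partner_type_label"].unique())
    per_type_pol = {}
    per_type_sums = {}
    obs_sums = {}
    observed = {}
    for t in types:
        if t not in overlap_profiles:
            raise ValueError(f"no overlap profile for RGC type {t!r}")
        syn_t = vg3_rgc_synapses[vg3_rgc_synapses["partner_type_label"] == t]
        w = share * overlap_profiles[t].at(depths)
        if w.sum() <= 0:
            raise ValueError(f"overlap profile for type {t!r} has no support "
                             "on the arbor")
        p = w / w.sum()
        picks = rng.choice(len(nodes), size=(n_reps, len(syn_t)), p=p)
        on_sum = on[picks].sum(axis=1)
        off_sum = off[picks].sum(axis=1)
        per_type_pol[t] = (on_sum - off_sum) / (on_sum + off_sum)
        per_type_sums[t] = (on_sum, off_sum)
        obs_pos = skel.index_of(syn_t["host_node_id"].to_numpy())
        o_on, o_off = on[obs_pos].sum(), off[obs_pos].sum()
        obs_sums[t] = (o_on, o_off)
        observed[t] = float((o_on - o_off) / (o_on + o_off))

    per_rep = pd.DataFrame(per_type_pol)
    ci = {t: ranked_ci(per_rep[t].to_numpy(), ci_fraction) for t in types}
    extras = {
        "quantiles": {
            t: np.quantile(per_rep[t], RELOCATION_QUANTILES).tolist() for t in types
        }
    }
    if on_types and off_types:
        def _pooled_pol(group, sums):
            cols = [t for t in group if t in sums]
            on_p = sum(sums[t][0] for t in cols)
            off_p = sum(sums[t][1] for t in cols)
            return (on_p - off_p) / (on_p + off_p)

        diff = _pooled_pol(on_types, per_type_sums) - _pooled_pol(
            off_types, per_type_sums)
        per_rep["on_minus_off"] = diff
        ci["on_minus_off"] = ranked_ci(diff, ci_fraction)
        observed["on_minus_off"] = float(
            _pooled_pol(on_types, obs_sums) - _pooled_pol(off_types, obs_sums))
    return NullResult(per_rep=per_rep, ci=ci, ci_fraction=ci_fraction,
                      seed=None if isinstance(seed, np.random.Generator) else seed,
                      observed=observed, extras=extras)


def depth_preserving_shuffle(
    skel: Skeleton,
    synapses: pd.DataFrame,
    bc_synapses: pd.DataFrame,
    tolerance_um: float = 0.5,
    n_reps: int = 1000,
    params: InfluenceParams = InfluenceParams(16.0),
    seed: int | np.random.Generator | None = None,
) -> NullResult:
    """Shuffle synapses across the arbor while preserving IPL depth (± tolerance).

    Each synapse is reassigned uniformly among nodes whose position along
    the IPL axis is within ``tolerance_um`` (in µm of tissue depth) of its
    own.  The statistic is the mean |local predicted polarity − cell mean
    polarity|: if observed synapses sit at polarity extremes, shuffling
    pulls the statistic toward the mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field = predict_polarity(skel, bc_synapses, None, params)
    pol = field["polarity"].to_numpy()
    cell_mean = float(np.nanmean(pol))

    z = skel.nodes["z"].to_numpy()
    syn_pos = skel.index_of(synapses["host_node_id"].to_numpy())
    order = np.argsort(z)
    z_sorted = z[order]

    candidates = []
    for i, p in enumerate(syn_pos):
        lo = np.searchsorted(z_sorted, z[p] - tolerance_um, side="left")
        hi = np.searchsorted(z_sorted, z[p] + tolerance_um, side="right")
        cand = order[lo:hi]
        if len(cand) == 0:
            raise ValueError(
                f"synapse {synapses['synapse_id'].iloc[i]!r} has no candidate "
                f"node within ±{tolerance_um} µm of depth")
        candidates.append(cand)

    observed = float(np.nanmean(np.abs(pol[syn_pos] - cell_mean)))
    shifts = np.empty(n_reps)
    for r in range(n_reps):
        picked = np.array([c[rng.integers(len(c))] for c in candidates])
        shifts[r] = np.nanmean(np.abs(pol[picked] - cell_mean))
    per_rep = pd.DataFrame({"mean_abs_dev_from_cell_mean": shifts})
    ci = {"mean_abs_dev_from_cell_mean": ranked_ci(shifts, 0.95)}
    return NullResult(per_rep=per_rep, ci=ci, ci_fraction=0.95,
                      seed=None if isinstance(seed, np.random.Generator) else seed,
                      observed={"mean_abs_dev_from_cell_mean": observed})


def arbor_depth_histogram(skel: Skeleton, bin_width: float = 0.02) -> pd.DataFrame:
    """Convenience: cable-only depth histogram for overlap weighting."""
    return depth_histogram(skel, None, bin_width)
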