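"""Synthetic VG3-like arbors, synapse placements, and simulated recordings.

The generator emulates the statistical structure the analysis assumes for a
VGluT3 amacrine-cell plexus: branched arbors confined to the 16–60% band of
inner-plexiform-layer (IPL) depth, bipolar-cell (BC) ribbon inputs drawn
from type-specific stratification profiles (OFF types in the outer
sublamina, ON types in the inner one, separated by a gap), amacrine (AMC)
inhibitory inputs enriched in that gap, output synapses intermixed along
the cable, and calcium polarity measurements generated by the
exponential-decay influence model plus Gaussian measurement noise.

Default scales follow the reconstructed cells the model targets: ~1243 µm
of cable per arbor, 0.062 BC and 0.169 AMC inputs per µm, 0.088 AMC and
0.066 RGC outputs per µm, a BC type mix dominated by type 3a (52.3%), and
a true length constant of 16 µm.  All randomness flows from one seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arbor import Skeleton, StratProfile, normalize_ipl_depth, resample_skeleton
from .influence import InfluenceParams, predict_polarity
from .length_constant import RoiSet
from .stats import StimulusProtocol

__all__ = [
    "GeneratorConfig",
    "DEFAULT_BC_MIX",
    "DEFAULT_RGC_MIX",
    "default_bc_profiles",
    "default_rgc_profiles",
    "generate_arbor",
    "place_synapses",
    "place_bc_rgc_synapses",
    "simulate_roi_records",
    "generate_plexus",
    "write_fixture",
]

# BC type mix observed across the six reconstructed cells (fractions of
# ribbon inputs, renormalized from rounded percentages); 3a/3b/4 are OFF
# types, the rest ON.
_BC_MIX_RAW = {
    "3a": 0.523, "3b": 0.081, "4": 0.099,
    "5o": 0.158, "5i": 0.061, "5t": 0.035, "xbc": 0.031, "6": 0.010,
}
DEFAULT_BC_MIX = {k: v / sum(_BC_MIX_RAW.values()) for k, v in _BC_MIX_RAW.items()}
OFF_BC_TYPES = ("3a", "3b", "4")

# Centers (IPL fraction) of the synthetic Gaussian stratification profiles.
BC_TYPE_DEPTH = {
    "3a": 0.27, "3b": 0.24, "4": 0.21,
    "5o": 0.47, "5i": 0.50, "5t": 0.53, "xbc": 0.50, "6": 0.57,
}

# RGC output mix over the most frequently innervated types.
DEFAULT_RGC_MIX = {
    "5ti": 0.215, "4ow": 0.170, "6sw": 0.151, "37": 0.137, "63": 0.126,
    "4i": 0.084, "4on": 0.065, "6sn": 0.052,
}
RGC_TYPE_DEPTH = {
    "4ow": 0.30, "4i": 0.28, "4on": 0.32,          # monostratified OFF
    "6sw": 0.52, "6sn": 0.55, "63": 0.48,          # monostratified ON
    "5ti": 0.40, "37": 0.38,                        # broad / ON-OFF
}
RGC_TYPE_SD = {"5ti": 0.12, "37": 0.14}            # bistratified-ish: broad


def default_bc_profiles(grid=None) -> dict[str, StratProfile]:
    return {t: StratProfile.gaussian(t, c, 0.05, grid) for t, c in BC_TYPE_DEPTH.items()}


def default_rgc_profiles(grid=None) -> dict[str, StratProfile]:
    return {
        t: StratProfile.gaussian(t, c, RGC_TYPE_SD.get(t, 0.05), grid)
        for t, c in RGC_TYPE_DEPTH.items()
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic plexus."""

    rng_seed: int = 0
    n_cells: int = 1
    target_cable_length_um: float = 1243.0
    ipl_band: tuple[float, float] = (0.16, 0.60)
    ipl_thickness_um: float = 40.0
    diameter_log_mean: float = float(np.log(0.5))
    diameter_log_sd: float = 0.35
    bc_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_BC_MIX))
    bc_input_density_per_um: float = 0.062
    amc_input_density_per_um: float = 0.169
    amc_output_density_per_um: float = 0.088
    rgc_output_density_per_um: float = 0.066
    rgc_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_RGC_MIX))
    amc_gap_enrichment: float = 3.0
    amc_gap: tuple[float, float] = (0.32, 0.42)
    true_lambda_um: float = 16.0
    noise_sd: float = 0.1
    on_scale_true: float = 1.0
    # growth process
    step_um: float = 1.0
    branch_prob_per_um: float = 0.05
    direction_jitter: float = 0.35
    resample_spacing_um: float = 0.1
    # BC axon terminal size (synapses of one BC cell cluster within this radius)
    bc_terminal_radius_um: float = 12.0
    mean_synapses_per_bc_cell: float = 4.0
    # functional sampling: ~56 ROIs/cell matches the ~334 initial points
    # of a six-cell recording session; the full 32-position bar protocol
    # gives distinct BC cells distinguishable position tuning
    rois_per_cell: int = 56
    n_trials: int = 4
    trial_noise_sd: float = 0.15
    bc_gain_sd: float = 0.4         # per-trial BC release fluctuation
    pixel_noise: float = 0.02       # additive trace noise per frame
    trace_amplitude: float = 5.0    # peak dF/F scale of transients
    roi_protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        tot = sum(self.bc_type_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"bc_type_mix sums to {tot}, expected 1")
        if self.ipl_band[1] <= self.ipl_band[0]:
            raise ValueError("IPL band must have positive height")
        for name in ("bc_input_density_per_um", "amc_input_density_per_um",
                     "amc_output_density_per_um", "rgc_output_density_per_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Arbor growth
# ---------------------------------------------------------------------------

def generate_arbor(
    config: GeneratorConfig, rng: np.random.Generator | None = None,
    cell_id: str = "synthVG3-0",
) -> Skeleton:
    """Grow one arbor by a stochastic branching random walk.

    Active tips extend in persistent, jittered directions with step
    ``step_um``; the depth component reflects at the IPL-band borders so the
    cable stays confined; tips branch at ``branch_prob_per_um``.  Growth
    stops when the cumulative cable length reaches the target.  The result
    is resampled to ``resample_spacing_um`` internode distance with
    lognormal diameters (median 0.5 µm) smoothed along branches, and IPL
    depth normalized against the synthetic tissue borders.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    z_lo = config.ipl_band[0] * config.ipl_thickness_um
    z_hi = config.ipl_band[1] * config.ipl_thickness_um

    xyz = [np.array([0.0, 0.0, z_lo + 0.05 * (z_hi - z_lo)])]
    parent = [-1]
    # start with two primary dendrites heading into the band
    tips: list[tuple[int, np.ndarray]] = []
    for ang in rng.uniform(0, 2 * np.pi, size=2):
        d = np.array([np.cos(ang), np.sin(ang), 0.6])
        tips.append((0, d / np.linalg.norm(d)))

    total = 0.0
    step = config.step_um
    while total < config.target_cable_length_um and tips:
        k = rng.integers(len(tips))
        node, direction = tips.pop(k)
        direction = direction + config.direction_jitter * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pos = xyz[node] + step * direction
        # reflect depth at band borders
        if pos[2] < z_lo:
            pos[2] = 2 * z_lo - pos[2]
            direction[2] = -direction[2]
        elif pos[2] > z_hi:
            pos[2] = 2 * z_hi - pos[2]
            direction[2] = -direction[2]
        xyz.append(pos)
        parent.append(node)
        new = len(xyz) - 1
        total += step
        tips.append((new, direction))
        if rng.random() < config.branch_prob_per_um * step:
            d2 = direction + 0.8 * rng.standard_normal(3)
            tips.append((new, d2 / np.linalg.norm(d2)))

    xyz = np.asarray(xyz)
    n = len(xyz)
    # lognormal diameters, median 0.5 µm, smoothed so neighbors are similar
    raw = np.exp(config.diameter_log_mean
                 + config.diameter_log_sd * rng.standard_normal(n))
    diam = raw.copy()
    for i in range(1, n):
        diam[i] = 0.5 * diam[parent[i]] + 0.5 * raw[i]
    nodes = pd.DataFrame(
        {"node_id": np.arange(n), "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
         "diameter": diam, "parent_id": parent}
    )
    skel = Skeleton(cell_id=cell_id, nodes=nodes, cell_type="VG3")
    skel = normalize_ipl_depth(skel, 0.0, config.ipl_thickness_um)
    return resample_skeleton(skel, config.resample_spacing_um)


# ---------------------------------------------------------------------------
# Synapse placement
# ---------------------------------------------------------------------------

def _sample_nodes(skel: Skeleton, weights: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    p = weights / weights.sum()
    pos = rng.choice(skel.n_nodes, size=n, p=p)
    return skel.nodes["node_id"].to_numpy()[pos]


def place_synapses(
    skel: Skeleton,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    bc_profiles: dict[str, StratProfile] | None = None,
    rgc_profiles: dict[str, StratProfile] | None = None,
) -> pd.DataFrame:
    """Place input and output synapses on a resampled arbor.

    BC ribbon inputs: per-type counts multinomial around the type mix, node
    positions weighted by cable share × the type's stratification profile.
    AMC inputs: cable-share weights with the inter-strata gap (and hence
    primary dendrites crossing it) enriched ``amc_gap_enrichment``-fold.
    Outputs: AMC targets uniform on cable; RGC targets per-type with the
    target type's stratification profile.  BC partner-cell identities
    cluster each cell's synapses within an axon-terminal radius.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    bc_profiles = bc_profiles or default_bc_profiles()
    rgc_profiles = rgc_profiles or default_rgc_profiles()
    share = skel.node_share_lengths()
    depths = skel.nodes["ipl_depth"].to_numpy()
    L = skel.total_length
    records: list[dict] = []
    sid = 0

    def add(node_id, direction, partner_cell, partner_class, type_label,
            polarity, ribbon):
        nonlocal sid
        records.append({
            "synapse_id": f"{skel.cell_id}-s{sid}",
            "host_cell_id": skel.cell_id,
            "host_node_id": int(node_id),
            "direction": direction,
            "partner_cell_id": partner_cell,
            "partner_class": partner_class,
            "partner_type_label": type_label,
            "polarity_class": polarity,
            "ribbon": ribbon,
        })
        sid += 1

    # --- BC ribbon inputs -------------------------------------------------
    n_bc = int(round(config.bc_input_density_per_um * L))
    types = list(config.bc_type_mix)
    counts = rng.multinomial(n_bc, [config.bc_type_mix[t] for t in types])
    xyz = skel.node_positions()
    for t, n_t in zip(types, counts):
        if n_t == 0:
            continue
        w = share * bc_profiles[t].at(depths)
        if w.sum() <= 0:
            w = share
        nodes_t = _sample_nodes(skel, w, n_t, rng)
        # cluster synapses into BC cells by nearest terminal center
        n_cells = max(1, int(round(n_t / config.mean_synapses_per_bc_cell)))
        pos_t = xyz[skel.index_of(nodes_t)][:, :2]
        centers = pos_t[rng.choice(len(pos_t), size=n_cells, replace=False)]
        centers = centers + rng.normal(0, 2.0, size=centers.shape)
        owner = np.argmin(
            np.linalg.norm(pos_t[:, None, :] - centers[None, :, :], axis=2), axis=1
        )
        pol = "OFF" if t in OFF_BC_TYPES else "ON"
        for node, c in zip(nodes_t, owner):
            add(node, "input", f"BC{t}-{c}", "BC", t, pol, True)

    # --- AMC inputs ---------------------------------------------------------
    n_amc = int(round(config.amc_input_density_per_um * L))
    gap = (depths >= config.amc_gap[0]) & (depths < config.amc_gap[1])
    w = share * np.where(gap, config.amc_gap_enrichment, 1.0)
    for node in _sample_nodes(skel, w, n_amc, rng):
        add(node, "input", f"AMC-{rng.integers(20)}", "AMC", "amc", "none", False)

    # --- outputs ------------------------------------------------------------
    n_amc_out = int(round(config.amc_output_density_per_um * L))
    for node in _sample_nodes(skel, share, n_amc_out, rng):
        add(node, "output", f"AMCt-{rng.integers(20)}", "AMC", "amc", "none", False)

    n_rgc = int(round(config.rgc_output_density_per_um * L))
    rtypes = list(config.rgc_type_mix)
    rmix = np.array([config.rgc_type_mix[t] for t in rtypes], dtype=float)
    rcounts = rng.multinomial(n_rgc, rmix / rmix.sum())
    for t, n_t in zip(rtypes, rcounts):
        if n_t == 0:
            continue
        w = share * rgc_profiles[t].at(depths)
        if w.sum() <= 0:
            w = share
        cells = [f"RGC{t}-{i}" for i in range(max(1, min(3, n_t // 8 + 1)))]
        for node in _sample_nodes(skel, w, n_t, rng):
            add(node, "output", cells[rng.integers(len(cells))], "RGC", t, "none",
                False)

    df = pd.DataFrame(records)
    df.attrs["seed"] = config.rng_seed
    return df


def place_bc_rgc_synapses(
    skel: Skeleton,
    synapses: pd.DataFrame,
    rng: np.random.Generator,
    shared_ribbon_prob: float = 0.3,
    extra_pair_prob: float = 0.4,
) -> pd.DataFrame:
    """Direct BC→RGC connections for triad/dyad statistics.

    Each ribbon synapse onto the arbor may, as a dyad, also innervate a
    nearby RGC (``shared_ribbon_prob``); additionally some BC cells form
    standalone synapses onto RGCs they co-innervate.  Returns a frame with
    ``bc_cell_id``, ``rgc_cell_id``, ``ribbon_synapse_id`` (NaN for
    standalone contacts) and a host node on the BC side for geometry.
    """
    ribbons = synapses[synapses["ribbon"]]
    rgc_out = synapses[(synapses["direction"] == "output")
                       & (synapses["partner_class"] == "RGC")]
    if len(rgc_out) == 0 or len(ribbons) == 0:
        return pd.DataFrame(columns=["bc_cell_id", "rgc_cell_id",
                                     "ribbon_synapse_id", "host_node_id"])
    xyz = skel.node_positions()
    rgc_pos = xyz[skel.index_of(rgc_out["host_node_id"].to_numpy())]
    rows = []
    for _, rib in ribbons.iterrows():
        p = xyz[skel.index_of([rib["host_node_id"]])[0]]
        near = np.linalg.norm(rgc_pos - p, axis=1)
        order = np.argsort(near)
        if rng.random() < shared_ribbon_prob:
            tgt = rgc_out.iloc[order[int(rng.integers(min(3, len(order))))]]
            rows.append({"bc_cell_id": rib["partner_cell_id"],
                         "rgc_cell_id": tgt["partner_cell_id"],
                         "ribbon_synapse_id": rib["synapse_id"],
                         "host_node_id": rib["host_node_id"]})
        elif rng.random() < extra_pair_prob:
            tgt = rgc_out.iloc[order[int(rng.integers(min(10, len(order))))]]
            rows.append({"bc_cell_id": rib["partner_cell_id"],
                         "rgc_cell_id": tgt["partner_cell_id"],
                         "ribbon_synapse_id": None,
                         "host_node_id": rib["host_node_id"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulated functional recordings
# ---------------------------------------------------------------------------

def _transient_kernel(frame_rate: float, n_frames: int,
                      tau_rise: float = 0.06, tau_decay: float = 0.25,
                      support_s: float = 1.25) -> np.ndarray:
    """Peak-normalized double-exponential calcium transient.

    Truncated past ``support_s`` (where it has decayed to <1% anyway) so a
    transient never bleeds into the pre-onset baseline of the next stimulus
    epoch.
    """
    t = np.arange(n_frames) / frame_rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k[t > support_s] = 0.0
    return k / k.max() if k.max() > 0 else k


def _synth_trace(
    polarities_per_trial: np.ndarray,
    on_pattern: np.ndarray,
    off_pattern: np.ndarray,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    pixel_noise: float = 0.02,
    amplitude: float = 5.0,
) -> np.ndarray:
    """Stimulus-locked trace for one ROI.

    ON/OFF transient amplitudes encode the per-trial polarity; the
    (n_trials, n_positions) response patterns — normalized to sum 1 over
    bar positions per trial, so they cancel in the polarity index — carry
    the ROI's bipolar-cell receptive-field signature and its presynaptic
    cells' trial-to-trial fluctuations, giving co-driven ROIs correlated
    traces.
    """
    fpe = protocol.frames_per_epoch
    kern = _transient_kernel(protocol.frame_rate_hz, fpe)
    onset_f = 0
    offset_f = int(round(protocol.on_duration_s * protocol.frame_rate_hz))
    trace = np.zeros(protocol.n_frames)
    for r, p in enumerate(polarities_per_trial):
        a_on, a_off = amplitude * (1 + p) / 2, amplitude * (1 - p) / 2
        for i in range(protocol.n_positions):
            base = (r * protocol.n_positions + i) * fpe
            ep = np.zeros(fpe)
            ep[onset_f:] += a_on * on_pattern[r, i] * kern[: fpe - onset_f]
            ep[offset_f:] += a_off * off_pattern[r, i] * kern[: fpe - offset_f]
            trace[base: base + fpe] += ep
    return trace + pixel_noise * rng.standard_normal(protocol.n_frames)


def _roi_response_patterns(skel, bc_synapses, query_nodes, params, protocol,
                           rng: np.random.Generator, n_trials: int,
                           bc_gain_sd: float = 0.4):
    """Per-ROI ON and OFF (n_trials, n_positions) response patterns.

    Each BC cell gets a Gaussian receptive-field envelope over bar
    positions plus multiplicative trial-to-trial gain fluctuations
    (``bc_gain_sd``); an ROI's pattern is the influence-weighted mixture of
    its presynaptic cells' patterns (at the true λ), normalized to sum 1
    over positions per trial so the pattern cancels out of the polarity
    index.  Co-driven ROIs thereby share both receptive-field shape and
    trial fluctuations, the structure the trace-correlation estimator reads.
    """
    from .influence import _bc_cell_weights

    cells, w_cell, is_on = _bc_cell_weights(skel, bc_synapses, query_nodes, params)
    n_pos = protocol.n_positions
    pos = np.arange(n_pos)
    centers = rng.uniform(-1, n_pos, size=len(cells))
    env = np.exp(-0.5 * ((pos[None, :] - centers[:, None]) / 1.5) ** 2) + 0.05
    # (n_cells, n_trials, n_pos): envelope with per-trial per-position gain
    gain = np.exp(bc_gain_sd * rng.standard_normal((len(cells), n_trials, n_pos))
                  - bc_gain_sd**2 / 2)
    pat = env[:, None, :] * gain
    pat /= pat.sum(axis=2, keepdims=True)

    def mix(mask):
        w = w_cell[mask]  # (n_sel, n_query)
        num = np.einsum("cq,ctp->qtp", w, pat[mask])
        tot = num.sum(axis=2, keepdims=True)
        return np.where(tot > 0, num / np.where(tot > 0, tot, 1), 1.0 / n_pos)

    return mix(is_on), mix(~is_on)


def simulate_roi_records(
    skel: Skeleton,
    synapses: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    n_planes: int = 6,
) -> RoiSet:
    """Sample functional ROIs on the arbor.

    Ground-truth polarity at each sampled node comes from the influence
    model at the true length constant; the measured polarity adds Gaussian
    noise (sd ``noise_sd``) and clips to [−1, 1].  Fluorescence traces are
    stimulus-locked double-exponential transients whose ON/OFF amplitudes
    reproduce the measured polarity (per trial, with ``trial_noise_sd``
    trial-to-trial scatter).  ROIs are assigned to imaging planes by depth.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    bc = synapses[synapses["ribbon"]]
    nodes = skel.nodes["node_id"].to_numpy()
    share = skel.node_share_lengths()
    pick = rng.choice(skel.n_nodes, size=config.rois_per_cell, replace=False,
                      p=share / share.sum())
    query = nodes[pick]
    params = InfluenceParams(config.true_lambda_um, 0.0, config.on_scale_true)
    field = predict_polarity(skel, bc, query, params)
    truth = field["polarity"].to_numpy()
    measured = np.clip(truth + config.noise_sd * rng.standard_normal(len(truth)),
                       -1, 1)
    depths = skel.nodes["ipl_depth"].to_numpy()[pick]
    lo, hi = config.ipl_band
    plane = np.clip(((depths - lo) / (hi - lo) * n_planes).astype(int), 0,
                    n_planes - 1)

    trial_pol = np.clip(
        measured[:, None] + config.trial_noise_sd
        * rng.standard_normal((len(truth), config.n_trials)),
        -1, 1,
    )
    proto = config.roi_protocol
    on_pat, off_pat = _roi_response_patterns(skel, bc, query, params, proto, rng,
                                             config.n_trials, config.bc_gain_sd)
    traces = np.stack([
        _synth_trace(trial_pol[i], on_pat[i], off_pat[i], proto, rng,
                     config.pixel_noise, config.trace_amplitude)
        for i in range(len(truth))
    ])
    frame = pd.DataFrame(
        {
            "roi_id": [f"{skel.cell_id}-r{i}" for i in range(len(truth))],
            "plane_id": [f"plane{p}" for p in plane],
            "cell_id": skel.cell_id,
            "node_id": query,
            "polarity_measured": measured,
            "polarity_true": truth,
        }
    )
    return RoiSet(frame=frame, traces=traces, trial_polarities=trial_pol,
                  protocol=proto, seed=config.rng_seed)


# ---------------------------------------------------------------------------
# Whole-plexus convenience and frozen fixture
# ---------------------------------------------------------------------------

def generate_plexus(config: GeneratorConfig) -> list[dict]:
    """Generate ``n_cells`` independent cells: skeleton, synapses, ROIs."""
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for i in range(config.n_cells):
        skel = generate_arbor(config, rng, cell_id=f"synthVG3-{i}")
        syn = place_synapses(skel, config, rng)
        rois = simulate_roi_records(skel, syn, config, rng)
        out.append({"skeleton": skel, "synapses": syn, "rois": rois})
    return out


def write_fixture(outdir, seed: int = 7, n_cells: int = 3,
                  cable_um: float = 400.0) -> None:
    """Emit a small frozen dataset (SWC + CSV) for test and demo use."""
    from pathlib import Path
    from .arbor import write_swc, write_synapse_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(rng_seed=seed, n_cells=n_cells,
                          target_cable_length_um=cable_um,
                          resample_spacing_um=0.5)
    cells = generate_plexus(cfg)
    for c in cells:
        skel = c["skeleton"]
        write_swc(skel, outdir / f"{skel.cell_id}.swc")
        write_synapse_csv(c["synapses"], outdir / f"{skel.cell_id}_synapses.csv")
        c["rois"].frame.to_csv(outdir / f"{skel.cell_id}_rois.csv", index=False)
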