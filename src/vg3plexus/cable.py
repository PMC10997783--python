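"""Passive multicompartment cable model of a skeletonized arbor.

Every resampled skeleton node becomes a compartment: membrane area
π·d·ℓ (ℓ = half of each incident internode edge), capacitance cm·area,
leak conductance gm·area, and axial conductance between neighbors
(π·d²/4)/(Ra·ℓ).  Synapses are conductance-based double-exponential
("Exp2Syn") point processes, peak-normalized so the weight is the peak
conductance in µS.  Integration is implicit (backward Euler) on the
tree's sparse structure, so arbitrarily large conductances stay stable.

The polarity experiment mirrors the two-trial protocol: one trial
activates all OFF bipolar inputs plus every inhibitory synapse, the other
all ON bipolar inputs plus inhibition scaled by ``on_scale`` (ON-stimulus
inhibition is weaker); the per-node polarity is
(ΔV_ON − ΔV_OFF)/(ΔV_ON + ΔV_OFF) of the maximum absolute deviations from
rest.

Internal unit system: mV, ms, µS, nF, nA (the NEURON convention);
``gm`` is specific membrane conductance in S/cm², ``Ra`` axial
resistivity in Ω·cm, diameters/lengths in µm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import splu

from .arbor import Skeleton

logger = logging.getLogger(__name__)

__all__ = [
    "CableParams",
    "SynapseKinetics",
    "ActiveSynapse",
    "CableModel",
    "SweepGrid",
    "build_compartments",
    "run_trial",
    "polarity_experiment",
    "score_fit",
    "sweep",
    "analytic_lambda",
    "smooth_diameters",
    "steady_state_voltage",
]


@dataclass(frozen=True)
class CableParams:
    """Passive membrane and cytoplasm properties.

    cm µF/cm²; Ra Ω·cm; gm S/cm²; reversal potentials in mV.  The
    temperature is recorded for provenance only — passive dynamics have no
    temperature dependence here.
    """

    cm: float = 1.0
    Ra: float = 100.0
    gm: float = 1e-4
    E_rest: float = -50.0
    E_e: float = 0.0
    E_i: float = -60.0
    temperature_c: float = 33.0
    min_diameter_um: float = 0.1

    def __post_init__(self) -> None:
        if self.gm < 0 or self.cm <= 0 or self.Ra <= 0:
            raise ValueError("conductances/capacitance must be non-negative")
        if not (self.E_i < self.E_rest < self.E_e):
            raise ValueError("expected E_i < E_rest < E_e")


@dataclass(frozen=True)
class SynapseKinetics:
    """Double-exponential conductance time courses (ms)."""

    tau_rise: float = 1.0
    tau_decay_exc: float = 1.0
    tau_decay_inh: float = 3.0


@dataclass(frozen=True)
class ActiveSynapse:
    """A conductance source: compartment index, peak conductance (µS),
    reversal potential (mV), and rise/decay taus (ms)."""

    node_index: int
    weight_uS: float
    reversal_mV: float
    tau_rise: float
    tau_decay: float


def _exp2_waveform(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalized double exponential; alpha-function in the equal-tau limit."""
    t = np.maximum(t_ms, 0.0)
    if abs(tau_rise - tau_decay) < 1e-9:
        tau = tau_decay
        g = (t / tau) * np.exp(1 - t / tau)
    else:
        tp = (tau_rise * tau_decay) / (tau_decay - tau_rise) * np.log(
            tau_decay / tau_rise)
        peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
        g = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / peak
    g[t_ms < 0] = 0.0
    return g


@dataclass
class CableModel:
    """Compartmentalized arbor ready for simulation."""

    skeleton: Skeleton
    params: CableParams
    diameter_um: np.ndarray          # per compartment, floored
    length_um: np.ndarray            # per-compartment cable share
    capacitance_nF: np.ndarray
    leak_uS: np.ndarray
    axial: csr_matrix                # symmetric off-diagonal axial conductances, µS
    axial_diag: np.ndarray           # row sums of axial

    @property
    def n(self) -> int:
        return len(self.diameter_um)

    @property
    def membrane_area_um2(self) -> np.ndarray:
        return np.pi * self.diameter_um * self.length_um


def build_compartments(skel: Skeleton, params: CableParams) -> CableModel:
    """Convert a (resampled) skeleton into a compartment model."""
    child, parent, lengths = skel.edges()
    if len(child) == 0:
        raise ValueError("skeleton has no edges")
    diam = np.maximum(skel.nodes["diameter"].to_numpy(dtype=float),
                      params.min_diameter_um)
    share = np.zeros(skel.n_nodes)
    np.add.at(share, child, lengths / 2)
    np.add.at(share, parent, lengths / 2)

    area_cm2 = np.pi * diam * share * 1e-8          # µm² -> cm²
    cap_nF = params.cm * area_cm2 * 1e3             # µF -> nF
    leak_uS = params.gm * area_cm2 * 1e6            # S -> µS

    d_edge = (diam[child] + diam[parent]) / 2
    # (π d²/4)/(Ra ℓ) with d, ℓ in cm, converted to µS
    g_ax = (np.pi * d_edge**2 / 4.0) / (params.Ra * lengths) * 100.0
    n = skel.n_nodes
    axial = csr_matrix(
        (np.r_[g_ax, g_ax], (np.r_[child, parent], np.r_[parent, child])),
        shape=(n, n),
    )
    return CableModel(skel, params, diam, share, cap_nF, leak_uS, axial,
                      np.asarray(axial.sum(axis=1)).ravel())


def smooth_diameters(model: CableModel, uniform_diameter_um: float = 0.5) -> CableModel:
    """Rebuild the model with every compartment set to one diameter."""
    skel = model.skeleton.copy()
    skel.nodes["diameter"] = uniform_diameter_um
    return build_compartments(skel, model.params)


def analytic_lambda(params: CableParams, diameter_um: float = 0.5) -> float:
    """Steady-state length constant λ = sqrt((d/4)·(1/gm)/Ra) in µm.

    For an infinite uniform cylinder; gm = 0 returns infinity.
    """
    if params.gm == 0:
        return float("inf")
    d_cm = diameter_um * 1e-4
    lam_cm = np.sqrt((d_cm / 4.0) / (params.gm * params.Ra))
    return float(lam_cm * 1e4)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def run_trial(
    model: CableModel,
    active_synapses: list[ActiveSynapse],
    duration_ms: float = 30.0,
    dt_ms: float = 0.025,
    onset_ms: float = 5.0,
    injections_nA: np.ndarray | None = None,
    return_trace: bool = False,
):
    """Integrate the passive tree and return per-node max |V − E_rest| (mV).

    Backward-Euler stepping: at each step the linear system
    (C/dt + g_leak + g_syn(t) + L_axial) V = C/dt·V_prev + driving terms
    is solved with a sparse LU factorization (re-used whenever the synaptic
    conductances are constant).  All synapses switch on at ``onset_ms``.
    A solver error is raised if any voltage exceeds 500 mV in magnitude.
    """
    p = model.params
    if dt_ms > 0.1:
        raise ValueError("dt must resolve the 1 ms rise tau (dt <= 0.1 ms)")
    n_steps = int(round(duration_ms / dt_ms))
    n = model.n
    v = np.full(n, p.E_rest)
    inj = np.zeros(n) if injections_nA is None else np.asarray(injections_nA,
                                                               dtype=float)
    t_grid = (np.arange(1, n_steps + 1) * dt_ms) - onset_ms
    g_syn_t = np.zeros((len(active_synapses), n_steps))
    for s_i, s in enumerate(active_synapses):
        if s.weight_uS > 0:
            g_syn_t[s_i] = s.weight_uS * _exp2_waveform(t_grid, s.tau_rise,
                                                        s.tau_decay)
    syn_nodes = np.array([s.node_index for s in active_synapses], dtype=int)
    syn_rev = np.array([s.reversal_mV for s in active_synapses])

    c_dt = model.capacitance_nF / dt_ms
    base_diag = c_dt + model.leak_uS + model.axial_diag
    rhs_const = model.leak_uS * p.E_rest + inj
    static = len(active_synapses) == 0 or not g_syn_t.any()
    lu = None
    max_dev = np.zeros(n)
    trace = np.empty((n_steps, n)) if return_trace else None

    neg_axial = -model.axial
    for k in range(n_steps):
        g_now = g_syn_t[:, k] if len(active_synapses) else np.empty(0)
        diag_extra = np.zeros(n)
        rhs_syn = np.zeros(n)
        if len(active_synapses):
            np.add.at(diag_extra, syn_nodes, g_now)
            np.add.at(rhs_syn, syn_nodes, g_now * syn_rev)
        A = neg_axial + diags(base_diag + diag_extra)
        if static:
            if lu is None:
                lu = splu(A.tocsc())
            solver = lu
        else:
            solver = splu(A.tocsc())
        v = solver.solve(c_dt * v + rhs_const + rhs_syn)
        if np.max(np.abs(v)) > 500.0:
            raise FloatingPointError("cable solver unstable: |V| > 500 mV")
        dev = np.abs(v - p.E_rest)
        np.maximum(max_dev, dev, out=max_dev)
        if return_trace:
            trace[k] = v
    if return_trace:
        return max_dev, trace
    return max_dev


def steady_state_voltage(
    model: CableModel, injections_nA: np.ndarray | None = None,
    synapse_conductances: list[tuple[int, float, float]] | None = None,
) -> np.ndarray:
    """Direct steady-state solve (no capacitive term).

    ``synapse_conductances`` is a list of (node_index, g_µS, reversal_mV)
    held constant.  Returns the membrane potential per node (mV).
    """
    p = model.params
    n = model.n
    diag_extra = np.zeros(n)
    rhs = model.leak_uS * p.E_rest
    if injections_nA is not None:
        rhs = rhs + injections_nA
    for node, g, rev in synapse_conductances or []:
        diag_extra[node] += g
        rhs[node] += g * rev
    A = -model.axial + diags(model.leak_uS + model.axial_diag + diag_extra)
    return splu(A.tocsc()).solve(rhs)


# ---------------------------------------------------------------------------
# ON/OFF polarity experiment, scoring, sweeps
# ---------------------------------------------------------------------------

def _make_synapses(model, synapse_table, weight, reversal, tau_rise, tau_decay):
    idx = model.skeleton.index_of(synapse_table["host_node_id"].to_numpy())
    return [ActiveSynapse(int(i), weight, reversal, tau_rise, tau_decay)
            for i in idx]


def polarity_experiment(
    model: CableModel,
    bc_synapses: pd.DataFrame,
    inh_synapses: pd.DataFrame,
    Ge_uS: float,
    Gi_uS: float,
    on_scale: float = 1.0,
    kinetics: SynapseKinetics = SynapseKinetics(),
    duration_ms: float = 30.0,
    dt_ms: float = 0.025,
) -> np.ndarray:
    """Per-node predicted ON/OFF polarity from two stimulation trials.

    ON trial: ON bipolar inputs at Ge plus all inhibitory synapses at
    Gi·on_scale.  OFF trial: OFF bipolar inputs at Ge plus inhibition at
    Gi.  Polarity = (ΔV_ON − ΔV_OFF)/(ΔV_ON + ΔV_OFF) of maximum absolute
    deviations from rest; NaN where both are zero.
    """
    p, kin = model.params, kinetics
    on_bc = bc_synapses[bc_synapses["polarity_class"] == "ON"]
    off_bc = bc_synapses[bc_synapses["polarity_class"] == "OFF"]

    def trial(bc, gi):
        syns = _make_synapses(model, bc, Ge_uS, p.E_e, kin.tau_rise,
                              kin.tau_decay_exc)
        if gi > 0:
            syns += _make_synapses(model, inh_synapses, gi, p.E_i, kin.tau_rise,
                                   kin.tau_decay_inh)
        return run_trial(model, syns, duration_ms, dt_ms)

    dv_on = trial(on_bc, Gi_uS * on_scale)
    dv_off = trial(off_bc, Gi_uS)
    tot = dv_on + dv_off
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, (dv_on - dv_off) / np.where(tot > 0, tot, 1),
                        np.nan)


def score_fit(
    predicted: np.ndarray, measured: np.ndarray, weighting: str = "density",
    bin_width: float = 0.1,
) -> dict:
    """Compare predicted vs measured polarities.

    ``error`` is the (optionally sampling-density-weighted) mean absolute
    polarity difference — density weighting divides each ROI's weight by
    the occupancy of its measured-polarity histogram bin, so oversampled
    polarities do not dominate.  Also returns the Pearson correlation and
    the ON/OFF match (fraction with the same binarized bias; polarity ≥ 0
    counts as ON).
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    ok = ~(np.isnan(predicted) | np.isnan(measured))
    if not ok.any():
        raise ValueError("no defined predictions to score")
    pred, meas = predicted[ok], measured[ok]
    if weighting == "density":
        edges = np.arange(-1, 1 + bin_width / 2, bin_width)
        counts, _ = np.histogram(meas, bins=edges)
        bin_idx = np.clip(np.digitize(meas, edges) - 1, 0, len(counts) - 1)
        w = 1.0 / counts[bin_idx]
    elif weighting == "uniform":
        w = np.ones(len(meas))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    err = float(np.sum(w * np.abs(pred - meas)))
    if pred.std() > 0 and meas.std() > 0:
        cc = float(np.corrcoef(pred, meas)[0, 1])
    else:
        cc = np.nan
    match = float(np.mean((pred >= 0) == (meas >= 0)))
    return {"error": err, "corrcoef": cc, "match": match}


@dataclass
class SweepGrid:
    """Factorial grids over (gm, Ge, Gi, OnScale).

    Defaults are log-spaced over the manually bounded plausible ranges; the
    Gi grid includes 0 for the no-inhibition case.
    """

    gm_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-7, -1, 7))        # S/cm²
    Ge_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, -1, 4))        # µS
    Gi_grid: np.ndarray = field(
        default_factory=lambda: np.r_[0.0, np.logspace(-4, -1, 4)])  # µS
    on_scale_grid: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 0.5, 1.0, 1.25]))

    def combinations(self):
        return itertools.product(self.gm_grid, self.Ge_grid, self.Gi_grid,
                                 self.on_scale_grid)


def sweep(
    skel: Skeleton,
    bc_synapses: pd.DataFrame,
    inh_synapses: pd.DataFrame,
    roi_nodes: np.ndarray,
    roi_polarities: np.ndarray,
    grids: SweepGrid,
    base_params: CableParams = CableParams(),
    kinetics: SynapseKinetics = SynapseKinetics(),
    duration_ms: float = 30.0,
    dt_ms: float = 0.025,
    weighting: str = "density",
) -> pd.DataFrame:
    """Full factorial (gm, Ge, Gi, OnScale) evaluation against measured ROIs.

    Returns a frame ranked by mean polarity error, one row per combination
    (Gi = 0 rows carry ``no_inhibition = True`` and on_scale is collapsed
    to a single value there since it has no effect without inhibition).
    """
    rows = []
    roi_idx = skel.index_of(np.asarray(roi_nodes))
    for gm in grids.gm_grid:
        params = replace(base_params, gm=float(gm))
        model = build_compartments(skel, params)
        for Ge, Gi, on_scale in itertools.product(
                grids.Ge_grid, grids.Gi_grid, grids.on_scale_grid):
            if Gi == 0 and on_scale != grids.on_scale_grid[0]:
                continue  # OnScale is moot without inhibition
            pol = polarity_experiment(model, bc_synapses, inh_synapses,
                                      float(Ge), float(Gi), float(on_scale),
                                      kinetics, duration_ms, dt_ms)
            score = score_fit(pol[roi_idx], roi_polarities, weighting)
            rows.append({"gm": gm, "Ge": Ge, "Gi": Gi, "on_scale": on_scale,
                         "no_inhibition": Gi == 0, **score})
    out = pd.DataFrame(rows).sort_values("error").reset_index(drop=True)
    logger.info("sweep: %d combinations, best error %.4f", len(out),
                out["error"].iloc[0])
    return out
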