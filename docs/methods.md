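# Methods

`vg3plexus` analyzes how a plexus of VGluT3-expressing (VG3) amacrine-cell
dendrites — which carry input and output synapses intermixed on the same
neurites — integrates ON and OFF bipolar-cell (BC) drive and passes it on to
retinal ganglion cells (RGCs). This note documents the models, their
assumptions, the synthetic data used to exercise them, and the numerical
choices made where the design was genuinely open.

## The influence model

Signal spread along a dendrite is summarized by a single functional length
constant λ. A BC ribbon input at geodesic (along-the-arbor) distance *d*
from a point contributes influence

    W = e^(−d/λ) + ε

with unit weight per ribbon; ε is a small additive offset (default 0)
applied once per BC-cell–point pair, compensating the tendency of pixel
noise to pull measured polarity indices toward 0. The predicted ON/OFF
polarity at a point is

    polarity = (s·ON − OFF) / (s·ON + OFF) ∈ [−1, 1]

where ON and OFF are the summed influences of ON- and OFF-type BC cells and
*s* (default 1) scales only the ON side, mirroring the asymmetric ON-trial
inhibition of the cable model. A point that receives no influence has an
**undefined** polarity (NaN), never 0. All distances are geodesic; Euclidean
shortcuts are never used anywhere in the package.

Assumptions: every ribbon input counts equally (no synapse-strength
heterogeneity); influence has no temporal dynamics; for ROIs spanning
several overlapping cells, per-cell fields would simply be summed — the
package computes per-cell fields and the caller combines them.

## Length-constant estimation

Three estimators, deliberately independent in what they consume:

1. **Depth-polarity fit** — the influence model's polarity-vs-IPL-depth
   curve (node polarities averaged within ±0.25 µm of each target depth,
   measured along the tissue axis) is compared to target polarities by
   summed absolute difference over a λ grid of 1–150 µm in 1 µm steps.
   The published depth/polarity arrays for this cell class ship as the
   default target fixture. Depths are weighted equally.
2. **ROI-polarity fit** — grid search over λ × ε (0–0.005 in 0.001 steps) ×
   ON-scale (0.5–2.0 in 0.25 steps, a configurable default since no range
   is established for this factor) minimizing the mean |predicted −
   measured| polarity over skeleton-matched ROIs. The report includes the λ
   level set under a slightly relaxed error ceiling, which conveys how flat
   the error valley is.
3. **Trace-correlation fit** — polarity-free: for ROI pairs in the same
   imaging plane with similar measured polarity (|Δ| < 0.25, configurable),
   the Pearson correlation of their raw calcium traces is compared with the
   Pearson correlation of their per-BC-cell influence vectors; the best λ
   maximizes the correlation between the two coefficient sets across pairs.
   Degenerate (zero-variance) coefficient sets are flagged as errors rather
   than fit.

Grid-argmin ties take the smallest λ — the conservative choice, claiming
less signal spread. The consensus estimate is the arithmetic mean of the
available estimates, rounded to the nearest µm.

**ROI quality control** mirrors the recording workflow: imaging planes
whose removal reduces the mean close-neighbor (<3 µm geodesic) polarity
disagreement by ≥1/3 (relative, configurable) are dropped worst-first;
surviving ROIs within 1 µm merge (single-linkage; polarities and traces
averaged); optionally, ROIs whose per-trial polarity SD exceeds 0.3
(configurable; no established value exists) are excluded. The leave-one-
plane-out contribution is our operationalization of "a plane responsible
for most of the error".

## Passive cable model

A self-contained compartmental solver replaces an external simulator. Every
node of the 0.1 µm-resampled skeleton is a compartment: membrane area
π·d·ℓ (ℓ = half of each incident edge), capacitance cm·area (cm = 1
µF/cm²), leak gm·area, axial conductance (π·d²/4)/(Ra·ℓ) with Ra = 100
Ω·cm. Diameters are floored at 0.1 µm to keep segmentation artifacts from
destabilizing the model. E_rest = −50 mV, E_e = 0 mV, E_i = −60 mV;
temperature (33 °C) is recorded but has no effect on passive dynamics.

Synapses are conductance-based double-exponential point processes
(rise 1 ms; decay 1 ms excitatory, 3 ms inhibitory), peak-normalized so the
weight is the peak conductance in µS. The equal-tau excitatory case is the
standard alpha-function limit. Weights quoted in nS in the literature for
this model family are interpreted as peak conductances; gm is interpreted
in S/cm², an interpretation pinned by the analytic length-constant checks
(0.5 µm dendrite: λ = 35 µm at gm = 10⁻², 354 µm at 10⁻⁴).

Integration is backward Euler (A-stable, so arbitrarily strong shunting
conductances cannot blow up) with dt = 0.025 ms default, 30 ms trials, all
synapses switching on at 5 ms; each step solves the sparse tree system by
LU factorization, re-using the factorization whenever conductances are
constant. A trial errors out if |V| exceeds 500 mV. Peak responses converge
to better than 0.5% under dt halving.

The polarity experiment activates (a) all ON BC inputs plus inhibition
scaled by OnScale, and (b) all OFF BC inputs plus unscaled inhibition;
per-node polarity is (ΔV_ON − ΔV_OFF)/(ΔV_ON + ΔV_OFF) of maximum
**absolute** deviations from rest (the signed/absolute choice is open; we
use absolute so purely hyperpolarizing nodes still register a response).
Sweeps evaluate a full factorial (gm, Ge, Gi, OnScale) grid, report the
Gi = 0 slice separately (OnScale is moot there and is collapsed), and rank
by a sampling-density-weighted mean polarity error: each ROI's weight is
the inverse occupancy of its measured-polarity histogram bin (width 0.1),
so overrepresented polarities do not dominate. The printed sweep bound for
Gi in the source material conflicts with its own best-fit value, so the
grids are user-configurable with defaults spanning both.

## Monte Carlo null models

All nulls ask whether observed connectivity exceeds what depth
co-stratification alone predicts. Per-type weights are the summed product
of the host arbor's cable-depth histogram and the candidate type's
stratification profile (normalized over candidates). Reference profiles for
real cell types can be supplied as CSV; synthetic types use Gaussians
(sd 0.05 IPL fraction) centered on their sublamina.

- **Type reassignment**: the observed synapse count is multinomially
  reassigned to types by overlap weight, 10,000 repetitions.
- **Relocation**: output synapses of each RGC type are moved to arbor
  *nodes* sampled with probability ∝ cable share × overlap-profile density
  at the node's depth (sampling nodes rather than depths guarantees
  on-arbor placement); the ON/OFF influence at relocated positions is
  summed per type into a polarity, with quantile whiskers at
  0.001/0.25/0.5/0.75/0.999. The pooled ON-type-vs-OFF-type polarity
  difference is computed after per-type relocation (per-type-then-pool was
  an open choice; flagged here).
- **Depth-preserving shuffle**: synapses are reassigned uniformly among
  nodes within ±0.5 µm of their own position along the tissue depth axis
  (tolerance read in µm of IPL-axis distance), 1000 repetitions; the
  statistic is the mean |local polarity − cell-mean polarity|.
- **Same-pair pruning**: before depth nulls, synapses between one cell pair
  are greedily thinned (ascending synapse id — the order is unspecified in
  the source, so the deterministic one is used) to ≥10 µm separations.

Confidence intervals come from the ranked per-repetition results centered
at the median: with n sorted values, bounds sit at fractional ranks
(n+1)/2 ± ci·n/2, linearly interpolated (for 1..100 at 95% this yields
exactly (3, 98)).

## Bootstrap statistics

`boot_diff_ci` is the reverse-percentile bootstrap: resample both groups
10,000 times, take the percentile bounds of the resampled mean differences,
and reflect them through twice the observed difference. `parametric_diff_ci`
is Δ̂ ± z·√(SE²_a + SE²_b). The polarity index of a stimulus-locked trace is
PI = Σ(R_ON − R_OFF)/Σ(R_ON + R_OFF) over bar positions, with responses
summed 0.05–1.2 s after stimulus onset/offset on per-position medians over
repeats. Baseline is the mean of the 0.25 s preceding onset (the tail of
the previous epoch; the first epoch wraps) — baseline handling is not
established, so this is a documented, configurable choice. Whether
per-position medians are taken before or after baseline subtraction is also
open; subtraction happens first here. Negative windowed responses are kept
so the index retains its full range.

## Synthetic data

Because the reconstruction this analysis style targets is not publicly
downloadable, a generator produces data with the statistical structure the
analysis assumes. Its defaults are the study conditions, not tuning knobs:

- **Arbor**: stochastic branching random walk (1 µm steps, branch
  probability 0.05/µm, persistent jittered directions) whose depth
  component reflects at the 16–60% IPL band borders, grown to 1243 µm of
  cable (the mean reconstructed arbor length), then resampled to 0.1 µm
  internode spacing. The synthetic IPL is 40 µm thick. Diameters are
  lognormal with median 0.5 µm, smoothed along branches.
- **Synapses**: BC ribbon densities 0.062/µm split multinomially over types
  (3a 52.3%, 3b 8.1%, 4 9.9%, 5o 15.8%, 5i 6.1%, 5t 3.5%, xbc 3.1%, 6 1.0%,
  renormalized from rounded percentages); per-type Gaussian stratification
  profiles with OFF types in the outer sublamina and ON types in the inner
  one. AMC inputs at 0.169/µm, enriched 3× in the inter-strata gap
  (0.32–0.42). Outputs (AMC 0.088/µm uniform; RGC 0.066/µm by target-type
  profile). BC partner identities cluster each cell's synapses within an
  axon-terminal radius (12 µm), giving the spatial coherence the
  correlation estimator relies on.
- **Functional records**: ~56 ROIs per cell (the initial-point density of
  a six-cell recording session) with ground-truth polarity from the
  influence model at the true λ = 16 µm; measured polarity adds Gaussian
  noise (sd 0.1 default) clipped to [−1, 1]. Traces are stimulus-locked
  double-exponential transients at 9.5 frames/s under the full 32-position
  bar protocol (25 µm steps over 800 µm) whose ON/OFF amplitudes encode
  the assigned polarity exactly (verified to machine precision with trace
  noise off); each ROI's position-tuning is the influence-weighted mixture
  of its presynaptic BC cells' receptive-field envelopes with shared
  per-trial gain fluctuations (sd 0.4), so co-driven ROIs have correlated
  traces — the feature the trace-correlation estimator reads. The number
  of bar positions matters: with too few, distinct BC cells have
  indistinguishable position tuning and the correlation estimator loses
  spatial resolution.

What the generator does **not** emulate: EM imaging noise and tracing
errors, mosaic interactions between neighboring cells (cells are
independent), spatial autocorrelation of measurement noise between nearby
ROIs (independence assumed), and manual skeleton corrections. Passing tests
therefore demonstrate that the estimators and nulls are correct and
well-calibrated under the model's own assumptions — not that those
assumptions hold in any particular tissue.

## Problem sizes and determinism

Parameter-recovery runs use 6 cells × ~1243 µm (≈480 synapses and 40 ROIs
per cell) over 10 seeds; cable sweeps use 300 µm arbors at 0.5 µm
compartment spacing, which keeps a full factorial sweep in the tens of
seconds while leaving >500 compartments — the package's choice of a
desk-scale configuration that preserves every qualitative regime of the
full model. All randomness flows from explicit seeds; every pipeline run
writes a manifest with the seed, config hash, and per-stage record counts,
and repeated runs with one seed are bit-identical.

## Known limitations

- The influence model is static; it ignores synaptic depression, timing,
  and calcium-to-release nonlinearities.
- The cable model is passive; no voltage-gated conductances or calcium
  dynamics, so its polarity predictions are about spread of depolarization
  only.
- λ estimators share the skeleton and synapse annotations; annotation
  errors bias all three coherently.
- The trace-correlation estimator needs enough co-driven same-plane ROI
  pairs; below ~3 eligible pairs it refuses to fit, and at small sample
  sizes its estimate is coarse.
- Same-pair pruning and merge rules are order-dependent by design
  (deterministic), which can matter for pathological synapse layouts.
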