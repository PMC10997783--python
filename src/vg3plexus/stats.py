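"""Polarity indices from stimulus-locked traces and difference CIs.

The stimulus is a flashing vertical bar stepped across positions; each
position is shown for ``on_duration`` seconds followed by an equally long
blank, repeated ``n_repeats`` times.  The polarity index of a trace is

    PI = Σ_i (Response_ON,i − Response_OFF,i) / Σ_i (Response_ON,i + Response_OFF,i)

over bar positions i, where the ON (OFF) response is the baseline-subtracted
calcium signal summed in a window after stimulus onset (offset), computed on
the per-position median over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StimulusProtocol",
    "compute_polarity_index",
    "boot_diff_ci",
    "parametric_diff_ci",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Flashing-bar stimulus and response-window geometry.

    Defaults follow a 50 µm bar flashed for 1.5 s with 1.5 s gaps at 25 µm
    steps, imaged at 9.5 frames/s; responses are scored 0.05–1.2 s after
    stimulus onset and offset, against a baseline from the 0.25 s preceding
    onset.
    """

    bar_width_um: float = 50.0
    bar_height_um: float = 70.0
    on_duration_s: float = 1.5
    inter_stimulus_s: float = 1.5
    position_step_um: float = 25.0
    n_positions: int = 32
    n_repeats: int = 4
    frame_rate_hz: float = 9.5
    window_s: tuple[float, float] = (0.05, 1.2)
    baseline_s: float = 0.25

    @property
    def epoch_s(self) -> float:
        return self.on_duration_s + self.inter_stimulus_s

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.frame_rate_hz))

    @property
    def n_frames(self) -> int:
        return self.frames_per_epoch * self.n_positions * self.n_repeats

    def _window_frames(self, t0_s: float) -> np.ndarray:
        lo, hi = self.window_s
        f = np.arange(self.frames_per_epoch) / self.frame_rate_hz
        return np.flatnonzero((f >= t0_s + lo) & (f <= t0_s + hi))


def compute_polarity_index(trace, protocol: StimulusProtocol) -> float:
    """Polarity index of a stimulus-aligned fluorescence trace.

    ``trace`` holds ``protocol.n_frames`` samples ordered as repeats of the
    full position sweep (positions fastest).  Per position, the median over
    repeats is taken, the mean of the pre-onset baseline frames subtracted,
    and the ON/OFF windows summed.  Negative windowed responses are kept.
    Returns NaN when the summed denominator is zero.
    """
    trace = np.asarray(trace, dtype=float)
    fpe = protocol.frames_per_epoch
    expected = protocol.n_frames
    if trace.size != expected:
        raise ValueError(f"trace has {trace.size} frames, protocol expects {expected}")
    # baseline: mean of the 0.25 s preceding each onset, i.e. the tail of
    # the previous epoch (the first epoch wraps to the end of the trace)
    flat = trace.reshape(protocol.n_repeats * protocol.n_positions, fpe)
    n_base = max(1, int(round(protocol.baseline_s * protocol.frame_rate_hz)))
    baselines = np.roll(flat[:, -n_base:].mean(axis=1), 1)
    flat = flat - baselines[:, None]
    # (repeat, position, frame-within-epoch) -> median over repeats
    med = np.median(flat.reshape(protocol.n_repeats, protocol.n_positions, fpe),
                    axis=0)

    on_f = protocol._window_frames(0.0)
    off_f = protocol._window_frames(protocol.on_duration_s)
    resp_on = med[:, on_f].sum(axis=1)
    resp_off = med[:, off_f].sum(axis=1)
    denom = float((resp_on + resp_off).sum())
    if denom == 0:
        return float("nan")
    return float((resp_on - resp_off).sum() / denom)


def boot_diff_ci(
    group_a,
    group_b,
    n_boot: int = 10000,
    ci: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Reverse-percentile bootstrap CI for mean(a) − mean(b).

    Both groups are resampled with replacement ``n_boot`` times; the
    percentile bounds of the resampled differences are subtracted from twice
    the observed difference: CI = 2·Δ̂ − [upper, lower].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    obs = a.mean() - b.mean()
    if a.std() == 0 and b.std() == 0:
        return (obs, obs)
    means_a = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    means_b = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    diffs = means_a - means_b
    alpha = (1 - ci) / 2
    lo_p, hi_p = np.quantile(diffs, [alpha, 1 - alpha])
    return (2 * obs - hi_p, 2 * obs - lo_p)


def parametric_diff_ci(group_a, group_b, ci: float = 0.95) -> tuple[float, float]:
    """Normal-theory CI: Δ̂ ± z · sqrt(SE_a² + SE_b²)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    obs = a.mean() - b.mean()
    se = np.hypot(a.std(ddof=1) / np.sqrt(len(a)), b.std(ddof=1) / np.sqrt(len(b)))
    z = sps.norm.ppf(0.5 + ci / 2)
    return (obs - z * se, obs + z * se)
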