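"""Seeded synthetic recordings with the statistical structure the analysis
pipeline assumes.

The generative model is a slow burst envelope multiplying a network of
Kuramoto phase oscillators: each cell i carries a resonance-shift proxy

    s_i(t) = A_cond * A_i * b_i(t) * (1 + m cos theta_i(t)) + sigma xi_i(t)

where b_i is a raised-cosine-edged square-wave burst envelope (shared clock,
per-cell onset jitter, optional plateau floor) and the phases follow

    dtheta_j/dt = 2 pi (f + df_j) + kappa * sum_i w_ij sin(theta_i - theta_j)
                  + sqrt(2 D(t)) eta_j(t)

integrated by Euler-Maruyama at the sampling step. The coupling matrix
``w_ij`` is the directed influence of cell i on cell j and is the ground
truth for connectivity recovery; per-cell frequency detuning ``df`` gives
directed edges a reproducible lead-lag sign. Phase noise D may be boosted
inside bursts to emulate burst-synchronised but spike-incoherent activity
(envelopes correlate while phases decohere). Condition tags (baseline /
glucose / nifedipine) scale the oscillation amplitude and, optionally, the
coupling, emulating glucose stimulation and L-type calcium-channel block.

Resonance shifts become intensity traces through the SPR operating-point
gradient (cells and background have opposite-sign gradients, so correlated
shifts produce anticorrelated intensities), or are rendered into an image
stack with a Gaussian extracellular spread kernel. A separate generator
produces cell-attached patch-clamp-like current traces with downward
action-current events at condition-dependent Poisson rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_roi import ImageStack, ROISet, TraceTable

__all__ = [
    "NetworkSimConfig",
    "SyntheticRecording",
    "SceneConfig",
    "PatchSimResult",
    "simulate_burst_oscillators",
    "transduce_spr",
    "render_image_stack",
    "simulate_patch_trace",
    "chain_coupling",
]

DEFAULT_AMPLITUDES = {"baseline": 1.0, "glucose": 2.0, "nifedipine": 0.3}


def chain_coupling(n_cells: int, weight: float = 1.0) -> np.ndarray:
    """Feed-forward chain adjacency: cell i drives cell i+1."""
    W = np.zeros((n_cells, n_cells))
    for i in range(n_cells - 1):
        W[i, i + 1] = weight
    return W


@dataclass
class NetworkSimConfig:
    """Parameters of the burst-oscillator network generator.

    ``coupling[i, j]`` is the directed influence of cell i on cell j.
    ``duration_s`` is the length of each condition segment. Frequencies are
    in Hz, phase noise D in rad^2/s. ``burst_floor`` keeps a residual
    oscillation amplitude between bursts (plateau vs. silent phases);
    ``burst_phase_noise_boost`` multiplies D by (1 + boost * burst) to make
    spikes incoherent within synchronised bursts.
    """

    n_cells: int = 6
    coupling: np.ndarray | None = None
    burst_rate_hz: float = 0.05
    burst_duty: float = 0.5
    burst_edge_frac: float = 0.1
    burst_jitter_s: float = 0.2
    burst_floor: float = 0.0
    spike_rate_hz: float = 5.0
    freq_detuning_hz: np.ndarray | None = None
    phase_coupling: float = 8.0
    phase_noise: float = 0.5
    burst_phase_noise_boost: float = 0.0
    modulation_depth: float = 0.8
    amplitude_per_condition: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    coupling_per_condition: Mapping[str, float] | None = None
    burst_suppressed_conditions: tuple[str, ...] = ()
    silent_cells: tuple[int, ...] = ()
    noise_sd: float = 0.05
    fs: float = 100.0
    duration_s: float = 100.0
    seed: int = 0
    n_background: int = 2
    gradient_cell: float = -0.5
    gradient_bg: float = 0.5
    baseline_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = chain_coupling(self.n_cells)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n_cells, self.n_cells):
            raise ValueError("coupling must be n_cells x n_cells")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("self-coupling w_ii must be zero")
        if np.any(self.coupling < 0):
            raise ValueError("coupling weights must be nonnegative")
        if any(a < 0 for a in self.amplitude_per_condition.values()):
            raise ValueError("condition amplitudes must be nonnegative")
        if not (0 < self.burst_duty < 1):
            raise ValueError("burst_duty must lie in (0, 1)")
        if self.fs <= 2 * self.spike_rate_hz:
            raise ValueError("fs must exceed twice the fast oscillation frequency")
        if self.freq_detuning_hz is not None:
            self.freq_detuning_hz = np.asarray(self.freq_detuning_hz, dtype=float)
            if self.freq_detuning_hz.shape != (self.n_cells,):
                raise ValueError("freq_detuning_hz must have one entry per cell")

    @property
    def conditions(self) -> list[str]:
        return list(self.amplitude_per_condition)

    def coupling_scale(self, condition: str) -> float:
        if self.coupling_per_condition is None:
            return 1.0
        return float(self.coupling_per_condition.get(condition, 1.0))


@dataclass
class SyntheticRecording:
    """Generator output plus ground truth for every downstream estimator."""

    shifts: pd.DataFrame  # per-cell resonance-shift proxy
    intensity: TraceTable  # transduced cell + background intensity traces
    truth_adjacency: np.ndarray
    truth_phases: np.ndarray  # (T, n_cells)
    burst_envelope: np.ndarray  # (T, n_cells)
    condition_labels: np.ndarray  # per-sample tag
    fs: float
    config: NetworkSimConfig

    @property
    def cell_names(self) -> list[str]:
        return list(self.shifts.columns)


def _burst_wave(phase: np.ndarray, duty: float, edge: float) -> np.ndarray:
    """Raised-cosine-edged square wave on cycle phase in [0, 1)."""
    w = np.zeros_like(phase)
    rise = phase < edge
    w[rise] = 0.5 * (1 - np.cos(np.pi * phase[rise] / edge))
    plateau = (phase >= edge) & (phase < duty)
    w[plateau] = 1.0
    fall = (phase >= duty) & (phase < duty + edge)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (phase[fall] - duty) / edge))
    return w


def simulate_burst_oscillators(config: NetworkSimConfig) -> SyntheticRecording:
    """Run the burst-envelope Kuramoto generator over all condition segments."""
    cfg = config
    max_in = float(cfg.coupling.sum(axis=0).max())
    worst_scale = 1.0 if cfg.coupling_per_condition is None else max(
        [cfg.coupling_scale(c) for c in cfg.conditions] or [1.0]
    )
    if cfg.phase_coupling * worst_scale * max_in / cfg.fs > 0.1:
        raise ValueError(
            "unstable Euler step: phase_coupling * max in-strength / fs exceeds 0.1"
        )

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    dt = 1.0 / cfg.fs
    n_seg = int(round(cfg.duration_s * cfg.fs))
    conditions = cfg.conditions
    T = n_seg * len(conditions)
    t = np.arange(T) * dt

    labels = np.repeat(conditions, n_seg)
    amp_cond = np.repeat([cfg.amplitude_per_condition[c] for c in conditions], n_seg)
    kappa_cond = np.repeat([cfg.phase_coupling * cfg.coupling_scale(c) for c in conditions], n_seg)

    jitter = rng.uniform(-cfg.burst_jitter_s, cfg.burst_jitter_s, n)
    period = 1.0 / cfg.burst_rate_hz
    phase_cycle = ((t[:, None] + jitter[None, :]) / period) % 1.0
    edge = cfg.burst_edge_frac * cfg.burst_duty
    wave = _burst_wave(phase_cycle, cfg.burst_duty, edge)
    # a Ca-channel-blocked condition abolishes bursting: envelope pinned at the floor
    suppressed = np.isin(labels, list(cfg.burst_suppressed_conditions))
    wave[suppressed, :] = 0.0
    envelope = cfg.burst_floor + (1 - cfg.burst_floor) * wave
    shared_wave = _burst_wave((t / period) % 1.0, cfg.burst_duty, edge)
    shared_wave[suppressed] = 0.0

    detune = cfg.freq_detuning_hz if cfg.freq_detuning_hz is not None else np.zeros(n)
    omega = 2 * np.pi * (cfg.spike_rate_hz + detune)
    WT = cfg.coupling.T  # WT[j, i] = w_ij: influence of i on receiver j

    theta = np.empty((T, n))
    theta[0] = rng.uniform(0, 2 * np.pi, n)
    D_t = cfg.phase_noise * (1 + cfg.burst_phase_noise_boost * shared_wave)
    noise = rng.standard_normal((T - 1, n))
    for k in range(T - 1):
        th = theta[k]
        E = np.exp(1j * th)
        coup = np.imag(np.exp(-1j * th) * (WT @ E))
        drift = omega + kappa_cond[k] * coup
        theta[k + 1] = th + drift * dt + np.sqrt(2 * D_t[k] * dt) * noise[k]

    amp_cell = np.ones(n)
    for idx in cfg.silent_cells:
        amp_cell[idx] = 0.0
    clean = amp_cond[:, None] * amp_cell[None, :] * envelope * (1 + cfg.modulation_depth * np.cos(theta))
    shifts = clean + cfg.noise_sd * rng.standard_normal((T, n))
    cell_names = [f"cell{i + 1}" for i in range(n)]
    shifts_df = pd.DataFrame(shifts, columns=cell_names)

    # background ROIs mix the noiseless cell sources (extracellular spread),
    # then add their own sensor noise
    bg = {}
    for b in range(cfg.n_background):
        wmix = rng.dirichlet(np.ones(n))
        bg[f"bg{b + 1}"] = clean @ wmix + cfg.noise_sd * rng.standard_normal(T)
    all_shifts = shifts_df.copy()
    for name, series in bg.items():
        all_shifts[name] = series

    gradients = {name: cfg.gradient_cell for name in cell_names}
    gradients.update({name: cfg.gradient_bg for name in bg})
    kinds = {name: "cell" for name in cell_names}
    kinds.update({name: "background" for name in bg})
    intensity = transduce_spr(all_shifts, gradients, cfg.baseline_intensity, cfg.fs, kinds=kinds)
    intensity.condition = labels

    return SyntheticRecording(
        shifts=shifts_df,
        intensity=intensity,
        truth_adjacency=cfg.coupling.copy(),
        truth_phases=theta,
        burst_envelope=envelope,
        condition_labels=labels,
        fs=cfg.fs,
        config=cfg,
    )


def transduce_spr(
    shifts: pd.DataFrame,
    gradients: Mapping[str, float],
    baseline_intensity: float = 1000.0,
    fs: float = 100.0,
    kinds: Mapping[str, str] | None = None,
) -> TraceTable:
    """Linearised SPR readout: I_roi(t) = I0 * (1 + g_roi * s_roi(t)).

    ``g_roi`` is the reflectivity gradient at the operating angle (per unit
    resonance-shift proxy); opposite signs for cell and background ROIs
    reproduce the anticorrelated intensities of a shared resonance shift.
    """
    missing = [c for c in shifts.columns if c not in gradients]
    if missing:
        raise ValueError(f"no gradient supplied for {missing}")
    out = {}
    for name in shifts.columns:
        out[name] = baseline_intensity * (1.0 + gradients[name] * shifts[name].to_numpy())
    table_kinds = dict(kinds) if kinds else {name: "cell" for name in shifts.columns}
    return TraceTable(pd.DataFrame(out), fs, table_kinds)


@dataclass
class SceneConfig:
    """Spatial layout for rendering an image stack.

    Field sizes in micrometres; ``spread_length_um`` is the scale of the
    Gaussian kernel carrying each cell's signal into the extracellular
    space. Cell and background intensity gradients must have opposite signs
    by default (the SPR operating point).
    """

    field_size_um: tuple[float, float] = (85.0, 91.0)  # (width, height)
    pixel_size_um: float = 1.0
    cell_centres_um: tuple[tuple[float, float], ...] = ()
    cell_radii_um: tuple[float, ...] = ()
    spread_length_um: float = 5.0
    gradient_cell: float = -0.5
    gradient_bg: float = 0.5
    baseline: float = 1000.0
    pixel_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if len(self.cell_centres_um) != len(self.cell_radii_um):
            raise ValueError("one radius per cell centre")
        if self.gradient_cell * self.gradient_bg >= 0:
            raise ValueError("cell and background gradients must have opposite signs")
        W, H = self.field_size_um
        for (x, y), r in zip(self.cell_centres_um, self.cell_radii_um):
            if not (0 <= x <= W and 0 <= y <= H):
                raise ValueError(f"cell centre ({x}, {y}) outside the field")
            if r <= 0:
                raise ValueError("cell radii must be positive")


def default_scene(n_cells: int = 6) -> SceneConfig:
    """Six ~8 um cells scattered over the 85 x 91 um field."""
    centres = ((20.0, 20.0), (45.0, 18.0), (68.0, 30.0), (25.0, 50.0), (52.0, 55.0), (70.0, 72.0))
    radii = (8.0, 7.0, 8.0, 7.5, 8.0, 7.0)
    return SceneConfig(cell_centres_um=centres[:n_cells], cell_radii_um=radii[:n_cells])


def render_image_stack(
    scene: SceneConfig,
    recording: SyntheticRecording,
    max_frames: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, ROISet]:
    """Render per-cell shifts into a T x H x W movie plus ground-truth masks.

    Pixel value = baseline + sum_i K_i(x) * g(x) * s_i(t) * I0 + noise,
    with K_i = 1 inside cell i and Gaussian-decaying outside it, and g(x)
    the cell gradient inside any cell mask, the background gradient
    elsewhere.
    """
    cfg = recording.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    W_um, H_um = scene.field_size_um
    px = scene.pixel_size_um
    W = int(round(W_um / px))
    H = int(round(H_um / px))
    n_cells = len(scene.cell_centres_um)
    if n_cells != recording.shifts.shape[1]:
        raise ValueError("scene cell count must match the recording")

    xs = (np.arange(W) + 0.5) * px
    ys = (np.arange(H) + 0.5) * px
    XX, YY = np.meshgrid(xs, ys)
    K = np.empty((n_cells, H, W))
    inside_any = np.zeros((H, W), dtype=bool)
    labels = np.zeros((H, W), dtype=np.int32)
    for i, ((cx, cy), r) in enumerate(zip(scene.cell_centres_um, scene.cell_radii_um)):
        d = np.hypot(XX - cx, YY - cy)
        outside = np.clip(d - r, 0, None)
        if scene.spread_length_um > 0:
            K[i] = np.exp(-(outside**2) / (2 * scene.spread_length_um**2))
        else:
            K[i] = (outside == 0).astype(float)
        inside = d <= r
        labels[inside & (labels == 0)] = i + 1
        inside_any |= inside

    g = np.where(inside_any, scene.gradient_cell, scene.gradient_bg)
    M = (K * g[None, :, :]).reshape(n_cells, -1)  # (n_cells, H*W)

    S = recording.shifts.to_numpy()
    if max_frames is not None:
        S = S[:max_frames]
    T = S.shape[0]
    frames = scene.baseline * (1.0 + (S @ M).reshape(T, H, W))
    frames += scene.pixel_noise_sd * rng.standard_normal(frames.shape)

    names = recording.cell_names
    rois = ROISet(labels, names, ["cell"] * n_cells)
    stack = ImageStack(frames.astype(np.float32), recording.fs, px)
    return stack, rois


@dataclass
class PatchSimResult:
    trace_pa: np.ndarray
    fs: float
    truth_times_s: np.ndarray
    truth_conditions: np.ndarray  # per-event condition
    condition_labels: np.ndarray  # per-sample condition
    segment_bounds_s: dict


def simulate_patch_trace(
    rates_per_condition: Mapping[str, float],
    duration_s: float | Mapping[str, float] = 100.0,
    event_amplitude_pa: float = 3.0,
    event_width_s: float = 0.002,
    noise_sd_pa: float = 0.2,
    fs: float = 10_000.0,
    refractory_s: float = 0.05,
    seed: int = 0,
    noise_dist: str = "uniform",
) -> PatchSimResult:
    """Cell-attached-like current trace with downward action-current events.

    Per condition segment, event times form a refractory-modified Poisson
    (renewal) process: inter-event gaps are the refractory period plus an
    exponential whose scale is chosen so the realised event rate equals the
    requested spikes/s. Each event adds a downward Gaussian deflection of
    FWHM ``event_width_s`` to zero-median noise of standard deviation
    ``noise_sd_pa``.

    The default noise is uniform (bounded support): a median/MAD threshold
    at baseline - 3 * MAD then sits strictly outside the noise band, so the
    detector's operating regime is well defined at any sampling rate. With
    ``noise_dist='gaussian'`` the same threshold lies near 2 sigma and
    unbounded noise produces a high background crossing rate at 10 kHz;
    that variant exists to study the detector's failure mode, not as the
    reference condition.
    """
    import warnings

    if fs * event_width_s < 2:
        warnings.warn("event width below two samples; events may be missed", stacklevel=2)
    if noise_dist not in ("uniform", "gaussian"):
        raise ValueError("noise_dist must be 'uniform' or 'gaussian'")
    rng = np.random.default_rng(seed)
    conditions = list(rates_per_condition)
    durations = (
        {c: float(duration_s) for c in conditions}
        if np.isscalar(duration_s)
        else {c: float(duration_s[c]) for c in conditions}
    )
    for c, rate in rates_per_condition.items():
        if rate < 0:
            raise ValueError("rates must be nonnegative")

    seg_samples = {c: int(round(durations[c] * fs)) for c in conditions}
    T = sum(seg_samples.values())
    if noise_dist == "uniform":
        half_width = noise_sd_pa * np.sqrt(3.0)  # uniform(-w, w) has sd w/sqrt(3)
        trace = rng.uniform(-half_width, half_width, T)
    else:
        trace = noise_sd_pa * rng.standard_normal(T)
    labels = np.repeat(conditions, [seg_samples[c] for c in conditions])

    sigma = event_width_s / 2.355  # FWHM -> Gaussian sigma
    half = max(1, int(round(4 * sigma * fs)))
    kernel_t = (np.arange(-half, half + 1)) / fs
    kernel = -event_amplitude_pa * np.exp(-(kernel_t**2) / (2 * sigma**2))

    times, ev_conds = [], []
    t0 = 0.0
    bounds = {}
    for c in conditions:
        dur = durations[c]
        bounds[c] = (t0, t0 + dur)
        rate = rates_per_condition[c]
        if rate > 0:
            scale = 1.0 / rate - refractory_s
            if scale <= 0:
                raise ValueError(f"rate {rate}/s incompatible with the {refractory_s}s refractory period")
            t = rng.exponential(scale)
            while t < dur:
                times.append(t0 + t)
                ev_conds.append(c)
                t += refractory_s + rng.exponential(scale)
        t0 += dur

    for t_ev in times:
        idx = int(round(t_ev * fs))
        lo = max(0, idx - half)
        hi = min(T, idx + half + 1)
        trace[lo:hi] += kernel[lo - (idx - half) : hi - (idx - half)]

    return PatchSimResult(
        trace_pa=trace,
        fs=fs,
        truth_times_s=np.asarray(times),
        truth_conditions=np.asarray(ev_conds),
        condition_labels=labels,
        segment_bounds_s=bounds,
    )
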