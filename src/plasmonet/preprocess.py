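"""Signal conditioning: zero-phase band-pass filtering, analytic-signal
decomposition, envelope smoothing, condition-wise standardisation and
downsampling.

All operations are deterministic. Band-pass filtering uses a Butterworth
design applied forward and backward (zero net phase, squared magnitude
response). The analytic signal z(t) = R(t) e^{i theta(t)} comes from the
Hilbert transform; R is the amplitude envelope and theta the instantaneous
phase used by the phase-locking connectivity estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "PRESETS",
    "AnalyticSignal",
    "bandpass_zero_phase",
    "analytic_signal",
    "smooth_envelope",
    "standardize_across_conditions",
    "downsample",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (edges in Hz)."""

    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


#: Named band presets: the 1-15 Hz network band, the 0.1-15 Hz slow-activity
#: band with its sub-bands, and the 0.1-5 Hz calcium-imaging band.
PRESETS: dict[str, FilterSpec] = {
    "network_1_15": FilterSpec(1.0, 15.0),
    "mea_0p1_15": FilterSpec(0.1, 15.0),
    "sub_0p1_1": FilterSpec(0.1, 1.0),
    "sub_1_10": FilterSpec(1.0, 10.0),
    "sub_10_15": FilterSpec(10.0, 15.0),
    "calcium_0p1_5": FilterSpec(0.1, 5.0),
}


@dataclass
class AnalyticSignal:
    """Amplitude envelope and instantaneous phase of one trace."""

    amplitude: np.ndarray
    phase: np.ndarray  # wrapped to (-pi, pi]
    phase_unwrapped: np.ndarray
    phase_defined: bool = True

    @property
    def z(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


def bandpass_zero_phase(trace: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Forward-backward Butterworth band-pass; length preserved.

    The two passes square the magnitude response and cancel the phase, so
    in-band features keep their timing. Edge transients are suppressed by
    odd-reflection padding inside ``sosfiltfilt``.
    """
    if spec.high_hz >= fs / 2:
        raise ValueError("high band edge must be below Nyquist")
    x = np.asarray(trace, dtype=float)
    multi = x.ndim == 2
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos")
    if not spec.zero_phase:
        return sps.sosfilt(sos, x, axis=-1)
    padlen = min(x.shape[-1] - 1, max(3 * (2 * sos.shape[0] + 1), int(3 * fs / spec.low_hz) if spec.low_hz > 0 else 0, 150))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def analytic_signal(trace: np.ndarray) -> AnalyticSignal:
    """Hilbert-transform decomposition into envelope and phase.

    Returns z(t) = x(t) + i H[x](t) split into R = |z| and theta = arg z.
    An all-zero input has zero amplitude and an undefined phase, flagged via
    ``phase_defined``.
    """
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if np.all(x == 0):
        zeros = np.zeros_like(x)
        return AnalyticSignal(zeros, zeros.copy(), zeros.copy(), phase_defined=False)
    z = sps.hilbert(x, axis=-1)
    phase = np.angle(z)
    return AnalyticSignal(np.abs(z), phase, np.unwrap(phase, axis=-1))


def smooth_envelope(envelope: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centred moving average with edge-truncated (shrinking) windows."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(envelope, dtype=float)
    w = max(1, int(round(window_s * fs)))
    if w == 1:
        return x.copy()
    kernel = np.ones(w)

    def _smooth_1d(v: np.ndarray) -> np.ndarray:
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        return sums / counts

    if x.ndim == 1:
        return _smooth_1d(x)
    return np.apply_along_axis(_smooth_1d, -1, x)


def standardize_across_conditions(traces_by_condition: dict) -> dict:
    """Divide each trace by its standard deviation pooled over all conditions.

    Input/output: mapping condition -> DataFrame-like of per-cell traces
    (columns = cells). The concatenation of each cell's standardised
    segments has unit standard deviation, so amplitudes are comparable
    across conditions.
    """
    import pandas as pd

    if not traces_by_condition:
        raise ValueError("need at least one condition")
    frames = {c: pd.DataFrame(v) for c, v in traces_by_condition.items()}
    cols = list(next(iter(frames.values())).columns)
    for df in frames.values():
        if list(df.columns) != cols:
            raise ValueError("conditions must share the same cells")
    pooled = pd.concat(list(frames.values()), axis=0)
    sd = pooled.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero variance across all conditions for {bad}")
    return {c: df / sd for c, df in frames.items()}


def downsample(trace: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    """Decimate a (band-limited) trace from ``fs`` to ``target_fs``.

    Integer ratios decimate by plain striding (the caller has already
    band-limited the signal below target_fs/2, e.g. with a 0.1-15 Hz
    band-pass before going to 400 Hz); non-integer ratios go through a
    polyphase rational resampler.
    """
    if target_fs >= fs:
        raise ValueError("target_fs must be below fs")
    x = np.asarray(trace, dtype=float)
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        return x[..., :: int(round(ratio))].copy(), target_fs
    from fractions import Fraction

    frac = Fraction(target_fs / fs).limit_denominator(10_000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return y, target_fs
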