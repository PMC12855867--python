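"""Spike detection and condition-comparison statistics.

Events are detected with a robust dynamic threshold: baseline is the signal
median, the noise scale is the median absolute deviation (MAD), and a spike
is a downward excursion below baseline - k * noise (k = 3 by default) with a
refractory period suppressing re-triggers. The raw MAD is used as the noise
scale by default; a Gaussian-consistency factor (1.4826) is available as an
option. Event times are placed at the excursion extremum and the refractory
period is enforced between event times.

Condition comparisons use paired t-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeTrain",
    "ZeroNoiseError",
    "detect_spikes",
    "windowed_rates",
    "compare_conditions",
    "GAUSSIAN_MAD_SCALE",
]

GAUSSIAN_MAD_SCALE = 1.4826


class ZeroNoiseError(ValueError):
    """The MAD noise estimate is zero; an explicit noise floor is required."""


@dataclass
class SpikeTrain:
    """Detected events with the detector's provenance."""

    times_s: np.ndarray
    amplitudes: np.ndarray  # extremum minus baseline (signed)
    detector_params: dict = field(default_factory=dict)
    condition: str | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times_s) != len(self.amplitudes):
            raise ValueError("times and amplitudes must align")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.times_s)


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    k: float = 3.0,
    refractory_s: float = 0.05,
    polarity: str = "down",
    mad_scale: float = 1.0,
    noise_floor: float | None = None,
    condition: str | None = None,
) -> SpikeTrain:
    """Dynamic-threshold event detection on a single trace.

    threshold = baseline - k * noise (``polarity='down'``; mirrored for
    'up'), with baseline = median and noise = mad_scale * MAD. A contiguous
    below-threshold excursion yields one event at its minimum; an excursion
    starting within ``refractory_s`` of the previous event time merges into
    it (the event follows the deepest point of the merged group) rather than
    triggering anew. Detection is invariant under positive rescaling and
    additive offsets of the trace.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if polarity not in ("down", "up"):
        raise ValueError("polarity must be 'down' or 'up'")

    baseline = float(np.median(x))
    noise = mad_scale * float(np.median(np.abs(x - baseline)))
    if noise == 0:
        if noise_floor is None:
            raise ZeroNoiseError(
                "MAD noise estimate is zero; pass noise_floor explicitly for a noiseless trace"
            )
        noise = float(noise_floor)

    y = x - baseline if polarity == "down" else baseline - x
    thr = -k * noise
    below = y < thr
    if not below.any():
        return SpikeTrain(
            np.empty(0), np.empty(0),
            {"baseline": baseline, "noise": noise, "threshold": baseline + (thr if polarity == "down" else -thr),
             "k": k, "refractory_s": refractory_s, "polarity": polarity, "mad_scale": mad_scale},
            condition,
        )

    edges = np.diff(below.astype(np.int8))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(y)]

    # merge below-threshold runs that fall within the refractory period of
    # the current event (noise can fragment one deflection into several
    # crossings); the event time tracks the deepest point of the merged group
    times, amps = [], []
    for s0, e0 in zip(starts, ends):
        seg = y[s0:e0]
        i_min = s0 + int(np.argmin(seg))
        t_run = i_min / fs
        if times and s0 / fs - times[-1] < refractory_s:
            if y[i_min] < y[int(round(times[-1] * fs))]:
                times[-1] = t_run
                amps[-1] = x[i_min] - baseline
            continue
        times.append(t_run)
        amps.append(x[i_min] - baseline)

    return SpikeTrain(
        np.asarray(times), np.asarray(amps),
        {"baseline": baseline, "noise": noise,
         "threshold": baseline + (thr if polarity == "down" else -thr),
         "k": k, "refractory_s": refractory_s, "polarity": polarity, "mad_scale": mad_scale},
        condition,
    )


def windowed_rates(
    train: SpikeTrain,
    duration_s: float,
    window_s: float = 10.0,
    step_s: float = 2.0,
    t_start: float = 0.0,
) -> pd.DataFrame:
    """Firing rate in sliding windows [t, t + window) on the step grid.

    Returns a DataFrame with columns window_start_s and rate_hz.
    """
    if window_s > duration_s:
        raise ValueError("window longer than the trace")
    starts = []
    t = t_start
    while t + window_s <= t_start + duration_s + 1e-12:
        starts.append(t)
        t += step_s
    starts = np.asarray(starts)
    times = train.times_s
    rates = np.array([np.sum((times >= s) & (times < s + window_s)) / window_s for s in starts])
    return pd.DataFrame({"window_start_s": starts, "rate_hz": rates})


def compare_conditions(
    samples: dict,
    comparisons: list[tuple[str, str]] | None = None,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Paired t-tests between conditions with Bonferroni adjustment.

    ``samples`` maps condition -> 1-D array of paired measurements (same
    subjects/windows in the same order). Zero-variance differences are
    reported with NaN statistics and an explanatory note rather than a
    fabricated p-value. p_adj = min(1, p * n_comparisons).
    """
    conditions = list(samples)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]]
    if n_comparisons is None:
        n_comparisons = len(comparisons)
    rows = []
    for a, b in comparisons:
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if len(xa) != len(xb):
            raise ValueError(f"unequal paired sample sizes for ({a}, {b})")
        if len(xa) < 2:
            raise ValueError("need at least two pairs")
        diff = xa - xb
        if np.std(diff, ddof=1) == 0:
            rows.append({"a": a, "b": b, "t": np.nan, "p": np.nan, "p_adj": np.nan,
                         "note": "zero-variance differences; t undefined"})
            continue
        t, p = stats.ttest_rel(xa, xb)
        rows.append({"a": a, "b": b, "t": float(t), "p": float(p),
                     "p_adj": float(min(1.0, p * n_comparisons)), "note": ""})
    return pd.DataFrame(rows)
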