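"""Image-stack and trace-table I/O, ROI integration, and grid channelisation.

An :class:`ImageStack` is a T x H x W intensity movie with acquisition
metadata (frame rate, pixel size). Time series are carried in a
:class:`TraceTable`: a pandas DataFrame of uniformly sampled traces (one
column per ROI or grid channel) plus the sampling rate, per-trace metadata
and an optional per-sample condition tag.

Stacks round-trip through multi-page TIFF with a JSON metadata payload in
the image description; traces round-trip through CSV with a leading
``time_s`` column. Grid channels tile the field of view with non-overlapping
squares from the top-left origin, discarding partial edge tiles; channel
labels are 1-based ``ch{row}_{col}`` in human-facing output while grid
coordinates are kept 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "ROISet",
    "TraceTable",
    "MissingMetadataError",
    "read_stack",
    "write_stack",
    "extract_roi_traces",
    "grid_channels",
]


class MissingMetadataError(ValueError):
    """A required acquisition-metadata field is absent from a stack file."""


@dataclass
class ImageStack:
    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float
    pixel_size_um: float
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ROISet:
    """Named regions of interest over an H x W field.

    ``labels`` is an integer label image: 0 = unassigned, ROI k occupies the
    pixels labelled k+1 (k indexing ``names``/``kinds``).
    """

    labels: np.ndarray
    names: list[str]
    kinds: list[str]  # per-ROI: "cell" or "background"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be an H x W image")
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must align")
        present = set(np.unique(self.labels)) - {0}
        expected = set(range(1, len(self.names) + 1))
        missing = expected - present
        if missing:
            raise ValueError(f"empty ROI label(s): {sorted(missing)}")


@dataclass
class TraceTable:
    """Labelled, uniformly sampled time series.

    ``values``: DataFrame, one column per trace, RangeIndex in samples.
    ``kinds``: per-column role ("cell" / "background" / "channel").
    ``grid_coords``: 0-based (row, col) per grid channel, when applicable.
    ``condition``: per-sample condition tag, or None.
    """

    values: pd.DataFrame
    fs: float
    kinds: dict[str, str] = field(default_factory=dict)
    grid_coords: dict[str, tuple[int, int]] | None = None
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.condition is not None and len(self.condition) != len(self.values):
            raise ValueError("condition tags must match the number of samples")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def segment(self, condition: str) -> "TraceTable":
        """Sub-table of the samples tagged with the given condition."""
        if self.condition is None:
            raise ValueError("table carries no condition tags")
        mask = np.asarray(self.condition) == condition
        if not mask.any():
            raise KeyError(f"no samples tagged {condition!r}")
        vals = self.values.loc[mask].reset_index(drop=True)
        return TraceTable(vals, self.fs, dict(self.kinds), self.grid_coords, None)

    def conditions(self) -> list[str]:
        if self.condition is None:
            return []
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "time_s", self.time_s)
        if self.condition is not None:
            out["condition"] = self.condition
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "TraceTable":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise MissingMetadataError("trace CSV lacks a time_s column")
        t = df.pop("time_s").to_numpy()
        condition = df.pop("condition").to_numpy() if "condition" in df.columns else None
        if fs is None:
            if len(t) < 2:
                raise MissingMetadataError("cannot infer fs from a single sample")
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(df, float(fs), condition=condition)


# ---------------------------------------------------------------------------
# stack I/O

def write_stack(stack: ImageStack, path) -> None:
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
    }
    if stack.exposure_ms is not None:
        meta["exposure_ms"] = stack.exposure_ms
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta))


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    for key in ("frame_rate_hz", "pixel_size_um"):
        if key not in meta:
            raise MissingMetadataError(f"stack {Path(path).name} lacks metadata field {key!r}")
    return ImageStack(
        frames,
        float(meta["frame_rate_hz"]),
        float(meta["pixel_size_um"]),
        float(meta["exposure_ms"]) if "exposure_ms" in meta else None,
    )


# ---------------------------------------------------------------------------
# trace extraction

def extract_roi_traces(stack: ImageStack, rois: ROISet, reduce: str = "sum") -> TraceTable:
    """Per-frame reduction of pixel intensities over each ROI.

    ``reduce='sum'`` integrates intensity over the ROI (the default);
    ``'mean'`` averages it, as in fluorescence ROI pipelines.
    """
    if reduce not in ("sum", "mean"):
        raise ValueError("reduce must be 'sum' or 'mean'")
    if rois.labels.shape != stack.shape_hw:
        raise ValueError("ROI label image does not match the stack field")
    T = stack.n_frames
    flat = stack.frames.reshape(T, -1)
    lab = rois.labels.ravel()
    n_roi = len(rois.names)
    cols = {}
    for k, name in enumerate(rois.names):
        mask = lab == k + 1
        vals = flat[:, mask].sum(axis=1, dtype=np.float64)
        if reduce == "mean":
            vals = vals / mask.sum()
        cols[name] = vals
    kinds = dict(zip(rois.names, rois.kinds))
    return TraceTable(pd.DataFrame(cols), stack.frame_rate_hz, kinds)


def grid_channel_count(width_px: int, height_px: int, pixel_size_um: float, channel_size_um: float) -> tuple[int, int]:
    """(rows, cols) of full channel tiles: floor(extent / channel) per axis."""
    cols = int(np.floor(width_px * pixel_size_um / channel_size_um))
    rows = int(np.floor(height_px * pixel_size_um / channel_size_um))
    return rows, cols


def grid_channels(stack: ImageStack, channel_size_um: float = 1.0) -> TraceTable:
    """Integrated trace per non-overlapping channel tile of the field.

    Tiles are squares of side ``channel_size_um`` laid from the top-left
    origin; pixels are assigned to the tile containing their top-left
    corner, and partial tiles at the right/bottom edges are discarded.
    """
    if channel_size_um < stack.pixel_size_um:
        raise ValueError("channel size must be at least one pixel")
    H, W = stack.shape_hw
    rows, cols = grid_channel_count(W, H, stack.pixel_size_um, channel_size_um)
    if rows == 0 or cols == 0:
        raise ValueError("field too small for a single channel")

    px = stack.pixel_size_um
    col_idx = np.floor(np.arange(W) * px / channel_size_um).astype(int)
    row_idx = np.floor(np.arange(H) * px / channel_size_um).astype(int)
    valid_c = col_idx < cols
    valid_r = row_idx < rows
    chan_map = np.full((H, W), -1, dtype=int)
    rr, cc = np.meshgrid(row_idx, col_idx, indexing="ij")
    ok = valid_r[:, None] & valid_c[None, :]
    chan_map[ok] = rr[ok] * cols + cc[ok]

    T = stack.n_frames
    flat_map = chan_map.ravel()
    sel = flat_map >= 0
    idx = flat_map[sel]
    frames = stack.frames.reshape(T, -1)[:, sel]
    traces = np.zeros((T, rows * cols))
    for t in range(T):
        traces[t] = np.bincount(idx, weights=frames[t], minlength=rows * cols)

    names = [f"ch{r + 1}_{c + 1}" for r in range(rows) for c in range(cols)]
    coords = {f"ch{r + 1}_{c + 1}": (r, c) for r in range(rows) for c in range(cols)}
    df = pd.DataFrame(traces, columns=names)
    kinds = {name: "channel" for name in names}
    return TraceTable(df, stack.frame_rate_hz, kinds, grid_coords=coords)
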