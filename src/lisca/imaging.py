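"""ROI-grid extraction of single-cell traces from micropatterned image stacks.

Cells sit on a square lattice of adhesion sites (30 x 30 um sites on a
90 um pitch in the reference acquisition).  A :class:`ROIGrid` maps each
lattice site (row, col) to a half-open pixel rectangle; per frame the
total integrated fluorescence inside each occupied rectangle becomes one
sample of that cell's :class:`Trace`.

Conventions used throughout (documented once, here):

* pixel rectangles are half-open ``[start, start + size)``,
* pixel indices are 0-based and row-major with origin at the top-left,
* frame order equals time order; timestamps are hours since the first
  exposure after compound administration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "ROIGrid",
    "ImageStack",
    "build_roi_grid",
    "background_correct",
    "extract_traces",
    "occupancy_from_frame",
    "flag_suspicious_sites",
]


@dataclass
class Trace:
    """One cell x one marker intensity time series with uniform sampling."""

    cell_id: object
    marker: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def sampling_interval(self) -> float:
        """Median frame spacing in hours."""
        if self.n < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class ROIGrid:
    """Square ROI lattice aligned to the micropattern.

    ``origin`` is the (row, col) pixel of the first site's top-left
    corner; ``pitch_px`` is the centre-to-centre lattice spacing and
    ``site_px`` the square site edge, both in pixels.  ``um_per_px`` is
    metadata only (physical calibration).
    """

    origin: tuple[int, int]
    site_px: int
    pitch_px: int
    rows: int
    cols: int
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.site_px <= 0 or self.pitch_px <= 0:
            raise ValueError("site_px and pitch_px must be positive")
        if self.site_px > self.pitch_px:
            raise ValueError(
                f"site_px ({self.site_px}) must not exceed pitch_px ({self.pitch_px})"
            )
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")
        if min(self.origin) < 0:
            raise ValueError("origin must be non-negative")

    def site_slices(self, row: int, col: int) -> tuple[slice, slice]:
        """Half-open pixel rectangle of site (row, col)."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"site ({row}, {col}) outside {self.rows}x{self.cols} grid")
        r0 = self.origin[0] + row * self.pitch_px
        c0 = self.origin[1] + col * self.pitch_px
        return slice(r0, r0 + self.site_px), slice(c0, c0 + self.site_px)

    def sites(self) -> Iterator[tuple[int, int]]:
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c

    def frame_extent(self) -> tuple[int, int]:
        """Minimal (height, width) frame that contains every site."""
        h = self.origin[0] + (self.rows - 1) * self.pitch_px + self.site_px
        w = self.origin[1] + (self.cols - 1) * self.pitch_px + self.site_px
        return h, w

    def check_frame(self, frame_shape: tuple[int, int]) -> None:
        """Raise listing every site that falls outside ``frame_shape``."""
        bad = []
        for r, c in self.sites():
            rs, cs = self.site_slices(r, c)
            if rs.stop > frame_shape[0] or cs.stop > frame_shape[1]:
                bad.append((r, c))
        if bad:
            raise ValueError(
                f"grid exceeds frame {frame_shape}: offending sites {bad}"
            )

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean (H, W) array, True inside any ROI."""
        m = np.zeros(frame_shape, dtype=bool)
        for r, c in self.sites():
            rs, cs = self.site_slices(r, c)
            m[rs, cs] = True
        return m


def build_roi_grid(
    origin: tuple[int, int],
    site_px: int,
    pitch_px: int,
    rows: int,
    cols: int,
    frame_shape: tuple[int, int] | None = None,
    um_per_px: float | None = None,
) -> ROIGrid:
    """Construct a validated :class:`ROIGrid`.

    If ``frame_shape`` is given, every site must fit inside it; the
    error message lists the offending sites.
    """
    grid = ROIGrid(
        origin=(int(origin[0]), int(origin[1])),
        site_px=int(site_px),
        pitch_px=int(pitch_px),
        rows=int(rows),
        cols=int(cols),
        um_per_px=um_per_px,
    )
    if frame_shape is not None:
        grid.check_frame(frame_shape)
    return grid


@dataclass
class ImageStack:
    """Ordered 2-D frames of one fluorescence channel.

    ``times`` are hours since the first frame; they must be strictly
    increasing and uniform within a 1% tolerance on the frame interval.
    """

    frames: np.ndarray
    times: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] != self.times.size:
            raise ValueError("number of frames must match number of timestamps")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValueError("timestamps must be strictly increasing")
            mean_dt = dt.mean()
            if np.max(np.abs(dt - mean_dt)) > 0.01 * mean_dt:
                raise ValueError("timestamps must be uniform within 1%")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


class BackgroundResult(NamedTuple):
    stack: "ImageStack"
    background: np.ndarray  # per-frame scalar estimate, logged for QC


def background_correct(
    stack: ImageStack,
    grid: ROIGrid,
    method: str = "median-outside",
    percentile: float | None = None,
) -> BackgroundResult:
    """Subtract a per-frame scalar background estimated outside all ROIs.

    The default estimator is the median of all out-of-ROI pixels, which
    is robust to sparse bright cells.  ``method='percentile-outside'``
    uses the given percentile instead.  Negative pixels after the
    subtraction are clamped to 0 because the integrated intensities feed
    positive-amplitude models downstream.

    Returns the corrected stack together with the per-frame background
    estimates.
    """
    grid.check_frame(stack.frame_shape)
    outside = ~grid.mask(stack.frame_shape)
    if not outside.any():
        raise ValueError(
            "no pixels outside the ROI grid; use a percentile-within "
            "estimator or a sparser grid"
        )
    if method == "median-outside":
        est = np.median(stack.frames[:, outside], axis=1)
    elif method == "percentile-outside":
        if percentile is None:
            raise ValueError("percentile-outside requires a percentile value")
        est = np.percentile(stack.frames[:, outside], percentile, axis=1)
    else:
        raise ValueError(f"unknown background method {method!r}")
    corrected = stack.frames.astype(float) - est[:, None, None]
    np.clip(corrected, 0.0, None, out=corrected)
    logger.debug(
        "background_correct[%s]: per-frame estimates %.3g..%.3g",
        stack.channel, float(np.min(est)), float(np.max(est)),
    )
    return BackgroundResult(
        ImageStack(frames=corrected, times=stack.times.copy(), channel=stack.channel),
        np.asarray(est, dtype=float),
    )


def _occupancy_items(
    occupancy: Mapping[tuple[int, int], object] | pd.DataFrame,
) -> list[tuple[int, int, object]]:
    if isinstance(occupancy, pd.DataFrame):
        items = []
        for rec in occupancy.itertuples(index=False):
            cell = rec.cell_id
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                continue
            items.append((int(rec.site_row), int(rec.site_col), cell))
        return items
    return [(int(r), int(c), cid) for (r, c), cid in occupancy.items()]


def extract_traces(
    stack: ImageStack,
    grid: ROIGrid,
    occupancy: Mapping[tuple[int, int], object] | pd.DataFrame,
    background_corrected: bool = True,
) -> list[Trace]:
    """Integrate each occupied ROI per frame into a single-cell trace.

    ``occupancy`` maps lattice site (row, col) to a cell id — either a
    dict or a DataFrame with columns ``site_row``, ``site_col``,
    ``cell_id`` (empty / NaN cell ids mark vacant sites, which are
    skipped).  One trace is returned per occupied site, intensity being
    the sum of pixel values in the site's half-open rectangle.
    """
    grid.check_frame(stack.frame_shape)
    if not background_corrected:
        logger.warning(
            "extract_traces called on a stack not marked background-corrected"
        )
    items = _occupancy_items(occupancy)
    for r, c, _ in items:
        if not (0 <= r < grid.rows and 0 <= c < grid.cols):
            raise ValueError(f"occupancy references site ({r}, {c}) outside the grid")
    traces = []
    for r, c, cell_id in items:
        rs, cs = grid.site_slices(r, c)
        intensities = stack.frames[:, rs, cs].sum(axis=(1, 2)).astype(float)
        traces.append(
            Trace(
                cell_id=cell_id,
                marker=stack.channel,
                times=stack.times.copy(),
                intensities=intensities,
            )
        )
    return traces


def occupancy_from_frame(df: pd.DataFrame) -> dict[tuple[int, int], object]:
    """Convert an occupancy table (site_row, site_col, cell_id) to a dict."""
    return {(r, c): cid for r, c, cid in _occupancy_items(df)}


def flag_suspicious_sites(
    stack: ImageStack,
    grid: ROIGrid,
    occupancy: Mapping[tuple[int, int], object] | pd.DataFrame,
    max_intensity_factor: float = 3.0,
) -> list[tuple[int, int]]:
    """Flag occupied sites whose peak integrated intensity looks multi-cellular.

    A site is flagged when its maximum integrated intensity exceeds
    ``max_intensity_factor`` times the median peak across occupied sites.
    Purely advisory: the occupancy table is the authoritative QC input
    and is never overridden.
    """
    traces = extract_traces(stack, grid, occupancy, background_corrected=True)
    if not traces:
        return []
    peaks = {t.cell_id: float(np.max(t.intensities)) for t in traces}
    med = float(np.median(list(peaks.values())))
    if med <= 0:
        return []
    flagged = []
    for r, c, cell_id in _occupancy_items(occupancy):
        if peaks.get(cell_id, 0.0) > max_intensity_factor * med:
            flagged.append((r, c))
    return flagged
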