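"""CSV / TIFF / YAML interchange for traces, fits, events and grids.

All tabular interchange is plain CSV: traces in long format
(cell_id, marker, frame, time_h, intensity), events as
(cell_id, marker, event_kind, t_event_h, quality), fits as one row per
cell x marker with the union of model parameter columns.  Image stacks
are multi-page TIFF, one file per channel, frame order equal to time
order, 16-bit unsigned, row-major with origin at the top-left;
timestamps come from a sidecar CSV or a uniform-interval configuration.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fitting import EventSet, ModelFit, RosRate
from .imaging import ImageStack, ROIGrid, Trace, build_roi_grid
from .models import PARAM_FIELDS, params_to_dict

__all__ = [
    "write_traces", "read_traces",
    "write_events", "read_events",
    "write_fits",
    "write_ros_rates", "read_ros_rates",
    "write_occupancy", "read_occupancy",
    "write_image_stack", "read_image_stack",
    "write_grid_yaml", "read_grid_yaml",
]


def write_traces(traces: Iterable[Trace], path) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for frame, (t, v) in enumerate(zip(tr.times, tr.intensities)):
            rows.append(
                dict(cell_id=tr.cell_id, marker=tr.marker, frame=frame,
                     time_h=t, intensity=v)
            )
    df = pd.DataFrame(rows, columns=["cell_id", "marker", "frame", "time_h", "intensity"])
    df.to_csv(path, index=False)
    return df


def read_traces(path) -> list[Trace]:
    df = pd.read_csv(path)
    traces = []
    for (cell_id, marker), group in df.groupby(["cell_id", "marker"], sort=True):
        group = group.sort_values("frame")
        traces.append(
            Trace(
                cell_id=cell_id,
                marker=str(marker),
                times=group["time_h"].to_numpy(dtype=float),
                intensities=group["intensity"].to_numpy(dtype=float),
            )
        )
    return traces


def write_events(events: EventSet, path) -> pd.DataFrame:
    df = events.to_frame()
    df.to_csv(path, index=False)
    return df


def read_events(path, offset_applied: bool = True) -> EventSet:
    df = pd.read_csv(path)
    return EventSet.from_frame(df, offset_applied=offset_applied)


_ALL_PARAM_COLUMNS = tuple(
    dict.fromkeys(PARAM_FIELDS["early"] + PARAM_FIELDS["late"])
)


def write_fits(fits: Sequence[ModelFit], statuses: Sequence[str], path) -> pd.DataFrame:
    rows = []
    for fit, status in zip(fits, statuses):
        row = dict(cell_id=fit.cell_id, marker=fit.marker, kind=fit.marker_kind)
        for col in _ALL_PARAM_COLUMNS:
            row[col] = np.nan
        if fit.params is not None:
            row.update({k: v for k, v in params_to_dict(fit.params).items() if k != "kind"})
        row.update(
            eta=fit.eta, sse=fit.sse, null_sse=fit.null_sse,
            converged=fit.converged, domain_start=fit.domain[0],
            domain_end=fit.domain[1], status=status,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_ros_rates(rates: Iterable[RosRate], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [dict(cell_id=r.cell_id, rate=r.rate, t0_h=r.eval_times[0], t1_h=r.eval_times[1])
         for r in rates],
        columns=["cell_id", "rate", "t0_h", "t1_h"],
    )
    df.to_csv(path, index=False)
    return df


def read_ros_rates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_occupancy(occupancy: pd.DataFrame, path) -> None:
    occupancy.to_csv(path, index=False)


def read_occupancy(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["cell_id"] = df["cell_id"].where(df["cell_id"].notna(), "")
    return df


def write_image_stack(path, stack: ImageStack, dtype=np.uint16) -> None:
    """Write a stack as multi-page TIFF (values clipped to the dtype range)."""
    frames = stack.frames
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    else:
        frames = frames.astype(dtype)
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_image_stack(
    path,
    channel: str = "",
    times: np.ndarray | None = None,
    sampling_interval_h: float | None = None,
    t0_h: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF; timestamps from ``times`` or a uniform grid."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    n = frames.shape[0]
    if times is None:
        if sampling_interval_h is None:
            raise ValueError("provide times or sampling_interval_h")
        times = t0_h + np.arange(n) * sampling_interval_h
    return ImageStack(frames=np.asarray(frames, dtype=float), times=np.asarray(times, dtype=float),
                      channel=channel or os.path.splitext(os.path.basename(path))[0])


def write_grid_yaml(grid: ROIGrid, path) -> None:
    data = dict(
        origin=[int(grid.origin[0]), int(grid.origin[1])],
        site_px=int(grid.site_px),
        pitch_px=int(grid.pitch_px),
        rows=int(grid.rows),
        cols=int(grid.cols),
        um_per_px=grid.um_per_px,
    )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_grid_yaml(path) -> ROIGrid:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return build_roi_grid(
        origin=tuple(data["origin"]),
        site_px=data["site_px"],
        pitch_px=data["pitch_px"],
        rows=data["rows"],
        cols=data["cols"],
        um_per_px=data.get("um_per_px"),
    )
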