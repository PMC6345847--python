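"""Pipeline orchestration: simulate -> extract -> fit -> correlate.

A :class:`RunConfig` bundles the cohort description, grid geometry,
fitting and correlation settings under a single seed; ``run_pipeline``
executes the selected stages in order, writes their CSV/JSON/TIFF
artifacts into the output directory and records a manifest (per-stage
record counts, output checksums, parameter echo, seed and package
version) so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .fitting import (
    EventSet,
    FitConfig,
    QCConfig,
    apply_time_offset,
    process_trace,
)
from .imaging import ROIGrid, background_correct, build_roi_grid, extract_traces
from .stats import (
    cluster_ellipse,
    diagonal_partition,
    fit_lognormal,
    mean_shift_cluster,
    pair_events,
    rate_vs_event,
)
from .synthetic import (
    MARKER_KINDS,
    CohortConfig,
    ConfigError,
    MarkerLaw,
    PathwaySpec,
    RenderOptics,
    cohort_traces,
    render_image_stack,
    simulate_cohort,
)

__all__ = [
    "GridGeometry",
    "FitStageConfig",
    "CorrelateStageConfig",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

VERSION = "0.1.0"
ALL_STAGES = ("simulate", "extract", "fit", "correlate")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and record."""


@dataclass
class GridGeometry:
    """Grid geometry in pixels (defaults: 30 um sites on a 90 um pitch
    imaged at 3 um per pixel)."""

    origin: tuple[int, int] = (10, 10)
    site_px: int = 10
    pitch_px: int = 30
    rows: int = 8
    cols: int = 8
    um_per_px: float = 3.0

    def build(self) -> ROIGrid:
        return build_roi_grid(
            origin=self.origin, site_px=self.site_px, pitch_px=self.pitch_px,
            rows=self.rows, cols=self.cols, um_per_px=self.um_per_px,
        )


@dataclass
class FitStageConfig:
    kappa: float = 3.0               # breakdown threshold multiple of eta
    k_amp: float = 5.0               # minimum dynamic range in eta units
    min_delta_bic: float = 10.0      # event vs no-event model margin
    multistart: int = 8
    resolution_h: float = 1.0 / 60.0  # event-grid resolution (1 min)


@dataclass
class CorrelateStageConfig:
    pair: tuple[str, str] = ("LMP", "MOMP")
    bandwidth_h: float = 2.0
    tolerance_h: float = 0.5          # coincidence band around the diagonal
    min_cluster_fraction: float = 0.05
    make_plots: bool = False


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    cohort: CohortConfig
    grid: GridGeometry = field(default_factory=GridGeometry)
    optics: RenderOptics = field(default_factory=RenderOptics)
    fit: FitStageConfig = field(default_factory=FitStageConfig)
    correlate: CorrelateStageConfig = field(default_factory=CorrelateStageConfig)
    stages: tuple[str, ...] = ("simulate", "fit", "correlate")
    render_images: bool = False
    seed: int | None = None           # overrides cohort.seed when given

    def effective_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return replace(self.cohort, seed=int(self.seed))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return _jsonify(d)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        c = dict(data["cohort"])
        c["pathways"] = {
            k: PathwaySpec(
                markers=tuple(v["markers"]),
                mean_delays=tuple(v["mean_delays"]),
                jitter_sd=v.get("jitter_sd", 0.5),
            )
            for k, v in c["pathways"].items()
        }
        c["marker_laws"] = {
            k: MarkerLaw(**v) for k, v in c["marker_laws"].items()
        }
        cohort = CohortConfig(**c)
        grid = GridGeometry(**{**data.get("grid", {}),
                               **({"origin": tuple(data["grid"]["origin"])}
                                  if "grid" in data and "origin" in data["grid"] else {})})
        optics_d = dict(data.get("optics", {}))
        if "background_gradient" in optics_d:
            optics_d["background_gradient"] = tuple(optics_d["background_gradient"])
        optics = RenderOptics(**optics_d)
        fit = FitStageConfig(**data.get("fit", {}))
        corr_d = dict(data.get("correlate", {}))
        if "pair" in corr_d:
            corr_d["pair"] = tuple(corr_d["pair"])
        correlate = CorrelateStageConfig(**corr_d)
        return cls(
            cohort=cohort, grid=grid, optics=optics, fit=fit, correlate=correlate,
            stages=tuple(data.get("stages", ("simulate", "fit", "correlate"))),
            render_images=bool(data.get("render_images", False)),
            seed=data.get("seed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the selected stages and return (and write) the run manifest."""
    os.makedirs(outdir, exist_ok=True)
    cohort_config = config.effective_cohort()
    try:
        cohort_config.validate()
    except ConfigError as exc:
        raise PipelineError(f"stage=config: {exc}") from exc

    manifest: dict = {
        "version": VERSION,
        "seed": cohort_config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    paths = {
        "truth": os.path.join(outdir, "truth.csv"),
        "traces": os.path.join(outdir, "traces.csv"),
        "occupancy": os.path.join(outdir, "occupancy.csv"),
        "flux": os.path.join(outdir, "flux.csv"),
        "images": os.path.join(outdir, "images"),
        "fits": os.path.join(outdir, "fits.csv"),
        "events": os.path.join(outdir, "events.csv"),
        "ros": os.path.join(outdir, "ros_rates.csv"),
        "pairs": os.path.join(outdir, "pairs.csv"),
        "clusters": os.path.join(outdir, "clusters.json"),
        "summary": os.path.join(outdir, "lognormal_summary.csv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise PipelineError(f"stage={stage}: unknown stage")
        try:
            if stage == "simulate":
                _stage_simulate(config, cohort_config, paths, manifest)
            elif stage == "extract":
                _stage_extract(config, cohort_config, paths, manifest)
            elif stage == "fit":
                _stage_fit(config, cohort_config, paths, manifest)
            elif stage == "correlate":
                _stage_correlate(config, paths, manifest)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage={stage}: {exc}") from exc

    with open(paths["manifest"], "w") as fh:
        json.dump(_jsonify(manifest), fh, indent=2, sort_keys=True)
    return manifest


def _record_outputs(manifest: dict, stage: str, counts: dict, files: list[str]) -> None:
    manifest["stages"][stage] = {
        "counts": counts,
        "outputs": {os.path.basename(p): _sha256(p) for p in files if os.path.isfile(p)},
    }


def _stage_simulate(config, cohort_config, paths, manifest) -> None:
    cohort = simulate_cohort(cohort_config)
    truth = cohort.to_frame()
    truth.to_csv(paths["truth"], index=False)
    files = [paths["truth"]]
    counts = {"cells": cohort.n_cells, "truth_rows": len(truth)}
    if config.render_images:
        grid = config.grid.build()
        result = render_image_stack(cohort, grid, config.optics)
        os.makedirs(paths["images"], exist_ok=True)
        for marker, stack in result.stacks.items():
            tif = os.path.join(paths["images"], f"{marker}.tif")
            lio.write_image_stack(tif, stack)
            files.append(tif)
        lio.write_occupancy(result.occupancy, paths["occupancy"])
        result.flux.to_csv(paths["flux"], index=False)
        files += [paths["occupancy"], paths["flux"]]
        counts["channels"] = len(result.stacks)
    else:
        traces = cohort_traces(cohort)
        df = lio.write_traces(traces, paths["traces"])
        files.append(paths["traces"])
        counts["traces"] = len(traces)
        counts["trace_rows"] = len(df)
    _record_outputs(manifest, "simulate", counts, files)


def _stage_extract(config, cohort_config, paths, manifest) -> None:
    grid = config.grid.build()
    occupancy = lio.read_occupancy(paths["occupancy"])
    traces = []
    markers = sorted(
        f[:-4] for f in os.listdir(paths["images"]) if f.endswith(".tif")
    )
    background_log = {}
    for marker in markers:
        stack = lio.read_image_stack(
            os.path.join(paths["images"], f"{marker}.tif"),
            channel=marker,
            sampling_interval_h=cohort_config.sampling_interval_h,
        )
        corrected, bg = background_correct(stack, grid)
        background_log[marker] = [float(bg.min()), float(bg.max())]
        traces += extract_traces(corrected, grid, occupancy)
    # traces carry integer-like cell ids read from CSV; normalize
    df = lio.write_traces(traces, paths["traces"])
    _record_outputs(
        manifest, "extract",
        {"channels": len(markers), "traces": len(traces), "trace_rows": len(df),
         "background_range": background_log},
        [paths["traces"]],
    )


def _stage_fit(config, cohort_config, paths, manifest) -> None:
    traces = lio.read_traces(paths["traces"])
    fit_config = FitConfig(multistart=config.fit.multistart, seed=cohort_config.seed)
    qc = QCConfig(k_amp=config.fit.k_amp, min_delta_bic=config.fit.min_delta_bic)
    fits, statuses, records, ros_rates = [], [], [], []
    for trace in traces:
        kind = MARKER_KINDS.get(trace.marker)
        if kind is None:
            raise PipelineError(
                f"stage=fit: unknown marker {trace.marker!r} for cell {trace.cell_id!r}"
            )
        fit, status, record, ros = process_trace(
            trace, kind, fit_config, qc,
            kappa=config.fit.kappa, resolution=config.fit.resolution_h,
            want_ros=(trace.marker == "OxBurst"),
        )
        fits.append(fit)
        statuses.append(status)
        records.append(record)
        if ros is not None:
            ros_rates.append(ros)
    events = EventSet(records=records)
    events = apply_time_offset(events, cohort_config.admin_offset_h)
    lio.write_fits(fits, statuses, paths["fits"])
    lio.write_events(events, paths["events"])
    lio.write_ros_rates(ros_rates, paths["ros"])
    qc_table: dict[str, dict[str, int]] = {}
    for record in records:
        qc_table.setdefault(record.marker, {})
        qc_table[record.marker][record.quality] = (
            qc_table[record.marker].get(record.quality, 0) + 1
        )
    _record_outputs(
        manifest, "fit",
        {"traces": len(traces),
         "accepted_events": sum(r.accepted for r in records),
         "ros_rates": len(ros_rates),
         "qc": qc_table,
         "offset_applied_h": cohort_config.admin_offset_h},
        [paths["fits"], paths["events"], paths["ros"]],
    )


def _stage_correlate(config, paths, manifest) -> None:
    events = lio.read_events(paths["events"])
    df = events.to_frame()
    m1, m2 = config.correlate.pair
    set1 = EventSet.from_frame(df[df["marker"] == m1])
    set2 = EventSet.from_frame(df[df["marker"] == m2])
    pairs = pair_events(set1, set2)
    pairs.table.to_csv(paths["pairs"], index=False)

    clusters_payload: dict = {
        "pair": [m1, m2],
        "bandwidth_h": config.correlate.bandwidth_h,
        "tolerance_h": config.correlate.tolerance_h,
        "delay_definition": "difference of cluster-centre coordinates (t2 - t1)",
        "n_pairs": pairs.n,
        "clusters": [],
    }
    if pairs.n >= 5:
        members, modes = mean_shift_cluster(
            pairs.points(), config.correlate.bandwidth_h,
            min_cluster_fraction=config.correlate.min_cluster_fraction,
        )
        pts = pairs.points()
        for idx, mode in zip(members, modes):
            entry: dict = {
                "n": int(idx.size),
                "mode": [float(mode[0]), float(mode[1])],
            }
            try:
                ell = cluster_ellipse(pts[idx])
                entry.update(
                    center=list(ell.center),
                    major_direction=list(ell.major_direction),
                    l_major_plus=ell.l_major_plus,
                    l_major_minus=ell.l_major_minus,
                    l_minor=ell.l_minor,
                    delay_h=ell.delay_h,
                    side=ell.side,
                )
            except ValueError:
                entry["degenerate"] = True
            clusters_payload["clusters"].append(entry)
        fractions = diagonal_partition(pairs, config.correlate.tolerance_h)
        clusters_payload["diagonal_fractions"] = {
            "above": fractions.above, "below": fractions.below,
            "coincident": fractions.coincident,
        }
    with open(paths["clusters"], "w") as fh:
        json.dump(_jsonify(clusters_payload), fh, indent=2, sort_keys=True)

    summary_rows = []
    for marker, group in df[df["quality"] == "accepted"].groupby("marker"):
        times = group["t_event_h"].to_numpy(dtype=float)
        if times.size >= 3 and np.all(times > 0) and np.std(np.log(times)) > 0:
            ln = fit_lognormal(times)
            summary_rows.append(
                dict(marker=marker, n=ln.n, mu=ln.mu, sigma=ln.sigma,
                     mode_h=ln.mode, median_h=ln.median)
            )
    pd.DataFrame(
        summary_rows, columns=["marker", "n", "mu", "sigma", "mode_h", "median_h"]
    ).to_csv(paths["summary"], index=False)

    files = [paths["pairs"], paths["clusters"], paths["summary"]]

    if os.path.isfile(paths["ros"]):
        rates = lio.read_ros_rates(paths["ros"])
        for marker in (m1, m2):
            subset = EventSet.from_frame(df[df["marker"] == marker])
            try:
                _, pcc = rate_vs_event(rates, subset)
            except ValueError:
                continue
            clusters_payload.setdefault("ros_pcc", {})[marker] = pcc
        with open(paths["clusters"], "w") as fh:
            json.dump(_jsonify(clusters_payload), fh, indent=2, sort_keys=True)

    if config.correlate.make_plots:
        from .plots import plot_event_histogram, plot_event_scatter
        from .stats import ClusterEllipse

        ells = [
            ClusterEllipse(
                center=tuple(e["center"]),
                major_direction=tuple(e["major_direction"]),
                minor_direction=(-e["major_direction"][1], e["major_direction"][0]),
                l_major_plus=e["l_major_plus"],
                l_major_minus=e["l_major_minus"],
                l_minor=e["l_minor"],
                n_members=e["n"],
            )
            for e in clusters_payload["clusters"] if "center" in e
        ]
        scatter_path = os.path.join(os.path.dirname(paths["pairs"]), "scatter.png")
        plot_event_scatter(pairs, ells, path=scatter_path)
        files.append(scatter_path)
        for row in summary_rows:
            marker = row["marker"]
            times = df[(df["marker"] == marker) & (df["quality"] == "accepted")][
                "t_event_h"
            ].to_numpy(dtype=float)
            hist_path = os.path.join(
                os.path.dirname(paths["pairs"]), f"hist_{marker}.png"
            )
            plot_event_histogram(
                times, LogNormalFitFromRow(row), path=hist_path, label=marker
            )
            files.append(hist_path)

    _record_outputs(
        manifest, "correlate",
        {"pairs": pairs.n, "clusters": len(clusters_payload["clusters"]),
         "lognormal_fits": len(summary_rows)},
        files,
    )


def LogNormalFitFromRow(row):
    from .stats import LogNormalFit

    return LogNormalFit(mu=row["mu"], sigma=row["sigma"], n=row["n"])
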