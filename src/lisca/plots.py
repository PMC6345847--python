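"""Diagnostic plots: event-time scatter with ellipses, histograms with fits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .stats import ClusterEllipse, LogNormalFit, PairedEvents

__all__ = ["plot_event_scatter", "plot_event_histogram", "ellipse_outline"]


def ellipse_outline(ellipse: ClusterEllipse, num: int = 200) -> np.ndarray:
    """Parametric outline of an asymmetric one-sigma ellipse, (num, 2)."""
    theta = np.linspace(0, 2 * np.pi, num)
    major = np.where(np.cos(theta) >= 0, ellipse.l_major_plus, ellipse.l_major_minus)
    u = np.asarray(ellipse.major_direction)
    v = np.asarray(ellipse.minor_direction)
    pts = (
        np.asarray(ellipse.center)
        + np.outer(major * np.cos(theta), u)
        + np.outer(ellipse.l_minor * np.sin(theta), v)
    )
    return pts


def plot_event_scatter(
    pairs: PairedEvents,
    ellipses: list[ClusterEllipse] | None = None,
    path=None,
    ax=None,
):
    """Scatter of paired event times with the coincidence diagonal and
    asymmetric one-sigma cluster ellipses."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    pts = pairs.points()
    ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6, color="tab:blue")
    lo = float(min(pts.min(), 0)) if pts.size else 0.0
    hi = float(pts.max()) * 1.05 if pts.size else 1.0
    ax.plot([lo, hi], [lo, hi], color="0.5", lw=1, ls="--")
    for ell in ellipses or []:
        outline = ellipse_outline(ell)
        ax.plot(outline[:, 0], outline[:, 1], color="tab:red", lw=1.5)
        ax.plot(*ell.center, marker="+", color="tab:red", ms=8)
    ax.set_xlabel(f"t_event({pairs.marker_1}) [h]")
    ax.set_ylabel(f"t_event({pairs.marker_2}) [h]")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_event_histogram(
    times,
    fit: LogNormalFit | None = None,
    path=None,
    bins: int = 30,
    ax=None,
    label: str = "",
):
    """Normalized event-time histogram with an optional log-normal overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    times = np.asarray(times, dtype=float)
    ax.hist(times, bins=bins, density=True, alpha=0.6, color="tab:blue", label=label)
    if fit is not None and fit.sigma > 0:
        grid = np.linspace(max(times.min() * 0.5, 1e-3), times.max() * 1.2, 400)
        ax.plot(grid, fit.pdf(grid), color="k", lw=1.5, label="log-normal fit")
    ax.set_xlabel("event time [h]")
    ax.set_ylabel("density")
    if label or fit is not None:
        ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
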