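"""Population statistics of single-cell event times.

Event-time histograms are summarized by log-normal fits; pairs of
marker events are joined per cell into two-dimensional scatter data,
clustered by mean-shift, and each cluster is summarized by an
asymmetric one-sigma ellipse whose semi-axes lie along the principal
components (the major axis may have different root-mean-square lengths
on its positive and negative sides, capturing skewed clusters).  The
signed delay time of a cluster is the difference of its centre
coordinates; its sign encodes the event order relative to the scatter
diagonal.  Pearson correlation links ROS production rates to event
times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fitting import EventSet, RosRate

__all__ = [
    "LogNormalFit",
    "PairedEvents",
    "ClusterEllipse",
    "DiagonalFractions",
    "fit_lognormal",
    "pair_events",
    "mean_shift_cluster",
    "cluster_ellipse",
    "diagonal_partition",
    "pearson",
    "rate_vs_event",
    "silverman_bandwidth",
]


@dataclass(frozen=True)
class LogNormalFit:
    """Maximum-likelihood log-normal summary of positive event times.

    ``mu`` and ``sigma`` are the mean and (uncorrected) standard
    deviation of log event times; the distribution maximum (mode) is
    ``exp(mu - sigma**2)`` and the median ``exp(mu)``.
    """

    mu: float
    sigma: float
    n: int

    @property
    def mode(self) -> float:
        return float(np.exp(self.mu - self.sigma**2))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        if self.sigma == 0:
            return out
        z = (np.log(t[pos]) - self.mu) / self.sigma
        out[pos] = np.exp(-0.5 * z * z) / (t[pos] * self.sigma * np.sqrt(2 * np.pi))
        return out


def fit_lognormal(times: Sequence[float]) -> LogNormalFit:
    """MLE log-normal fit: mu = mean(ln t), sigma = uncorrected sd(ln t)."""
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise ValueError(f"need at least 3 event times, got {t.size}")
    if np.any(t <= 0):
        raise ValueError("event times must be strictly positive")
    logs = np.log(t)
    return LogNormalFit(mu=float(np.mean(logs)), sigma=float(np.std(logs)), n=int(t.size))


@dataclass
class PairedEvents:
    """Per-cell joined event times of two markers (accepted events only)."""

    marker_1: str
    marker_2: str
    table: pd.DataFrame  # columns: cell_id, t1, t2

    @property
    def n(self) -> int:
        return len(self.table)

    def points(self) -> np.ndarray:
        return self.table[["t1", "t2"]].to_numpy(dtype=float)


def _accepted_times(events) -> pd.DataFrame:
    if isinstance(events, EventSet):
        df = events.to_frame()
    else:
        df = pd.DataFrame(events)
    dup = df.duplicated(subset=["cell_id", "marker"])
    if dup.any():
        raise ValueError("duplicate (cell, marker) event records")
    df = df[df["quality"] == "accepted"]
    return df[["cell_id", "marker", "t_event_h"]]


def pair_events(events_1, events_2) -> PairedEvents:
    """Inner-join two markers' accepted events on cell id.

    Only cells with both events accepted enter the pairing (disjoint
    cell ids yield an empty pairing, not an error).
    """
    df1 = _accepted_times(events_1)
    df2 = _accepted_times(events_2)
    m1 = df1["marker"].iloc[0] if len(df1) else ""
    m2 = df2["marker"].iloc[0] if len(df2) else ""
    joined = df1.merge(df2, on="cell_id", suffixes=("_1", "_2"))
    table = pd.DataFrame(
        {
            "cell_id": joined["cell_id"],
            "t1": joined["t_event_h_1"].astype(float),
            "t2": joined["t_event_h_2"].astype(float),
        }
    )
    return PairedEvents(marker_1=str(m1), marker_2=str(m2), table=table)


def mean_shift_cluster(
    points: np.ndarray,
    bandwidth: float,
    min_cluster_fraction: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Mean-shift clustering of 2-D event-time scatter (deterministic).

    Every point ascends the kernel density estimate by iterating the
    mean-shift fixed point (uniform kernel of radius ``bandwidth``: the
    window mean of the in-radius points) until the step falls below
    ``tol`` hours or ``max_iter`` iterations.  Converged positions
    closer than ``bandwidth / 2`` are merged into one mode; clusters
    holding fewer than ``min_cluster_fraction`` of all points are
    dissolved into the nearest surviving mode.

    Returns (member index arrays, modes) with clusters ordered by
    decreasing size.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 points, got {n}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    Y = X.copy()
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        d = cdist(Y[active], X)
        inside = d <= bandwidth
        counts = inside.sum(axis=1)
        # every point is within bandwidth of itself, counts >= 1
        new = (inside[:, :, None] * X[None, :, :]).sum(axis=1) / counts[:, None]
        step = np.linalg.norm(new - Y[active], axis=1)
        Y[active] = new
        still = step >= tol
        idx = np.nonzero(active)[0]
        active[idx[~still]] = False

    # merge converged positions closer than bandwidth / 2
    mode_positions: list[np.ndarray] = []
    mode_members: list[list[int]] = []
    for i in range(n):
        for k, m in enumerate(mode_positions):
            if np.linalg.norm(Y[i] - m) < bandwidth / 2.0:
                mode_members[k].append(i)
                break
        else:
            mode_positions.append(Y[i].copy())
            mode_members.append([i])
    modes = np.array(
        [Y[members].mean(axis=0) for members in mode_members]
    )

    # dissolve sub-threshold clusters into the nearest surviving mode
    min_size = min_cluster_fraction * n
    sizes = np.array([len(m) for m in mode_members])
    keep = sizes >= min_size
    if not keep.any():
        keep[np.argmax(sizes)] = True
    surviving = np.nonzero(keep)[0]
    labels = np.empty(n, dtype=int)
    for k, members in enumerate(mode_members):
        if keep[k]:
            labels[members] = k
        else:
            nearest = surviving[
                np.argmin(np.linalg.norm(modes[surviving] - modes[k], axis=1))
            ]
            labels[members] = nearest

    clusters = []
    for k in surviving:
        clusters.append(np.nonzero(labels == k)[0])
    order = np.argsort([-c.size for c in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    modes = modes[surviving][order]
    return clusters, modes


@dataclass(frozen=True)
class ClusterEllipse:
    """Asymmetric one-sigma ellipse summary of one event-time cluster.

    The centre is the cluster mean; the orthonormal directions are the
    principal components of the (1/n-normalized) sample covariance, the
    first chosen with non-negative component along the diagonal
    (1, 1)/sqrt(2).  The minor length is the RMS projection onto the
    second direction over all points; the major lengths are RMS
    projections onto the first direction computed separately over the
    strictly positive and strictly negative sides (an empty side
    inherits the other side's length).  ``delay_h`` is the signed
    difference centre_2 - centre_1.
    """

    center: tuple[float, float]
    major_direction: tuple[float, float]
    minor_direction: tuple[float, float]
    l_major_plus: float
    l_major_minus: float
    l_minor: float
    n_members: int

    @property
    def delay_h(self) -> float:
        return self.center[1] - self.center[0]

    @property
    def side(self) -> str:
        d = self.delay_h
        if d > 1e-9:
            return "above"
        if d < -1e-9:
            return "below"
        return "on"


def cluster_ellipse(points: np.ndarray) -> ClusterEllipse:
    """Principal-component asymmetric ellipse of a 2-D point cluster."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    center = X.mean(axis=0)
    X0 = X - center
    cov = X0.T @ X0 / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate (collinear) point cluster")
    first = evecs[:, 1]
    if first @ np.array([1.0, 1.0]) < 0:
        first = -first
    second = np.array([-first[1], first[0]])
    proj1 = X0 @ first
    proj2 = X0 @ second
    l_minor = float(np.sqrt(np.mean(proj2**2)))
    pos = proj1[proj1 > 0]
    neg = proj1[proj1 < 0]
    l_plus = float(np.sqrt(np.mean(pos**2))) if pos.size else None
    l_minus = float(np.sqrt(np.mean(neg**2))) if neg.size else None
    if l_plus is None and l_minus is None:
        raise ValueError("degenerate cluster: no spread along the major axis")
    if l_plus is None:
        l_plus = l_minus
    if l_minus is None:
        l_minus = l_plus
    return ClusterEllipse(
        center=(float(center[0]), float(center[1])),
        major_direction=(float(first[0]), float(first[1])),
        minor_direction=(float(second[0]), float(second[1])),
        l_major_plus=l_plus,
        l_major_minus=l_minus,
        l_minor=l_minor,
        n_members=int(X.shape[0]),
    )


class DiagonalFractions(NamedTuple):
    above: float
    below: float
    coincident: float


def diagonal_partition(pairs, tolerance: float = 0.0) -> DiagonalFractions:
    """Fractions of pairs above / below / on the scatter diagonal.

    A pair is *above* when ``t2 - t1 > tolerance`` (event 2 follows
    event 1), *below* symmetrically; the remainder count as temporally
    coincident.  Fractions sum to 1.
    """
    if isinstance(pairs, PairedEvents):
        pts = pairs.points()
    else:
        pts = np.asarray(pairs, dtype=float)
    if pts.shape[0] < 1:
        raise ValueError("need at least one pair")
    d = pts[:, 1] - pts[:, 0]
    n = d.size
    above = float(np.sum(d > tolerance)) / n
    below = float(np.sum(d < -tolerance)) / n
    return DiagonalFractions(above=above, below=below, coincident=1.0 - above - below)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx = np.std(x)
    sy = np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in input")
    return float(np.mean((x - np.mean(x)) * (y - np.mean(y))) / (sx * sy))


def rate_vs_event(
    rates: Iterable[RosRate] | pd.DataFrame,
    events,
) -> tuple[pd.DataFrame, float]:
    """Join ROS production rates with event times and correlate them.

    Inner join on cell id (accepted events only); returns the joined
    table (cell_id, rate, t_event_h) and its Pearson coefficient.
    Fewer than 3 joined cells raise.
    """
    if isinstance(rates, pd.DataFrame):
        rdf = rates[["cell_id", "rate"]].copy()
    else:
        rdf = pd.DataFrame(
            [dict(cell_id=r.cell_id, rate=r.rate) for r in rates],
            columns=["cell_id", "rate"],
        )
    edf = _accepted_times(events)
    joined = rdf.merge(edf[["cell_id", "t_event_h"]], on="cell_id")
    if len(joined) < 3:
        raise ValueError(f"need at least 3 joined cells, got {len(joined)}")
    pcc = pearson(joined["rate"].to_numpy(), joined["t_event_h"].to_numpy())
    return joined, pcc


def silverman_bandwidth(points: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth for 2-D mean-shift clustering.

    Provided as a starting point only; analyses should fix the
    bandwidth explicitly for reproducibility.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    sigma = float(np.mean(np.std(X, axis=0)))
    return sigma * n ** (-1.0 / 6.0)
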