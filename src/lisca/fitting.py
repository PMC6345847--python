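"""Maximum-likelihood trace fitting and event-time extraction.

Under the i.i.d. Gaussian constant-variance noise model adopted here,
maximum likelihood estimation of the marker model parameters reduces to
least squares; the optimizer is run from several deterministic starting
points (half-rise / breakdown candidates at the steepest observed
intensity change plus quantiles of the time span) and the best
sum-of-squared-errors solution is kept.

Event definitions:

* **Breakdown time** (early markers): earliest time at which the fitted
  curve deviates from its pre-breakdown polynomial by more than
  ``kappa`` times the noise level, evaluated on a fine uniform grid
  (1-min resolution by default).
* **Onset time** (late markers): intersection of the tangent at the
  half-maximum of the fitted sigmoidal rise with the basal fluorescence
  level.
* **ROS production rate**: slope of the line through the first two
  points of the fitted CellROX model evaluated at 1-min resolution.

The noise level ``eta`` is a robust residual scale
(1.4826 x median absolute residual), insensitive to the event region.
Traces with no discernible event are rejected by amplitude and BIC
model-selection rules (see :func:`classify_trace`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .imaging import Trace
from .models import (
    EarlyModelParams,
    LateModelParams,
    early_model,
    late_model,
    late_model_derivative,
)

__all__ = [
    "FitConfig",
    "QCConfig",
    "ModelFit",
    "EventRecord",
    "EventSet",
    "RosRate",
    "fit_trace",
    "classify_trace",
    "extract_breakdown_time",
    "extract_onset_time",
    "ros_production_rate",
    "apply_time_offset",
    "process_trace",
    "MIN_SAMPLES",
]

MIN_SAMPLES = 12

_EARLY_NAMES = ("a0", "a1", "a2", "t_b", "tau_b", "c")
_LATE_NAMES = ("B", "A", "t_h", "tau_o", "lam")

# Floor on the noise level when forming threshold multiples, so that
# noiseless (perfect-fit) traces still yield finite thresholds.
ETA_FLOOR = 1e-6


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_trace`.

    ``multistart`` initial points are tried (deterministic candidates
    first, uniformly drawn extras seeded by ``seed`` if more are
    requested); ``tau_inits`` are the initial step widths paired with
    each time candidate.
    """

    multistart: int = 8
    seed: int = 0
    tau_inits: tuple[float, ...] = (0.2, 1.0)
    max_nfev: int = 400


@dataclass(frozen=True)
class QCConfig:
    """Trace rejection rules: minimum amplitude multiple and BIC margin."""

    k_amp: float = 5.0
    min_delta_bic: float = 10.0


@dataclass
class ModelFit:
    """Fitted marker model with noise level and nested no-event fit."""

    marker_kind: str
    params: EarlyModelParams | LateModelParams | None
    eta: float
    sse: float
    null_sse: float
    converged: bool
    domain: tuple[float, float]
    n_samples: int
    n_params: int
    null_n_params: int
    cell_id: object = None
    marker: str = ""
    failure: str | None = None

    def model(self, t):
        if self.params is None:
            raise ValueError("fit has no parameters (failed before optimization)")
        if self.marker_kind == "early":
            return early_model(t, self.params)
        return late_model(t, self.params)

    def dynamic_range(self, num: int = 512) -> float:
        """Max minus min of the fitted model over the fit domain."""
        grid = np.linspace(self.domain[0], self.domain[1], num)
        vals = self.model(grid)
        return float(np.max(vals) - np.min(vals))

    def bic(self) -> float:
        return _bic(self.sse, self.n_samples, self.n_params)

    def null_bic(self) -> float:
        return _bic(self.null_sse, self.n_samples, self.null_n_params)


@dataclass(frozen=True)
class EventRecord:
    """Per-cell event time (or rejection) for one marker."""

    cell_id: object
    marker: str
    event_kind: str        # "breakdown" | "onset"
    t_event_h: float       # NaN when rejected
    quality: str           # "accepted" | "rejected:<reason>"

    @property
    def accepted(self) -> bool:
        return self.quality == "accepted"


@dataclass
class EventSet:
    """A collection of event records with a one-shot offset guard."""

    records: list[EventRecord] = field(default_factory=list)
    offset_applied: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    cell_id=r.cell_id,
                    marker=r.marker,
                    event_kind=r.event_kind,
                    t_event_h=r.t_event_h,
                    quality=r.quality,
                )
                for r in self.records
            ],
            columns=["cell_id", "marker", "event_kind", "t_event_h", "quality"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, offset_applied: bool = False) -> "EventSet":
        records = [
            EventRecord(
                cell_id=row.cell_id,
                marker=row.marker,
                event_kind=row.event_kind,
                t_event_h=float(row.t_event_h),
                quality=row.quality,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, offset_applied=offset_applied)

    def accepted_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["quality"] == "accepted"].reset_index(drop=True)


@dataclass(frozen=True)
class RosRate:
    """ROS production rate of one cell (a.u. h^-1) and its evaluation times."""

    cell_id: object
    rate: float
    eval_times: tuple[float, float]


def _bic(sse: float, n: int, k: int) -> float:
    return n * np.log(max(sse, 1e-300) / n) + k * np.log(n)


def _steepest_candidate(t: np.ndarray, y: np.ndarray, direction: str) -> float:
    dy = np.diff(y)
    i = int(np.argmin(dy)) if direction == "down" else int(np.argmax(dy))
    return float(0.5 * (t[i] + t[i + 1]))


def _time_candidates(t: np.ndarray, y: np.ndarray, direction: str) -> list[float]:
    span = t[-1] - t[0]
    cands = [_steepest_candidate(t, y, direction)]
    for q in (0.5, 0.25, 0.75):
        cands.append(float(t[0] + q * span))
    # drop near-duplicates, preserving priority order
    out: list[float] = []
    for c in cands:
        if all(abs(c - o) > 0.05 * span for o in out):
            out.append(c)
    return out


def _early_starts(t, y, config: FitConfig) -> list[np.ndarray]:
    starts = []
    for tc in _time_candidates(t, y, "down"):
        pre = t < tc - 0.5
        if pre.sum() >= 5:
            coef = np.polyfit(t[pre], y[pre], 2)
        else:
            coef = np.polyfit(t, y, 2)
        post = t > tc + 0.5
        c0 = float(np.mean(y[post])) if post.any() else float(y[-1])
        c0 = max(c0, 0.0)
        for tau0 in config.tau_inits:
            starts.append(np.array([coef[2], coef[1], coef[0], tc, tau0, c0]))
    return starts


def _late_starts(t, y, config: FitConfig) -> list[np.ndarray]:
    starts = []
    n_head = max(3, t.size // 10)
    for tc in _time_candidates(t, y, "up"):
        pre = y[t < tc - 0.5]
        B0 = float(np.median(pre)) if pre.size >= 3 else float(np.median(y[:n_head]))
        A0 = max(float(np.max(y)) - B0, 1e-3)
        for tau0 in config.tau_inits:
            starts.append(np.array([B0, A0, tc, tau0, 0.05]))
    return starts


def _bounds(kind: str, t: np.ndarray):
    span = t[-1] - t[0]
    if kind == "early":
        lo = np.array([-np.inf, -np.inf, -np.inf, t[0] - 0.25 * span, 1e-4, 0.0])
        hi = np.array([np.inf, np.inf, np.inf, t[-1] + 0.25 * span, span, np.inf])
    else:
        lo = np.array([-np.inf, 1e-9, t[0] - 0.25 * span, 1e-4, 0.0])
        hi = np.array([np.inf, np.inf, t[-1] + 0.25 * span, span, 50.0])
    return lo, hi


def _make_params(kind: str, x: np.ndarray):
    if kind == "early":
        return EarlyModelParams(*[float(v) for v in x])
    return LateModelParams(*[float(v) for v in x])


def fit_trace(
    trace: Trace,
    marker_kind: str,
    config: FitConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> ModelFit:
    """Fit the marker model to a trace by (Gaussian-noise) maximum likelihood.

    Returns the best multistart least-squares solution together with the
    robust noise level ``eta`` and the nested no-event fit (polynomial
    only for early markers, constant for late markers) used by the
    rejection rules.  ``fixed`` pins named parameters at given values
    (useful for reduced problems and oracle comparisons).

    Traces with fewer than ``MIN_SAMPLES`` samples yield a failed fit
    (``failure='too-few-samples'``); non-finite intensities raise.
    """
    if marker_kind not in ("early", "late"):
        raise ValueError(f"unknown marker_kind {marker_kind!r}")
    if config is None:
        config = FitConfig()
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace intensities must be finite")
    names = _EARLY_NAMES if marker_kind == "early" else _LATE_NAMES
    n_params_full = len(names)
    null_k = 3 if marker_kind == "early" else 1
    if t.size < MIN_SAMPLES:
        return ModelFit(
            marker_kind=marker_kind, params=None, eta=float("nan"),
            sse=float("nan"), null_sse=float("nan"), converged=False,
            domain=(float(t[0]) if t.size else 0.0, float(t[-1]) if t.size else 0.0),
            n_samples=int(t.size), n_params=n_params_full, null_n_params=null_k,
            cell_id=trace.cell_id, marker=trace.marker, failure="too-few-samples",
        )

    fixed = dict(fixed or {})
    for name in fixed:
        if name not in names:
            raise ValueError(f"cannot fix unknown parameter {name!r} for {marker_kind}")
    free_idx = [i for i, name in enumerate(names) if name not in fixed]
    model = early_model if marker_kind == "early" else late_model

    def full_vector(x_free: np.ndarray) -> np.ndarray:
        full = np.empty(n_params_full)
        for i, name in enumerate(names):
            full[i] = fixed[name] if name in fixed else np.nan
        full[free_idx] = x_free
        return full

    def residuals(x_free: np.ndarray) -> np.ndarray:
        return model(t, _make_params(marker_kind, full_vector(x_free))) - y

    lo_full, hi_full = _bounds(marker_kind, t)
    lo, hi = lo_full[free_idx], hi_full[free_idx]

    starts = _early_starts(t, y, config) if marker_kind == "early" else _late_starts(t, y, config)
    if len(starts) > config.multistart:
        starts = starts[: config.multistart]
    elif len(starts) < config.multistart:
        rng = np.random.default_rng(config.seed)
        base = starts[0].copy()
        t_idx = names.index("t_b" if marker_kind == "early" else "t_h")
        for _ in range(config.multistart - len(starts)):
            extra = base.copy()
            extra[t_idx] = rng.uniform(t[0], t[-1])
            starts.append(extra)

    best_x = None
    best_sse = np.inf
    converged = False
    for x0_full in starts:
        x0 = np.clip(x0_full[free_idx], lo, hi)
        # keep strictly inside bounds where required
        x0 = np.minimum(np.maximum(x0, lo + 1e-12), hi - 1e-12 * np.isfinite(hi))
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if sse < best_sse:
            best_sse = sse
            best_x = res.x
            converged = bool(res.success) or converged
        if best_sse < 1e-10:
            break

    if best_x is None:
        return ModelFit(
            marker_kind=marker_kind, params=None, eta=float("nan"),
            sse=float("nan"), null_sse=float("nan"), converged=False,
            domain=(float(t[0]), float(t[-1])), n_samples=int(t.size),
            n_params=n_params_full, null_n_params=null_k,
            cell_id=trace.cell_id, marker=trace.marker, failure="optimizer-failed",
        )

    params = _make_params(marker_kind, full_vector(best_x))
    resid = model(t, params) - y
    eta = float(1.4826 * np.median(np.abs(resid)))

    if marker_kind == "early":
        coef = np.polyfit(t, y, 2)
        null_resid = np.polyval(coef, t) - y
    else:
        null_resid = np.full_like(y, np.mean(y)) - y
    null_sse = float(np.sum(null_resid**2))

    return ModelFit(
        marker_kind=marker_kind, params=params, eta=eta, sse=best_sse,
        null_sse=null_sse, converged=converged,
        domain=(float(t[0]), float(t[-1])), n_samples=int(t.size),
        n_params=len(free_idx), null_n_params=null_k,
        cell_id=trace.cell_id, marker=trace.marker,
    )


def classify_trace(fit: ModelFit, qc: QCConfig | None = None) -> str:
    """Accept or reject a fitted trace; the reason is the first failing rule.

    Rejection rules, in order: (i) optimizer did not converge, (ii) the
    fitted model's dynamic range is below ``k_amp`` times the noise
    level, (iii) the event model does not beat the nested no-event model
    by at least ``min_delta_bic`` BIC points.
    """
    if qc is None:
        qc = QCConfig()
    if fit.failure is not None:
        return f"rejected:{fit.failure}"
    if not fit.converged:
        return "rejected:not-converged"
    eta_eff = max(fit.eta, ETA_FLOOR)
    if fit.dynamic_range() < qc.k_amp * eta_eff:
        return "rejected:amplitude"
    if fit.null_bic() - fit.bic() < qc.min_delta_bic:
        return "rejected:no-event"
    return "accepted"


def _fine_grid(domain: tuple[float, float], resolution: float) -> np.ndarray:
    t0, t1 = domain
    n = max(int(round((t1 - t0) / resolution)), 1)
    return t0 + np.arange(n + 1) * (t1 - t0) / n


def extract_breakdown_time(
    fit: ModelFit,
    kappa: float = 3.0,
    resolution: float = 1.0 / 60.0,
    offset: float = 0.0,
) -> EventRecord:
    """Breakdown time of an early-marker fit.

    The deviation ``P(t) - f(t)`` of the fit from its pre-breakdown
    polynomial is evaluated on a uniform grid at ``resolution`` over the
    fit domain; the breakdown is the earliest grid time exceeding
    ``kappa`` times the noise level (floored at ``ETA_FLOOR``).  The
    administration offset is added to the event time.
    """
    if fit.marker_kind != "early":
        raise ValueError("extract_breakdown_time requires an early-marker fit")
    if fit.params is None:
        return EventRecord(fit.cell_id, fit.marker, "breakdown", float("nan"),
                           f"rejected:{fit.failure or 'no-fit'}")
    grid = _fine_grid(fit.domain, resolution)
    delta = fit.params.polynomial(grid) - early_model(grid, fit.params)
    threshold = kappa * max(fit.eta, ETA_FLOOR)
    above = np.nonzero(delta > threshold)[0]
    if above.size == 0:
        return EventRecord(fit.cell_id, fit.marker, "breakdown", float("nan"),
                           "rejected:no-breakdown")
    return EventRecord(fit.cell_id, fit.marker, "breakdown",
                       float(grid[above[0]] + offset), "accepted")


def extract_onset_time(
    fit: ModelFit,
    resolution: float = 1.0 / 60.0,
    offset: float = 0.0,
) -> EventRecord:
    """Onset time of a late-marker fit (tangent-intersection construction).

    The earliest time at which the fit reaches halfway between baseline
    and its maximum over the fit domain is located (bracketed on a fine
    grid, refined by root finding); the tangent there, taken from the
    analytic derivative, is intersected with the basal level ``B``.
    A non-positive tangent slope yields ``rejected:degenerate-onset``.
    """
    if fit.marker_kind != "late":
        raise ValueError("extract_onset_time requires a late-marker fit")
    if fit.params is None:
        return EventRecord(fit.cell_id, fit.marker, "onset", float("nan"),
                           f"rejected:{fit.failure or 'no-fit'}")
    p = fit.params
    grid = _fine_grid(fit.domain, resolution)
    g = late_model(grid, p)
    g_max = float(np.max(g))
    half = p.B + 0.5 * (g_max - p.B)
    at_or_above = np.nonzero(g >= half)[0]
    if at_or_above.size == 0:
        return EventRecord(fit.cell_id, fit.marker, "onset", float("nan"),
                           "rejected:degenerate-onset")
    i = int(at_or_above[0])
    if i == 0:
        t_half = float(grid[0])
    else:
        t_half = float(
            brentq(lambda tt: float(late_model(tt, p)) - half,
                   grid[i - 1], grid[i], xtol=1e-12)
        )
    slope = float(late_model_derivative(t_half, p))
    if slope <= 0:
        return EventRecord(fit.cell_id, fit.marker, "onset", float("nan"),
                           "rejected:degenerate-onset")
    t_onset = t_half - (half - p.B) / slope
    return EventRecord(fit.cell_id, fit.marker, "onset",
                       float(t_onset + offset), "accepted")


def ros_production_rate(
    fit: ModelFit,
    resolution: float = 1.0 / 60.0,
) -> RosRate:
    """Slope of the fitted model through its first two fine-grid points.

    The fitted (CellROX) model is evaluated at the start of the fit
    domain and one ``resolution`` step later (1 min by default); the
    returned rate is the finite-difference slope in a.u. h^-1.
    """
    if fit.marker_kind != "early":
        raise ValueError("ros_production_rate requires an early-marker fit")
    if fit.params is None:
        raise ValueError("fit has no parameters")
    t0 = fit.domain[0]
    t1 = t0 + resolution
    f0 = float(early_model(t0, fit.params))
    f1 = float(early_model(t1, fit.params))
    return RosRate(cell_id=fit.cell_id, rate=(f1 - f0) / resolution,
                   eval_times=(t0, t1))


def apply_time_offset(events: EventSet, offset: float) -> EventSet:
    """Add the administration-to-first-frame delay to all accepted events.

    Guarded against double application: the returned set carries an
    ``offset_applied`` flag and re-applying raises.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if events.offset_applied:
        raise RuntimeError("administration offset already applied to this event set")
    shifted = [
        replace(r, t_event_h=r.t_event_h + offset) if r.accepted else r
        for r in events.records
    ]
    return EventSet(records=shifted, offset_applied=True)


def process_trace(
    trace: Trace,
    marker_kind: str,
    fit_config: FitConfig | None = None,
    qc: QCConfig | None = None,
    kappa: float = 3.0,
    resolution: float = 1.0 / 60.0,
    want_ros: bool = False,
) -> tuple[ModelFit, str, EventRecord, RosRate | None]:
    """Fit, classify and extract the event for one trace.

    Convenience wrapper used by the pipeline: returns the fit, its QC
    status, the event record (rejected records carry the QC reason) and,
    when requested and accepted, the ROS production rate.
    """
    fit = fit_trace(trace, marker_kind, fit_config)
    status = classify_trace(fit, qc)
    event_kind = "breakdown" if marker_kind == "early" else "onset"
    if status != "accepted":
        record = EventRecord(trace.cell_id, trace.marker, event_kind,
                             float("nan"), status)
        return fit, status, record, None
    if marker_kind == "early":
        record = extract_breakdown_time(fit, kappa=kappa, resolution=resolution)
    else:
        record = extract_onset_time(fit, resolution=resolution)
    ros = ros_production_rate(fit, resolution) if (want_ros and record.accepted) else None
    return fit, status, record, ros
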