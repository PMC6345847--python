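"""Phenomenological models for cell-death marker fluorescence traces.

Two trace shapes cover the marker panel used on single-cell arrays:

* **Early markers** (LysoTracker, TMRM, CellROX) show a slow parabolic
  rise or plateau that collapses in a sharp sigmoidal breakdown when the
  monitored compartment is permeabilized.  The model is a falling
  logistic step multiplied with a quadratic polynomial, relaxing to a
  constant floor after the breakdown::

      f(t) = s(t) * P(t) + (1 - s(t)) * c
      P(t) = a0 + a1*t + a2*t**2
      s(t) = 1 / (1 + exp((t - t_b) / tau_b))

* **Late markers** (Caspase 3/7 reporter, pSIVA, PI / Toto-3) switch on
  with a sharp sigmoidal onset and then bleach or degrade smoothly::

      g(t) = B + A * s(t) * exp(-lam * max(0, t - t_h))
      s(t) = 1 / (1 + exp(-(t - t_h) / tau_o))

All times are in hours since the first frame, intensities in arbitrary
units of integrated fluorescence.  The logistic forms were chosen for
their analytic tangents and sharp-step limits, which make the event-time
definitions (breakdown threshold crossing, onset tangent intersection)
exactly computable from fitted parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
from scipy.special import expit

__all__ = [
    "EarlyModelParams",
    "LateModelParams",
    "early_model",
    "late_model",
    "late_model_derivative",
    "params_to_dict",
    "params_from_dict",
    "PARAM_FIELDS",
]


@dataclass(frozen=True)
class EarlyModelParams:
    """Parameters of the breakdown (early-marker) model.

    Attributes
    ----------
    a0, a1, a2 : float
        Pre-breakdown polynomial coefficients (a.u., a.u. h^-1, a.u. h^-2).
        A plateau marker such as TMRM is the special case ``a1 == a2 == 0``.
    t_b : float
        Breakdown centre in hours (the midpoint of the sigmoidal collapse).
    tau_b : float
        Breakdown width in hours, strictly positive.
    c : float
        Post-breakdown fluorescence floor (a.u.), non-negative.
    """

    a0: float
    a1: float = 0.0
    a2: float = 0.0
    t_b: float = 15.0
    tau_b: float = 0.3
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_b > 0:
            raise ValueError(f"tau_b must be > 0, got {self.tau_b}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    def polynomial(self, t):
        """Pre-breakdown polynomial P(t) = a0 + a1*t + a2*t**2."""
        t = np.asarray(t, dtype=float)
        return self.a0 + self.a1 * t + self.a2 * t * t

    def __call__(self, t):
        return early_model(t, self)


@dataclass(frozen=True)
class LateModelParams:
    """Parameters of the onset (late-marker) model.

    Attributes
    ----------
    B : float
        Basal fluorescence before the onset (a.u.).
    A : float
        Onset amplitude (a.u.), strictly positive.
    t_h : float
        Half-rise time in hours (midpoint of the sigmoidal onset).
    tau_o : float
        Rise width in hours, strictly positive.
    lam : float
        Post-onset decay rate in h^-1 (photobleaching / degradation),
        non-negative; ``lam == 0`` gives a monotone rise to ``B + A``.
    """

    B: float
    A: float
    t_h: float
    tau_o: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if not self.tau_o > 0:
            raise ValueError(f"tau_o must be > 0, got {self.tau_o}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")

    def __call__(self, t):
        return late_model(t, self)


def early_model(t, params: EarlyModelParams):
    """Evaluate the early-marker breakdown model at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    s = expit(-(t - params.t_b) / params.tau_b)
    poly = params.a0 + params.a1 * t + params.a2 * t * t
    return s * poly + (1.0 - s) * params.c


def late_model(t, params: LateModelParams):
    """Evaluate the late-marker onset model at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    s = expit((t - params.t_h) / params.tau_o)
    decay = np.exp(-params.lam * np.maximum(0.0, t - params.t_h))
    return params.B + params.A * s * decay


def late_model_derivative(t, params: LateModelParams):
    """Analytic derivative of the late model in a.u. h^-1.

    At the kink introduced by ``max(0, t - t_h)`` the right-sided
    derivative is returned, matching the convention used by the onset
    tangent construction.
    """
    t = np.asarray(t, dtype=float)
    s = expit((t - params.t_h) / params.tau_o)
    ds = s * (1.0 - s) / params.tau_o
    dt_pos = np.maximum(0.0, t - params.t_h)
    decay = np.exp(-params.lam * dt_pos)
    post = t >= params.t_h
    return params.A * decay * (ds - np.where(post, params.lam * s, 0.0))


# Column layout shared by the fits CSV: union of both parameter sets.
PARAM_FIELDS = {
    "early": tuple(f.name for f in fields(EarlyModelParams)),
    "late": tuple(f.name for f in fields(LateModelParams)),
}


def params_to_dict(params) -> dict:
    """Serialize model parameters to a flat dict including the kind tag."""
    if isinstance(params, EarlyModelParams):
        kind = "early"
    elif isinstance(params, LateModelParams):
        kind = "late"
    else:
        raise TypeError(f"unknown parameter type {type(params)!r}")
    out = {"kind": kind}
    out.update(asdict(params))
    return out


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`; ignores irrelevant/NaN columns."""
    kind = d["kind"]
    if kind not in PARAM_FIELDS:
        raise ValueError(f"unknown model kind {kind!r}")
    cls = EarlyModelParams if kind == "early" else LateModelParams
    kwargs = {name: float(d[name]) for name in PARAM_FIELDS[kind]}
    return cls(**kwargs)
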