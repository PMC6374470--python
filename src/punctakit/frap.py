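"""FRAP trace normalization and single-exponential recovery fitting.

A FRAP experiment bleaches one punctum and records its fluorescence
every ``dt`` seconds.  After normalizing to the pre-bleach mean, the
recovery is fitted with the one-component exponential

    F(t) = F_inf - (F_inf - F_bleach) * exp(-t / tau)

whose parameters give the recovery time constant ``tau``, the half-time
``tau * ln 2`` and the mobile fraction
``(F_inf - F_bleach) / (1 - F_bleach)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

# traces whose post-bleach dynamic range is below this are treated as
# non-recovering: tau is unidentifiable
_FLAT_RANGE = 1e-9


@dataclass
class FRAPTrace:
    """Normalized FRAP trace; t = 0 is the first post-bleach sample and
    pre-bleach samples carry negative times."""

    t: np.ndarray            # s
    F: np.ndarray            # normalized intensity
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach sample")

    @property
    def t_post(self) -> np.ndarray:
        return self.t[self.n_prebleach:]

    @property
    def F_post(self) -> np.ndarray:
        return self.F[self.n_prebleach:]


@dataclass
class FRAPFit:
    F_bleach: float
    F_inf: float
    tau: float               # s
    half_time: float         # s, = tau * ln 2
    mobile_fraction: float
    residual_norm: float
    converged: bool = True
    tau_identifiable: bool = True


def normalize_trace(raw: np.ndarray, n_prebleach: int,
                    dt: float = 10.0, t: np.ndarray | None = None) -> FRAPTrace:
    """Normalize a raw intensity trace to its pre-bleach mean.

    ``raw`` holds ``n_prebleach`` pre-bleach samples followed by the
    post-bleach recovery.  Times default to a uniform grid of spacing
    ``dt`` rebased so the first post-bleach sample sits at t = 0; an
    explicit ``t`` (same convention) overrides the grid.
    """
    raw = np.asarray(raw, dtype=float)
    if n_prebleach < 1:
        raise ValueError("need at least one pre-bleach sample")
    if raw.size - n_prebleach < 4:
        raise ValueError("need at least 4 post-bleach samples")
    pre_mean = raw[:n_prebleach].mean()
    if pre_mean == 0:
        raise ValueError("pre-bleach mean is zero; cannot normalize")
    if t is None:
        t = dt * (np.arange(raw.size) - n_prebleach)
    return FRAPTrace(t=np.asarray(t, dtype=float), F=raw / pre_mean,
                     n_prebleach=n_prebleach)


def _model(t, f_inf, f_bleach, tau):
    return f_inf - (f_inf - f_bleach) * np.exp(-t / tau)


def _model_delta(t, f_bleach, delta, tau):
    # delta = F_inf - F_bleach >= 0 keeps the recovery non-decreasing
    return f_bleach + delta * (1.0 - np.exp(-t / tau))


def fit_recovery(trace: FRAPTrace) -> FRAPFit:
    """Least-squares fit of the single-exponential recovery model to the
    post-bleach samples.

    Initialization: F_bleach from the first post-bleach point, F_inf from
    the mean of the last three, tau from the time at which the trace
    first crosses halfway between them.  Bounds: F_bleach in [0, 1],
    F_inf in [F_bleach, 1.2], tau in (0, 10 t_max].  A non-recovering
    trace (F_inf == F_bleach) has mobile fraction 0 and an unidentifiable
    tau, flagged rather than fitted; failure to converge is flagged and
    the initialization returned with its residual.
    """
    t, F = trace.t_post, trace.F_post
    if t.size < 4:
        raise ValueError("need at least 4 post-bleach samples")
    f_b0 = float(np.clip(F[0], 0.0, 1.0))
    f_i0 = float(np.clip(np.mean(F[-3:]), f_b0, 1.2))
    t_max = float(t[-1])

    if f_i0 - f_b0 < _FLAT_RANGE:
        resid = float(np.linalg.norm(F - np.mean(F)))
        return FRAPFit(F_bleach=f_b0, F_inf=f_b0, tau=float("nan"),
                       half_time=float("nan"), mobile_fraction=0.0,
                       residual_norm=resid, converged=True,
                       tau_identifiable=False)

    half = f_b0 + 0.5 * (f_i0 - f_b0)
    above = np.nonzero(F >= half)[0]
    t_half = float(t[above[0]]) if above.size else 0.5 * t_max
    # at the half-crossing, t = tau ln 2
    tau0 = float(np.clip(t_half / math.log(2.0) if t_half > 0 else t[1],
                         1e-6, 10.0 * t_max))

    try:
        popt, _ = curve_fit(
            _model_delta, t, F, p0=[f_b0, f_i0 - f_b0, tau0],
            bounds=([0.0, 0.0, 1e-12], [1.0, 1.2, 10.0 * t_max]),
            xtol=1e-8, ftol=1e-12, maxfev=10_000)
        f_bleach, delta, tau = map(float, popt)
        f_inf = f_bleach + delta
        converged = True
    except RuntimeError:
        f_inf, f_bleach, tau = f_i0, f_b0, tau0
        converged = False
    resid = float(np.linalg.norm(F - _model(t, f_inf, f_bleach, tau)))
    denom = 1.0 - f_bleach
    mobile = (f_inf - f_bleach) / denom if denom > 1e-9 else float("nan")
    return FRAPFit(F_bleach=f_bleach, F_inf=f_inf, tau=tau,
                   half_time=tau * math.log(2.0),
                   mobile_fraction=float(min(mobile, 1.05)),
                   residual_norm=resid, converged=converged)
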