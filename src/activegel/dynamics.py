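"""Minimal critically damped dynamic model of gel contraction.

The boundary-to-boundary span of an activated region relaxes from ``L_init``
to ``L_fin = K * L_init`` like the step response of a critically damped
oscillator started at rest:

    L(t) = K L_init + (1 - K) L_init (1 + t/tau) exp(-t/tau).

The speed ``-dL/dt`` vanishes at t = 0 and t -> inf and peaks at the
compression time ``t = tau`` with magnitude ``L_init (1 - K) / (e tau)``;
the same ``tau`` sets the long-time exponential tail.  The compression time
is size-independent, so the maximal speed is proportional to the initial
span — the hallmark of boundary-governed contraction.

For rectangles of initial aspect ratio ``alpha = X_init / Y_init > 1`` the
two principal axes contract with coupled compression times

    tau_X = tau_c * alpha^((1-gamma)/2),   tau_Y = tau_c * alpha^(-(1-gamma)/2),

so that ``tau_X * tau_Y = tau_c**2`` and the ratio of maximal axis speeds is
``alpha**gamma`` (empirically gamma ≈ 0.4).  The short axis contracts first,
producing a transient overshoot of the aspect ratio (alpha_max > alpha_init)
although the final aspect ratio returns to the initial one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ContractionCurve", "RectangleDynamics", "PAPER_PRESET",
    "TrajectoryFit", "fit_trajectory", "gamma_scan", "v_max_numeric",
]

#: global parameter set of the reference experiments at n = 20 cycles
PAPER_PRESET = {"K": 0.23, "tau_c": 12.0, "gamma": 0.4}


@dataclass
class ContractionCurve:
    """Critically damped contraction of one linear dimension."""

    L_init: float
    K: float
    tau: float

    def __post_init__(self):
        if self.L_init <= 0:
            raise ValueError("L_init must be positive")
        if not (0 < self.K <= 1):
            raise ValueError("contraction ratio K must lie in (0, 1]")
        if self.tau <= 0:
            raise ValueError("compression time tau must be positive")

    @property
    def L_fin(self) -> float:
        return self.K * self.L_init

    @property
    def v_max(self) -> float:
        """Peak contraction speed, attained at t = tau."""
        return self.L_init * (1.0 - self.K) / (math.e * self.tau)

    def __call__(self, times):
        return self.evaluate(times)

    def evaluate(self, times):
        """L(t) for t >= 0 (scalar or array)."""
        t = np.asarray(times, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        s = t / self.tau
        L = self.L_fin + (self.L_init - self.L_fin) * (1.0 + s) * np.exp(-s)
        return L if np.ndim(times) else float(L)

    def velocity(self, times):
        """Closing speed -dL/dt (nonnegative)."""
        t = np.asarray(times, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        v = (self.L_init - self.L_fin) * t / self.tau ** 2 * np.exp(-t / self.tau)
        return v if np.ndim(times) else float(v)


@dataclass
class RectangleDynamics:
    """Coupled two-axis contraction of a rectangular activated region.

    Axes are ordered so that ``X_init >= Y_init`` (swap otherwise); both
    share the contraction ratio K but carry their own compression times
    tied by the aspect ratio and the coupling exponent gamma.
    """

    X_init: float
    Y_init: float
    K: float = PAPER_PRESET["K"]
    tau_c: float = PAPER_PRESET["tau_c"]
    gamma: float = PAPER_PRESET["gamma"]
    swapped: bool = field(init=False, default=False)

    def __post_init__(self):
        if self.X_init <= 0 or self.Y_init <= 0:
            raise ValueError("axis half-lengths must be positive")
        if self.X_init < self.Y_init:
            self.X_init, self.Y_init = self.Y_init, self.X_init
            self.swapped = True
        if not (0 < self.gamma < 1):
            # gamma = 1 is the uncoupled naive limit; allow it for comparison
            if self.gamma != 1.0:
                raise ValueError("coupling exponent gamma must lie in (0, 1]")

    @property
    def alpha_init(self) -> float:
        return self.X_init / self.Y_init

    @property
    def tau_X(self) -> float:
        return self.tau_c * self.alpha_init ** ((1.0 - self.gamma) / 2.0)

    @property
    def tau_Y(self) -> float:
        return self.tau_c * self.alpha_init ** (-(1.0 - self.gamma) / 2.0)

    @property
    def curve_X(self) -> ContractionCurve:
        return ContractionCurve(self.X_init, self.K, self.tau_X)

    @property
    def curve_Y(self) -> ContractionCurve:
        return ContractionCurve(self.Y_init, self.K, self.tau_Y)

    @property
    def alpha_fin(self) -> float:
        """Final aspect ratio; equals alpha_init since both axes share K."""
        return (self.K * self.X_init) / (self.K * self.Y_init)

    @property
    def v_max_ratio(self) -> float:
        """Ratio of maximal axis speeds v_max_X / v_max_Y = alpha**gamma."""
        return self.curve_X.v_max / self.curve_Y.v_max

    def curves(self, times):
        """(X(t), Y(t), alpha(t)) sampled at the given times."""
        X = self.curve_X.evaluate(times)
        Y = self.curve_Y.evaluate(times)
        return X, Y, X / Y

    def alpha_max(self, horizon: float = 12.0, samples: int = 4001) -> float:
        """Maximum of alpha(t) over [0, horizon * tau_X] by dense sampling."""
        t = np.linspace(0.0, horizon * self.tau_X, samples)
        return float((self.curve_X.evaluate(t) / self.curve_Y.evaluate(t)).max())


@dataclass
class TrajectoryFit:
    L_init: float
    K: float
    tau: float
    residual_sum_squares: float
    tau_identifiable: bool
    warnings: list

    def to_dict(self) -> dict:
        return {
            "L_init": self.L_init, "K": self.K, "tau": self.tau,
            "residual_sum_squares": self.residual_sum_squares,
            "tau_identifiable": self.tau_identifiable,
            "warnings": list(self.warnings),
        }


def fit_trajectory(series) -> TrajectoryFit:
    """Fit (L_init, K, tau) of a critically damped curve to a (t, L) series.

    ``series`` is a DataFrame (or mapping) with columns ``t`` and ``L``.
    A constant series returns K = 1 with ``tau_identifiable=False``;
    short or non-monotone series produce warnings in the result.
    """
    df = pd.DataFrame(series)
    if not {"t", "L"}.issubset(df.columns):
        raise ValueError("series must provide columns 't' and 'L'")
    df = df.sort_values("t")
    t = df["t"].to_numpy(dtype=float)
    L = df["L"].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(L <= 0):
        raise ValueError("require t >= 0 and L > 0")

    notes: list[str] = []
    if np.ptp(L) < 1e-12 * max(L.max(), 1.0):
        notes.append("constant series: compression time not identifiable")
        return TrajectoryFit(L_init=float(L.mean()), K=1.0, tau=float("nan"),
                             residual_sum_squares=0.0, tau_identifiable=False,
                             warnings=notes)
    if len(t) < 5:
        notes.append("fewer than 5 time points: fit may be unreliable")
    rough_noise = np.std(np.diff(L, 2)) if len(L) > 2 else 0.0
    if np.any(np.diff(L) > 3 * rough_noise + 1e-12):
        notes.append("series increases by more than the noise level")

    L0_guess = float(L[0])
    K_guess = float(np.clip(L.min() / L0_guess, 1e-3, 1.0 - 1e-6))
    span = float(t.max() - t.min()) or 1.0

    def resid(theta):
        L0, K, tau = theta
        return ContractionCurve(L0, K, tau).evaluate(t) - L

    best = None
    for tau_guess in (span / 10, span / 3, span):
        sol = least_squares(
            resid, x0=[L0_guess, K_guess, tau_guess],
            bounds=([1e-9, 1e-6, 1e-9], [np.inf, 1.0, np.inf]), method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    L0, K, tau = best.x
    if t.max() < 2 * tau:
        notes.append("series spans less than 2 compression times")
    return TrajectoryFit(
        L_init=float(L0), K=float(K), tau=float(tau),
        residual_sum_squares=float(2 * best.cost),
        tau_identifiable=True, warnings=notes,
    )


def v_max_numeric(curve: ContractionCurve, t_max: Optional[float] = None,
                  step: Optional[float] = None) -> tuple[float, float]:
    """Peak closing speed and its time, from central differences.

    Samples L(t) on a grid of step <= tau/200 (the default) and returns
    (v_max, t_at_max).
    """
    if t_max is None:
        t_max = 10.0 * curve.tau
    if step is None:
        step = curve.tau / 200.0
    t = np.arange(0.0, t_max + step, step)
    L = curve.evaluate(t)
    v = -(L[2:] - L[:-2]) / (2 * step)
    i = int(np.argmax(v))
    return float(v[i]), float(t[i + 1])


def gamma_scan(alphas: Sequence[float], K: float = PAPER_PRESET["K"],
               tau_c: float = PAPER_PRESET["tau_c"],
               gamma: float = PAPER_PRESET["gamma"],
               area: float = 10_000.0) -> float:
    """Recover the coupling exponent from simulated rectangle contractions.

    For each initial aspect ratio, a rectangle of the given area is
    simulated, each axis's maximal speed is extracted by central differences
    on a dense time grid, and log(speed ratio) is regressed on log(aspect
    ratio); the slope is the fitted exponent.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if len(alphas) < 3:
        raise ValueError("need at least 3 aspect ratios")
    if np.any(alphas <= 1):
        raise ValueError("aspect ratios must exceed 1")
    ratios = []
    for a in alphas:
        Y = math.sqrt(area / a)
        dyn = RectangleDynamics(X_init=a * Y, Y_init=Y, K=K, tau_c=tau_c,
                                gamma=gamma)
        vX, _ = v_max_numeric(dyn.curve_X)
        vY, _ = v_max_numeric(dyn.curve_Y)
        ratios.append(vX / vY)
    slope = np.polyfit(np.log(alphas), np.log(ratios), 1)[0]
    return float(slope)
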