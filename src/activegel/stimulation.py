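"""Stimulation-efficiency model: from light-scan cycles to contraction.

Each stimulation cycle activates a fraction ``P`` of the not-yet-activated
myosin (activated material cannot be stimulated twice), so the
spring-coefficient ratio after ``n`` cycles is

    K(n) = 1 + (K_inf - 1) * [1 - (1 - P)^n],

which decays monotonically from K(0) = 1 to the saturated ratio
``K_inf = lim_{n->inf} K(n)``.  Since the static spring network predicts a
contraction ratio C_fin/C_init = K, observed contraction ratios versus n can
be fit directly for (P, K_inf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["StimulationFit", "K_of_n", "fit_stimulation", "v_max_of_n"]


def _validate(P: float, K_inf: float) -> None:
    if not (0.0 <= P <= 1.0):
        raise ValueError("stimulation efficiency P must lie in [0, 1]")
    if not (0.0 < K_inf <= 1.0):
        raise ValueError("saturated ratio K_inf must lie in (0, 1]")


def K_of_n(n, P: float, K_inf: float):
    """Spring-coefficient ratio K after ``n`` stimulation cycles.

    Accepts a scalar or array of nonnegative cycle counts; returns values in
    ``[K_inf, 1]``.
    """
    _validate(P, K_inf)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("cycle count n must be nonnegative")
    out = 1.0 + (K_inf - 1.0) * (1.0 - (1.0 - P) ** n_arr)
    return out if np.ndim(n) else float(out)


def v_max_of_n(n, C_init: float, P: float, K_inf: float, tau_c: float):
    """Maximal boundary-closing speed after ``n`` cycles.

    The critically damped contraction of a span of initial boundary-to-
    boundary distance ``D_init = 2 * C_init`` reaches its maximal speed
    ``D_init (1 - K(n)) / (e tau_c)`` at the compression time ``tau_c``.
    ``C_init`` is the radius (half-span); the returned speed is that of the
    full diameter, matching boundary positions tracked on opposite sides.
    """
    if C_init <= 0:
        raise ValueError("C_init must be positive")
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    K = K_of_n(n, P, K_inf)
    D_init = 2.0 * C_init
    return D_init * (1.0 - np.asarray(K)) / (math.e * tau_c) if np.ndim(n) \
        else D_init * (1.0 - K) / (math.e * tau_c)


@dataclass
class StimulationFit:
    P: float
    K_inf: float
    residual_sum_squares: float
    P_halfwidth: float          # ~95% confidence half-width from the Jacobian
    K_inf_halfwidth: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "P": self.P, "K_inf": self.K_inf,
            "residual_sum_squares": self.residual_sum_squares,
            "P_halfwidth": self.P_halfwidth,
            "K_inf_halfwidth": self.K_inf_halfwidth,
            "n_points": self.n_points,
        }


def fit_stimulation(data) -> StimulationFit:
    """Least-squares fit of (P, K_inf) to observed contraction ratios.

    ``data`` is a DataFrame (or mapping) with columns ``n`` (cycles) and
    ``ratio`` (observed C_fin/C_init).  Uses bounded trust-region least
    squares with multiple starts in P, since the objective can be flat when
    the sampled n range does not bracket the K(n) knee.
    """
    df = pd.DataFrame(data)
    if not {"n", "ratio"}.issubset(df.columns):
        raise ValueError("data must provide columns 'n' and 'ratio'")
    n = df["n"].to_numpy(dtype=float)
    ratio = df["ratio"].to_numpy(dtype=float)
    if np.any(n < 0) or np.any((ratio <= 0) | (ratio > 1 + 1e-9)):
        raise ValueError("require n >= 0 and ratio in (0, 1]")
    if len(np.unique(n)) < 3:
        raise ValueError("non-identifiable: need at least 3 distinct n values")
    if np.ptp(ratio) < 1e-12:
        raise ValueError("non-identifiable: contraction ratios are constant")

    def resid(theta):
        P, K_inf = theta
        return K_of_n(n, P, K_inf) - ratio

    best = None
    k0 = float(np.clip(ratio.min(), 1e-3, 1.0))
    for p0 in (0.05, 0.2, 0.5):
        sol = least_squares(resid, x0=[p0, k0],
                            bounds=([1e-9, 1e-9], [1.0, 1.0]), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol

    rss = float(2 * best.cost)
    dof = max(len(n) - 2, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
        half = 1.96 * np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        warnings.warn("singular Jacobian; confidence half-widths unavailable",
                      stacklevel=2)
        half = np.array([np.nan, np.nan])
    return StimulationFit(
        P=float(best.x[0]), K_inf=float(best.x[1]),
        residual_sum_squares=rss,
        P_halfwidth=float(half[0]), K_inf_halfwidth=float(half[1]),
        n_points=len(n),
    )
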