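"""Saturation fits of MD backbone-RMSD trajectories and the warm/cold
flexibility contrast.

A trajectory's backbone RMSD rises from zero toward a plateau; the
saturation model RMSD(t) = t * RMSD_max / (t^n + const) captures that rise
with three positive parameters.  RMSD_max is the asymptotic deviation when
n = 1 and an effective plateau scale otherwise.  ΔRMSD, the difference
between the RMSD_max fitted at 27 °C and at 4 °C, is used as a flexibility
proxy: a negative value means the molecule moves more in the cold, the
cold-adaptation signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["TrajectoryFit", "DeltaRmsd", "rmsd_model", "fit_rmsd_curve",
           "delta_rmsd"]


@dataclass
class TrajectoryFit:
    rmsd_max: float
    n: float
    const: float
    temperature_label: str
    rss: float
    n_points: int


@dataclass
class DeltaRmsd:
    value: float
    warm_label: str
    cold_label: str


def rmsd_model(t: np.ndarray, rmsd_max: float, n: float,
               const: float, hill: bool = False) -> np.ndarray:
    """RMSD(t) = t * RMSD_max / (t^n + const); with ``hill`` the
    t^n * RMSD_max / (t^n + const) variant (saturating for all n)."""
    t = np.asarray(t, float)
    num = np.power(t, n) if hill else t
    return num * rmsd_max / (np.power(t, n) + const)


def fit_rmsd_curve(times, rmsds, init: tuple[float, float, float] | None = None,
                   seed: int = 0, temperature_label: str = "",
                   hill: bool = False, fix_n: float | None = None,
                   n_restarts: int = 5) -> TrajectoryFit:
    """Nonlinear least-squares fit of the saturation model.

    Parameters are constrained positive.  Default initialization is
    (max(rmsds), 1, median(times)); ``n_restarts`` jittered restarts
    (seeded) are run and the lowest-RSS solution returned, so the result is
    reproducible bit-for-bit given seed and inputs.  ``fix_n`` pins the
    exponent (e.g. at 1 for the strictly saturating form).
    """
    t = np.asarray(times, float)
    y = np.asarray(rmsds, float)
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly positive and increasing")
    if np.max(y) <= 0:
        raise ValueError("flat/zero trajectory: RMSD_max at the 0 boundary")
    if init is None:
        init = (float(np.max(y)), 1.0, float(np.median(t)))
    rng = np.random.default_rng(seed)

    if fix_n is None:
        def resid(p):
            return rmsd_model(t, p[0], p[1], p[2], hill=hill) - y
        x0_full = np.array(init, float)
        lo, hi = [1e-12] * 3, [np.inf] * 3
    else:
        def resid(p):
            return rmsd_model(t, p[0], fix_n, p[1], hill=hill) - y
        x0_full = np.array([init[0], init[2]], float)
        lo, hi = [1e-12] * 2, [np.inf] * 2

    best = None
    starts = [x0_full] + [x0_full * np.exp(rng.normal(0, 0.3, x0_full.size))
                          for _ in range(n_restarts - 1)]
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("all fit restarts failed to converge")
    rss, p = best
    if fix_n is None:
        rmax, n, const = p
    else:
        rmax, const = p
        n = fix_n
    return TrajectoryFit(rmsd_max=float(rmax), n=float(n), const=float(const),
                         temperature_label=temperature_label, rss=rss,
                         n_points=len(t))


def delta_rmsd(fit_warm: TrajectoryFit, fit_cold: TrajectoryFit) -> DeltaRmsd:
    """RMSD_max(warm) − RMSD_max(cold); the sign is preserved (negative
    means higher flexibility in the cold)."""
    if fit_warm.temperature_label == fit_cold.temperature_label:
        raise ValueError("warm and cold fits carry the same label")
    return DeltaRmsd(value=fit_warm.rmsd_max - fit_cold.rmsd_max,
                     warm_label=fit_warm.temperature_label,
                     cold_label=fit_cold.temperature_label)
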