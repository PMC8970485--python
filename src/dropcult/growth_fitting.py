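"""Normalization and logistic fitting of droplet-pool growth curves.

Plate-reader fluorescence of a pool of droplets is background-subtracted and
divided by its initial net value, giving a fold-change curve that starts at 1.
Fold-change curves are then fit by least squares to the logistic growth
equation, optionally modified with a lag time τ:

    N(t) = K / (1 + ((K − P0)/P0) · exp(−r·(t − τ)))

with the initial population P0 fixed at 1 by the normalization.  The fitted K
is the "growth capacity" (fold increase from inoculation to saturation), r the
maximum specific growth rate (hr⁻¹), and τ the lag time (h).

A brute-force grid-search fitter is included as an independent cross-check of
the least-squares optimizer; it is intended for tests, not for routine use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "logistic_eval",
    "synthetic_logistic_curve",
    "normalize_raw_curve",
    "fit_growth_curve",
    "fit_oracle_grid",
    "curves_to_frame",
    "curves_from_frame",
    "fits_to_frame",
]

#: A curve whose maximum fold change stays below this is treated as flat
#: (no detectable growth); its rate is unidentifiable.
FLAT_CURVE_THRESHOLD = 1.1


@dataclass(frozen=True)
class GrowthCurve:
    """A normalized fold-change growth curve.

    ``values`` are strictly positive and start at 1 for normalized data
    (model-generated lag curves may start below 1, since the lag-modified
    logistic evaluates under P0 before τ); ``time_h`` is strictly
    increasing, in hours.  ``meta`` carries well/strain/condition labels.
    """

    time_h: np.ndarray
    values: np.ndarray
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("time_h and values must be matching 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if v.size:
            if v[0] > 1.0 + 1e-9:
                raise ValueError(
                    f"fold-change curve must start at or below 1, got {v[0]}"
                )
            if np.any(v <= 0):
                raise ValueError("normalized values must be positive")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted parameters of the (lag-modified) logistic growth equation."""

    K: float
    r: float
    tau: float = 0.0
    P0: float = 1.0
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.K < 1.0:
            raise ValueError(f"growth capacity K must be >= 1, got {self.K}")
        if self.r < 0:
            raise ValueError(f"growth rate r must be >= 0, got {self.r}")
        if self.tau < 0:
            raise ValueError(f"lag time tau must be >= 0, got {self.tau}")
        if self.P0 != 1.0:
            raise ValueError("P0 is fixed at 1 by the fold-change normalization")


def logistic_eval(
    fit: LogisticFit, t: float | np.ndarray, with_lag: bool = True
) -> float | np.ndarray:
    """Evaluate the (lag-modified) logistic equation at time ``t`` (hours).

    With ``with_lag=False`` the lag is dropped (τ treated as 0).  At t = τ the
    value is exactly P0 = 1; as t → ∞ it approaches K.
    """
    tau = fit.tau if with_lag else 0.0
    return _logistic(np.asarray(t, dtype=float), fit.K, fit.r, tau)


def _logistic(t: np.ndarray, K: float, r: float, tau: float) -> np.ndarray:
    # P0 = 1; exponent clipped to keep exp() finite for extreme (r, tau).
    z = np.clip(-r * (t - tau), -700.0, 700.0)
    return K / (1.0 + (K - 1.0) * np.exp(z))


def synthetic_logistic_curve(
    K: float,
    r: float,
    tau: float,
    time_h: Sequence[float],
    meta: Mapping[str, str] | None = None,
    pin_start: bool = False,
) -> GrowthCurve:
    """Noise-free curve evaluated from the lag-modified logistic.

    Useful for round-trip identifiability checks of the fitter.  With
    ``pin_start=True`` the t=0 sample is forced to exactly 1, as it would be
    in fold-change-normalized data (the lag-modified logistic itself
    evaluates below 1 for t < τ).
    """
    t = np.asarray(time_h, dtype=float)
    y = _logistic(t, K, r, tau).copy()
    if pin_start:
        y[0] = 1.0
    return GrowthCurve(time_h=t, values=y, meta=dict(meta or {}))


def normalize_raw_curve(
    time_h: Sequence[float],
    raw: Sequence[float],
    background: float | Sequence[float] | None = None,
    meta: Mapping[str, str] | None = None,
) -> GrowthCurve:
    """Background-subtract and fold-change-normalize a raw fluorescence series.

    ``background`` may be a scalar, a blank time series of the same length, or
    None, in which case it is estimated as the minimum of the first three
    readings (a conservative floor when no blank well is available; note that
    if the first reading is itself that minimum the net initial signal is zero
    and the curve is unusable — prefer passing a measured background).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(raw, dtype=float)
    if y.size == 0:
        raise ValueError("raw series must be non-empty")
    if background is None:
        background = float(np.min(y[:3]))
    bg = np.asarray(background, dtype=float)
    net = y - bg
    if net[0] <= 0:
        raise ValueError(
            f"non-positive initial net signal ({net[0]:.4g}); curve unusable"
        )
    # readings at or below background are floored just above zero so the
    # fold-change curve stays positive
    net = np.maximum(net, 1e-6 * net[0])
    return GrowthCurve(time_h=t, values=net / net[0], meta=dict(meta or {}))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic (K0, r0, tau0): plateau, max log-slope, first crossing of 2."""
    K0 = max(float(np.max(y)), 1.0 + 1e-6)
    logy = np.log(y)
    window = min(5, len(t) - 1)
    r0 = 0.5
    if window >= 1:
        slopes = (logy[window:] - logy[:-window]) / (t[window:] - t[:-window])
        if slopes.size:
            r0 = float(np.clip(np.max(slopes), 1e-3, 5.0))
    above = np.nonzero(y > 2.0)[0]
    tau0 = float(t[above[0]]) if above.size else 0.0
    return K0, r0, tau0


def fit_growth_curve(
    curve: GrowthCurve,
    with_lag: bool = True,
    *,
    x0: tuple[float, float, float] | None = None,
    max_rate: float = 5.0,
) -> LogisticFit:
    """Least-squares fit of the (lag-modified) logistic to a fold-change curve.

    P0 is fixed at 1.  Bounds: K ∈ [1, 10·max(values)], r ∈ [0, max_rate]
    hr⁻¹, τ ∈ [0, t_end].  Plain unweighted least squares.  A flat curve
    (max fold change < 1.1) is returned as K≈1 with ``converged=False`` since
    the rate is unidentifiable from it.
    """
    t = curve.time_h
    y = curve.values
    if t.size < 10:
        raise ValueError(f"need >= 10 time points to fit, got {t.size}")

    if float(np.max(y)) < FLAT_CURVE_THRESHOLD:
        rss = float(np.sum((y - 1.0) ** 2))
        return LogisticFit(K=1.0, r=0.0, tau=0.0, rss=rss, converged=False)

    K0, r0, tau0 = x0 if x0 is not None else _initial_guess(t, y)
    t_end = float(t[-1])
    hi_K = 10.0 * float(np.max(y))

    if with_lag:
        lo = np.array([1.0, 0.0, 0.0])
        hi = np.array([hi_K, max_rate, t_end])
        p0 = np.clip([K0, r0, tau0], lo, hi)

        def resid(p: np.ndarray) -> np.ndarray:
            return _logistic(t, p[0], p[1], p[2]) - y

    else:
        lo = np.array([1.0, 0.0])
        hi = np.array([hi_K, max_rate])
        p0 = np.clip([K0, r0], lo, hi)

        def resid(p: np.ndarray) -> np.ndarray:
            return _logistic(t, p[0], p[1], 0.0) - y

    result = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-14,
                           ftol=1e-14, gtol=1e-14)
    params = result.x
    rss = float(np.sum(result.fun**2))
    K, r = float(params[0]), float(params[1])
    tau = float(params[2]) if with_lag else 0.0
    return LogisticFit(K=K, r=r, tau=tau, rss=rss, converged=bool(result.success))


def fit_oracle_grid(
    curve: GrowthCurve,
    k_grid: Sequence[float],
    r_grid: Sequence[float],
    tau_grid: Sequence[float] = (0.0,),
) -> LogisticFit:
    """Exhaustive grid search over (K, r, τ), returning the minimum-RSS point.

    Independent of the least-squares path; meant as a verification oracle on
    small grids (≤ 50 points per axis).
    """
    k_grid = np.asarray(k_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if max(k_grid.size, r_grid.size, tau_grid.size) > 50:
        raise ValueError("oracle grids are limited to 50 points per axis")
    t = curve.time_h
    y = curve.values
    best: tuple[float, float, float, float] | None = None
    for K in k_grid:
        for r in r_grid:
            for tau in tau_grid:
                rss = float(np.sum((_logistic(t, K, r, tau) - y) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, float(K), float(r), float(tau))
    assert best is not None
    rss, K, r, tau = best
    return LogisticFit(K=K, r=r, tau=tau, rss=rss, converged=True)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Long-format table: well, strain, time_h, value."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well": c.meta.get("well", ""),
                    "strain": c.meta.get("strain", ""),
                    "time_h": c.time_h,
                    "value": c.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def curves_from_frame(frame: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for (well, strain), grp in frame.groupby(["well", "strain"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                time_h=grp["time_h"].to_numpy(),
                values=grp["value"].to_numpy(),
                meta={"well": str(well), "strain": str(strain)},
            )
        )
    return curves


def fits_to_frame(fits: Mapping[tuple[str, str], LogisticFit]) -> pd.DataFrame:
    """Fit table keyed by (well, strain): well, strain, K, r, tau, rss, converged."""
    records = [
        {
            "well": well,
            "strain": strain,
            "K": f.K,
            "r": f.r,
            "tau": f.tau,
            "rss": f.rss,
            "converged": f.converged,
        }
        for (well, strain), f in fits.items()
    ]
    return pd.DataFrame.from_records(
        records, columns=["well", "strain", "K", "r", "tau", "rss", "converged"]
    )
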