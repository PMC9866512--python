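"""Arrhenius fitting and fragile-to-strong crossover detection.

A strong liquid's diffusivity obeys the Arrhenius law
D = D0·exp(-ΔU/kB·T); a fragile liquid is super-Arrhenius.  Confined water
shows a crossover: curved (non-Arrhenius) ln D vs 1/T at high temperature
turning linear below a crossover temperature T0.  The crossover is
formalised here as a continuous two-segment linear fit in Arrhenius
coordinates with the breakpoint scanned over interior grid points; the
verdict requires both a corrected-information-criterion win over the
single-line fit and a slope difference beyond its joint uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress, t as t_dist

#: Boltzmann constant, kJ/(mol K).
KB = 0.0083145


@dataclass
class TemperatureSeries:
    """Sorted (T, D_z) data: T in K strictly increasing, D in 1e-5 cm²/s."""

    T: np.ndarray
    D: np.ndarray
    err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.T.shape != self.D.shape:
            raise ValueError("T and D must have the same shape")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.D <= 0):
            raise ValueError("diffusion coefficients must be positive")

    @property
    def n(self) -> int:
        return self.T.size


@dataclass
class ArrheniusFit:
    """D0·exp(-ΔU/kB·T) by linear regression of ln D on 1/T."""

    D0: float
    dU: float            # kJ/mol
    dU_err: float
    D0_err: float
    slope: float         # d lnD / d(1/T), K
    r_squared: float
    residual: float
    n_points: int


@dataclass
class CrossoverFit:
    """Segmented Arrhenius-plot fit and fragile-to-strong verdict."""

    verdict: str                     # "crossover" | "none"
    T0: float | None
    T0_interval: tuple | None
    dU_low: float | None             # low-T (strong) branch, kJ/mol
    D0_low: float | None
    dU_high: float | None            # local-slope apparent activation energy
    delta_aicc: float
    slope_diff: float
    slope_diff_se: float
    boundary_warning: bool = False


def arrhenius_fit(series: TemperatureSeries, T_range=None) -> ArrheniusFit:
    """Fit the Arrhenius law over an optional temperature window.

    ΔU = -slope·kB with slope from the regression of ln D on 1/T;
    uncertainties come from the regression covariance.
    """
    sel = np.ones(series.n, dtype=bool)
    if T_range is not None:
        sel = (series.T >= T_range[0]) & (series.T <= T_range[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the temperature range")
    x = 1.0 / series.T[sel]
    y = np.log(series.D[sel])
    res = linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return ArrheniusFit(D0=math.exp(res.intercept),
                        dU=-res.slope * KB,
                        dU_err=res.stderr * KB,
                        D0_err=math.exp(res.intercept) * res.intercept_stderr,
                        slope=res.slope,
                        r_squared=res.rvalue ** 2,
                        residual=float(np.linalg.norm(resid)),
                        n_points=int(sel.sum()))


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def detect_crossover(series: TemperatureSeries, min_points: int = 3,
                     aicc_window: float = 2.0) -> CrossoverFit:
    """Detect a non-Arrhenius → Arrhenius crossover in a D(T) series.

    Continuous two-segment linear model in (1/T, ln D) with the hinge
    scanned over interior data points (≥ ``min_points`` per side).  The
    verdict is "crossover" only if the two-segment model beats the single
    line by corrected AIC *and* the slope difference exceeds twice its
    standard error; otherwise "none" (a valid outcome).  T0 is the hinge
    temperature; its interval collects hinge positions within
    ``aicc_window`` of the optimum.  A best hinge at the edge of the
    admissible range is unidentifiable and reported as "none" with a
    boundary warning.
    """
    n = series.n
    if n < 2 * min_points:
        raise ValueError(f"need at least {2 * min_points} points")
    x = 1.0 / series.T[::-1]          # ascending in 1/T (descending in T)
    y = np.log(series.D[::-1])

    res_line = linregress(x, y)
    rss_line = float(np.sum((y - res_line.intercept - res_line.slope * x) ** 2))
    aicc_line = _aicc(rss_line, n, 2)

    cand = np.arange(min_points - 1, n - min_points + 1)
    fits = []
    for i in cand:
        xb = x[i]
        A = np.column_stack([np.ones(n), x, np.clip(x - xb, 0.0, None)])
        beta, rss_arr, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ beta
        rss = float(np.sum((y - pred) ** 2))
        fits.append((rss, i, beta, A))
    rss_best, i_best, beta, A = min(fits, key=lambda f: f[0])
    aicc_seg = _aicc(rss_best, n, 4)
    delta = aicc_line - aicc_seg

    dof = n - 3
    sigma2 = rss_best / max(dof, 1)
    cov = sigma2 * np.linalg.inv(A.T @ A)
    slope_diff = float(beta[2])
    slope_diff_se = float(np.sqrt(cov[2, 2]))
    tcrit = t_dist.ppf(0.975, max(dof, 1))
    significant = abs(slope_diff) > tcrit * slope_diff_se

    xb = x[i_best]
    T0 = 1.0 / xb
    in_window = [i for (rss, i, *_rest) in fits
                 if _aicc(rss, n, 4) <= aicc_seg + aicc_window]
    T_cand = [1.0 / x[i] for i in in_window]
    interval = (float(min(T_cand)), float(max(T_cand)))

    # low-T branch = large-1/T side of the hinge
    slope_low = beta[1] + beta[2]
    intercept_low = beta[0] - beta[2] * xb
    dU_low = -slope_low * KB
    dU_high = -beta[1] * KB
    boundary = i_best in (cand[0], cand[-1])

    verdict = ("crossover"
               if (delta > 0 and significant and not boundary) else "none")
    return CrossoverFit(
        verdict=verdict,
        T0=float(T0) if verdict == "crossover" else None,
        T0_interval=interval if verdict == "crossover" else None,
        dU_low=float(dU_low) if verdict == "crossover" else None,
        D0_low=float(math.exp(intercept_low)) if verdict == "crossover" else None,
        dU_high=float(dU_high) if verdict == "crossover" else None,
        delta_aicc=float(delta),
        slope_diff=slope_diff,
        slope_diff_se=slope_diff_se,
        boundary_warning=boundary)


def fit_vogel_fulcher(series: TemperatureSeries, T_range=None):
    """Optional super-Arrhenius fit ln D = ln A - B/(T - T_vf).

    Provided for characterising the fragile branch; not used for the
    crossover verdict.
    Returns (A, B, T_vf).
    """
    sel = np.ones(series.n, dtype=bool)
    if T_range is not None:
        sel = (series.T >= T_range[0]) & (series.T <= T_range[1])
    T = series.T[sel]
    y = np.log(series.D[sel])
    if T.size < 4:
        raise ValueError("need at least 4 points for a Vogel-Fulcher fit")

    def model(t, ln_a, b, t_vf):
        return ln_a - b / (t - t_vf)

    p0 = (y.max() + 1.0, 300.0, max(T.min() - 100.0, 1.0))
    popt, _ = curve_fit(model, T, y, p0=p0,
                        bounds=([-np.inf, 0.0, 0.0],
                                [np.inf, np.inf, T.min() - 1.0]),
                        maxfev=10000)
    return math.exp(popt[0]), float(popt[1]), float(popt[2])
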