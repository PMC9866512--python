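"""Axial mean-squared displacement, anomalous-diffusion regime fitting and
axial diffusion-coefficient extraction.

The axial MSD is computed with multiple time origins inside fixed-length
analysis windows (default 1 ns at 1 ps sampling, up to 50 windows), using
only spans where the molecule is continuously resident in the channel.  In
the long-time limit MSD(t) = 2·d·D_z·t^α with d = 1 for purely axial
motion: α = 1 is Fickian diffusion, α = 0.5 single-file, α = 2 ballistic.
The regime structure is read off a continuous piecewise power law fitted
in log-log coordinates with an exhaustive breakpoint scan and
small-sample-corrected information-criterion model selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len

from .trajectory import (ResidencyTable, Trajectory, TubeGeometry,
                         WaterSystem, cylindrical_transform, residency)

#: Å²/ps expressed in 1e-5 cm²/s.
A2_PER_PS_TO_1E5_CM2_PER_S = 10.0

#: α thresholds interpolating the named anchor regimes (0.5, 1, 2).
MODE_THRESHOLDS = {"single_file": 0.6, "subdiffusive": 0.9,
                   "fickian": 1.1, "superdiffusive": 1.8}


@dataclass
class MSDCurve:
    """Lag-time (ps) vs mean squared axial displacement (Å²) with the
    number of (molecule, origin) samples contributing per lag."""

    lags: np.ndarray
    msd: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.lags[0] == 0 and abs(self.msd[0]) > 1e-12:
            raise ValueError("MSD(0) must be 0")


@dataclass
class PiecewiseFit:
    """Continuous piecewise power law in log-log space."""

    breakpoints: np.ndarray   # ps, possibly empty
    exponents: np.ndarray     # slope per segment, first to last
    intercept: float          # log MSD at log t = 0 for the first segment
    aicc: float
    n_breakpoints: int
    rss: float
    terminal_alpha: float | None = None  # refined long-time exponent

    def predict_log(self, log_t: np.ndarray) -> np.ndarray:
        y = self.intercept + self.exponents[0] * log_t
        for bp, s_prev, s_next in zip(np.log(self.breakpoints),
                                      self.exponents[:-1], self.exponents[1:]):
            y = y + (s_next - s_prev) * np.clip(log_t - bp, 0.0, None)
        return y

    @property
    def long_time_alpha(self) -> float:
        if self.terminal_alpha is not None:
            return float(self.terminal_alpha)
        return float(self.exponents[-1])

    def long_time_prefactor(self) -> float:
        """c such that MSD ≈ c·t^α on the last segment (t in ps)."""
        if self.n_breakpoints == 0:
            return math.exp(self.intercept)
        x_ref = math.log(self.breakpoints[-1])
        y_ref = float(self.predict_log(np.array([x_ref]))[0])
        return math.exp(y_ref - self.long_time_alpha * x_ref)


@dataclass
class DiffusionResult:
    """Axial diffusion coefficient in 1e-5 cm²/s with its regime label."""

    Dz: float
    alpha: float
    mode: str
    caveat: bool = False
    shell: tuple | None = None
    n_samples: int = 0


# ---------------------------------------------------------------------------
# MSD estimation
# ---------------------------------------------------------------------------

def _msd_fft(Z: np.ndarray) -> np.ndarray:
    """All-origin MSD per series.  Z: (n_series, m) -> (n_series, m)."""
    n_series, m = Z.shape
    nfft = next_fast_len(2 * m)
    F = np.fft.rfft(Z, nfft, axis=1)
    ac = np.fft.irfft(F * np.conj(F), nfft, axis=1)[:, :m].real
    csq = np.concatenate([np.zeros((n_series, 1)), np.cumsum(Z * Z, axis=1)],
                         axis=1)
    k = np.arange(m)
    ss = csq[:, m - k] + csq[:, [m]] - csq[:, k]
    return (ss - 2.0 * ac) / (m - k)[None, :]


def _windows(n_frames: int, w: int, n_intervals: int) -> list:
    """Window start frames: consecutive non-overlapping windows first,
    falling back to half-window overlap when fewer than requested fit."""
    starts = list(range(0, n_frames - w + 1, w))
    if 0 < len(starts) < n_intervals:
        extra = [s for s in range(w // 2, n_frames - w + 1, w)
                 if s not in starts]
        starts = sorted(starts + extra)
    return starts[:n_intervals]


def axial_msd_from_tracks(z: np.ndarray, mask: np.ndarray | None, dt: float,
                          window: float = 1000.0, sampling: float = 1.0,
                          n_intervals: int = 50,
                          remove_com: bool = False) -> MSDCurve:
    """Axial MSD from raw tracks.

    z : (n_frames, n_molecules) axial coordinate (unwrapped within each
    residency span); mask : boolean in-channel indicator of the same shape
    (None = always resident).  Origins and lags live on the ``sampling``
    grid (the track is decimated to that grid); only origin/lag pairs fully
    inside a contiguous resident span contribute.  ``remove_com`` subtracts
    the per-frame mean axial position of the (resident) molecules first —
    standard drift removal, which for a finite periodic system strips the
    spurious centre-of-mass diffusion term 2(D/N)t.
    """
    z = np.asarray(z, dtype=float)
    if remove_com:
        if mask is None:
            z = z - z.mean(axis=1, keepdims=True)
        else:
            cnt = np.maximum(mask.sum(axis=1, keepdims=True), 1)
            com = np.where(mask, z, 0.0).sum(axis=1, keepdims=True) / cnt
            z = z - com
    n_frames, n_mol = z.shape
    stride = max(1, int(round(sampling / dt)))
    zs = z[::stride]
    ms = None if mask is None else mask[::stride]
    dts = dt * stride
    w = int(round(window / dts))
    if w < 2 or zs.shape[0] < w:
        raise ValueError("trajectory shorter than the MSD window")
    msd_sum = np.zeros(w)
    counts = np.zeros(w)
    lag_k = np.arange(w)
    for start in _windows(zs.shape[0], w, n_intervals):
        block = zs[start:start + w]
        if ms is None:
            res = _msd_fft(block.T)
            msd_sum += (res * (w - lag_k)[None, :]).sum(axis=0)
            counts += n_mol * (w - lag_k)
            continue
        mblock = ms[start:start + w]
        full = mblock.all(axis=0)
        if full.any():
            res = _msd_fft(block[:, full].T)
            msd_sum += (res * (w - lag_k)[None, :]).sum(axis=0)
            counts += int(full.sum()) * (w - lag_k)
        for j in np.flatnonzero(~full):
            col = mblock[:, j]
            if not col.any():
                continue
            edges = np.flatnonzero(np.diff(
                np.concatenate(([0], col.view(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2]):
                m = b - a
                if m < 2:
                    continue
                res = _msd_fft(block[a:b, j][None, :])[0]
                msd_sum[:m] += res * (m - np.arange(m))
                counts[:m] += m - np.arange(m)
    if counts[1:].sum() == 0:
        raise ValueError("no molecule resident for any full lag")
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(counts > 0, msd_sum / np.maximum(counts, 1), np.nan)
    msd[0] = 0.0
    return MSDCurve(lags=lag_k * dts, msd=msd, counts=counts)


def axial_msd(traj: Trajectory, ws: WaterSystem, tube: TubeGeometry,
              window: float = 1000.0, sampling: float = 1.0,
              n_intervals: int = 50, remove_com: bool = False,
              table: ResidencyTable | None = None) -> MSDCurve:
    """Axial MSD of in-channel molecules (wrapper over the track kernel)."""
    coords = cylindrical_transform(traj, ws, tube)
    if table is None:
        table = residency(traj, ws, tube, coords=coords)
    return axial_msd_from_tracks(coords.z, table.mask(), traj.dt,
                                 window=window, sampling=sampling,
                                 n_intervals=n_intervals,
                                 remove_com=remove_com)


# ---------------------------------------------------------------------------
# regime fitting
# ---------------------------------------------------------------------------

def _fit_grid(lags: np.ndarray, max_points_linear: int = 0) -> np.ndarray:
    """Indices of the fitting grid: linear at full resolution up to a tenth
    of the maximum lag, log-spaced beyond (keeps long-lag noise from
    dominating the fit)."""
    t_max = lags[-1]
    lin = np.flatnonzero(lags <= t_max / 10.0)
    rest = np.flatnonzero(lags > t_max / 10.0)
    if rest.size > 50:
        pick = np.unique(np.geomspace(1, rest.size, 50).astype(int) - 1)
        rest = rest[pick]
    return np.concatenate([lin, rest])


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_regimes(curve: MSDCurve, max_breakpoints: int = 3,
                n_candidates: int = 30, min_seg: int = 4,
                min_span_decades: float = 0.3,
                slope_merge_tol: float = 0.02) -> PiecewiseFit:
    """Weighted continuous piecewise power-law fit of log MSD vs log t.

    Breakpoints are scanned exhaustively over a log-spaced candidate grid;
    continuity is enforced through hinge basis functions; the model order
    (0..max_breakpoints breakpoints) is chosen by small-sample-corrected
    AIC.  Weights are the per-lag sample counts.  Every segment must span
    at least ``min_span_decades`` in log10 time — long-lag MSD estimates
    are strongly correlated, and without a span floor a short tail segment
    can fit pure noise.
    """
    sel = (curve.lags > 0) & np.isfinite(curve.msd) & (curve.counts > 0)
    if np.any(curve.msd[sel] <= 0):
        sel &= curve.msd > 0
    if sel.sum() < 10:
        raise ValueError("need at least 10 positive lag points")
    lags = curve.lags[sel]
    grid = _fit_grid(lags)
    x = np.log(lags[grid])
    y = np.log(curve.msd[sel][grid])
    # weight = sample count × local log-spacing: counts set the statistical
    # precision, the spacing factor makes each log-time interval contribute
    # by its extent rather than by how densely it happens to be gridded
    dx = np.gradient(x)
    wgt = curve.counts[sel][grid].astype(float) * dx
    wgt /= wgt.mean()
    sw = np.sqrt(wgt)
    n = x.size

    cand = np.unique(np.clip(
        np.round(np.geomspace(min_seg, n - min_seg, n_candidates)).astype(int),
        min_seg, n - min_seg))
    span = min_span_decades * math.log(10.0)
    cand = cand[(x[cand] - x[0] >= span) & (x[-1] - x[cand] >= span)]

    def solve(bps_idx):
        cols = [np.ones_like(x), x]
        for bi in bps_idx:
            cols.append(np.clip(x - x[bi], 0.0, None))
        A = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        rss = float(np.sum(wgt * (A @ beta - y) ** 2))
        return beta, rss

    best = None
    for nb in range(max_breakpoints + 1):
        if nb == 0:
            combos = [()]
        else:
            combos = [c for c in itertools.combinations(cand, nb)
                      if all(b - a >= min_seg and x[b] - x[a] >= span
                             for a, b in zip(c, c[1:]))]
        if not combos:
            continue
        local = min(((solve(c), c) for c in combos),
                    key=lambda t: t[0][1])
        (beta, rss), combo = local
        k = 2 + 2 * nb  # slopes/intercept + breakpoint positions
        score = _aicc(rss, n, k)
        if best is None or score < best[0]:
            best = (score, beta, rss, combo)
    score, beta, rss, combo = best
    slopes = np.cumsum(np.concatenate(([beta[1]], beta[2:])))
    bps = np.exp(x[list(combo)])
    # merge segments whose slopes are indistinguishable (resolution floor);
    # a noiseless knee otherwise splits into duplicate-slope segments
    keep_bp, keep_slope = [], [slopes[0]]
    for bp, s_next in zip(bps, slopes[1:]):
        if abs(s_next - keep_slope[-1]) < slope_merge_tol:
            continue
        keep_bp.append(bp)
        keep_slope.append(s_next)
    # terminal refinement: the limiting exponent is re-estimated over the
    # final half-decade of lags (or the last segment, if it starts later)
    # at full lag resolution — a piecewise-linear model averages residual
    # crossover curvature into its last segment, biasing the hinge slope
    t_max = lags[-1]
    t_lo = max(keep_bp[-1] if keep_bp else 0.0, t_max / math.sqrt(10.0))
    term = lags >= t_lo
    terminal_alpha = None
    if term.sum() >= 3:
        xt = np.log(lags[term])
        yt = np.log(curve.msd[sel][term])
        wt = curve.counts[sel][term].astype(float)
        wt /= wt.mean()
        terminal_alpha = float(np.polyfit(xt, yt, 1, w=np.sqrt(wt))[0])
    return PiecewiseFit(breakpoints=np.asarray(keep_bp),
                        exponents=np.asarray(keep_slope),
                        intercept=float(beta[0]),
                        aicc=float(score), n_breakpoints=len(keep_bp),
                        rss=rss, terminal_alpha=terminal_alpha)


def classify_mode(alpha: float) -> str:
    """Diffusion-mode label from the time exponent α.

    single_file (α<0.6) / subdiffusive (<0.9) / fickian (≤1.1) /
    superdiffusive (<1.8) / ballistic (≥1.8); thresholds interpolate the
    anchor regimes α = 0.5, 1 and 2.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if alpha < MODE_THRESHOLDS["single_file"]:
        return "single_file"
    if alpha < MODE_THRESHOLDS["subdiffusive"]:
        return "subdiffusive"
    if alpha <= MODE_THRESHOLDS["fickian"]:
        return "fickian"
    if alpha < MODE_THRESHOLDS["superdiffusive"]:
        return "superdiffusive"
    return "ballistic"


def extract_D(fit: PiecewiseFit, dims: int = 1,
              curve: MSDCurve | None = None,
              shell: tuple | None = None) -> DiffusionResult:
    """D_z from the long-time segment: MSD = 2·d·D_z·t^α.

    D_z = prefactor / (2·dims), converted from Å²/ps to 1e-5 cm²/s.  When
    the long-time segment classifies as Fickian and the curve is supplied,
    the prefactor is re-estimated by a count-weighted linear regression of
    MSD on t over that segment (the free-exponent prefactor trades off
    against α and is much noisier).  A non-Fickian long-time segment still
    yields a value, flagged with a caveat.
    """
    alpha = fit.long_time_alpha
    mode = classify_mode(alpha)
    d_a2ps = fit.long_time_prefactor() / (2.0 * dims)
    if mode == "fickian" and curve is not None:
        t0 = fit.breakpoints[-1] if fit.n_breakpoints else 0.0
        sel = (curve.lags > t0) & np.isfinite(curve.msd) & (curve.counts > 0)
        if sel.sum() >= 3:
            t = curve.lags[sel]
            m = curve.msd[sel]
            w = curve.counts[sel].astype(float)
            A = np.column_stack([np.ones_like(t), t])
            sw = np.sqrt(w / w.mean())[:, None]
            beta, *_ = np.linalg.lstsq(A * sw, m * sw[:, 0], rcond=None)
            if beta[1] > 0:
                d_a2ps = beta[1] / (2.0 * dims)
    return DiffusionResult(Dz=d_a2ps * A2_PER_PS_TO_1E5_CM2_PER_S,
                           alpha=alpha, mode=mode,
                           caveat=(mode != "fickian"), shell=shell)


def per_shell_D(traj: Trajectory, ws: WaterSystem, tube: TubeGeometry,
                shells, window: float = 1000.0, sampling: float = 1.0,
                n_intervals: int = 50, occupancy: float = 0.8,
                table: ResidencyTable | None = None,
                max_breakpoints: int = 2) -> list:
    """Axial D_z per coaxial shell.

    A molecule-window contributes to a shell's MSD only if the molecule is
    resident for the whole window and spends at least ``occupancy`` of its
    frames in that shell; shells that collect no sample are flagged.
    """
    coords = cylindrical_transform(traj, ws, tube)
    if table is None:
        table = residency(traj, ws, tube, coords=coords)
    res_mask = table.mask()
    intervals = list(shells.intervals) if hasattr(shells, "intervals") else list(shells)
    stride = max(1, int(round(sampling / traj.dt)))
    zs = coords.z[::stride]
    rs = coords.r[::stride]
    msk = res_mask[::stride]
    dts = traj.dt * stride
    w = int(round(window / dts))
    if w < 2 or zs.shape[0] < w:
        raise ValueError("trajectory shorter than the MSD window")
    lag_k = np.arange(w)
    out = []
    for (lo, hi) in intervals:
        msd_sum = np.zeros(w)
        counts = np.zeros(w)
        n_windows = 0
        for start in _windows(zs.shape[0], w, n_intervals):
            block_r = rs[start:start + w]
            block_m = msk[start:start + w]
            in_shell = (block_r >= lo) & (block_r < hi)
            ok = block_m.all(axis=0) & (in_shell.mean(axis=0) >= occupancy)
            if not ok.any():
                continue
            res = _msd_fft(zs[start:start + w][:, ok].T)
            msd_sum += (res * (w - lag_k)[None, :]).sum(axis=0)
            counts += int(ok.sum()) * (w - lag_k)
            n_windows += int(ok.sum())
        if n_windows == 0:
            out.append(DiffusionResult(Dz=np.nan, alpha=np.nan,
                                       mode="unpopulated", caveat=True,
                                       shell=(lo, hi), n_samples=0))
            continue
        msd = np.where(counts > 0, msd_sum / np.maximum(counts, 1), np.nan)
        msd[0] = 0.0
        curve = MSDCurve(lags=lag_k * dts, msd=msd, counts=counts)
        fit = fit_regimes(curve, max_breakpoints=max_breakpoints)
        result = extract_D(fit, curve=curve, shell=(lo, hi))
        result.n_samples = n_windows
        out.append(result)
    return out
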