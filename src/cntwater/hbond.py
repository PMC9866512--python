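"""Hydrogen-bond detection, intermittent autocorrelation and lifetimes.

A hydrogen bond between a donor and an acceptor water molecule is called
present when the O···O distance and the donor OH···O angle both fall within
geometric cutoffs (defaults 3.50 Å and 30°, inclusive).  The intermittent
autocorrelation C(t) of the bond indicator — rebinding after breakage
counts — is fitted with a biexponential, and the hydrogen-bond lifetime is
the amplitude-weighted mean of the two decay times:

    C(t) ≈ A1·exp(-t/τ1) + (1-A1)·exp(-t/τ2),   τ_HB = A1·τ1 + (1-A1)·τ2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.optimize import least_squares

from .trajectory import (CylindricalCoords, ResidencyTable, Trajectory,
                         TubeGeometry, WaterSystem, cylindrical_transform,
                         inside_mask)


@dataclass
class HBondCriteria:
    """Geometric bond criteria.

    angle_vertex="donor" (default): angle at the donor O between O–H and
    O···O.  angle_vertex="hydrogen": deviation of the O–H···O angle at the
    H from linearity.  Both use ``angle_max`` degrees, inclusive.
    """

    r_max: float = 3.50
    angle_max: float = 30.0
    angle_vertex: str = "donor"

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError("r_max must be positive")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must lie in (0, 90) degrees")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")


@dataclass
class HBondSeries:
    """Directed bonded-pair indicator over frames.

    pairs[k] = (donor molecule index, acceptor molecule index); matrix is
    boolean with shape (n_pairs, n_frames).
    """

    pairs: list
    matrix: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if len(self.pairs) != len(set(self.pairs)):
            raise ValueError("pair list contains duplicates")
        if self.matrix.shape[0] != len(self.pairs):
            raise ValueError("matrix rows must match pair count")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class HBACFCurve:
    """Intermittent hydrogen-bond autocorrelation estimate."""

    lags: np.ndarray    # ps
    c: np.ndarray
    counts: np.ndarray  # bonded origins contributing per lag


@dataclass
class BiexpFit:
    """Constrained biexponential fit of an HBACF (τ1 ≤ τ2 canonical)."""

    a1: float
    tau1: float
    tau2: float
    tau_hb: float
    residual: float
    converged: bool
    n_points: int = 0


def detect_hbonds(frame_positions: np.ndarray, ws: WaterSystem,
                  criteria: HBondCriteria | None = None,
                  include=None) -> set:
    """Directed (donor, acceptor) molecule pairs bonded in one frame.

    ``include`` optionally restricts the molecule indices considered (both
    partners must be included).  Vectorised all-pairs evaluation; the test
    suite holds an independent scalar brute-force oracle against this.
    """
    c = criteria or HBondCriteria()
    frame_positions = np.asarray(frame_positions, dtype=float)
    mols = np.arange(ws.n_molecules) if include is None else np.asarray(include)
    if mols.size < 2:
        return set()
    o_pos = frame_positions[[ws.molecules[m][0] for m in mols]]
    h1 = frame_positions[[ws.molecules[m][1] for m in mols]]
    h2 = frame_positions[[ws.molecules[m][2] for m in mols]]
    diff = o_pos[None, :, :] - o_pos[:, None, :]   # donor -> acceptor
    roo = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(roo, np.inf)
    cand_d, cand_a = np.nonzero(roo <= c.r_max)
    if cand_d.size == 0:
        return set()
    cos_max = np.cos(np.deg2rad(c.angle_max))
    out = set()
    if c.angle_vertex == "donor":
        oo = diff[cand_d, cand_a]
        oo_n = oo / np.linalg.norm(oo, axis=1, keepdims=True)
        ok = np.zeros(cand_d.size, dtype=bool)
        for h in (h1, h2):
            oh = h[cand_d] - o_pos[cand_d]
            oh_n = oh / np.linalg.norm(oh, axis=1, keepdims=True)
            cosang = np.einsum("ij,ij->i", oh_n, oo_n)
            # inclusive cutoff with a guard against roundoff at the boundary
            ok |= cosang >= cos_max - 1e-12
    else:
        ok = np.zeros(cand_d.size, dtype=bool)
        for h in (h1, h2):
            ho = o_pos[cand_d] - h[cand_d]
            ha = o_pos[cand_a] - h[cand_d]
            cosang = (np.einsum("ij,ij->i", ho, ha)
                      / (np.linalg.norm(ho, axis=1) * np.linalg.norm(ha, axis=1)))
            # linear arrangement has cos = -1; deviation ≤ angle_max
            ok |= cosang <= -np.cos(np.deg2rad(c.angle_max)) + 1e-12
    for d, a in zip(cand_d[ok], cand_a[ok]):
        out.add((int(mols[d]), int(mols[a])))
    return out


def mean_hbonds_per_molecule(traj: Trajectory, ws: WaterSystem,
                             tube: TubeGeometry,
                             criteria: HBondCriteria | None = None,
                             coords: CylindricalCoords | None = None) -> float:
    """Time-averaged 2 × (bond count) / (in-channel molecule count).

    Each bond is counted once for each of the two molecules it involves;
    frames with no in-channel molecule are skipped.
    """
    if coords is None:
        coords = cylindrical_transform(traj, ws, tube)
    mask = inside_mask(coords, tube)
    vals = []
    for f in range(traj.n_frames):
        mols = np.flatnonzero(mask[f])
        if mols.size == 0:
            continue
        bonds = detect_hbonds(traj.positions[f], ws, criteria, include=mols)
        vals.append(2.0 * len(bonds) / mols.size)
    if not vals:
        raise ValueError("no in-channel molecules in any frame")
    return float(np.mean(vals))


def hbond_series(traj: Trajectory, ws: WaterSystem, tube: TubeGeometry,
                 criteria: HBondCriteria | None = None,
                 coords: CylindricalCoords | None = None,
                 frames=None) -> HBondSeries:
    """Per-frame directed bond indicator for every pair ever bonded.

    Both partners must be in-channel at the evaluated frame for the bond to
    count.
    """
    if coords is None:
        coords = cylindrical_transform(traj, ws, tube)
    mask = inside_mask(coords, tube)
    frames = range(traj.n_frames) if frames is None else list(frames)
    per_frame = []
    pair_index: dict = {}
    for f in frames:
        mols = np.flatnonzero(mask[f])
        bonds = (detect_hbonds(traj.positions[f], ws, criteria, include=mols)
                 if mols.size >= 2 else set())
        per_frame.append(bonds)
        for p in bonds:
            pair_index.setdefault(p, len(pair_index))
    matrix = np.zeros((len(pair_index), len(per_frame)), dtype=bool)
    for fi, bonds in enumerate(per_frame):
        for p in bonds:
            matrix[pair_index[p], fi] = True
    pairs = [None] * len(pair_index)
    for p, k in pair_index.items():
        pairs[k] = p
    return HBondSeries(pairs=pairs, matrix=matrix, dt=traj.dt)


def hbacf(series: HBondSeries, max_lag: float | None = None) -> HBACFCurve:
    """Intermittent autocorrelation C(t) = <h(τ)h(τ+t)> / <h(τ)>.

    Origins τ run over all frames with τ + t in range, pooled over pairs;
    h is boolean so <h²> = <h>.  C(0) = 1 exactly whenever any bond exists.
    """
    H = series.matrix
    if not H.any():
        raise ValueError("no bond present in the series")
    n = series.n_frames
    max_k = n - 1 if max_lag is None else min(n - 1, int(round(max_lag / series.dt)))
    nfft = next_fast_len(2 * n)
    F = np.fft.rfft(H.astype(np.float64), nfft, axis=1)
    power = (F * np.conj(F)).sum(axis=0)
    # the autocorrelation of a 0/1 signal is non-negative; clamp FFT roundoff
    num = np.maximum(np.fft.irfft(power, nfft)[:max_k + 1].real, 0.0)
    prefix = np.concatenate(([0.0], np.cumsum(H.sum(axis=0, dtype=np.float64))))
    ks = np.arange(max_k + 1)
    den = prefix[n - ks]
    c = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    return HBACFCurve(lags=ks * series.dt, c=c, counts=den)


def _biexp(t, a1, tau1, tau2):
    return a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2)


def fit_biexp(curve: HBACFCurve, max_lag: float | None = None,
              c_floor: float = 0.01, n_starts: int = 5) -> BiexpFit:
    """Constrained nonlinear least squares of the biexponential model.

    Fits lags with C(t) > ``c_floor`` (the noise tail destabilises τ2) and
    t ≤ ``max_lag``; A1 ∈ [0, 1], τ > 0.  Multi-start from log-spaced τ
    guesses; the best run wins; τ1 ≤ τ2 is enforced by swapping.
    """
    sel = curve.c > c_floor
    if max_lag is not None:
        sel &= curve.lags <= max_lag
    t = curve.lags[sel]
    y = curve.c[sel]
    if t.size < 6:
        raise ValueError("need at least 6 lag points above the noise floor")
    t_pos = t[t > 0]
    scale = np.geomspace(max(t_pos.min(), 1e-6), t_pos.max(), n_starts)
    best = None
    for tau_guess in scale:
        x0 = np.array([0.5, tau_guess / 3.0, tau_guess * 3.0])
        try:
            res = least_squares(
                lambda p: _biexp(t, *p) - y, x0,
                bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, t.size)
    a1, tau1, tau2 = best.x
    if tau1 > tau2:
        a1, tau1, tau2 = 1.0 - a1, tau2, tau1
    tau_hb = a1 * tau1 + (1.0 - a1) * tau2
    return BiexpFit(a1=float(a1), tau1=float(tau1), tau2=float(tau2),
                    tau_hb=float(tau_hb),
                    residual=float(np.sqrt(2.0 * best.cost)),
                    converged=bool(best.success), n_points=int(t.size))


@dataclass
class ShellLifetimeRow:
    shell: tuple
    tau_hb: float
    tau_err: float
    a1: float
    tau1: float
    tau2: float
    n_pairs: int
    reliable: bool
    converged: bool


def per_shell_lifetime(traj: Trajectory, ws: WaterSystem, tube: TubeGeometry,
                       shells, criteria: HBondCriteria | None = None,
                       max_lag: float | None = None, n_blocks: int = 5,
                       min_events: int = 10,
                       attribution: str = "averaged") -> pd.DataFrame:
    """Hydrogen-bond lifetime per coaxial shell.

    A bond is attributed to the shell of its donor's time-averaged radial
    coordinate over the analysis window (``attribution="instantaneous"``
    uses the donor radius at the bond's first bonded frame instead).  The
    uncertainty is the standard error over ``n_blocks`` time-block
    estimates; shells with fewer than ``min_events`` ever-bonded pairs are
    flagged unreliable.
    """
    coords = cylindrical_transform(traj, ws, tube)
    series = hbond_series(traj, ws, tube, criteria, coords=coords)
    intervals = list(shells.intervals) if hasattr(shells, "intervals") else list(shells)
    rows = []
    for (lo, hi) in intervals:
        keep = []
        for k, (donor, _acc) in enumerate(series.pairs):
            if attribution == "averaged":
                r_d = float(coords.r[:, donor].mean())
            else:
                first = int(np.argmax(series.matrix[k]))
                r_d = float(coords.r[first, donor])
            if lo <= r_d < hi:
                keep.append(k)
        reliable = len(keep) >= min_events
        if not keep:
            rows.append(ShellLifetimeRow((lo, hi), np.nan, np.nan, np.nan,
                                         np.nan, np.nan, 0, False, False))
            continue
        sub = HBondSeries(pairs=[series.pairs[k] for k in keep],
                          matrix=series.matrix[keep], dt=series.dt)
        fit = fit_biexp(hbacf(sub, max_lag=max_lag))
        block_taus = []
        edges = np.linspace(0, sub.n_frames, n_blocks + 1).astype(int)
        for b in range(n_blocks):
            blk = sub.matrix[:, edges[b]:edges[b + 1]]
            if not blk.any():
                continue
            try:
                bf = fit_biexp(hbacf(
                    HBondSeries(pairs=sub.pairs, matrix=blk, dt=sub.dt)))
            except ValueError:
                continue
            if bf.converged and np.isfinite(bf.tau_hb):
                block_taus.append(bf.tau_hb)
        err = (float(np.std(block_taus, ddof=1) / np.sqrt(len(block_taus)))
               if len(block_taus) >= 2 else np.nan)
        rows.append(ShellLifetimeRow((lo, hi), fit.tau_hb, err, fit.a1,
                                     fit.tau1, fit.tau2, len(keep),
                                     reliable, fit.converged))
    return pd.DataFrame(
        {"shell_lo": [r.shell[0] for r in rows],
         "shell_hi": [r.shell[1] for r in rows],
         "tau_hb": [r.tau_hb for r in rows],
         "tau_err": [r.tau_err for r in rows],
         "a1": [r.a1 for r in rows],
         "tau1": [r.tau1 for r in rows],
         "tau2": [r.tau2 for r in rows],
         "n_pairs": [r.n_pairs for r in rows],
         "reliable": [r.reliable for r in rows],
         "converged": [r.converged for r in rows]})
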