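"""Synthetic trajectory, bond-process and D(T) generators with ground truth.

These generators emulate the statistical structure the analysis chain
assumes — layered radial density, axial motion with a prescribed diffusion
mode, a two-population bond-survival process with an exactly biexponential
intermittent autocorrelation, and Arrhenius / super-Arrhenius diffusivity
series — without any molecular-dynamics physics.  Every generator is
deterministic for a fixed seed and returns a ground-truth record from which
all downstream targets (D, α, A1, τ1, τ2, τ_HB, T0, ΔU) follow directly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .hbond import HBondSeries
from .trajectory import Trajectory, TubeGeometry

#: Boltzmann constant in kJ/(mol K), so activation energies are in kJ/mol.
KB = 0.0083145

#: TIP-style O-H bond length used for generated hydrogens, Å.
OH_BOND = 0.9572


def chirality_to_diameter(n: int, m: int, a: float = 1.418) -> float:
    """Nanotube diameter (Å) from chirality indices.

    d = (√3/π) · a · √(n² + m² + nm), with a the C-C bond length in Å.
    """
    if n < m or m < 0 or n <= 0:
        raise ValueError("chirality requires n >= m >= 0 and n > 0")
    return math.sqrt(3.0) / math.pi * a * math.sqrt(n * n + m * m + n * m)


# ---------------------------------------------------------------------------
# axial trajectories
# ---------------------------------------------------------------------------

@dataclass
class AxialSimSpec:
    """Specification of an axial-motion trajectory.

    mode="fickian": independent Gaussian z-increments of variance 2·D·dt.
    mode="single_file": independent Brownian walkers on a periodic line of
    length n_molecules / line_density, rank-labelled so trajectories never
    cross; the tagged-particle MSD approaches (2/ρ)·√(D t / π).
    mode="ballistic": constant per-molecule velocity ~ Normal(0, v_sigma²).

    shells: list of (target radius Å, radial jitter Å, occupancy fraction);
    molecules are placed on coaxial sheets with per-frame Gaussian radial
    jitter and a static azimuth.
    """

    n_molecules: int
    n_frames: int
    dt: float = 1.0
    mode: str = "fickian"
    D: float | None = None            # Å²/ps (fickian, single_file)
    v_sigma: float | None = None      # Å/ps (ballistic)
    shells: tuple = ((4.0, 0.3, 1.0),)
    tube: TubeGeometry | None = None
    line_density: float | None = None  # molecules/Å (single_file)
    z_extent: float = 100.0           # initial axial spread (fickian/ballistic)
    seed: int = 0
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if self.mode not in ("fickian", "single_file", "ballistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("fickian", "single_file"):
            if self.D is None or not self.D > 0:
                raise ValueError("fickian/single_file require D > 0")
        if self.mode == "ballistic":
            if self.v_sigma is None or not self.v_sigma > 0:
                raise ValueError("ballistic requires v_sigma > 0")
        if self.mode == "single_file" and self.line_density is None:
            raise ValueError("single_file requires line_density")
        occ = sum(s[2] for s in self.shells)
        if abs(occ - 1.0) > 1e-9:
            raise ValueError("shell occupancy fractions must sum to 1")
        if not (self.n_molecules > 0 and self.n_frames > 1 and self.dt > 0):
            raise ValueError("invalid size parameters")


def _single_file_tracks(n: int, n_frames: int, dt: float, D: float,
                        density: float, rng) -> np.ndarray:
    """Non-crossing Brownian motion on a periodic line, exactly in law.

    Independent walkers are simulated unwrapped; the k-th single-file
    particle is the k-th order statistic of the wrapped positions, with a
    cyclic label shift equal to the net number of boundary crossings and an
    explicit winding term.  This reproduces hard-core (identity-exchange)
    dynamics without collision handling and is fully vectorised.
    """
    L = n / density
    y0 = np.sort(rng.uniform(0.0, L, size=n))
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt),
                       size=(n_frames - 1, n))
    y = np.empty((n_frames, n))
    y[0] = y0
    np.cumsum(steps, axis=0, out=y[1:])
    y[1:] += y0
    wind = np.floor(y / L)
    shift = (wind.sum(axis=1) - wind[0].sum()).astype(np.int64)  # net crossings
    v = np.sort(y - wind * L, axis=1)
    idx = np.arange(n)[None, :] + shift[:, None]
    z = np.take_along_axis(v, idx % n, axis=1) + L * (idx // n)
    return z


def gen_axial_tracks(spec: AxialSimSpec):
    """Ground-truth axial tracks z (n_frames, n_molecules) plus record."""
    rng = np.random.default_rng(spec.seed)
    n, f, dt = spec.n_molecules, spec.n_frames, spec.dt
    if spec.mode == "fickian":
        z0 = rng.uniform(0.0, spec.z_extent, size=n)
        steps = rng.normal(0.0, math.sqrt(2.0 * spec.D * dt), size=(f - 1, n))
        z = np.empty((f, n))
        z[0] = z0
        np.cumsum(steps, axis=0, out=z[1:])
        z[1:] += z0
        alpha = 1.0
    elif spec.mode == "ballistic":
        z0 = rng.uniform(0.0, spec.z_extent, size=n)
        vel = rng.normal(0.0, spec.v_sigma, size=n)
        z = z0[None, :] + vel[None, :] * (np.arange(f)[:, None] * dt)
        alpha = 2.0
    else:
        z = _single_file_tracks(n, f, dt, spec.D, spec.line_density, rng)
        alpha = 0.5
    truth = {
        "mode": spec.mode,
        "alpha": alpha,
        "D": spec.D,
        "v_sigma": spec.v_sigma,
        "line_density": spec.line_density,
        "dt": dt,
        "seed": spec.seed,
    }
    return z, truth, rng


def single_file_msd(t, D: float, density: float) -> np.ndarray:
    """Long-time tagged-particle MSD on a line: (2/ρ)·√(D t / π)."""
    return (2.0 / density) * np.sqrt(D * np.asarray(t, dtype=float) / math.pi)


def gen_axial(spec: AxialSimSpec):
    """Full synthetic trajectory (O + two dummy H per molecule) + truth.

    The radial coordinate is a shell radius plus per-frame Gaussian jitter;
    the azimuth is static per molecule.  Dummy hydrogens sit at fixed +z
    offsets from each O so that water-system construction works; hydrogen
    bond analyses are not meaningful on this output.
    """
    z, truth, rng = gen_axial_tracks(spec)
    n, f = spec.n_molecules, spec.n_frames
    radii = np.array([s[0] for s in spec.shells])
    jitter = np.array([s[1] for s in spec.shells])
    occ = np.array([s[2] for s in spec.shells])
    shell_of = rng.choice(len(radii), size=n, p=occ / occ.sum())
    # azimuths follow a golden-angle sequence over the axial rank within
    # each shell: molecules that are close in z at frame 0 end up far apart
    # on the shell circle, so the O-H grouping of the start configuration
    # is always unambiguous
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = np.empty(n)
    for s in range(len(radii)):
        members = np.flatnonzero(shell_of == s)
        order = members[np.argsort(z[0, members])]
        theta[order] = (np.arange(order.size) * golden
                        + rng.uniform(0.0, 2.0 * math.pi)) % (2.0 * math.pi)
    r = np.clip(radii[shell_of][None, :]
                + jitter[shell_of][None, :] * rng.normal(size=(f, n)), 0.0, None)
    x = r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]

    pos = np.empty((f, 3 * n, 3), dtype=spec.dtype)
    o_slice = slice(0, 3 * n, 3)
    pos[:, o_slice, 0] = x
    pos[:, o_slice, 1] = y
    pos[:, o_slice, 2] = z
    for k, off in enumerate((0.30, 0.60)):  # dummy H along +z, close to O
        h_slice = slice(k + 1, 3 * n, 3)
        pos[:, h_slice, :] = pos[:, o_slice, :]
        pos[:, h_slice, 2] += off
    labels = np.array(["O", "H", "H"] * n, dtype=object)

    tube = spec.tube
    if tube is None:
        r_tube = float(r.max()) + 1.0
        z_lo = float(z.min()) - 1.0
        z_hi = float(z.max()) + OH_BOND + 1.0
        tube = TubeGeometry(axis_point=np.zeros(3), axis_dir=np.array([0.0, 0.0, 1.0]),
                            radius=r_tube, z_range=(z_lo, z_hi))
    truth.update({
        "shell_of_molecule": shell_of.tolist(),
        "shell_radii": radii.tolist(),
        "molecule_atoms": [(3 * k, 3 * k + 1, 3 * k + 2) for k in range(n)],
        "tube": {"axis_point": list(map(float, tube.axis_point)),
                 "axis_dir": list(map(float, tube.axis_dir)),
                 "radius": float(tube.radius),
                 "z_range": [float(tube.z_range[0]), float(tube.z_range[1])]},
        "resident_all_frames": True,
    })
    traj = Trajectory(pos, spec.dt, labels,
                      {"generator": "gen_axial", "mode": spec.mode,
                       "seed": spec.seed})
    return traj, tube, truth


# ---------------------------------------------------------------------------
# bond processes
# ---------------------------------------------------------------------------

@dataclass
class BondProcessSpec:
    """Two-population bond-survival process.

    Each pair starts bonded and breaks permanently with per-frame survival
    exp(-dt/τ_pop).  ``a1`` is, by default, the *amplitude* of the fast
    component in the intermittent autocorrelation measured with all time
    origins (the quantity a biexponential fit reports): an all-origin
    estimator weights each population by its expected bonded duration, so
    the population assignment probability is q1 ∝ a1·(1 - e^(-dt/τ1)).
    With weighting="population", ``a1`` is instead the plain population
    fraction.
    """

    n_pairs: int
    a1: float
    tau1: float
    tau2: float
    dt: float = 0.1
    n_frames: int = 600
    seed: int = 0
    weighting: str = "amplitude"

    def __post_init__(self) -> None:
        if not 0 <= self.a1 <= 1:
            raise ValueError("a1 must lie in [0, 1]")
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("tau1, tau2 must be positive")
        if self.weighting not in ("amplitude", "population"):
            raise ValueError("weighting must be 'amplitude' or 'population'")


def bond_process_acf(spec: BondProcessSpec, lags_frames) -> np.ndarray:
    """Exact expectation of the all-origin intermittent ACF estimator.

    With survival s_p = e^(-dt/τ_p) and n frames, at integer lag k:
        C(k) = Σ_p w_p s_p^k (1 - s_p^(n-k)) / Σ_p w_p (1 - s_p^(n-k)),
    where w_p = q_p / (1 - s_p) and q_p is the assignment probability.
    In the amplitude convention the edge factors cancel to machine
    precision and C(k) = a1 e^(-k dt/τ1) + (1 - a1) e^(-k dt/τ2).
    """
    k = np.asarray(lags_frames, dtype=float)
    s1, s2 = math.exp(-spec.dt / spec.tau1), math.exp(-spec.dt / spec.tau2)
    q1, q2 = _assignment_probability(spec)
    w1, w2 = q1 / (1.0 - s1), q2 / (1.0 - s2)
    n = spec.n_frames
    num = (w1 * s1 ** k * (1.0 - s1 ** (n - k))
           + w2 * s2 ** k * (1.0 - s2 ** (n - k)))
    den = w1 * (1.0 - s1 ** (n - k)) + w2 * (1.0 - s2 ** (n - k))
    return num / den


def _assignment_probability(spec: BondProcessSpec) -> tuple:
    if spec.weighting == "population":
        return spec.a1, 1.0 - spec.a1
    s1, s2 = math.exp(-spec.dt / spec.tau1), math.exp(-spec.dt / spec.tau2)
    u1 = spec.a1 * (1.0 - s1)
    u2 = (1.0 - spec.a1) * (1.0 - s2)
    return u1 / (u1 + u2), u2 / (u1 + u2)


def gen_bond_process(spec: BondProcessSpec):
    """Sampled bond-survival series + ground truth.

    The number of bonded frames per pair is geometric: P(alive at frame k)
    = s^k exactly, with s = e^(-dt/τ) of the pair's population.
    """
    rng = np.random.default_rng(spec.seed)
    q1, _ = _assignment_probability(spec)
    pop = rng.random(spec.n_pairs) < q1
    tau = np.where(pop, spec.tau1, spec.tau2)
    s = np.exp(-spec.dt / tau)
    u = rng.random(spec.n_pairs)
    alive_frames = np.floor(np.log(u) / np.log(s)).astype(np.int64) + 1
    alive_frames = np.clip(alive_frames, 1, None)
    matrix = np.arange(spec.n_frames)[None, :] < alive_frames[:, None]
    pairs = [(2 * k, 2 * k + 1) for k in range(spec.n_pairs)]
    series = HBondSeries(pairs=pairs, matrix=matrix, dt=spec.dt)
    tau_hb = spec.a1 * spec.tau1 + (1.0 - spec.a1) * spec.tau2
    truth = {
        "a1": spec.a1, "tau1": spec.tau1, "tau2": spec.tau2,
        "tau_hb": tau_hb, "q1": q1, "weighting": spec.weighting,
        "dt": spec.dt, "n_pairs": spec.n_pairs, "seed": spec.seed,
        "population": pop.tolist() if spec.n_pairs <= 10000 else None,
    }
    return series, truth


# ---------------------------------------------------------------------------
# single-frame water configurations
# ---------------------------------------------------------------------------

@dataclass
class WaterPlacement:
    """One water molecule: O position and two O→H unit orientations."""

    o: tuple
    h1_dir: tuple
    h2_dir: tuple


def gen_water_config(placements, bond_length: float = OH_BOND) -> Trajectory:
    """Single-frame trajectory from explicit molecule placements.

    Warns if any two atoms end up closer than 0.5 Å.
    """
    atoms = []
    labels = []
    for p in placements:
        o = np.asarray(p.o, dtype=float)
        for lab, vec in (("O", None), ("H", p.h1_dir), ("H", p.h2_dir)):
            if vec is None:
                atoms.append(o)
            else:
                d = np.asarray(vec, dtype=float)
                d = d / np.linalg.norm(d)
                atoms.append(o + bond_length * d)
            labels.append(lab)
    pos = np.asarray(atoms)[None, :, :]
    from scipy.spatial.distance import pdist
    if len(atoms) > 1 and pdist(pos[0]).min() < 0.5:
        warnings.warn("overlapping atoms (< 0.5 Å) in generated configuration")
    return Trajectory(pos, 1.0, np.asarray(labels, dtype=object),
                      {"generator": "gen_water_config"})


def hbond_dimer(r_oo: float, donor_angle_deg: float = 0.0) -> list:
    """Two-molecule placement: donor at origin, acceptor at distance r_oo
    along +x, donor O-H rotated by the given angle from the O···O axis."""
    ang = math.radians(donor_angle_deg)
    return [
        WaterPlacement(o=(0.0, 0.0, 0.0),
                       h1_dir=(math.cos(ang), math.sin(ang), 0.0),
                       h2_dir=(-0.3, 0.0, 0.95)),
        WaterPlacement(o=(r_oo, 0.0, 0.0),
                       h1_dir=(0.55, 0.0, 0.84),
                       h2_dir=(0.55, 0.0, -0.84)),
    ]


# ---------------------------------------------------------------------------
# D(T) series
# ---------------------------------------------------------------------------

@dataclass
class CrossoverParams:
    """High-temperature Vogel-Fulcher branch: D = A·exp(-B/(T - T_vf)) for
    T > T0, with A fixed by continuity at T0."""

    T0: float
    B: float = 330.0
    T_vf: float = 150.0


@dataclass
class ArrheniusSpec:
    """D(T) series: Arrhenius D = D0·exp(-ΔU/kB·T), optionally switching to
    a continuous Vogel-Fulcher branch above a crossover temperature T0.

    D0 in 1e-5 cm²/s, dU in kJ/mol, temperatures in K; noise_sigma is the
    relative (lognormal) scatter.
    """

    D0: float
    dU: float
    T_list: tuple
    crossover: CrossoverParams | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.T_list = tuple(float(t) for t in self.T_list)
        if any(t <= 0 for t in self.T_list):
            raise ValueError("all temperatures must be positive")
        if self.crossover is not None:
            if not (min(self.T_list) < self.crossover.T0 < max(self.T_list)):
                raise ValueError("crossover T0 must lie inside T_list range")


def arrhenius_d(T, D0: float, dU: float) -> np.ndarray:
    return D0 * np.exp(-dU / (KB * np.asarray(T, dtype=float)))


def gen_arrhenius_series(spec: ArrheniusSpec):
    """(TemperatureSeries, truth).  ln D is exactly linear in 1/T below T0
    (or everywhere without crossover); the branches join continuously."""
    from .thermal import TemperatureSeries
    T = np.array(sorted(spec.T_list))
    D = arrhenius_d(T, spec.D0, spec.dU)
    if spec.crossover is not None:
        co = spec.crossover
        d_at_t0 = float(arrhenius_d(co.T0, spec.D0, spec.dU))
        A = d_at_t0 * math.exp(co.B / (co.T0 - co.T_vf))
        hi = T > co.T0
        D[hi] = A * np.exp(-co.B / (T[hi] - co.T_vf))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        D = D * np.exp(spec.noise_sigma * rng.normal(size=T.size))
    truth = {"D0": spec.D0, "dU": spec.dU, "kB": KB,
             "T0": None if spec.crossover is None else spec.crossover.T0,
             "noise_sigma": spec.noise_sigma, "seed": spec.seed}
    return TemperatureSeries(T=T, D=D), truth


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def write_ground_truth(truth: dict, path) -> None:
    """JSON ground-truth sidecar next to generated data files."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj
    with open(path, "w") as fh:
        json.dump(_clean(truth), fh, indent=1, sort_keys=True)
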