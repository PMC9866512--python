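"""Shared fixtures: small synthetic systems and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cntwater.trajectory import Trajectory, TubeGeometry, WaterSystem


def make_uniform_cylinder(n_molecules=100, n_frames=50, radius=10.0,
                          length=40.0, seed=0):
    """Molecules uniformly filling a cylinder, fresh positions each frame.

    The WaterSystem is constructed directly from the known atom layout
    (O, H, H per molecule) so dense random packings cannot make the
    geometric grouping ambiguous.
    """
    rng = np.random.default_rng(seed)
    pos = np.empty((n_frames, 3 * n_molecules, 3))
    for f in range(n_frames):
        r = radius * np.sqrt(rng.random(n_molecules))
        th = rng.uniform(0, 2 * math.pi, n_molecules)
        z = rng.uniform(0, length, n_molecules)
        o = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        pos[f, 0::3] = o
        pos[f, 1::3] = o + [0, 0, 0.3]
        pos[f, 2::3] = o + [0, 0, 0.6]
    traj = Trajectory(pos, 1.0, np.array(["O", "H", "H"] * n_molecules,
                                         dtype=object))
    ws = WaterSystem(molecules=[(3 * k, 3 * k + 1, 3 * k + 2)
                                for k in range(n_molecules)])
    tube = TubeGeometry((0, 0, 0), (0, 0, 1), radius=radius,
                        z_range=(0, length))
    return traj, ws, tube


def brute_force_hbonds(positions, ws, criteria):
    """Scalar O(N²) oracle for geometric hydrogen-bond detection."""
    out = set()
    cos_max = math.cos(math.radians(criteria.angle_max))
    for i, (oi, h1i, h2i) in enumerate(ws.molecules):
        for j, (oj, _h1j, _h2j) in enumerate(ws.molecules):
            if i == j:
                continue
            oo = positions[oj] - positions[oi]
            roo = math.sqrt(float(oo @ oo))
            if roo > criteria.r_max:
                continue
            for h in (h1i, h2i):
                oh = positions[h] - positions[oi]
                cosang = float(oh @ oo) / (math.sqrt(float(oh @ oh)) * roo)
                if cosang >= cos_max - 1e-12:
                    out.add((i, j))
                    break
    return out


def random_water_box(n_molecules, rng, box=16.0, min_sep=2.2):
    """Random molecule placements with a minimum O-O separation."""
    from cntwater.synthetic import WaterPlacement

    accepted = []
    while len(accepted) < n_molecules:
        cand = rng.uniform(-box / 2, box / 2, 3)
        if all(np.linalg.norm(cand - a) >= min_sep for a in accepted):
            accepted.append(cand)
    placements = []
    for o in accepted:
        d1 = rng.normal(size=3)
        d2 = rng.normal(size=3)
        placements.append(WaterPlacement(o=tuple(o), h1_dir=tuple(d1),
                                         h2_dir=tuple(d2)))
    return placements


@pytest.fixture
def uniform_cylinder():
    return make_uniform_cylinder()
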