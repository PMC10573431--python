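"""Vector geometry on active-site structures.

The central construction is the manual docking of the fluoride probe: the
ion is placed on the line defined by the P=O (phosphoryl) bond, on the
opposite side of the phosphorus from the phosphoryl oxygen, at a fixed
distance from P (2 Å by default).  Anti placement is the orientation that
puts the ion in the gorge, in line for backside nucleophilic attack on the
tetrahedral phosphorus.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .structures import AtomRecord

#: Default probe-placement distance from the phosphorus atom, Å.
PLACEMENT_DISTANCE = 2.0

#: Default nucleophilic-attack feasibility cutoff, Å.
ATTACK_CUTOFF = 4.0


def distance(a, b) -> float:
    """Euclidean distance between two 3-vectors, Å."""
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def angle(a, b, c) -> float:
    """Angle a–b–c in degrees (vertex at b)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("angle undefined: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def place_fluoride(p_coord, phosphoryl_o_coord, dist: float = PLACEMENT_DISTANCE) -> np.ndarray:
    """Coordinates for a fluoride probe collinear with the P=O bond.

    The returned point F satisfies |F − P| = ``dist`` with F, P and O
    collinear and F anti to the phosphoryl oxygen (beyond P on the O→P
    ray).

    Parameters
    ----------
    p_coord, phosphoryl_o_coord
        Cartesian coordinates (Å) of the phosphorus and phosphoryl oxygen.
    dist
        Distance from P at which to place the probe, Å.
    """
    p = np.asarray(p_coord, dtype=float)
    o = np.asarray(phosphoryl_o_coord, dtype=float)
    bond = p - o
    norm = np.linalg.norm(bond)
    if norm < 1e-9:
        raise GeometryError("P and phosphoryl O coincide; P=O direction undefined")
    if dist <= 0:
        raise GeometryError("placement distance must be positive")
    return p + bond / norm * dist


def is_attack_feasible(dist: float, cutoff: float = ATTACK_CUTOFF) -> bool:
    """Whether a nucleophile–electrophile distance permits attack.

    A pose is productive when the distance between the functionally
    significant atoms does not exceed the cutoff (boundary inclusive).
    """
    if dist < 0:
        raise ValueError("distance must be non-negative")
    return dist <= cutoff


def detect_hbond(
    donor: AtomRecord,
    hydrogen: AtomRecord,
    acceptor: AtomRecord,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> bool:
    """Geometric hydrogen-bond test on a donor–H···acceptor triple.

    True iff the donor–acceptor distance is ≤ ``d_cut`` and the
    donor–H–acceptor angle is ≥ ``angle_cut`` (degrees).  The caller is
    responsible for supplying a hydrogen covalently bonded to the donor.
    """
    d_da = distance(donor.coords, acceptor.coords)
    theta = angle(donor.coords, hydrogen.coords, acceptor.coords)
    return d_da <= d_cut and theta >= angle_cut
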