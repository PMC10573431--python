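"""Synthetic ground-truth inputs for every pipeline stage.

Real inputs to this analysis come from MD engines, docking programs and
semiempirical QM codes.  The generators here produce structurally faithful
stand-ins with *known* ground truth, so that geometry, trajectory and
scoring operations are testable without any of those toolchains:

* :func:`make_active_site` — a toy phosphylated-serine active-site
  fragment: tetrahedral P centre bonded to the serine Oγ (1.69 Å, a
  typical P–Oγ bond length in these adducts) and a phosphoryl oxygen
  (1.48 Å), a protonated histidine, a fluoride ion at a planted distance,
  and water molecules planted inside/outside the hydration shell.
* :func:`make_trajectory` — a tethered-ion trajectory: the ion fluctuates
  around a target P–ion distance (mean-reverting AR(1) radius with
  angular jitter) until a programmed escape time, then drifts away.  This
  reproduces the phenomenology of a fluoride ion that remains in the
  productive position for a known residence time and then leaves; it is a
  statistical emulation, not a physics claim.
* :func:`make_adduct_records` — charge/distance records with the
  statistical structure of the published AM1 tables (uniform draws inside
  the printed ranges).

Every generator is a pure function of its parameters and a mandatory seed;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scoring import ADDUCT_COLUMNS, AdductRecord
from .structures import AtomRecord, Structure

#: Typical P–Oγ bond length planted in the fragment, Å.
P_OG_BOND = 1.69
#: Phosphoryl P=O bond length, Å.
P_O_PHOSPHORYL = 1.48

_TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class TetherParams:
    """Parameters of the tethered/escaping ion process.

    ``tether_mean``/``tether_sd`` (Å) set the stationary distribution of
    the P–ion distance before escape; at ``escape_time`` (ps) the radial
    mean starts growing at ``post_escape_drift`` (Å/ps), capped at
    ``max_radius``.  Frames are ``frame_dt`` ps apart, ``n_frames`` total.
    """

    seed: int
    tether_mean: float = 3.2
    tether_sd: float = 0.15
    escape_time: float = 1300.0
    post_escape_drift: float = 0.1
    frame_dt: float = 10.0
    n_frames: int = 1000
    max_radius: float = 70.0
    ar_phi: float = 0.8  # AR(1) autocorrelation of the radial fluctuation

    def __post_init__(self) -> None:
        if self.tether_mean <= 0:
            raise ValueError("tether_mean must be > 0")
        if self.tether_sd < 0:
            raise ValueError("tether_sd must be >= 0")
        if self.frame_dt <= 0 or self.n_frames < 2:
            raise ValueError("need frame_dt > 0 and at least 2 frames")
        span = self.frame_dt * (self.n_frames - 1)
        if not 0 < self.escape_time <= span:
            raise ValueError(
                f"escape_time must lie within the simulated span (0, {span}] ps"
            )
        if not 0 <= self.ar_phi < 1:
            raise ValueError("ar_phi must lie in [0, 1)")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_active_site(
    n_waters_near: int,
    n_waters_far: int,
    plant_hbond: bool,
    seed: int,
    ion_distance: float = 3.0,
) -> Structure:
    """Build a toy active-site fragment with planted geometry.

    The fragment contains a tetrahedral phosphorus (residue ``ADT``) bonded
    to the serine Oγ at exactly 1.69 Å and a phosphoryl oxygen at 1.48 Å,
    two carbon substituents, a doubly protonated histidine whose Nε–H
    points at the ion, a fluoride ion anti to the P=O bond at
    ``ion_distance`` from P, ``n_waters_near`` water oxygens inside 3.5 Å
    of the ion and ``n_waters_far`` water oxygens beyond 5 Å.  With
    ``plant_hbond`` an extra water donates an ideal hydrogen bond to the
    serine Oγ (O···O 2.8 Å, linear O–H···O).  Deterministic per seed.
    """
    if n_waters_near < 0 or n_waters_far < 0:
        raise ValueError("water counts must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.zeros(3)
    og = p + P_OG_BOND * _TETRAHEDRAL[0]
    o1p = p + P_O_PHOSPHORYL * _TETRAHEDRAL[1]
    c1 = p + 1.80 * _TETRAHEDRAL[2]
    c2 = p + 1.80 * _TETRAHEDRAL[3]
    # ion anti to the phosphoryl oxygen, in line for backside attack
    ion = p + ion_distance * (p - o1p) / np.linalg.norm(p - o1p)

    atoms = [
        AtomRecord(1, "OG", "O", "SER", 198, "A", og),
        AtomRecord(2, "P", "P", "ADT", 900, "A", p),
        AtomRecord(3, "O1P", "O", "ADT", 900, "A", o1p),
        AtomRecord(4, "C1", "C", "ADT", 900, "A", c1),
        AtomRecord(5, "C2", "C", "ADT", 900, "A", c2),
    ]
    # protonated His Nε–H directed at the ion (the ion's stabiliser)
    ne2 = ion + 3.0 * _random_unit(rng)
    he2 = ne2 + 1.0 * (ion - ne2) / np.linalg.norm(ion - ne2)
    atoms.append(AtomRecord(6, "NE2", "N", "HIS", 438, "A", ne2))
    atoms.append(AtomRecord(7, "HE2", "H", "HIS", 438, "A", he2))
    atoms.append(AtomRecord(8, "F", "F", "F", 901, "A", ion))

    serial = 9
    res = 1000
    for _ in range(n_waters_near):
        coord = ion + rng.uniform(2.5, 3.2) * _random_unit(rng)
        atoms.append(AtomRecord(serial, "O", "O", "HOH", res, "W", coord))
        serial += 1
        res += 1
    for _ in range(n_waters_far):
        coord = ion + rng.uniform(5.5, 8.0) * _random_unit(rng)
        atoms.append(AtomRecord(serial, "O", "O", "HOH", res, "W", coord))
        serial += 1
        res += 1
    if plant_hbond:
        # water donating a linear H-bond to the serine Oγ
        direction = _random_unit(rng)
        w_o = og + 2.8 * direction
        w_h = og + (2.8 - 0.96) * direction
        atoms.append(AtomRecord(serial, "O", "O", "HOH", res, "W", w_o))
        atoms.append(AtomRecord(serial + 1, "H1", "H", "HOH", res, "W", w_h))
    return Structure(atoms=atoms, title=f"synthetic active site (seed {seed})")


def make_trajectory(params: TetherParams, reference: Structure):
    """Tethered/escaping ion trajectory around a reference fragment.

    Only the ion (atom named ``F``) moves; every other atom is static.
    The P–ion distance follows a mean-reverting AR(1) process around
    ``tether_mean`` (stationary s.d. ``tether_sd``) while the radial
    direction jitters isotropically; for times beyond ``escape_time`` the
    radial mean additionally grows at ``post_escape_drift`` Å/ps, so the
    measured residence time equals the planted escape time to within one
    frame spacing.  Bit-reproducible per seed.
    """
    from .trajectory import Trajectory

    rng = np.random.default_rng(params.seed)
    ion_idx = reference.index_of(901, "F")
    p_idx = reference.index_of(900, "P")
    p_coord = reference.atoms[p_idx].coords
    base = reference.coords_array()

    times = params.frame_dt * np.arange(params.n_frames)
    phi = params.ar_phi
    innovation_sd = params.tether_sd * np.sqrt(1.0 - phi**2)
    # stationary start so the pre-escape mean is tether_mean from frame 0
    fluct = rng.normal(0.0, params.tether_sd) if params.tether_sd > 0 else 0.0

    u = reference.atoms[ion_idx].coords - p_coord
    u = (
        u / np.linalg.norm(u)
        if np.linalg.norm(u) > 0
        else _random_unit(rng)
    )

    coords = np.repeat(base[None, :, :], params.n_frames, axis=0)
    for i, t in enumerate(times):
        if i > 0:
            noise = rng.normal(0.0, innovation_sd) if params.tether_sd > 0 else 0.0
            fluct = phi * fluct + noise
            u = u + 0.05 * rng.normal(size=3)
            u = u / np.linalg.norm(u)
        drift = max(0.0, t - params.escape_time) * params.post_escape_drift
        radius = min(params.tether_mean + drift, params.max_radius) + fluct
        radius = max(radius, 0.1)
        coords[i, ion_idx] = p_coord + radius * u
    return Trajectory(reference=reference, times=times, coords=coords)


def make_adduct_records(n: int, seed: int) -> list[AdductRecord]:
    """Charge/distance records drawn inside the published AM1 ranges.

    q_P ~ U(2.2, 2.4) e, q_O ~ U(−0.65, −0.54) e, q_F ~ U(−0.76, −0.70) e,
    distP–Oγ ~ U(1.68, 1.70) Å, distP–F ~ U(2.7, 4.0) Å.  Reproducible per
    seed; record ids are SYN1..SYNn.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        records.append(
            AdductRecord(
                adduct_id=f"SYN{i + 1}",
                protein="BChE",
                site_label="Ser198",
                r1="C2H5",
                r2="CH3",
                q_P=rng.uniform(2.2, 2.4),
                q_O=rng.uniform(-0.65, -0.54),
                q_F=rng.uniform(-0.76, -0.70),
                dist_P_O=rng.uniform(1.68, 1.70),
                dist_P_F=rng.uniform(2.7, 4.0),
            )
        )
    return records


def adduct_records_to_csv(records: list[AdductRecord], path: str | Path) -> None:
    """Write records as a CSV with the standard adduct column set."""
    import pandas as pd

    rows = [
        {
            "adduct_id": r.adduct_id,
            "protein": r.protein,
            "site": r.site_label,
            "r1": r.r1,
            "r2": r.r2,
            "stereo": r.stereo or "",
            "q_P": r.q_P,
            "q_O": r.q_O,
            "q_F": r.q_F,
            "dist_P_O": r.dist_P_O,
            "dist_P_F": r.dist_P_F,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ADDUCT_COLUMNS).to_csv(path, index=False)
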