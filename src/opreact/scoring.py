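"""Reactivation scoring: screened Coulomb energies and adduct ranking.

Fluoride reactivation of a phosphylated serine/tyrosine proceeds by
nucleophilic attack of F⁻ on the tetrahedral phosphorus, breaking the
P–Oγ(η) bond and forming P–F.  Two desk-scale criteria rank how hard that
is for a given adduct:

* **MM criterion** — the mean P–F distance ⟨distP–F⟩ over a stable MD
  interval; shorter means easier reactivation.
* **Semiempirical criterion** — the electrostatic barrier proxy
  ΔE_el = E_el(P–F) − E_el(P–Oγ), where each pair energy is a screened
  Coulomb term k·q₁·q₂/(ε·r) computed from semiempirical (AM1) partial
  charges and the P–Oγ / P–F distances of the productive complex.  Lower
  ΔE_el means the P–F attraction comes closer to compensating the P–Oγ
  attraction that must be overcome, i.e. easier reactivation.

The effective dielectric defaults to ε = 4, a screening constant
calibrated so that the screened Coulomb term reproduces published
reference energies for the eleven BChE adducts; it is overridable
everywhere it appears.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ClassificationError
from .geometry import ATTACK_CUTOFF
from .structures import PoseRecord

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻² (chemistry convention).
K_COULOMB = 332.0637

#: Calibrated effective (relative) dielectric for active-site screening.
DEFAULT_EPSILON = 4.0

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.98720425e-3

#: Reference temperature for ΔG → K_d conversion ("room temperature"), K.
DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class AdductRecord:
    """One covalent organophosphate adduct and its charge/distance tuple.

    Charges (elementary units) are for the phosphorus (``q_P``), the
    attacked serine Oγ / tyrosine Oη (``q_O``) and the fluoride probe
    (``q_F``) in the productive complex; distances are the P–O bond length
    and the P–F separation in Å.  Physically meaningful records have a
    positive phosphorus charge and negative O/F charges — validation can
    be disabled with ``validate=False`` for exploratory inputs.
    """

    adduct_id: str
    protein: str = "BChE"  # {"BChE", "HSA"}
    site_label: str = "Ser198"
    r1: str = ""
    r2: str = ""
    stereo: str | None = None  # {"R", "S", None}
    q_P: float = float("nan")
    q_O: float = float("nan")
    q_F: float = float("nan")
    dist_P_O: float = float("nan")
    dist_P_F: float = float("nan")
    validate: bool = True

    def __post_init__(self) -> None:
        if self.protein not in {"BChE", "HSA"}:
            raise ValueError(f"{self.adduct_id}: protein must be BChE or HSA")
        if self.stereo not in {None, "", "R", "S"}:
            raise ValueError(f"{self.adduct_id}: stereo must be R, S or absent")
        if not self.validate:
            return
        checks = [
            (self.q_P > 0, "q_P must be > 0"),
            (self.q_O < 0, "q_O must be < 0"),
            (self.q_F < 0, "q_F must be < 0"),
            (1.0 < self.dist_P_O < 2.5, "dist_P_O must lie in (1.0, 2.5) Å"),
            (self.dist_P_F > 0, "dist_P_F must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"{self.adduct_id}: {msg}")


@dataclass(frozen=True)
class ScoreResult:
    """Screened Coulomb pair energies and their difference, kcal/mol."""

    adduct_id: str
    e_el_P_O: float
    e_el_P_F: float

    @property
    def delta_e_el(self) -> float:
        return self.e_el_P_F - self.e_el_P_O


class AdductGroup(enum.Enum):
    """Structural grouping of the BChE adducts by substituent shape."""

    GROUP_I = "group_I"  # massive R2 carrying an electronegative atom (N/O)
    GROUP_II = "group_II"  # branched R1 of the form CH(X)–X′
    GROUP_III = "group_III"  # R1 of the form O–CH2–Y with R2 = CH3
    TRANSITIONAL = "transitional"  # R2 = C2H5, between groups I and III
    SPECIAL = "special"  # aromatic R1/R2 (CBDP adduct), outside the scheme


class RankingCriterion(enum.Enum):
    MM_DISTANCE = "mm_distance"  # ⟨distP–F⟩, Å, ascending = easiest first
    AM1_DELTA_E = "am1_delta_e"  # ΔE_el, kcal/mol, ascending = easiest first


@dataclass(frozen=True)
class RankingTable:
    """Adducts ordered by increasing complexity of reactivation."""

    criterion: RankingCriterion
    entries: tuple[tuple[str, float], ...]  # (adduct_id, key value)

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(adduct_id for adduct_id, _ in self.entries)


# ---------------------------------------------------------------------------
# Energies and thermodynamics
# ---------------------------------------------------------------------------


def coulomb_energy(q1: float, q2: float, r: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Screened Coulomb interaction energy k·q1·q2/(ε·r), kcal/mol.

    ``q1``, ``q2`` in elementary charges, ``r`` in Å, ``epsilon``
    dimensionless relative dielectric.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return K_COULOMB * q1 * q2 / (epsilon * r)


def delta_e_el(record: AdductRecord, epsilon: float = DEFAULT_EPSILON) -> ScoreResult:
    """Electrostatic barrier score for one adduct.

    Computes E_el(P–Oγ) and E_el(P–F) by screened Coulomb and returns
    their difference ΔE_el = E_el(P–F) − E_el(P–Oγ): both pair energies
    are attractive (negative), and since the bound Oγ sits closer to P
    than the probe ion, ΔE_el is positive — the residual attraction that
    must be overcome to swap the partners.
    """
    for name in ("q_P", "q_O", "q_F", "dist_P_O", "dist_P_F"):
        if math.isnan(getattr(record, name)):
            raise ValueError(f"{record.adduct_id}: missing field {name}")
    return ScoreResult(
        adduct_id=record.adduct_id,
        e_el_P_O=coulomb_energy(record.q_P, record.q_O, record.dist_P_O, epsilon),
        e_el_P_F=coulomb_energy(record.q_P, record.q_F, record.dist_P_F, epsilon),
    )


def kd_from_dg(delta_g: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (mol/L) from binding free energy (kcal/mol).

    K_d = exp(ΔG/(R·T)) against the 1 M standard state; ΔG ≈ −7 kcal/mol
    at room temperature corresponds to K_d of about 7 μM.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.exp(delta_g / (R_KCAL * temperature))


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`kd_from_dg` (kcal/mol from mol/L)."""
    if kd <= 0:
        raise ValueError("K_d must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return R_KCAL * temperature * math.log(kd)


# ---------------------------------------------------------------------------
# Structural classification
# ---------------------------------------------------------------------------

#: Controlled substituent vocabulary.  ``C*H(...)`` marks a stereocentre
#: at the first carbon; the R/S label lives in AdductRecord.stereo.
R1_VOCABULARY = frozenset(
    {
        "C2H5",
        "CH(CH3)2",
        "CH2-CH(CH3)2",
        "nC4H9",
        "cC6H11",
        "C*H(CH3)-C(CH3)3",
        "C6H4-CH3",
    }
)
R2_VOCABULARY = frozenset({"N-(CH3)2", "O-C2H5", "C2H5", "CH3", "O-CH2-C6H4-OH"})

_AROMATIC_R1 = frozenset({"C6H4-CH3"})
_ELECTRONEGATIVE_R2 = frozenset({"N-(CH3)2", "O-C2H5"})
_BRANCHED_R1 = frozenset({"CH(CH3)2", "cC6H11", "C*H(CH3)-C(CH3)3"})


def classify_adduct(r1: str, r2: str) -> AdductGroup:
    """Assign an adduct to a structural group from its substituents.

    Group I: massive R2 with an electronegative atom (N or O).  Group II:
    R1 branched at the first carbon, general formula CH(X)–X′ (isopropyl,
    cyclohexyl, pinacolyl).  Group III: less branched R1 of the form
    O–CH2–Y with R2 = CH3.  R2 = C2H5 is transitional between groups I
    and III; an aromatic R1 (the CBDP adduct) fits none of these and is
    classed as special.
    """
    r1, r2 = r1.strip(), r2.strip()
    if r1 not in R1_VOCABULARY:
        raise ClassificationError(f"unknown R1 substituent: {r1!r}")
    if r2 not in R2_VOCABULARY:
        raise ClassificationError(f"unknown R2 substituent: {r2!r}")
    if r1 in _AROMATIC_R1:
        return AdductGroup.SPECIAL
    if r2 in _ELECTRONEGATIVE_R2:
        return AdductGroup.GROUP_I
    if r2 == "C2H5":
        return AdductGroup.TRANSITIONAL
    # remaining vocabulary: r2 == "CH3"
    if r1 in _BRANCHED_R1:
        return AdductGroup.GROUP_II
    return AdductGroup.GROUP_III


# ---------------------------------------------------------------------------
# Ranking and pose filtering
# ---------------------------------------------------------------------------


def rank_adducts(
    records: Sequence[AdductRecord],
    criterion: RankingCriterion,
    scores: Sequence[float],
) -> RankingTable:
    """Order adducts by increasing complexity of reactivation.

    Stable ascending sort on the score (⟨distP–F⟩ or ΔE_el); ties are
    broken by adduct_id so the ordering is a pure function of the data.
    """
    if len(records) != len(scores):
        raise ValueError(
            f"got {len(records)} records but {len(scores)} scores"
        )
    pairs = sorted(
        ((rec.adduct_id, float(s)) for rec, s in zip(records, scores)),
        key=lambda p: (p[1], p[0]),
    )
    return RankingTable(criterion=criterion, entries=tuple(pairs))


def filter_productive_poses(
    poses: Iterable[PoseRecord], cutoff: float = ATTACK_CUTOFF
) -> list[PoseRecord]:
    """Keep poses whose functional-atom distance permits nucleophilic attack.

    Retains poses with a present distance ≤ cutoff (boundary inclusive);
    poses with an absent distance ("not found") are dropped.
    """
    return [
        p
        for p in poses
        if p.dist_functional is not None and p.dist_functional <= cutoff
    ]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

ADDUCT_COLUMNS = [
    "adduct_id",
    "protein",
    "site",
    "r1",
    "r2",
    "stereo",
    "q_P",
    "q_O",
    "q_F",
    "dist_P_O",
    "dist_P_F",
]


def read_adduct_table(path: str | Path, validate: bool = True) -> list[AdductRecord]:
    """Read adduct records from a CSV with the standard column set."""
    import pandas as pd

    from .errors import SchemaError

    table = pd.read_csv(path, dtype={"stereo": str}, keep_default_na=True)
    missing = set(ADDUCT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        stereo = row["stereo"]
        stereo = None if (not isinstance(stereo, str) or not stereo.strip()) else stereo.strip()
        records.append(
            AdductRecord(
                adduct_id=str(row["adduct_id"]),
                protein=str(row["protein"]),
                site_label=str(row["site"]),
                r1=str(row["r1"]),
                r2=str(row["r2"]),
                stereo=stereo,
                q_P=float(row["q_P"]),
                q_O=float(row["q_O"]),
                q_F=float(row["q_F"]),
                dist_P_O=float(row["dist_P_O"]),
                dist_P_F=float(row["dist_P_F"]),
                validate=validate,
            )
        )
    return records
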