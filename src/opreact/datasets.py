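"""Packaged reference tables.

Small published reference datasets for the fluoride-reactivation analysis
of organophosphate adducts on butyrylcholinesterase (BChE) and human serum
albumin (HSA):

* semiempirical (AM1) charges and P–Oγ / P–F distances of the productive
  fluoride complexes of the eleven BChE adducts, with the published
  screened-Coulomb energies as reference columns;
* mean P–F distances and fluoride hydration counts from MD simulations of
  the same adducts (the molecular-mechanics ranking input);
* the CBDP/HSA docking pose table (site, functional-atom distance, ΔG),
  including the two sites where no productive conformation was found;
* MD/AM1 summary scores for the paraoxon- and dimethylamido-type adducts
  on Tyr150 of HSA (underlying charges are not published, so these ship
  as values only and cannot be recomputed).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .scoring import AdductRecord, read_adduct_table
from .structures import PoseRecord, read_pose_table


def _data_path(name: str) -> Path:
    return Path(resources.files("opreact.data") / name)


def load_bche_am1_table() -> pd.DataFrame:
    """AM1 charge/distance table for the 11 BChE adducts.

    Columns ``e_el_P_O_ref``, ``e_el_P_F_ref`` and ``delta_e_el_ref`` hold
    the published screened-Coulomb energies (kcal/mol) for cross-checking
    recomputation; the remaining columns are the scoring inputs.
    """
    return pd.read_csv(_data_path("bche_am1_charges.csv"))


def load_bche_adducts() -> list[AdductRecord]:
    """The 11 BChE adducts as validated :class:`AdductRecord` objects."""
    return read_adduct_table(_data_path("bche_am1_charges.csv"))


def load_bche_mm_table() -> pd.DataFrame:
    """Mean P–F distances (Å) and fluoride hydration counts from MD."""
    return pd.read_csv(_data_path("bche_mm_distances.csv"))


def load_cbdp_docking_poses() -> list[PoseRecord]:
    """CBDP/HSA docking poses (13 sites, 2 without a productive pose)."""
    return read_pose_table(_data_path("hsa_cbdp_docking.csv"))


def load_hsa_tyr150_table() -> pd.DataFrame:
    """MD/AM1 summary scores for adducts on Tyr150 of HSA."""
    return pd.read_csv(_data_path("hsa_tyr150_scores.csv"))
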