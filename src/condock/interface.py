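"""Interface residue and contact identification.

A receptor/ligand residue pair is in contact when the minimum distance
over their heavy-atom pairs is at or below the cutoff (default 5 A,
the conventional interface criterion).  The production path prunes
candidate atom pairs with a k-d tree; tests pin exact agreement with a
brute-force all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structmodel import Pose, ResidueKey

DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class ContactRecord:
    receptor_residue: ResidueKey
    ligand_residue: ResidueKey
    min_distance: float


@dataclass
class InterfaceMap:
    contacts: list[ContactRecord]
    cutoff: float

    @property
    def interface_residues_receptor(self) -> set[ResidueKey]:
        return {c.receptor_residue for c in self.contacts}

    @property
    def interface_residues_ligand(self) -> set[ResidueKey]:
        return {c.ligand_residue for c in self.contacts}


def _residue_key_sort(key: ResidueKey) -> tuple:
    return (key[0], key[1], key[2])


def interface_map(pose: Pose, cutoff: float = DEFAULT_CUTOFF) -> InterfaceMap:
    """All residue-residue contacts of a pose at the heavy-atom cutoff."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    rec_coords = pose.receptor.heavy_coords()
    lig_coords = pose.ligand.heavy_coords()

    rec_res_of_atom = []
    for idx, res in enumerate(pose.receptor.residues):
        rec_res_of_atom.extend([idx] * len(res.heavy_atoms))
    lig_res_of_atom = []
    for idx, res in enumerate(pose.ligand.residues):
        lig_res_of_atom.extend([idx] * len(res.heavy_atoms))
    rec_res_of_atom = np.array(rec_res_of_atom)
    lig_res_of_atom = np.array(lig_res_of_atom)

    pairs = cKDTree(rec_coords).query_ball_tree(cKDTree(lig_coords), r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for ri, lig_atoms in enumerate(pairs):
        if not lig_atoms:
            continue
        d = np.linalg.norm(lig_coords[lig_atoms] - rec_coords[ri], axis=1)
        rres = rec_res_of_atom[ri]
        for li, dist in zip(lig_atoms, d):
            key = (int(rres), int(lig_res_of_atom[li]))
            if dist <= cutoff and dist < best.get(key, np.inf):
                best[key] = float(dist)

    contacts = [
        ContactRecord(pose.receptor.residues[ri].key,
                      pose.ligand.residues[li].key, dist)
        for (ri, li), dist in best.items()
    ]
    contacts.sort(key=lambda c: (_residue_key_sort(c.receptor_residue),
                                 _residue_key_sort(c.ligand_residue)))
    return InterfaceMap(contacts, cutoff)


def contact_table(imap: InterfaceMap) -> pd.DataFrame:
    """Tabular contact summary, one row per contact, distances to 2 dp."""
    rows = []
    for c in imap.contacts:
        rc, rs, ric, rn = c.receptor_residue
        lc, ls, lic, ln = c.ligand_residue
        rows.append({
            "receptor_chain": rc, "receptor_res_seq": rs, "receptor_i_code": ric,
            "receptor_res_name": rn,
            "ligand_chain": lc, "ligand_res_seq": ls, "ligand_i_code": lic,
            "ligand_res_name": ln,
            "min_distance": round(c.min_distance, 2),
        })
    columns = ["receptor_chain", "receptor_res_seq", "receptor_i_code",
               "receptor_res_name", "ligand_chain", "ligand_res_seq",
               "ligand_i_code", "ligand_res_name", "min_distance"]
    return pd.DataFrame(rows, columns=columns)


def residue_list(residues: Iterable[ResidueKey]) -> list[str]:
    """Flat ``chain:resSeq:resName`` text form of a residue set, sorted."""
    return [f"{c}:{s}{ic}:{n}"
            for c, s, ic, n in sorted(residues, key=_residue_key_sort)]
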