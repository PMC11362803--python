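"""Computational alanine scanning with a 12-6 contact potential.

Each interface residue is mutated to alanine by truncating its side
chain past CB (no repacking or minimisation), and the change in a
defined inter-chain interaction energy is reported as

    delta_affinity = E(mutant complex) - E(wild-type complex)

so a positive value means the mutant binds more weakly — the standard
alanine-scanning sign convention.  The energy is a pairwise
Lennard-Jones 12-6 contact potential over inter-chain heavy-atom pairs:

    E = sum_{r_ij <= cutoff} 4 eps0 [ (sigma_ij/r_ij)^12 - (sigma_ij/r_ij)^6 ],
    sigma_ij = (r_i + r_j) * 2^(-1/6)

with element van der Waals radii r_i, so each pair's minimum (-eps0)
sits exactly at contact distance r_i + r_j.  This is a shape/contact
score, not a free energy: it contains no electrostatics or solvation,
and rankings should be read accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import TopologyError, ValidationError
from .interface import interface_map
from .structmodel import Pose, ProteinStructure, Residue, ResidueKey

logger = logging.getLogger(__name__)

#: Heavy atoms retained after truncation to alanine.
ALA_KEEP = frozenset({"N", "CA", "C", "O", "CB", "OXT"})

SCAN_SIDES = ("receptor", "ligand", "both")


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the 12-6 contact potential."""

    epsilon0: float = 0.2
    vdw_radii: tuple[tuple[str, float], ...] = (
        ("C", 1.70), ("N", 1.55), ("O", 1.52), ("S", 1.80),
    )
    default_radius: float = 1.70
    pair_cutoff: float = 10.0

    def __post_init__(self) -> None:
        radii = dict(self.vdw_radii)
        if any(r <= 0 for r in radii.values()) or self.default_radius <= 0:
            raise ValidationError("van der Waals radii must be positive")
        max_r = max(list(radii.values()) + [self.default_radius])
        if self.pair_cutoff < 2 * max_r:
            raise ValidationError("pair_cutoff must exceed the largest contact distance")

    def radius_of(self, element: str) -> float:
        return dict(self.vdw_radii).get(element.upper(), self.default_radius)

    def radii_for(self, elements: Sequence[str]) -> np.ndarray:
        table = dict(self.vdw_radii)
        return np.array([table.get(e.upper(), self.default_radius) for e in elements])


@dataclass(frozen=True)
class MutantSpec:
    """A set of alanine substitutions, e.g. parsed from "A:595:ALA,A:610:ALA"."""

    substitutions: tuple[tuple[str, int, str], ...]   # (chain, res_seq, i_code)

    @classmethod
    def parse(cls, text: str) -> "MutantSpec":
        subs = []
        for token in text.split(","):
            parts = token.strip().split(":")
            if len(parts) != 3 or parts[2].upper() != "ALA":
                raise ValidationError(
                    f"bad substitution {token!r}; expected chain:resSeq:ALA"
                )
            seq = parts[1]
            i_code = ""
            if seq and seq[-1].isalpha():
                seq, i_code = seq[:-1], seq[-1]
            subs.append((parts[0], int(seq), i_code))
        return cls(tuple(subs))


def mutate_to_ala(structure: ProteinStructure, spec: MutantSpec) -> ProteinStructure:
    """Truncate the targeted residues' side chains past CB.

    Backbone and CB coordinates are untouched and res_name becomes ALA.
    GLY targets are a logged no-op (nothing to remove, name kept); PRO
    is truncated like any other residue, which ignores the backbone-ring
    coupling and is logged as geometrically approximate.
    """
    targets = set(spec.substitutions)
    found = {(r.chain_id, r.res_seq, r.i_code) for r in structure.residues} & targets
    missing = targets - found
    if missing:
        raise ValidationError(f"mutation target(s) not found: {sorted(missing)}")
    new_residues = []
    for res in structure.residues:
        if (res.chain_id, res.res_seq, res.i_code) not in targets:
            new_residues.append(res)
            continue
        if res.res_name == "GLY":
            logger.info("GLY %s:%d%s: alanine mutation is a no-op",
                        res.chain_id, res.res_seq, res.i_code)
            new_residues.append(res)
            continue
        if res.res_name == "PRO":
            logger.info("PRO %s:%d%s: truncation to CB is geometrically approximate",
                        res.chain_id, res.res_seq, res.i_code)
        kept = [a for a in res.atoms if a.name in ALA_KEEP or not a.is_heavy]
        new_residues.append(Residue(res.chain_id, res.res_seq, res.i_code, "ALA", kept))
    return ProteinStructure(structure.structure_id, new_residues, structure.frame_index)


def interaction_energy(pose: Pose, params: Optional[EnergyParams] = None) -> float:
    """Inter-chain 12-6 contact energy of a pose (lower = stronger binding)."""
    params = params or EnergyParams()
    rec = pose.receptor.heavy_coords()
    lig = pose.ligand.heavy_coords()
    r_rec = params.radii_for(pose.receptor.heavy_elements())
    r_lig = params.radii_for(pose.ligand.heavy_elements())
    d = cdist(rec, lig)
    n_overlap = int(np.sum(d < 0.5))
    if n_overlap:
        logger.warning("%d inter-chain atom pair(s) closer than 0.5 A", n_overlap)
    mask = d <= params.pair_cutoff
    if not np.any(mask):
        return 0.0
    sigma = (r_rec[:, None] + r_lig[None, :]) * 2.0 ** (-1.0 / 6.0)
    sr6 = (sigma[mask] / d[mask]) ** 6
    return float(np.sum(4.0 * params.epsilon0 * (sr6 ** 2 - sr6)))


@dataclass
class AlaScanRow:
    residue: ResidueKey
    res_name: str
    delta_affinity: float
    n_contacts: float
    flags: str = ""


@dataclass
class AlaScanResult:
    scanned_side: str
    wt_affinity: float
    rows: list[AlaScanRow]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            c, s, ic, _ = row.residue
            records.append({
                "chain": c, "res_seq": s, "i_code": ic, "res_name": row.res_name,
                "delta_affinity": row.delta_affinity, "n_contacts": row.n_contacts,
                "flags": row.flags,
            })
        columns = ["chain", "res_seq", "i_code", "res_name",
                   "delta_affinity", "n_contacts", "flags"]
        return pd.DataFrame(records, columns=columns)


def _mutant_pose(pose: Pose, residue: ResidueKey, side: str) -> tuple[Pose, str]:
    chain, seq, icode, res_name = residue
    flags = []
    if res_name == "PRO":
        flags.append("PRO_approx")
    spec = MutantSpec(((chain, seq, icode),))
    if side == "receptor":
        mutant = Pose(pose.pose_id, mutate_to_ala(pose.receptor, spec),
                      pose.ligand, pose.engine, pose.rank)
    else:
        mutant = Pose(pose.pose_id, pose.receptor,
                      mutate_to_ala(pose.ligand, spec), pose.engine, pose.rank)
    return mutant, ";".join(flags)


def _scan_targets(pose: Pose, side: str, cutoff: float) -> list[tuple[ResidueKey, str, int]]:
    """Interface residues to scan: (key, side-of-residue, n_contacts)."""
    imap = interface_map(pose, cutoff)
    targets: list[tuple[ResidueKey, str, int]] = []
    if side in ("receptor", "both"):
        counts: dict[ResidueKey, int] = {}
        for c in imap.contacts:
            counts[c.receptor_residue] = counts.get(c.receptor_residue, 0) + 1
        targets.extend((k, "receptor", n) for k, n in counts.items())
    if side in ("ligand", "both"):
        counts = {}
        for c in imap.contacts:
            counts[c.ligand_residue] = counts.get(c.ligand_residue, 0) + 1
        targets.extend((k, "ligand", n) for k, n in counts.items())
    return targets


def alanine_scan(pose: Pose, side: str = "both", cutoff: float = 5.0,
                 params: Optional[EnergyParams] = None) -> AlaScanResult:
    """Alanine-scan the interface residues of a pose.

    The scan set is exactly the residues with at least one heavy-atom
    contact within ``cutoff`` on the chosen side(s); residues outside
    the interface are never scanned even if their side chains fall
    within the energy cutoff.  Rows are sorted by descending
    delta_affinity (largest predicted binding loss first).
    """
    if side not in SCAN_SIDES:
        raise ValidationError(f"side must be one of {SCAN_SIDES}")
    params = params or EnergyParams()
    e_wt = interaction_energy(pose, params)
    targets = _scan_targets(pose, side, cutoff)
    if not targets:
        logger.warning("empty interface at cutoff %.2f A; nothing to scan", cutoff)
    rows = []
    for residue, res_side, n_contacts in targets:
        res_name = residue[3]
        if res_name in ("GLY", "ALA"):
            rows.append(AlaScanRow(residue, res_name, 0.0, n_contacts,
                                   "GLY_noop" if res_name == "GLY" else "ALA_noop"))
            continue
        mutant, flags = _mutant_pose(pose, residue, res_side)
        delta = interaction_energy(mutant, params) - e_wt
        rows.append(AlaScanRow(residue, res_name, delta, n_contacts, flags))
    rows.sort(key=lambda r: (-r.delta_affinity, r.residue))
    return AlaScanResult(side, e_wt, rows)


def ensemble_scan(frames: Sequence[Pose], side: str = "both", cutoff: float = 5.0,
                  params: Optional[EnergyParams] = None) -> AlaScanResult:
    """Snapshot-averaged alanine scan over trajectory frames.

    The scan set is the union of the per-frame interface residues; each
    residue's delta_affinity is the unweighted mean over all frames of
    its single-frame value, and n_contacts the mean per-frame contact
    count.  All frames must share one topology.
    """
    if not frames:
        raise ValidationError("ensemble scan needs at least one frame")
    if side not in SCAN_SIDES:
        raise ValidationError(f"side must be one of {SCAN_SIDES}")
    params = params or EnergyParams()
    first = frames[0]
    for f in frames[1:]:
        if (f.receptor.heavy_identity() != first.receptor.heavy_identity()
                or f.ligand.heavy_identity() != first.ligand.heavy_identity()):
            raise TopologyError(f"frame {f.pose_id!r}: topology drift")

    union: dict[tuple[ResidueKey, str], list[int]] = {}
    for f in frames:
        seen = {}
        for residue, res_side, n_contacts in _scan_targets(f, side, cutoff):
            seen[(residue, res_side)] = n_contacts
        for key, n_contacts in seen.items():
            union.setdefault(key, []).append(n_contacts)

    wt_mean = float(np.mean([interaction_energy(f, params) for f in frames]))
    rows = []
    for (residue, res_side), contact_counts in union.items():
        res_name = residue[3]
        mean_contacts = float(np.sum(contact_counts)) / len(frames)
        if res_name in ("GLY", "ALA"):
            rows.append(AlaScanRow(residue, res_name, 0.0, mean_contacts,
                                   "GLY_noop" if res_name == "GLY" else "ALA_noop"))
            continue
        deltas = []
        flags = ""
        for f in frames:
            mutant, flags = _mutant_pose(f, residue, res_side)
            deltas.append(interaction_energy(mutant, params)
                          - interaction_energy(f, params))
        rows.append(AlaScanRow(residue, res_name, float(np.mean(deltas)),
                               mean_contacts, flags))
    rows.sort(key=lambda r: (-r.delta_affinity, r.residue))
    return AlaScanResult(side, wt_mean, rows)
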