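"""Synthetic multi-engine docking ensembles with planted binding modes.

Real consensus docking pools ranked rigid-body poses from several
engines; the dense region of the pooled ensemble is taken as the
answer.  This generator emulates exactly that input shape: E engines
each contribute a ranked list of poses of one ligand protomer on one
receptor protomer, where each pose is drawn from one of M planted
binding modes (a rigid placement of the ligand) plus small rotational
and translational noise.  Because the mode of every pose is recorded,
every downstream stage — clustering, cluster-number selection, the
representative pose — can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .geometry import RigidTransform
from .structmodel import (
    Atom,
    EnsembleLayout,
    Pose,
    ProteinStructure,
    Residue,
    merge_structures,
    write_pdb,
)

#: Engine labels used by the default synthetic layout (seven, as in a
#: typical multi-engine consensus run).
DEFAULT_ENGINES = tuple(f"engine{i}" for i in range(1, 8))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic ensemble.

    Defaults mirror the consensus-docking setting the pipeline targets:
    7 engines keeping their top 10 poses, three binding modes of
    decreasing weight, ~1 A translational and 8 degree rotational
    within-mode noise, and modes separated by 12 A so they are
    resolvable by construction.
    """

    n_engines: int = 7
    poses_per_engine: int = 10
    n_modes: int = 3
    mode_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    rot_sigma: float = 8.0      # degrees
    trans_sigma: float = 1.0    # Angstroms
    mode_separation: float = 12.0  # Angstroms, minimum inter-mode centroid distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_engines < 1 or self.poses_per_engine < 1 or self.n_modes < 1:
            raise ValidationError("engine, pose and mode counts must all be >= 1")
        if len(self.mode_weights) != self.n_modes:
            raise ValidationError("mode_weights length must equal n_modes")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ValidationError("mode_weights must sum to 1")
        if any(w <= 0 for w in self.mode_weights):
            raise ValidationError("mode_weights must be positive")
        if self.n_modes > 1 and not self.mode_separation > 6.0 * self.trans_sigma:
            raise ValidationError(
                "mode_separation must exceed 6 * trans_sigma so modes are resolvable"
            )

    @property
    def n_poses(self) -> int:
        return self.n_engines * self.poses_per_engine

    @property
    def engines(self) -> tuple[str, ...]:
        return tuple(f"engine{i}" for i in range(1, self.n_engines + 1))


@dataclass
class SyntheticTruth:
    """Ground truth for a generated ensemble."""

    mode_of_pose: dict[str, int]
    mode_transforms: list[RigidTransform]

    def to_frame(self, poses: list[Pose]) -> pd.DataFrame:
        rows = [
            {"pose_id": p.pose_id, "engine": p.engine, "rank": p.rank,
             "mode": self.mode_of_pose[p.pose_id]}
            for p in poses
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy complex construction
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O", "CB")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

# Helix parameters: ~100 degrees twist and 1.5 A rise per residue on a
# 2.3 A radius, the coarse shape of an alpha helix.
_TWIST = math.radians(100.0)
_RISE = 1.5
_RADIUS = 2.3


def _helix_chain(n_res: int, chain_id: str, jitter: np.ndarray) -> ProteinStructure:
    """Polyalanine-like helix with full backbone + CB heavy atoms."""
    ca = np.array([
        [_RADIUS * math.cos(i * _TWIST), _RADIUS * math.sin(i * _TWIST), i * _RISE]
        for i in range(n_res)
    ])
    residues = []
    for i in range(n_res):
        # local frame: helix tangent, outward radial, binormal
        t = ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)]
        t = t / np.linalg.norm(t)
        radial = np.array([ca[i, 0], ca[i, 1], 0.0])
        radial = radial / np.linalg.norm(radial)
        b = np.cross(t, radial)
        b = b / np.linalg.norm(b)
        offsets = {
            "N": -0.8 * t + 0.9 * b - 0.6 * radial,
            "CA": np.zeros(3),
            "C": 0.9 * t + 0.8 * b - 0.6 * radial,
            "O": 1.0 * t + 1.6 * b - 1.2 * radial,
            "CB": 1.0 * radial + 0.8 * b,
        }
        atoms = [
            Atom(name, _ELEMENT[name], ca[i] + off + jitter[i * len(_BACKBONE) + k])
            for k, (name, off) in enumerate(offsets.items())
        ]
        residues.append(Residue(chain_id, i + 1, "", "ALA", atoms))
    return ProteinStructure(f"toy_{chain_id}", residues)


def _min_interchain_distances(rec: ProteinStructure, lig: ProteinStructure) -> np.ndarray:
    from scipy.spatial.distance import cdist

    d = cdist(rec.heavy_coords(), lig.heavy_coords())
    return d


def _count_contact_pairs(rec: ProteinStructure, lig: ProteinStructure,
                         cutoff: float = 5.0) -> int:
    from scipy.spatial.distance import cdist

    count = 0
    lig_coords = [r_.heavy_atoms for r_ in lig.residues]
    for rres in rec.residues:
        rc = np.array([a.coord for a in rres.heavy_atoms])
        for lres, latoms in zip(lig.residues, lig_coords):
            lc = np.array([a.coord for a in latoms])
            if cdist(rc, lc).min() <= cutoff:
                count += 1
    return count


def make_toy_complex(n_res_receptor: int, n_res_ligand: int,
                     seed: int) -> tuple[ProteinStructure, ProteinStructure]:
    """Build a compact two-chain toy complex in contact.

    Receptor (chain A) and ligand (chain B) are clash-free
    polyalanine-like helices with N/CA/C/O/CB heavy atoms; the ligand is
    placed alongside the receptor so that at least three inter-chain
    residue pairs lie within 5 A.  Coordinates depend deterministically
    on the seed through a small (0.05 A) per-atom jitter.
    """
    if n_res_receptor < 5 or n_res_ligand < 5:
        raise ValidationError("toy complex needs at least 5 residues per chain")
    rng = np.random.default_rng(seed)
    rec = _helix_chain(n_res_receptor,
                       "A", rng.normal(0.0, 0.05, (n_res_receptor * 5, 3)))
    lig = _helix_chain(n_res_ligand,
                       "B", rng.normal(0.0, 0.05, (n_res_ligand * 5, 3)))

    # slide the parallel ligand helix toward the receptor along +x until
    # in contact but not clashing
    base = lig.heavy_coords()
    center_shift = np.array([0.0, 0.0,
                             (_RISE * (n_res_receptor - n_res_ligand)) / 2.0])
    best = None
    for gap in np.arange(14.0, 2.0, -0.25):
        shifted = base + np.array([gap, 0.0, 0.0]) + center_shift
        cand = lig.with_coords(shifted)
        d = _min_interchain_distances(rec, cand)
        if d.min() < 3.0:
            break
        if _count_contact_pairs(rec, cand) >= 3:
            best = cand  # tightest clash-free placement so far
    if best is None:
        raise GenerationError("could not place ligand in contact with receptor")
    return rec, best


def make_sidechain_complex(
    n_res_receptor: int, n_res_ligand: int, seed: int,
    sidechain_fraction: float = 0.4,
) -> tuple[ProteinStructure, ProteinStructure]:
    """Toy complex variant with explicit side chains for alanine scanning.

    Starts from :func:`make_toy_complex` and extends a deterministic
    subset of residues on each chain into lysine-like side chains
    (CG/CD/CE/NZ at 1.4 A steps beyond CB, pointing toward the partner
    chain), so truncation to alanine removes real inter-chain contacts
    and scan results carry signal.
    """
    rec, lig = make_toy_complex(n_res_receptor, n_res_ligand, seed)
    rng = np.random.default_rng(seed + 1)

    def decorate(structure: ProteinStructure, partner: ProteinStructure) -> ProteinStructure:
        partner_coords = partner.heavy_coords()
        partner_centroid = partner_coords.mean(axis=0)
        n_pick = max(1, int(round(sidechain_fraction * len(structure.residues))))
        picked = set(rng.choice(len(structure.residues), size=n_pick, replace=False).tolist())
        residues = []
        for i, res in enumerate(structure.residues):
            if i not in picked:
                residues.append(res)
                continue
            ca = next(a.coord for a in res.atoms if a.name == "CA")
            cb = next(a.coord for a in res.atoms if a.name == "CB")
            toward = partner_centroid - ca
            toward = toward / np.linalg.norm(toward)
            atoms = list(res.atoms)
            names = (("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N"))
            for k, (name, element) in enumerate(names, start=1):
                coord = cb + toward * (1.4 * k)
                # stop extending before the side chain pierces the partner
                if np.min(np.linalg.norm(partner_coords - coord, axis=1)) < 3.0:
                    break
                atoms.append(Atom(name, element, coord))
            residues.append(Residue(res.chain_id, res.res_seq, res.i_code, "LYS", atoms))
        return ProteinStructure(structure.structure_id, residues)

    # decorate sequentially so ligand side chains also avoid the
    # receptor's freshly added ones
    rec_dec = decorate(rec, lig)
    lig_dec = decorate(lig, rec_dec)
    return rec_dec, lig_dec


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def _axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle).as_matrix()


def _about_point(R: np.ndarray, point: np.ndarray,
                 extra_translation: np.ndarray) -> RigidTransform:
    """Rotation about ``point`` followed by an extra translation."""
    return RigidTransform(R, point - R @ point + extra_translation)


def generate_ensemble(
    spec: SyntheticSpec,
    complex_: tuple[ProteinStructure, ProteinStructure],
) -> tuple[list[Pose], SyntheticTruth]:
    """Generate the multi-engine pose ensemble defined by ``spec``.

    Mode 0 keeps the input ligand placement; further modes are random
    re-orientations placed along the receptor-to-ligand direction at
    multiples of ``mode_separation``, so all pairwise mode-centroid
    distances meet the separation by construction.  Per-pose noise is a
    rotation of |N(0, rot_sigma)| degrees about a uniform random axis
    through the ligand centroid plus an isotropic N(0, trans_sigma)
    translation.  The receptor is identical across poses.
    """
    receptor, ligand = complex_
    rng = np.random.default_rng(spec.seed)
    lig_base = ligand.heavy_coords()
    lig_centroid = lig_base.mean(axis=0)
    rec_centroid = receptor.heavy_coords().mean(axis=0)
    away = lig_centroid - rec_centroid
    away = away / np.linalg.norm(away)

    mode_transforms: list[RigidTransform] = [RigidTransform.identity()]
    for m in range(1, spec.n_modes):
        R = _random_rotation(rng)
        shift = away * (m * spec.mode_separation)
        mode_transforms.append(_about_point(R, lig_centroid, shift))

    mode_draws = rng.choice(spec.n_modes, size=spec.n_poses,
                            p=np.asarray(spec.mode_weights))

    poses: list[Pose] = []
    mode_of_pose: dict[str, int] = {}
    n_clash = 0
    rec_coords = receptor.heavy_coords()
    idx = 0
    for engine in spec.engines:
        for rank in range(1, spec.poses_per_engine + 1):
            mode = int(mode_draws[idx])
            idx += 1
            placed = mode_transforms[mode].apply(lig_base)
            centroid = placed.mean(axis=0)
            axis = rng.normal(size=3)
            axis = axis / np.linalg.norm(axis)
            angle = abs(rng.normal(0.0, math.radians(spec.rot_sigma)))
            shift = rng.normal(0.0, spec.trans_sigma, size=3)
            noise = _about_point(_axis_angle_rotation(axis, angle), centroid, shift)
            final = noise.apply(placed)
            pose_id = f"{engine}:pose_{rank:03d}"
            pose = Pose(
                pose_id=pose_id,
                receptor=receptor,
                ligand=ligand.with_coords(final, f"{pose_id}/ligand"),
                engine=engine,
                rank=rank,
            )
            if np.min(np.linalg.norm(rec_coords - final.mean(axis=0), axis=1)) < 2.0:
                n_clash += 1
            poses.append(pose)
            mode_of_pose[pose_id] = mode
    if n_clash > 0.5 * len(poses):
        raise GenerationError(
            f"{n_clash}/{len(poses)} poses bury the ligand centroid in the "
            "receptor; increase mode_separation"
        )
    return poses, SyntheticTruth(mode_of_pose, mode_transforms)


def write_ensemble(poses: list[Pose], truth: SyntheticTruth, out_dir: str | Path,
                   layout: Optional[EnsembleLayout] = None) -> EnsembleLayout:
    """Write an ensemble in the on-disk layout ``load_ensemble`` reads.

    One subdirectory per engine with ``pose_NNN.pdb`` complexes plus a
    ``truth.csv`` table (pose_id, engine, rank, mode) at the root.
    Returns the layout describing what was written.
    """
    out_dir = Path(out_dir)
    engines = tuple(dict.fromkeys(p.engine for p in poses))
    if layout is None:
        layout = EnsembleLayout(engines=engines)
    for pose in poses:
        engine_dir = out_dir / pose.engine
        engine_dir.mkdir(parents=True, exist_ok=True)
        complex_ = merge_structures(pose.receptor, pose.ligand, pose.pose_id)
        write_pdb(complex_, engine_dir / f"pose_{pose.rank:03d}.pdb")
    truth.to_frame(poses).to_csv(out_dir / "truth.csv", index=False)
    return layout
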