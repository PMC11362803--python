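"""Rigid-body superposition and the pose RMSD metric.

Poses from different docking engines arrive in unrelated coordinate
frames, so every pairwise comparison first superposes one pose's
receptor heavy atoms onto the other's (Kabsch, reflections excluded)
and then measures the heavy-atom RMSD of the transformed complex.  The
resulting pairwise dissimilarity matrix drives the hierarchical
clustering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, TopologyError, ValidationError
from .structmodel import Pose

logger = logging.getLogger(__name__)

RMSD_MODES = ("all_heavy", "ligand_only")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation matrix, translation in A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rigid transform needs a 3x3 rotation and 3-vector translation")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValidationError("rotation matrix has det != +1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion mapping ``mobile`` onto ``target``.

    Solved in closed form via the SVD of the cross-covariance matrix;
    the smallest singular vector is sign-flipped when needed so that a
    reflection is never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("point sets must both be (N, 3) with equal N")
    if mobile.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 points")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    P = mobile - cm
    Q = target - ct
    for name, X in (("mobile", P), ("target", Q)):
        # singular values via the 3x3 Gram matrix (cheap for large N)
        ev = np.linalg.eigvalsh(X.T @ X)
        s = np.sqrt(np.maximum(ev[::-1], 0.0))
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{name} point set is (near-)collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return RigidTransform(R, t)


def coords_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two already-aligned coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("coordinate arrays differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pose_rmsd(a: Pose, b: Pose, mode: str = "all_heavy") -> float:
    """Heavy-atom RMSD between two poses after receptor superposition.

    The pose with the lexicographically smaller ``pose_id`` acts as the
    target frame, which makes the value symmetric by construction (the
    a/b difference is below numerical noise regardless).
    ``mode='all_heavy'`` measures receptor + ligand atoms (the receptor
    contributes ~0 after superposition); ``'ligand_only'`` restricts to
    the ligand.
    """
    if mode not in RMSD_MODES:
        raise ValidationError(f"unknown RMSD mode {mode!r}; expected one of {RMSD_MODES}")
    if a.receptor.heavy_identity() != b.receptor.heavy_identity():
        raise TopologyError(f"poses {a.pose_id!r}, {b.pose_id!r}: receptor topology mismatch")
    if a.ligand.heavy_identity() != b.ligand.heavy_identity():
        raise TopologyError(f"poses {a.pose_id!r}, {b.pose_id!r}: ligand topology mismatch")
    if a.pose_id == b.pose_id:
        tgt, mob = a, b
    else:
        tgt, mob = (a, b) if a.pose_id < b.pose_id else (b, a)
    transform = kabsch(mob.receptor.heavy_coords(), tgt.receptor.heavy_coords())
    if mode == "ligand_only":
        moved = transform.apply(mob.ligand.heavy_coords())
        return coords_rmsd(moved, tgt.ligand.heavy_coords())
    moved = transform.apply(mob.all_heavy_coords())
    return coords_rmsd(moved, tgt.all_heavy_coords())


@dataclass
class RMSDMatrix:
    """Symmetric pairwise pose dissimilarity matrix in Angstroms."""

    pose_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        n = len(self.pose_ids)
        if V.shape != (n, n):
            raise ValidationError("matrix shape does not match pose id count")
        if np.any(np.abs(np.diag(V)) > 1e-12):
            raise ValidationError("RMSD matrix diagonal must be zero")
        if np.any(V < 0):
            raise ValidationError("RMSD values must be non-negative")
        if np.max(np.abs(V - V.T)) > 1e-9:
            raise ValidationError("RMSD matrix must be symmetric to 1e-9")
        self.values = V

    @property
    def n(self) -> int:
        return len(self.pose_ids)

    def submatrix(self, indices: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(indices, indices)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.pose_ids,
                     columns=self.pose_ids).to_csv(path, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RMSDMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        # round-tripped values may be asymmetric at the printed precision
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        return cls(list(df.index.astype(str)), values)


def _pair_rmsd(rec_t: np.ndarray, lig_t: np.ndarray,
               rec_m: np.ndarray, lig_m: np.ndarray, mode: str) -> float:
    """RMSD of mobile (rec_m, lig_m) onto target after receptor superposition."""
    transform = kabsch(rec_m, rec_t)
    if mode == "ligand_only":
        return coords_rmsd(transform.apply(lig_m), lig_t)
    moved = transform.apply(np.vstack([rec_m, lig_m]))
    return coords_rmsd(moved, np.vstack([rec_t, lig_t]))


def rmsd_matrix(ensemble: list[Pose], mode: str = "all_heavy") -> RMSDMatrix:
    """All-pairs pose RMSD matrix over an ensemble.

    Per-pose coordinate arrays are extracted once and topology is
    verified once against the first pose, so the pairwise loop runs on
    plain arrays; each pair is evaluated exactly as :func:`pose_rmsd`
    (target = lexicographically smaller pose_id).
    """
    if len(ensemble) < 2:
        raise ValidationError("an RMSD matrix needs at least 2 poses")
    if mode not in RMSD_MODES:
        raise ValidationError(f"unknown RMSD mode {mode!r}; expected one of {RMSD_MODES}")
    ref_rec = ensemble[0].receptor.heavy_identity()
    ref_lig = ensemble[0].ligand.heavy_identity()
    for p in ensemble[1:]:
        if p.receptor.heavy_identity() != ref_rec or p.ligand.heavy_identity() != ref_lig:
            raise TopologyError(
                f"pose {p.pose_id!r}: topology differs from {ensemble[0].pose_id!r}"
            )
    rec = [p.receptor.heavy_coords() for p in ensemble]
    lig = [p.ligand.heavy_coords() for p in ensemble]
    ids = [p.pose_id for p in ensemble]
    n = len(ensemble)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t, m = (i, j) if ids[i] < ids[j] else (j, i)
            try:
                d = _pair_rmsd(rec[t], lig[t], rec[m], lig[m], mode)
            except ValidationError as exc:
                raise ValidationError(
                    f"RMSD failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return RMSDMatrix(ids, values)
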