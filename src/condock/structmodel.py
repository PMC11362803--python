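"""Structure data model and PDB I/O.

The in-memory model is deliberately small: chains of residues of heavy
atoms with coordinates in Angstroms.  Hydrogens (and deuterium), waters,
HETATM records and non-standard residues never enter the model, because
every downstream computation (pose RMSD, interface contacts, the contact
potential) is defined on the heavy atoms of standard amino acids sharing
one topology.  Parsing and writing of the fixed-column PDB format is
delegated to biotite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ChainNotFoundError, TopologyError, ValidationError

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Elements excluded from the heavy-atom view.
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})

#: (chain_id, res_seq, i_code, res_name) identifying a residue.
ResidueKey = tuple[str, int, str, str]

#: ResidueKey extended by the atom name; the unit of topology comparison.
AtomKey = tuple[str, int, str, str, str]


@dataclass
class Atom:
    """A single atom with coordinates in Angstroms."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValidationError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValidationError(f"atom {self.name!r}: element symbol must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue; atoms are kept in file order."""

    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.i_code, self.res_name)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ProteinStructure:
    """An ordered collection of residues; one protomer or chain selection.

    ``frame_index`` is 0 for single-model files and the model index for
    frames taken from a multi-model (trajectory) file.
    """

    structure_id: str
    residues: list[Residue]
    frame_index: int = 0

    def __post_init__(self) -> None:
        keys = [r.key[:3] for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"structure {self.structure_id!r}: duplicate (chain, res_seq, i_code)"
            )
        if self.n_heavy_atoms == 0:
            raise ValidationError(f"structure {self.structure_id!r}: no heavy atoms")

    @property
    def n_heavy_atoms(self) -> int:
        return sum(len(r.heavy_atoms) for r in self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def iter_heavy(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.heavy_atoms:
                yield res, atom

    def heavy_coords(self) -> np.ndarray:
        """(N, 3) array of heavy-atom coordinates in structure order."""
        coords = [a.coord for _, a in self.iter_heavy()]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def heavy_identity(self) -> list[AtomKey]:
        """Ordered heavy-atom identity list; the topology fingerprint."""
        return [(*res.key, atom.name) for res, atom in self.iter_heavy()]

    def heavy_elements(self) -> list[str]:
        return [a.element.upper() for _, a in self.iter_heavy()]

    def get_residue(self, chain_id: str, res_seq: int, i_code: str = "") -> Residue:
        for r in self.residues:
            if (r.chain_id, r.res_seq, r.i_code) == (chain_id, res_seq, i_code):
                return r
        raise ValidationError(f"residue {chain_id}:{res_seq}{i_code} not found")

    def with_coords(self, coords: np.ndarray, structure_id: Optional[str] = None) -> "ProteinStructure":
        """Copy of this structure with heavy-atom coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_heavy_atoms, 3):
            raise ValidationError("coordinate array shape does not match heavy-atom count")
        new_residues = []
        i = 0
        for res in self.residues:
            new_atoms = []
            for atom in res.atoms:
                if atom.is_heavy:
                    new_atoms.append(Atom(atom.name, atom.element, coords[i].copy(),
                                          atom.occupancy, atom.alt_loc))
                    i += 1
                else:
                    new_atoms.append(Atom(atom.name, atom.element, atom.coord.copy(),
                                          atom.occupancy, atom.alt_loc))
            new_residues.append(Residue(res.chain_id, res.res_seq, res.i_code,
                                        res.res_name, new_atoms))
        return ProteinStructure(structure_id or self.structure_id, new_residues,
                                self.frame_index)


@dataclass
class Pose:
    """One predicted complex: a receptor/ligand pair with provenance."""

    pose_id: str
    receptor: ProteinStructure
    ligand: ProteinStructure
    engine: str
    rank: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"pose {self.pose_id!r}: rank must be >= 1")

    def all_heavy_coords(self) -> np.ndarray:
        return np.vstack([self.receptor.heavy_coords(), self.ligand.heavy_coords()])


@dataclass(frozen=True)
class EnsembleLayout:
    """On-disk layout of a multi-engine pose ensemble.

    One subdirectory per engine, each holding one PDB file per pose;
    lexicographic file order defines the engine's rank order.
    """

    engines: tuple[str, ...]
    pattern: str = "pose_*.pdb"
    receptor_chain: str = "A"
    ligand_chain: str = "B"


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    chain_filter: Optional[Iterable[str]] = None,
    model_index: Optional[int] = None,
) -> ProteinStructure:
    """Read a PDB file into the heavy-atom model.

    Keeps ATOM records of standard amino acids only; HETATM records,
    waters and hydrogens are excluded.  Alternate locations are resolved
    to the highest-occupancy conformer (tie: first in file order).
    ``model_index`` selects a frame of a multi-model file (0-based;
    default first model).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"PDB file not found: {path}")
    pdb_file = PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    frame = 0 if model_index is None else int(model_index)
    if frame < 0 or frame >= n_models:
        raise ValidationError(f"{path}: model_index {frame} out of range (file has {n_models})")
    atoms = pdb_file.get_structure(model=frame + 1, altloc="occupancy",
                                   extra_fields=["occupancy"])

    if chain_filter is not None:
        wanted = {str(c) for c in chain_filter}
        present = set(np.unique(atoms.chain_id))
        missing = wanted - present
        if missing:
            raise ChainNotFoundError(
                f"{path}: chain(s) not found: {sorted(missing)} (present: {sorted(present)})"
            )
        atoms = atoms[np.isin(atoms.chain_id, sorted(wanted))]

    standard = np.isin(atoms.res_name, sorted(STANDARD_AA))
    dropped = atoms[~atoms.hetero & ~standard]
    if dropped.array_length() > 0:
        names = sorted(set(dropped.res_name))
        logger.warning("%s: dropping %d atoms of non-standard residues %s",
                       path.name, dropped.array_length(), names)
    heavy = ~np.isin(np.char.upper(atoms.element), sorted(_HYDROGEN_ELEMENTS))
    atoms = atoms[~atoms.hetero & standard & heavy]
    if atoms.array_length() == 0:
        raise ValidationError(f"{path}: no heavy atoms left after filtering")

    residues: list[Residue] = []
    current_key: Optional[tuple] = None
    current_atoms: list[Atom] = []
    occ = atoms.occupancy if "occupancy" in atoms.get_annotation_categories() else None
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]).strip(), str(atoms.res_name[i]))
        if key != current_key:
            if current_key is not None:
                residues.append(Residue(*current_key, atoms=current_atoms))
            current_key, current_atoms = key, []
        current_atoms.append(Atom(
            name=str(atoms.atom_name[i]),
            element=str(atoms.element[i]).upper(),
            coord=atoms.coord[i].astype(float),
            occupancy=float(occ[i]) if occ is not None else 1.0,
        ))
    if current_key is not None:
        residues.append(Residue(*current_key, atoms=current_atoms))

    return ProteinStructure(structure_id=path.stem, residues=residues, frame_index=frame)


def _to_atom_array(structure: ProteinStructure) -> struc.AtomArray:
    n = structure.n_heavy_atoms
    array = struc.AtomArray(n)
    array.add_annotation("occupancy", dtype=float)
    coords = np.empty((n, 3))
    i = 0
    for res, atom in structure.iter_heavy():
        array.chain_id[i] = res.chain_id
        array.res_id[i] = res.res_seq
        array.ins_code[i] = res.i_code
        array.res_name[i] = res.res_name
        array.atom_name[i] = atom.name
        array.element[i] = atom.element
        array.hetero[i] = False
        array.occupancy[i] = atom.occupancy
        coords[i] = atom.coord
        i += 1
    array.coord = coords
    return array


def write_pdb(structure: ProteinStructure | Sequence[ProteinStructure],
              path: str | Path) -> None:
    """Write one structure (or a list of topologically identical frames,
    emitted as MODEL records) to a PDB file.

    Coordinates are written at the PDB fixed-format precision of three
    decimals; a read/write round trip is a fixed point at that precision.
    """
    path = Path(path)
    if isinstance(structure, ProteinStructure):
        array = _to_atom_array(structure)
    else:
        frames = list(structure)
        if not frames:
            raise ValidationError("no frames to write")
        first = frames[0].heavy_identity()
        for f in frames[1:]:
            if f.heavy_identity() != first:
                raise TopologyError("frames differ in heavy-atom topology")
        array = struc.stack([_to_atom_array(f) for f in frames])
    pdb_file = PDBFile()
    pdb_file.set_structure(array)
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc


def split_chains(structure: ProteinStructure, chain_ids: Iterable[str],
                 structure_id: Optional[str] = None) -> ProteinStructure:
    """Sub-structure holding only the requested chains, order preserved."""
    wanted = {str(c) for c in chain_ids}
    present = set(r.chain_id for r in structure.residues)
    missing = wanted - present
    if missing:
        raise ChainNotFoundError(f"chain(s) not found: {sorted(missing)}")
    residues = [r for r in structure.residues if r.chain_id in wanted]
    return ProteinStructure(structure_id or structure.structure_id, residues,
                            structure.frame_index)


def merge_structures(a: ProteinStructure, b: ProteinStructure,
                     structure_id: str) -> ProteinStructure:
    """Concatenate two structures (e.g. receptor + ligand) into one."""
    return ProteinStructure(structure_id, list(a.residues) + list(b.residues))


def load_ensemble(root: str | Path, layout: EnsembleLayout) -> list[Pose]:
    """Load a multi-engine pose ensemble from disk.

    Iterates engines in the order given by ``layout`` (never filesystem
    order), assigns ranks by lexicographic file order within an engine,
    and verifies that every pose shares the receptor and ligand topology
    of the first pose.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"ensemble root not found: {root}")
    poses: list[Pose] = []
    ref_receptor: Optional[list[AtomKey]] = None
    ref_ligand: Optional[list[AtomKey]] = None
    for engine in layout.engines:
        engine_dir = root / engine
        files = sorted(engine_dir.glob(layout.pattern)) if engine_dir.is_dir() else []
        if not files:
            logger.warning("engine %r: no pose files under %s; skipping", engine, engine_dir)
            continue
        for rank, f in enumerate(files, start=1):
            full = read_pdb(f, chain_filter={layout.receptor_chain, layout.ligand_chain})
            pose_id = f"{engine}:{f.stem}"
            receptor = split_chains(full, {layout.receptor_chain}, f"{pose_id}/receptor")
            ligand = split_chains(full, {layout.ligand_chain}, f"{pose_id}/ligand")
            if ref_receptor is None:
                ref_receptor = receptor.heavy_identity()
                ref_ligand = ligand.heavy_identity()
            else:
                if receptor.heavy_identity() != ref_receptor:
                    raise TopologyError(f"pose {pose_id!r}: receptor topology mismatch")
                if ligand.heavy_identity() != ref_ligand:
                    raise TopologyError(f"pose {pose_id!r}: ligand topology mismatch")
            poses.append(Pose(pose_id, receptor, ligand, engine=engine, rank=rank))
    if not poses:
        raise ValidationError(f"no poses loaded from {root}")
    return poses
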