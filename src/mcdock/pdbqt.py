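"""PDBQT and config-file I/O.

PDBQT is AutoDock's extension of the PDB format: atom records carry a partial
charge and an AutoDock atom type, and ligand files embed a torsion tree via
ROOT/ENDROOT and (nestable) BRANCH/ENDBRANCH records.  The receptor is rigid:
only its atom records matter.  The config file is the Vina-style ``key = value``
dialect giving the docking-box center/size and search hyperparameters.

Column conventions follow the AutoDock fixed-column layout: coordinates are
parsed from columns 31-54; the partial charge and atom type are taken from the
trailing whitespace-separated tokens (charge second-to-last, type last).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DimensionError,
    EmptyInputError,
    PDBQTParseError,
    StructureError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Receptor",
    "BranchNode",
    "LigandTree",
    "DockingBox",
    "read_receptor",
    "read_ligand",
    "parse_config",
    "write_poses",
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record: serial, name, AutoDock type, coords (Å), charge (e)."""

    serial: int
    name: str
    autodock_type: str
    coords: np.ndarray
    partial_charge: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise DimensionError("atom coords must be a finite 3-vector")
        if not self.autodock_type:
            raise ValueError("autodock_type must be non-empty")


@dataclass(frozen=True)
class Receptor:
    """A rigid receptor: an ordered sequence of atoms, fixed throughout docking."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise EmptyInputError("receptor contains no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class BranchNode:
    """One rotatable rigid body: axis (parent_serial -> child_serial) plus member atoms."""

    parent_serial: int
    child_serial: int
    atoms: list[AtomRecord] = field(default_factory=list)
    children: list["BranchNode"] = field(default_factory=list)


@dataclass
class LigandTree:
    """Torsion-tree ligand: rigid root atoms plus nested rotatable branches.

    ``nrot`` is always derived from the number of BRANCH records; a conflicting
    TORSDOF declaration only logs a warning because the kinematics is driven by
    the branch structure, not by the declared count.
    """

    root_atoms: list[AtomRecord]
    branches: list[BranchNode] = field(default_factory=list)
    torsdof: int | None = None

    @property
    def nrot(self) -> int:
        def count(nodes):
            return sum(1 + count(n.children) for n in nodes)

        return count(self.branches)

    @property
    def atoms(self) -> list[AtomRecord]:
        """All atoms in file (depth-first) order: root first, then each branch."""
        out = list(self.root_atoms)

        def walk(nodes):
            for n in nodes:
                out.extend(n.atoms)
                walk(n.children)

        walk(self.branches)
        return out


@dataclass(frozen=True)
class DockingBox:
    """Axis-aligned search box: center and edge lengths in Å."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "size", np.asarray(self.size, dtype=float))
        if self.center.shape != (3,) or self.size.shape != (3,):
            raise DimensionError("box center and size must be 3-vectors")
        if not np.all(self.size > 0):
            raise ConfigError("box sizes must all be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.size / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.size / 2.0


_ATOM_PREFIXES = ("ATOM", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBQTParseError("atom record shorter than coordinate columns", lineno)
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBQTParseError(f"non-integer serial field {line[6:11]!r}", lineno) from None
    name = line[12:16].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise PDBQTParseError(
            f"non-numeric coordinate field in {line[30:54]!r}", lineno
        ) from None
    tail = line[54:].split()
    if not tail:
        raise PDBQTParseError("missing atom-type token", lineno)
    atype = tail[-1]
    charge = 0.0
    if len(tail) >= 2:
        try:
            charge = float(tail[-2])
        except ValueError:
            charge = 0.0
    return AtomRecord(serial, name, atype, np.array([x, y, z]), charge)


def read_receptor(text: str) -> Receptor:
    """Parse a rigid receptor from PDBQT text.

    Every ATOM/HETATM record becomes one :class:`AtomRecord`, in file order;
    all other records are ignored.
    """
    atoms = []
    seen = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(_ATOM_PREFIXES):
            atom = _parse_atom_line(line, lineno)
            if atom.serial in seen:
                raise PDBQTParseError(f"duplicate atom serial {atom.serial}", lineno)
            seen.add(atom.serial)
            atoms.append(atom)
    if not atoms:
        raise EmptyInputError("receptor PDBQT contains no ATOM/HETATM records")
    return Receptor(tuple(atoms))


def read_ligand(text: str) -> LigandTree:
    """Parse a torsion-tree ligand from PDBQT text.

    Atoms between ROOT/ENDROOT populate the rigid root; each BRANCH opens a
    rotatable rigid body whose rotation axis is the (parent_serial,
    child_serial) bond; nesting defines the tree.  In multi-model files only
    the first MODEL is read.
    """
    root_atoms: list[AtomRecord] = []
    top_branches: list[BranchNode] = []
    stack: list[BranchNode] = []
    in_root = False
    seen_root = False
    seen_serials: set[int] = set()
    torsdof = None
    n_branches = 0
    in_model = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line.split()[0] if line.split() else ""
        if rec == "MODEL":
            in_model = True
            continue
        if rec == "ENDMDL":
            if in_model:
                break
            raise StructureError(f"line {lineno}: ENDMDL without MODEL")
        if rec == "ROOT":
            in_root = True
            seen_root = True
        elif rec == "ENDROOT":
            in_root = False
        elif rec == "BRANCH":
            parts = line.split()
            if len(parts) < 3:
                raise StructureError(f"line {lineno}: BRANCH needs two atom serials")
            p, c = int(parts[1]), int(parts[2])
            if p not in seen_serials:
                raise StructureError(
                    f"line {lineno}: BRANCH axis atom {p} not yet defined"
                )
            node = BranchNode(p, c)
            if stack:
                stack[-1].children.append(node)
            else:
                top_branches.append(node)
            stack.append(node)
            n_branches += 1
        elif rec == "ENDBRANCH":
            if not stack:
                raise StructureError(f"line {lineno}: ENDBRANCH without open BRANCH")
            node = stack.pop()
            if node.child_serial not in seen_serials:
                raise StructureError(
                    f"line {lineno}: BRANCH child atom {node.child_serial} "
                    "never defined inside its branch"
                )
        elif rec == "TORSDOF":
            torsdof = int(line.split()[1])
        elif line.startswith(_ATOM_PREFIXES):
            atom = _parse_atom_line(line, lineno)
            if atom.serial in seen_serials:
                raise PDBQTParseError(f"duplicate atom serial {atom.serial}", lineno)
            seen_serials.add(atom.serial)
            if stack:
                stack[-1].atoms.append(atom)
            elif in_root or not seen_root:
                root_atoms.append(atom)
            else:
                # atoms after ENDROOT but outside any branch: keep with root
                root_atoms.append(atom)

    if stack:
        raise StructureError(
            f"unbalanced BRANCH/ENDBRANCH: {len(stack)} branch(es) left open"
        )
    if not root_atoms:
        raise EmptyInputError("ligand PDBQT contains no root atoms")

    tree = LigandTree(root_atoms, top_branches, torsdof)
    if torsdof is not None and torsdof != n_branches:
        logger.warning(
            "TORSDOF=%d disagrees with BRANCH count %d; using BRANCH count",
            torsdof,
            n_branches,
        )
    return tree


_CONFIG_KEYS = {
    "receptor",
    "ligand",
    "center_x",
    "center_y",
    "center_z",
    "size_x",
    "size_y",
    "size_z",
    "out",
    "thread",
    "search_depth",
    "seed",
}
_FLOAT_KEYS = {"center_x", "center_y", "center_z", "size_x", "size_y", "size_z"}
_INT_KEYS = {"thread", "search_depth", "seed"}


def parse_config(text: str) -> tuple[DockingBox, dict]:
    """Parse a Vina-style ``key = value`` config file.

    Returns the docking box plus a dict of the remaining recognized settings
    (paths and search overrides).  Keys are case-sensitive; unknown keys are
    rejected; on duplicates the last value wins with a logged warning.
    """
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
        if key in values:
            logger.warning("duplicate config key %r; last value wins", key)
        try:
            if key in _FLOAT_KEYS:
                values[key] = float(val)
            elif key in _INT_KEYS:
                values[key] = int(val)
            else:
                values[key] = val
        except ValueError:
            raise ConfigError(f"line {lineno}: bad value {val!r} for {key!r}") from None

    box_keys = sorted(_FLOAT_KEYS - values.keys())
    if box_keys:
        raise ConfigError(f"missing required config keys: {', '.join(box_keys)}")
    box = DockingBox(
        center=[values.pop("center_x"), values.pop("center_y"), values.pop("center_z")],
        size=[values.pop("size_x"), values.pop("size_y"), values.pop("size_z")],
    )
    return box, values


def _format_atom_line(atom: AtomRecord, coords: np.ndarray) -> str:
    name = atom.name if len(atom.name) < 4 else atom.name[:4]
    return (
        f"ATOM  {atom.serial:>5} {name:<4}LIG A   1    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"  0.00  0.00    {atom.partial_charge:6.3f} {atom.autodock_type:<2}"
    )


def ligand_to_pdbqt(ligand: LigandTree, coords: np.ndarray | None = None) -> str:
    """Serialize a ligand tree (optionally with replacement coordinates in
    file-order) back to PDBQT, preserving the BRANCH structure."""
    atoms = ligand.atoms
    if coords is None:
        coords = np.array([a.coords for a in atoms])
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(atoms), 3):
        raise DimensionError(
            f"coords shape {coords.shape} does not match atom count {len(atoms)}"
        )
    pos = {id(a): coords[i] for i, a in enumerate(atoms)}

    lines = ["ROOT"]
    for a in ligand.root_atoms:
        lines.append(_format_atom_line(a, pos[id(a)]))
    lines.append("ENDROOT")

    def walk(node: BranchNode):
        lines.append(f"BRANCH {node.parent_serial:>4} {node.child_serial:>4}")
        for a in node.atoms:
            lines.append(_format_atom_line(a, pos[id(a)]))
        for child in node.children:
            walk(child)
        lines.append(f"ENDBRANCH {node.parent_serial:>4} {node.child_serial:>4}")

    for b in ligand.branches:
        walk(b)
    lines.append(f"TORSDOF {ligand.nrot}")
    return "\n".join(lines) + "\n"


def write_poses(ligand: LigandTree, poses, scores=None) -> str:
    """Serialize scored poses as a multi-MODEL PDBQT text.

    One MODEL/ENDMDL block per pose, each with a ``REMARK DOCKING SCORE``
    line (kcal/mol, 3 decimals) and atom records at the pose's realized
    coordinates.  ``poses`` must already be sorted by ascending energy;
    ``scores`` optionally overrides the reported score per pose (e.g. after
    conformational-entropy weighting), but must preserve the ordering.
    """
    poses = list(poses)
    if not poses:
        logger.warning("write_poses called with zero poses; writing empty output")
        return ""
    if scores is None:
        scores = [p.e for p in poses]
    if any(b < a - 1e-9 for a, b in zip(scores, scores[1:])):
        raise ValueError("poses must be sorted by ascending score")
    natom = len(ligand.atoms)
    blocks = []
    for i, (pose, s) in enumerate(zip(poses, scores), start=1):
        if pose.coords.shape[0] != natom:
            raise DimensionError(
                f"pose {i} has {pose.coords.shape[0]} atoms, ligand has {natom}"
            )
        body = ligand_to_pdbqt(ligand, pose.coords)
        blocks.append(
            f"MODEL {i}\nREMARK DOCKING SCORE {s:8.3f}\n{body}ENDMDL\n"
        )
    return "".join(blocks)
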