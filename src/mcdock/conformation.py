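"""Conformation state and ligand kinematics.

A ligand pose is parameterized by its POT state: Cartesian *position* of the
rigid root (3), *orientation* as a unit quaternion (4), and one *torsion*
angle per rotatable bond (Nrot), i.e. a (7 + Nrot)-dimensional vector.

The recursive torsion tree read from PDBQT is flattened into a node list in
depth-first order plus a boolean children map, so the forward kinematics is a
single iterative pass: torsions are applied node-by-node (parents before
children, each rotating its member atoms and all descendants about the current
parent->child bond axis, right-hand rule), then the whole ligand is rotated by
the quaternion about the root-atom centroid and translated to the position.
Applying the rigid transform last is equivalent to applying it first with
transformed axes, and keeps the pose gradient a textbook kinematic-chain
Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError
from .pdbqt import DockingBox, LigandTree

__all__ = [
    "Conformation",
    "FlatLigand",
    "MutationParams",
    "flatten_tree",
    "apply_conformation",
    "apply_pose",
    "random_conformation",
    "mutate",
    "rmsd",
    "quat_to_matrix",
    "quat_multiply",
]

_QUAT_NORM_TOL = 1e-9

# bond-detection thresholds on reference geometry (Å)
_BOND_MAX_HEAVY = 1.9
_BOND_MAX_H = 1.3
_HYDROGEN_TYPES = frozenset({"H", "HD"})


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from quaternion ``(a, b, c, d)``.

    Uses the quadratic form valid for unit quaternions; evaluated on a raw
    (non-normalized) quaternion it remains a smooth polynomial map, which is
    what the pose gradient differentiates.
    """
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


def quat_matrix_derivatives(q: np.ndarray) -> np.ndarray:
    """The four matrices dR/dq_k of :func:`quat_to_matrix` (linear in q)."""
    a, b, c, d = q
    da = 2 * np.array([[a, -d, c], [d, a, -b], [-c, b, a]])
    db = 2 * np.array([[b, c, d], [c, -b, -a], [d, a, -b]])
    dc = 2 * np.array([[-c, b, a], [b, c, d], [-a, d, -c]])
    dd = 2 * np.array([[-d, -a, b], [a, -d, c], [b, c, d]])
    return np.stack([da, db, dc, dd])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q, scalar-first convention."""
    a1, b1, c1, d1 = p
    a2, b2, c2, d2 = q
    return np.array(
        [
            a1 * a2 - b1 * b2 - c1 * c2 - d1 * d2,
            a1 * b2 + b1 * a2 + c1 * d2 - d1 * c2,
            a1 * c2 - b1 * d2 + c1 * a2 + d1 * b2,
            a1 * d2 + b1 * c2 - c1 * b2 + d1 * a2,
        ]
    )


def _axis_angle_matrix(u: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about unit axis ``u`` (right-hand rule)."""
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class Conformation:
    """POT state: position (Å), unit quaternion, torsions (rad, in (-π, π])."""

    position: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        object.__setattr__(self, "torsions", np.asarray(self.torsions, dtype=float))
        if self.position.shape != (3,):
            raise DimensionError("position must be a 3-vector")
        if self.orientation.shape != (4,):
            raise DimensionError("orientation must be a quaternion 4-vector")
        if abs(np.linalg.norm(self.orientation) - 1.0) > _QUAT_NORM_TOL:
            raise ValueError("orientation quaternion must have unit norm")

    @property
    def nrot(self) -> int:
        return len(self.torsions)

    def as_vector(self) -> np.ndarray:
        """The raw (7 + Nrot)-vector [x, y, z, a, b, c, d, ψ1..ψNrot]."""
        return np.concatenate([self.position, self.orientation, self.torsions])

    @classmethod
    def from_vector(cls, x: np.ndarray, normalize: bool = True) -> "Conformation":
        x = np.asarray(x, dtype=float)
        q = x[3:7]
        if normalize:
            q = q / np.linalg.norm(q)
        return cls(x[:3], q, x[7:])


@dataclass(frozen=True)
class MutationParams:
    """Uniform single-block POT mutation: amplitude for position moves (Å)."""

    position_amplitude: float = 2.0

    def __post_init__(self):
        if self.position_amplitude <= 0:
            raise ValueError("position_amplitude must be positive")


@dataclass(frozen=True)
class _Node:
    atom_idx: np.ndarray           # member atoms, indices into the atom array
    axis: tuple[int, int] | None   # (parent_atom_idx, child_atom_idx); None for root
    subtree_idx: np.ndarray        # atoms of this node and all descendants


@dataclass(frozen=True)
class FlatLigand:
    """Traversal-ordered node list replacing the recursive torsion tree.

    ``children_map[i, j]`` is True iff node j is a child of node i; nodes are
    in depth-first order so every parent index precedes its children.  Atom
    arrays are in file order (root atoms first, then branch atoms in
    depth-first order), matching :meth:`LigandTree.atoms`.
    """

    nodes: tuple[_Node, ...]
    children_map: np.ndarray
    atoms: tuple
    ref_coords: np.ndarray
    types: tuple[str, ...]
    root_centroid: np.ndarray
    bond_graph_dist: np.ndarray      # pairwise bond-path lengths (np.inf if disconnected)
    node_of_atom: np.ndarray
    intra_pairs: np.ndarray          # (npairs, 2) eligible intramolecular pairs

    @property
    def natom(self) -> int:
        return len(self.atoms)

    @property
    def nrot(self) -> int:
        return len(self.nodes) - 1


def _detect_bonds(coords: np.ndarray, types, extra_bonds) -> list[tuple[int, int]]:
    n = len(coords)
    is_h = np.array([t in _HYDROGEN_TYPES for t in types])
    bonds = set(tuple(sorted(b)) for b in extra_bonds)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            thr = _BOND_MAX_H if (is_h[i] or is_h[j]) else _BOND_MAX_HEAVY
            if d[i, j] <= thr:
                bonds.add((i, j))
    return sorted(bonds)


def _bond_path_lengths(n: int, bonds) -> np.ndarray:
    """All-pairs shortest bond-path lengths by BFS from each atom."""
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if not np.isfinite(dist[src, v]):
                        dist[src, v] = dist[src, u] + 1
                        nxt.append(v)
            queue = nxt
    return dist


def flatten_tree(tree: LigandTree) -> FlatLigand:
    """Flatten a torsion tree into depth-first node list + children map."""
    atoms = tree.atoms
    serial_to_idx = {a.serial: i for i, a in enumerate(atoms)}
    coords = np.array([a.coords for a in atoms])
    types = tuple(a.autodock_type for a in atoms)

    node_atoms: list[list[int]] = [[serial_to_idx[a.serial] for a in tree.root_atoms]]
    node_axes: list[tuple[int, int] | None] = [None]
    parent_of: list[int] = [-1]

    def visit(branch, parent_node):
        idx = len(node_atoms)
        node_atoms.append([serial_to_idx[a.serial] for a in branch.atoms])
        node_axes.append(
            (serial_to_idx[branch.parent_serial], serial_to_idx[branch.child_serial])
        )
        parent_of.append(parent_node)
        for child in branch.children:
            visit(child, idx)

    for b in tree.branches:
        visit(b, 0)

    n_nodes = len(node_atoms)
    children_map = np.zeros((n_nodes, n_nodes), dtype=bool)
    for j in range(1, n_nodes):
        children_map[parent_of[j], j] = True

    # subtree membership: node's own atoms first, then descendants, built
    # bottom-up so each node is resolved after all of its children
    subtree_idx: list[list[int] | None] = [None] * n_nodes
    for j in range(n_nodes - 1, -1, -1):
        acc = list(node_atoms[j])
        for c in np.flatnonzero(children_map[j]):
            acc.extend(subtree_idx[c])
        subtree_idx[j] = acc

    nodes = tuple(
        _Node(
            atom_idx=np.array(node_atoms[j], dtype=int),
            axis=node_axes[j],
            subtree_idx=np.array(subtree_idx[j], dtype=int),
        )
        for j in range(n_nodes)
    )

    node_of_atom = np.empty(len(atoms), dtype=int)
    for j, na in enumerate(node_atoms):
        node_of_atom[na] = j

    axis_bonds = [node_axes[j] for j in range(1, n_nodes)]
    bonds = _detect_bonds(coords, types, axis_bonds)
    gdist = _bond_path_lengths(len(atoms), bonds)

    pairs = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if node_of_atom[i] != node_of_atom[j] and gdist[i, j] >= 4:
                pairs.append((i, j))
    intra_pairs = (
        np.array(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)
    )

    root_centroid = coords[nodes[0].atom_idx].mean(axis=0)
    return FlatLigand(
        nodes=nodes,
        children_map=children_map,
        atoms=tuple(atoms),
        ref_coords=coords,
        types=types,
        root_centroid=root_centroid,
        bond_graph_dist=gdist,
        node_of_atom=node_of_atom,
        intra_pairs=intra_pairs,
    )


def _forward(flat: FlatLigand, x: np.ndarray):
    """Forward kinematics on a raw pose vector.

    Returns ``(coords, t, R, axes)`` where ``t`` are the torsion-frame
    coordinates before the rigid transform, ``R`` the orientation matrix, and
    ``axes`` the per-node (point, unit direction) of each rotation axis in the
    final frame (None for the root node).
    """
    nrot = flat.nrot
    if len(x) != 7 + nrot:
        raise DimensionError(f"pose vector length {len(x)} != {7 + nrot}")
    pos, q, torsions = x[:3], x[3:7], x[7:]

    t = flat.ref_coords.copy()
    axes_t = [None]
    for j in range(1, len(flat.nodes)):
        node = flat.nodes[j]
        pa, ca = node.axis
        p = t[pa]
        v = t[ca] - t[pa]
        u = v / np.linalg.norm(v)
        Rj = _axis_angle_matrix(u, torsions[j - 1])
        sub = node.subtree_idx
        t[sub] = (t[sub] - p) @ Rj.T + p
        axes_t.append((p, u))

    R = quat_to_matrix(q)
    coords = (t - flat.root_centroid) @ R.T + pos
    axes = [None]
    for j in range(1, len(flat.nodes)):
        p, u = axes_t[j]
        axes.append(((p - flat.root_centroid) @ R.T + pos, R @ u))
    return coords, t, R, axes


def apply_pose(flat: FlatLigand, x: np.ndarray) -> np.ndarray:
    """Cartesian coordinates (Natom × 3, Å) from a raw pose vector."""
    return _forward(flat, np.asarray(x, dtype=float))[0]


def apply_conformation(flat: FlatLigand, c: Conformation) -> np.ndarray:
    """Cartesian coordinates (Natom × 3, Å) from a validated conformation."""
    if c.nrot != flat.nrot:
        raise DimensionError(
            f"conformation has {c.nrot} torsions, ligand has {flat.nrot}"
        )
    return apply_pose(flat, c.as_vector())


def random_conformation(
    box: DockingBox, nrot: int, rng: np.random.Generator
) -> Conformation:
    """Uniform random POT state: position uniform in the box, orientation
    uniform on the quaternion sphere, torsions uniform in (-π, π]."""
    position = box.lo + rng.random(3) * box.size
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    torsions = np.pi - rng.random(nrot) * 2.0 * np.pi
    return Conformation(position, q, torsions)


def mutate(
    c: Conformation,
    params: MutationParams,
    rng: np.random.Generator,
    box: DockingBox | None = None,
) -> Conformation:
    """Mutate exactly one POT block, uniformly chosen among the available ones.

    Position: per-axis uniform displacement within ±amplitude, clamped to the
    box when one is given.  Orientation: rotation by a uniform angle in
    (-π, π] about a uniform random axis.  Torsion: one angle resampled
    uniformly over its full range.  Rigid ligands (Nrot = 0) never select the
    torsion block.
    """
    n_blocks = 2 if c.nrot == 0 else 3
    block = int(rng.integers(n_blocks))
    if block == 0:
        pos = c.position + rng.uniform(
            -params.position_amplitude, params.position_amplitude, 3
        )
        if box is not None:
            pos = np.clip(pos, box.lo, box.hi)
        return Conformation(pos, c.orientation, c.torsions)
    if block == 1:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.pi - rng.random() * 2.0 * np.pi
        rot = np.concatenate([[np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis])
        q = quat_multiply(rot, c.orientation)
        q /= np.linalg.norm(q)
        return Conformation(c.position, q, c.torsions)
    torsions = c.torsions.copy()
    torsions[int(rng.integers(c.nrot))] = np.pi - rng.random() * 2.0 * np.pi
    return Conformation(c.position, c.orientation, torsions)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between fixed-order coordinate sets (Å).

    No re-superposition and no symmetry correction: atoms are compared
    index-by-index, matching the redocking convention where both poses live
    in the receptor frame.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DimensionError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
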