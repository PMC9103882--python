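"""Independent recursive-kinematics oracle and random torsion-tree generator.

Shared by the unit and acceptance suites.  The oracle applies torsions by
direct recursion on the tree (depth-first, parents before children) and the
rigid transform through scipy's Rotation — a code path fully independent of
the flattened iterative kinematics it checks.
"""

import numpy as np
from scipy.spatial.transform import Rotation

import mcdock as m
from mcdock.pdbqt import AtomRecord, BranchNode, LigandTree


def _atom(serial, xyz, atype="C"):
    return AtomRecord(serial, f"C{serial}", atype, np.asarray(xyz, float))


def random_tree(rng) -> LigandTree:
    """Random torsion tree with <= 8 nodes and 1-3 atoms per node."""
    n_nodes = int(rng.integers(1, 9))
    serial = [0]

    def new_atoms(k):
        out = []
        for _ in range(k):
            serial[0] += 1
            out.append(_atom(serial[0], rng.normal(scale=3.0, size=3)))
        return out

    root_atoms = new_atoms(int(rng.integers(1, 4)))
    node_atoms = [root_atoms]
    node_objs: list[BranchNode | None] = [None]
    top_branches: list[BranchNode] = []
    for j in range(1, n_nodes):
        parent = int(rng.integers(0, j))
        atoms = new_atoms(int(rng.integers(1, 4)))
        pa = node_atoms[parent][int(rng.integers(len(node_atoms[parent])))]
        b = BranchNode(pa.serial, atoms[0].serial, atoms)
        node_atoms.append(atoms)
        node_objs.append(b)
        if parent == 0:
            top_branches.append(b)
        else:
            node_objs[parent].children.append(b)
    return LigandTree(root_atoms, top_branches)


def recursive_coords(tree: LigandTree, conf: m.Conformation) -> np.ndarray:
    """Reference coordinates by recursive depth-first torsion application."""
    coords = {a.serial: a.coords.copy() for a in tree.atoms}

    order = []

    def collect(branches):
        for b in branches:
            order.append(b)
            collect(b.children)

    collect(tree.branches)
    psi = {id(b): conf.torsions[k] for k, b in enumerate(order)}

    def subtree_serials(b):
        out = [a.serial for a in b.atoms]
        for c in b.children:
            out.extend(subtree_serials(c))
        return out

    def walk(b):
        p = coords[b.parent_serial]
        u = coords[b.child_serial] - p
        u = u / np.linalg.norm(u)
        rot = Rotation.from_rotvec(psi[id(b)] * u)
        for s in subtree_serials(b):
            coords[s] = rot.apply(coords[s] - p) + p
        for c in b.children:
            walk(c)

    for b in tree.branches:
        walk(b)

    a, bq, cq, dq = conf.orientation
    rigid = Rotation.from_quat([bq, cq, dq, a])  # scipy is scalar-last
    c0 = np.mean([coords[x.serial] for x in tree.root_atoms], axis=0)
    stacked = np.array([coords[x.serial] for x in tree.atoms])
    return rigid.apply(stacked - c0) + conf.position
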