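"""Synthetic docking fixtures with a planted global-minimum pose.

Real benchmark complexes need downloads and preparation; these generators
build small, fully deterministic receptor/ligand pairs in PDBQT text whose
lowest-energy pose is known *by construction*, so every pipeline stage is
testable offline.

The ligand is a zig-zag chain: a rigid root of backbone atoms continued by
``nrot`` nested branches of two atoms each (one on the rotation axis, one
off-axis so every torsion visibly moves atoms).  The first atom is a
nitrogen donor; everything else is hydrophobic carbon.  The receptor is a
groove of carbon atoms placed at near-optimal contact distance above and
below every backbone atom and alongside each off-axis atom, capped by a
hydrogen-bond acceptor (OA) next to the ligand's nitrogen end.  The acceptor
cap breaks the end-to-end flip symmetry of the chain, so the planted pose is
the unique deep minimum and recovery can be judged by plain RMSD.

No real chemistry is modeled and no PDB entry is reproduced; the geometry is
plumbing for a known energy funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conformation import Conformation, flatten_tree, random_conformation
from .errors import ParameterError
from .pdbqt import DockingBox, read_ligand, read_receptor
from .scoring import GridScorer, build_grid_cache

__all__ = [
    "PlantedComplex",
    "make_planted_complex",
    "make_ranked_universe",
    "prepare",
    "write_fixture_files",
]

_BACKBONE_DX = 1.4       # Å along the chain
_BACKBONE_DY = 0.45      # zig-zag amplitude
_OFFAXIS = np.array([0.0, 0.9, 1.3])   # branch off-axis atom offset (|.| = 1.58)
_CONTACT_CC = 3.9        # C-C center distance near the pair-potential minimum
_CONTACT_HBOND = 3.05    # N-OA center distance inside the H-bond well
_BOX_MARGIN = 4.0        # Å added to the ligand extent per axis
_BOX_MIN = 8.0


@dataclass(frozen=True)
class PlantedComplex:
    """A synthetic receptor/ligand pair whose global-minimum pose is known."""

    receptor_text: str
    ligand_text: str
    box: DockingBox
    planted_pose: Conformation
    planted_coords: np.ndarray
    natom: int
    nrot: int
    seed: int


def _atom_line(serial: int, name: str, atype: str, xyz, charge: float = 0.0) -> str:
    return (
        f"ATOM  {serial:>5} {name:<4}LIG A   1    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  0.00  0.00    "
        f"{charge:6.3f} {atype:<2}"
    )


def make_planted_complex(
    natom: int,
    nrot: int,
    seed: int,
    check: bool = True,
    n_check: int = 10_000,
) -> PlantedComplex:
    """Build a deterministic toy complex with ``natom`` ligand atoms and
    ``nrot`` rotatable bonds.

    Needs ``natom >= 2*nrot + 2`` (a two-atom rigid core plus two atoms per
    branch so no torsion is a null coordinate).  ``seed`` adds a small
    deterministic jitter to the receptor atoms so different seeds give
    distinct but equivalent pockets.  With ``check=True`` the planted pose is
    verified to score below ``n_check`` random conformations.
    """
    if natom < 2 * nrot + 2:
        raise ParameterError(
            f"infeasible sizes: need natom >= 2*nrot + 2, got ({natom}, {nrot})"
        )
    rng = np.random.default_rng(seed)

    m = natom - 2 * nrot                   # rigid root backbone atoms
    n_backbone = m + nrot

    def backbone(k: int) -> np.ndarray:
        return np.array([_BACKBONE_DX * k, _BACKBONE_DY * (k % 2), 0.0])

    # ligand atoms in file order: root backbone, then (axis atom, off-axis
    # atom) per branch
    lig_coords = [backbone(k) for k in range(m)]
    lig_types = ["N"] + ["C"] * (m - 1)
    lig_names = ["N1"] + [f"C{k}" for k in range(2, m + 1)]
    offaxis_idx = []
    for j in range(nrot):
        b = backbone(m + j)
        lig_coords.append(b)
        lig_types.append("C")
        lig_names.append(f"C{m + 2 * j + 1}")
        lig_coords.append(b + _OFFAXIS)
        lig_types.append("C")
        lig_names.append(f"C{m + 2 * j + 2}")
        offaxis_idx.append(len(lig_coords) - 1)
    lig_coords = np.array(lig_coords)

    # ligand PDBQT with nested chain branches
    lines = ["ROOT"]
    for k in range(m):
        lines.append(_atom_line(k + 1, lig_names[k], lig_types[k], lig_coords[k]))
    lines.append("ENDROOT")
    for j in range(nrot):
        parent_serial = m + 2 * (j - 1) + 1 if j > 0 else m
        child_serial = m + 2 * j + 1
        lines.append(f"BRANCH {parent_serial:>4} {child_serial:>4}")
        for off in (0, 1):
            idx = m + 2 * j + off
            lines.append(
                _atom_line(idx + 1, lig_names[idx], lig_types[idx], lig_coords[idx])
            )
    for j in range(nrot - 1, -1, -1):
        parent_serial = m + 2 * (j - 1) + 1 if j > 0 else m
        child_serial = m + 2 * j + 1
        lines.append(f"ENDBRANCH {parent_serial:>4} {child_serial:>4}")
    lines.append(f"TORSDOF {nrot}")
    ligand_text = "\n".join(lines) + "\n"

    # receptor groove around the planted (= reference) ligand coordinates:
    # contact atoms above/below every backbone atom, a cap past the tail, and
    # one atom alongside each off-axis branch atom; candidates that would
    # clash with any planted ligand atom (negative surface distance) are
    # dropped so the planted pose sits in a purely attractive pocket
    u_off = _OFFAXIS / np.linalg.norm(_OFFAXIS)
    candidates = []
    for k in range(n_backbone):
        b = backbone(k)
        candidates.append(("C", b + np.array([0.0, 0.0, _CONTACT_CC])))
        candidates.append(("C", b + np.array([0.0, 0.0, -_CONTACT_CC])))
    candidates.append(
        ("C", backbone(n_backbone - 1) + np.array([_CONTACT_CC, 0.0, 0.0]))
    )
    for idx in offaxis_idx:
        candidates.append(("C", lig_coords[idx] + _CONTACT_CC * u_off))

    rec = [("OA", lig_coords[0] + np.array([-_CONTACT_HBOND, 0.0, 0.0]))]
    for atype, xyz in candidates:
        gaps = np.linalg.norm(lig_coords - xyz, axis=1) - (1.9 + 1.9)
        if gaps.min() >= 0.0:
            rec.append((atype, xyz))

    rec_lines = []
    for i, (atype, xyz) in enumerate(rec, start=1):
        jittered = xyz + rng.uniform(-0.05, 0.05, 3)
        rec_lines.append(_atom_line(i, f"R{i}", atype, jittered))
    receptor_text = "\n".join(rec_lines) + "\n"

    extent = lig_coords.max(axis=0) - lig_coords.min(axis=0)
    size = np.maximum(extent + _BOX_MARGIN, _BOX_MIN)
    box = DockingBox(center=lig_coords.mean(axis=0), size=size)

    flat = flatten_tree(read_ligand(ligand_text))
    planted_pose = Conformation(
        flat.root_centroid.copy(), np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(nrot)
    )
    pc = PlantedComplex(
        receptor_text=receptor_text,
        ligand_text=ligand_text,
        box=box,
        planted_pose=planted_pose,
        planted_coords=lig_coords,
        natom=natom,
        nrot=nrot,
        seed=seed,
    )
    if check:
        _spot_check_planted(pc, flat, n_check)
    return pc


def _spot_check_planted(pc: PlantedComplex, flat, n_check: int) -> None:
    receptor = read_receptor(pc.receptor_text)
    cache = build_grid_cache(receptor, pc.box, set(flat.types))
    scorer = GridScorer(flat, cache)
    e_planted = scorer.energy(pc.planted_pose.as_vector())[0]
    rng = np.random.default_rng(pc.seed + 1)
    for _ in range(n_check):
        c = random_conformation(pc.box, pc.nrot, rng)
        if scorer.energy(c.as_vector())[0] < e_planted:
            raise RuntimeError(
                "planted pose is not the sampled minimum; fixture construction broken"
            )


def prepare(pc: PlantedComplex, spacing: float = 0.375):
    """Parse and grid a planted complex: ``(receptor, flat_ligand, cache)``."""
    receptor = read_receptor(pc.receptor_text)
    flat = flatten_tree(read_ligand(pc.ligand_text))
    cache = build_grid_cache(receptor, pc.box, set(flat.types), spacing=spacing)
    return receptor, flat, cache


def write_fixture_files(pc: PlantedComplex, directory) -> dict[str, Path]:
    """Write receptor/ligand PDBQT plus a matching config.txt into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "receptor": directory / "receptor.pdbqt",
        "ligand": directory / "ligand.pdbqt",
        "config": directory / "config.txt",
    }
    paths["receptor"].write_text(pc.receptor_text)
    paths["ligand"].write_text(pc.ligand_text)
    c, s = pc.box.center, pc.box.size
    paths["config"].write_text(
        "receptor = receptor.pdbqt\n"
        "ligand = ligand.pdbqt\n"
        f"center_x = {c[0]:.3f}\ncenter_y = {c[1]:.3f}\ncenter_z = {c[2]:.3f}\n"
        f"size_x = {s[0]:.3f}\nsize_y = {s[1]:.3f}\nsize_z = {s[2]:.3f}\n"
    )
    return paths


def make_ranked_universe(n: int, overlap: float, seed: int):
    """Two rankings of ``n`` synthetic compound ids whose top-(n/10) Jaccard
    index approximates ``overlap``.

    ``overlap = 1`` returns two identical rankings; ``overlap = 0`` returns
    rankings with disjoint top sets.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ParameterError("overlap must be in [0, 1]")
    if n < 10:
        raise ParameterError("need n >= 10")
    rng = np.random.default_rng(seed)
    ids = [f"CMP{k:05d}" for k in range(n)]
    a = list(rng.permutation(ids))
    if overlap == 1.0:
        return a, list(a)
    i = max(1, n // 10)
    s = int(round(2 * i * overlap / (1.0 + overlap)))
    s = min(s, i)
    top_a = a[:i]
    rest_a = a[i:]
    shared = list(rng.choice(top_a, size=s, replace=False)) if s else []
    fresh = list(rng.choice(rest_a, size=i - s, replace=False))
    top_b = shared + fresh
    rng.shuffle(top_b)
    tail_b = [x for x in a if x not in set(top_b)]
    rng.shuffle(tail_b)
    return a, top_b + tail_b
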