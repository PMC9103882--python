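"""Scoring function, grid cache, and pose gradient.

The binding energy of a pose is ``e = einter + eintra``: the ligand-receptor
interaction energy plus the intramolecular energy of eligible ligand atom
pairs.  Both use the published AutoDock Vina functional form — five weighted
terms (two attractive gaussians, a quadratic steric repulsion, a hydrophobic
ramp and a hydrogen-bond ramp) evaluated on the *surface distance*
``d = r − Ri − Rj`` and truncated at an 8 Å center-center cutoff.  Each pair
potential is shifted by its own value at the cutoff so the energy goes to
zero continuously there.

``einter`` is evaluated by trilinear interpolation of per-atom-type grid maps
precomputed over the docking box (the grid cache); ``eintra`` sums direct
pair potentials over ligand atom pairs that are at least 4 bonds apart and
belong to different rigid bodies of the torsion tree.

The gradient of the energy over the (7 + Nrot)-dimensional POT vector is
assembled from per-atom Cartesian forces through the kinematic chain: the
position block is the net force, the quaternion block contracts the forces
with the four derivative matrices of the rotation, and each torsion component
is the torque of its subtree's forces about the bond axis.

Points that leave the grid hull are clamped to it and charged a quadratic
distance penalty (1 kcal/mol/Å² per axis), keeping the optimizer inside the
box with finite, differentiable energies.

The conformational-entropy weighting 1/(1 + w·Nrot) is pose-independent and
is therefore applied only to final reported scores, never during search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import (
    Conformation,
    FlatLigand,
    _forward,
    quat_matrix_derivatives,
)
from .errors import DimensionError, ResourceError, TypingError
from .pdbqt import DockingBox, Receptor

__all__ = [
    "AtomKind",
    "ATOM_KINDS",
    "TERM_WEIGHTS",
    "CUTOFF",
    "NROT_WEIGHT",
    "pair_potential",
    "GridCache",
    "build_grid_cache",
    "interp_energy",
    "ScoredPose",
    "score",
    "gradient",
    "GridScorer",
    "DirectScorer",
    "entropy_weighted_score",
    "export_grid",
]

# Vina term weights (kcal/mol), exposed as a module-level config table.
TERM_WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}

CUTOFF = 8.0          # center-center cutoff, Å
NROT_WEIGHT = 0.05846  # conformational-entropy weight per rotatable bond
_OUT_OF_GRID_PENALTY = 1.0  # kcal/mol/Å² quadratic penalty outside the hull


@dataclass(frozen=True)
class AtomKind:
    """Interaction parameters of one AutoDock atom type."""

    radius: float          # van der Waals radius, Å
    hydrophobic: bool
    donor: bool
    acceptor: bool
    skip: bool = False     # hydrogens carry no interaction terms


ATOM_KINDS: dict[str, AtomKind] = {
    "C": AtomKind(1.9, True, False, False),
    "A": AtomKind(1.9, True, False, False),
    "N": AtomKind(1.8, False, True, False),
    "NA": AtomKind(1.8, False, False, True),
    "O": AtomKind(1.7, False, False, True),
    "OA": AtomKind(1.7, False, False, True),
    "S": AtomKind(2.0, False, False, False),
    "SA": AtomKind(2.0, False, False, True),
    "P": AtomKind(2.1, False, False, False),
    "F": AtomKind(1.5, True, False, False),
    "Cl": AtomKind(1.8, True, False, False),
    "Br": AtomKind(2.0, True, False, False),
    "I": AtomKind(2.2, True, False, False),
    "Mg": AtomKind(1.2, False, True, False),
    "Mn": AtomKind(1.2, False, True, False),
    "Zn": AtomKind(1.2, False, True, False),
    "Ca": AtomKind(1.2, False, True, False),
    "Fe": AtomKind(1.2, False, True, False),
    "H": AtomKind(1.0, False, False, False, skip=True),
    "HD": AtomKind(1.0, False, False, False, skip=True),
}


def _kind(t: str) -> AtomKind:
    try:
        return ATOM_KINDS[t]
    except KeyError:
        raise TypingError(f"unknown AutoDock atom type {t!r}") from None


def _pair_flags(ki: AtomKind, kj: AtomKind) -> tuple[bool, bool]:
    hp = ki.hydrophobic and kj.hydrophobic
    hb = (ki.donor and kj.acceptor) or (ki.acceptor and kj.donor)
    return hp, hb


def _raw_terms(d, hp, hb):
    """Unshifted weighted term sum at surface distance d (vectorized)."""
    d = np.asarray(d, dtype=float)
    v = TERM_WEIGHTS["gauss1"] * np.exp(-((d / 0.5) ** 2))
    v = v + TERM_WEIGHTS["gauss2"] * np.exp(-(((d - 3.0) / 2.0) ** 2))
    v = v + TERM_WEIGHTS["repulsion"] * np.where(d < 0.0, d * d, 0.0)
    v = v + np.where(hp, TERM_WEIGHTS["hydrophobic"], 0.0) * np.clip(1.5 - d, 0.0, 1.0)
    v = v + np.where(hb, TERM_WEIGHTS["hbond"], 0.0) * np.clip(-d / 0.7, 0.0, 1.0)
    return v


def _raw_terms_deriv(d, hp, hb):
    """d/dd of :func:`_raw_terms` (vectorized)."""
    d = np.asarray(d, dtype=float)
    g = TERM_WEIGHTS["gauss1"] * np.exp(-((d / 0.5) ** 2)) * (-8.0 * d)
    g = g + TERM_WEIGHTS["gauss2"] * np.exp(-(((d - 3.0) / 2.0) ** 2)) * (
        -(d - 3.0) / 2.0
    )
    g = g + TERM_WEIGHTS["repulsion"] * np.where(d < 0.0, 2.0 * d, 0.0)
    g = g + np.where(hp, TERM_WEIGHTS["hydrophobic"], 0.0) * np.where(
        (d > 0.5) & (d < 1.5), -1.0, 0.0
    )
    g = g + np.where(hb, TERM_WEIGHTS["hbond"], 0.0) * np.where(
        (d > -0.7) & (d < 0.0), -1.0 / 0.7, 0.0
    )
    return g


def pair_potential(type_i: str, type_j: str, distance: float) -> float:
    """Shifted pair potential (kcal/mol) at center-center ``distance`` (Å).

    Zero for any pair involving a hydrogen type and zero at or beyond the
    8 Å cutoff; continuous (exactly zero) at the cutoff thanks to the shift.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    ki, kj = _kind(type_i), _kind(type_j)
    if ki.skip or kj.skip:
        return 0.0
    if distance >= CUTOFF:
        return 0.0
    hp, hb = _pair_flags(ki, kj)
    rsum = ki.radius + kj.radius
    d = distance - rsum
    dcut = CUTOFF - rsum
    return float(_raw_terms(d, hp, hb) - _raw_terms(dcut, hp, hb))


def _trilinear(flatmaps, strides, tidx, origin, spacing, dims_arr, p, want_grad):
    """Vectorized 8-corner trilinear lookup with hull clamp + quadratic penalty.

    ``flatmaps`` is the raveled (ntypes, nx, ny, nz) stack, ``strides`` its
    element strides, ``tidx`` the per-point map index.  Returns
    ``(values, grads_or_None)``.
    """
    lo = origin
    hi = origin + (dims_arr - 1) * spacing
    excess_lo = np.maximum(lo - p, 0.0)
    excess_hi = np.maximum(p - hi, 0.0)
    penalty = _OUT_OF_GRID_PENALTY * np.sum(excess_lo**2 + excess_hi**2, axis=1)
    pc = np.clip(p, lo, hi)
    f = (pc - lo) * (1.0 / spacing)
    i0 = f.astype(np.int64)
    np.minimum(i0, dims_arr - 2, out=i0)
    w = f - i0
    wx, wy, wz = w[:, 0], w[:, 1], w[:, 2]

    st, sx, sy, sz = strides
    base = tidx * st + i0[:, 0] * sx + i0[:, 1] * sy + i0[:, 2] * sz
    c000 = flatmaps[base]
    c001 = flatmaps[base + sz]
    c010 = flatmaps[base + sy]
    c011 = flatmaps[base + sy + sz]
    c100 = flatmaps[base + sx]
    c101 = flatmaps[base + sx + sz]
    c110 = flatmaps[base + sx + sy]
    c111 = flatmaps[base + sx + sy + sz]

    c00 = c000 + (c100 - c000) * wx
    c01 = c001 + (c101 - c001) * wx
    c10 = c010 + (c110 - c010) * wx
    c11 = c011 + (c111 - c011) * wx
    c0 = c00 + (c10 - c00) * wy
    c1 = c01 + (c11 - c01) * wy
    val = c0 + (c1 - c0) * wz + penalty
    if not want_grad:
        return val, None

    dx00 = c100 - c000
    dx01 = c101 - c001
    dx10 = c110 - c010
    dx11 = c111 - c011
    gx = ((dx00 + (dx10 - dx00) * wy) * (1 - wz)
          + (dx01 + (dx11 - dx01) * wy) * wz) / spacing
    gy = ((c10 - c00) * (1 - wz) + (c11 - c01) * wz) / spacing
    gz = (c1 - c0) / spacing
    grad = np.stack([gx, gy, gz], axis=1)
    clamped = (excess_lo > 0) | (excess_hi > 0)
    grad[clamped] = 0.0
    grad += 2.0 * _OUT_OF_GRID_PENALTY * (excess_hi - excess_lo)
    return val, grad


@dataclass(frozen=True)
class GridCache:
    """Per-atom-type lattice of precomputed receptor interaction energies.

    The lattice covers the docking box plus one cell of margin; ``maps[t]``
    has shape ``dims`` and holds kcal/mol values at lattice nodes.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    maps: dict[str, np.ndarray]
    box: DockingBox

    @property
    def hull_hi(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    def interpolate(self, atype: str, points: np.ndarray):
        """Trilinear interpolation of one type's map at ``points`` (n, 3).

        Returns ``(values, gradients)``; outside the hull the point is
        clamped and a quadratic distance penalty is added (its gradient
        replaces the interpolation gradient along the clamped axes).
        """
        if atype not in self.maps:
            raise TypingError(f"no grid map for atom type {atype!r}")
        values = self.maps[atype]
        p = np.atleast_2d(np.asarray(points, dtype=float))
        nx, ny, nz = self.dims
        strides = (nx * ny * nz, ny * nz, nz, 1)
        val, grad = _trilinear(
            np.ascontiguousarray(values).ravel(),
            strides,
            np.zeros(len(p), dtype=np.int64),
            self.origin,
            self.spacing,
            np.array(self.dims),
            p,
            True,
        )
        return val, grad


def build_grid_cache(
    receptor: Receptor,
    box: DockingBox,
    ligand_types,
    spacing: float = 0.375,
    max_points: int = 20_000_000,
) -> GridCache:
    """Precompute per-type receptor interaction maps over the docking box.

    Each lattice node of each ligand atom type stores the sum of
    :func:`pair_potential` over all receptor atoms within the cutoff.  The
    lattice spans the box plus one cell of margin on every side.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    types = sorted(set(ligand_types))
    for t in types:
        _kind(t)

    lo = box.lo - spacing
    dims = np.ceil((box.size + 2 * spacing) / spacing).astype(int) + 1
    dims = np.maximum(dims, 2)
    n_points = int(np.prod(dims))
    if n_points * max(len(types), 1) > max_points:
        raise ResourceError(
            f"grid of {n_points} points x {len(types)} types exceeds the "
            f"memory guard of {max_points} values; increase spacing or shrink the box"
        )

    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    rec_atoms = [a for a in receptor.atoms if not _kind(a.autodock_type).skip]
    maps = {}
    for t in types:
        kt = ATOM_KINDS[t]
        acc = np.zeros(n_points)
        if not kt.skip:
            for a in rec_atoms:
                ka = ATOM_KINDS[a.autodock_type]
                r = np.linalg.norm(nodes - a.coords, axis=1)
                mask = r < CUTOFF
                if not np.any(mask):
                    continue
                hp, hb = _pair_flags(kt, ka)
                rsum = kt.radius + ka.radius
                d = r[mask] - rsum
                shift = _raw_terms(CUTOFF - rsum, hp, hb)
                acc[mask] += _raw_terms(d, hp, hb) - shift
        maps[t] = acc.reshape(tuple(dims))
    return GridCache(lo, float(spacing), tuple(int(k) for k in dims), maps, box)


def interp_energy(cache: GridCache, atype: str, point: np.ndarray) -> float:
    """Interpolated receptor interaction energy of one atom at ``point``."""
    val, _ = cache.interpolate(atype, np.asarray(point, dtype=float)[None, :])
    return float(val[0])


@dataclass(frozen=True)
class ScoredPose:
    """A conformation with realized coordinates and its energy decomposition."""

    conformation: Conformation
    coords: np.ndarray
    e: float
    einter: float
    eintra: float

    def __post_init__(self):
        if abs(self.e - (self.einter + self.eintra)) > 1e-9:
            raise ValueError("e must equal einter + eintra")


class _PairTable:
    """Precomputed per-pair parameters for the eligible intra-ligand pairs."""

    def __init__(self, flat: FlatLigand):
        kinds = [_kind(t) for t in flat.types]
        pairs = flat.intra_pairs
        keep, rsum, hp, hb, shift = [], [], [], [], []
        for i, j in pairs:
            ki, kj = kinds[i], kinds[j]
            if ki.skip or kj.skip:
                continue
            keep.append((i, j))
            s = ki.radius + kj.radius
            fhp, fhb = _pair_flags(ki, kj)
            rsum.append(s)
            hp.append(fhp)
            hb.append(fhb)
            shift.append(float(_raw_terms(CUTOFF - s, fhp, fhb)))
        self.idx = np.array(keep, dtype=int) if keep else np.empty((0, 2), dtype=int)
        self.rsum = np.array(rsum)
        self.hp = np.array(hp, dtype=bool)
        self.hb = np.array(hb, dtype=bool)
        self.shift = np.array(shift)

    def energy_forces(self, coords: np.ndarray, forces: np.ndarray | None):
        if len(self.idx) == 0:
            return 0.0
        i, j = self.idx[:, 0], self.idx[:, 1]
        diff = coords[i] - coords[j]
        r = np.linalg.norm(diff, axis=1)
        mask = r < CUTOFF
        d = r - self.rsum
        vals = np.where(mask, _raw_terms(d, self.hp, self.hb) - self.shift, 0.0)
        if forces is not None:
            dv = np.where(mask, _raw_terms_deriv(d, self.hp, self.hb), 0.0)
            f = (dv / np.maximum(r, 1e-12))[:, None] * diff
            np.add.at(forces, i, f)
            np.add.at(forces, j, -f)
        return float(vals.sum())


def _chain_rule(flat: FlatLigand, x, coords, t, axes, forces):
    """Map per-atom Cartesian forces to the (7 + Nrot) POT gradient."""
    q = x[3:7]
    grad = np.empty(7 + flat.nrot)
    grad[:3] = forces.sum(axis=0)
    rel = t - flat.root_centroid
    dR = quat_matrix_derivatives(q)
    for k in range(4):
        grad[3 + k] = float(np.sum(forces * (rel @ dR[k].T)))
    for jn in range(1, len(flat.nodes)):
        p_f, u_f = axes[jn]
        sub = flat.nodes[jn].subtree_idx
        arm = coords[sub] - p_f
        grad[7 + jn - 1] = float(np.sum(forces[sub] * np.cross(u_f, arm)))
    return grad


class GridScorer:
    """Fast energy/gradient evaluator binding one ligand to one grid cache."""

    def __init__(self, flat: FlatLigand, cache: GridCache):
        self.flat = flat
        self.cache = cache
        self.pairs = _PairTable(flat)
        # one stacked flat lookup for all non-hydrogen atoms
        used = sorted({t for t in flat.types if not _kind(t).skip})
        type_pos = {t: k for k, t in enumerate(used)}
        self.heavy_idx = np.array(
            [i for i, t in enumerate(flat.types) if not _kind(t).skip], dtype=int
        )
        self.tidx = np.array(
            [type_pos[flat.types[i]] for i in self.heavy_idx], dtype=np.int64
        )
        stack = np.stack([np.ascontiguousarray(cache.maps[t]) for t in used])
        self._flatmaps = stack.ravel()
        nx, ny, nz = cache.dims
        self._strides = (nx * ny * nz, ny * nz, nz, 1)
        self._dims_arr = np.array(cache.dims)

    def _inter(self, coords, want_grad):
        vals, grads = _trilinear(
            self._flatmaps,
            self._strides,
            self.tidx,
            self.cache.origin,
            self.cache.spacing,
            self._dims_arr,
            coords[self.heavy_idx],
            want_grad,
        )
        return float(vals.sum()), grads

    def energy(self, x: np.ndarray):
        """(e, einter, eintra, coords) at a raw pose vector."""
        coords = _forward(self.flat, x)[0]
        einter, _ = self._inter(coords, False)
        eintra = self.pairs.energy_forces(coords, None)
        return einter + eintra, einter, eintra, coords

    def energy_and_gradient(self, x: np.ndarray):
        coords, t_coords, _, axes = _forward(self.flat, x)
        forces = np.zeros_like(coords)
        einter, grads = self._inter(coords, True)
        forces[self.heavy_idx] += grads
        eintra = self.pairs.energy_forces(coords, forces)
        grad = _chain_rule(self.flat, x, coords, t_coords, axes, forces)
        return einter + eintra, grad


class DirectScorer:
    """Grid-free evaluator: einter by direct ligand-receptor pair sums.

    Used for host-side refinement of top poses (removing interpolation error)
    and as the independent oracle against the grid pathway.
    """

    def __init__(self, flat: FlatLigand, receptor: Receptor):
        self.flat = flat
        rec = [a for a in receptor.atoms if not _kind(a.autodock_type).skip]
        self.rec_coords = np.array([a.coords for a in rec])
        lig_idx, rsum, hp, hb, shift = [], [], [], [], []
        for i, tname in enumerate(flat.types):
            ki = _kind(tname)
            if ki.skip:
                continue
            for a in rec:
                ka = ATOM_KINDS[a.autodock_type]
                s = ki.radius + ka.radius
                fhp, fhb = _pair_flags(ki, ka)
                lig_idx.append(i)
                rsum.append(s)
                hp.append(fhp)
                hb.append(fhb)
                shift.append(float(_raw_terms(CUTOFF - s, fhp, fhb)))
        self.lig_idx = np.array(lig_idx, dtype=int)
        n_rec = len(rec)
        self.rec_idx = (
            np.tile(np.arange(n_rec), len(self.lig_idx) // n_rec)
            if n_rec
            else np.empty(0, dtype=int)
        )
        self.rsum = np.array(rsum)
        self.hp = np.array(hp, dtype=bool)
        self.hb = np.array(hb, dtype=bool)
        self.shift = np.array(shift)
        self.pairs = _PairTable(flat)

    def _inter(self, coords, forces):
        if len(self.lig_idx) == 0:
            return 0.0
        diff = coords[self.lig_idx] - self.rec_coords[self.rec_idx]
        r = np.linalg.norm(diff, axis=1)
        mask = r < CUTOFF
        d = r - self.rsum
        vals = np.where(mask, _raw_terms(d, self.hp, self.hb) - self.shift, 0.0)
        if forces is not None:
            dv = np.where(mask, _raw_terms_deriv(d, self.hp, self.hb), 0.0)
            f = (dv / np.maximum(r, 1e-12))[:, None] * diff
            np.add.at(forces, self.lig_idx, f)
        return float(vals.sum())

    def energy(self, x: np.ndarray):
        coords = _forward(self.flat, x)[0]
        einter = self._inter(coords, None)
        eintra = self.pairs.energy_forces(coords, None)
        return einter + eintra, einter, eintra, coords

    def energy_and_gradient(self, x: np.ndarray):
        coords, t_coords, _, axes = _forward(self.flat, x)
        forces = np.zeros_like(coords)
        einter = self._inter(coords, forces)
        eintra = self.pairs.energy_forces(coords, forces)
        grad = _chain_rule(self.flat, x, coords, t_coords, axes, forces)
        return einter + eintra, grad


def score(flat: FlatLigand, c: Conformation, cache: GridCache) -> ScoredPose:
    """Score one conformation against the grid cache."""
    if c.nrot != flat.nrot:
        raise DimensionError(
            f"conformation has {c.nrot} torsions, ligand has {flat.nrot}"
        )
    e, einter, eintra, coords = GridScorer(flat, cache).energy(c.as_vector())
    return ScoredPose(c, coords, e, einter, eintra)


def gradient(flat: FlatLigand, c: Conformation, cache: GridCache) -> np.ndarray:
    """Analytic gradient of the energy over the (7 + Nrot) POT vector."""
    if c.nrot != flat.nrot:
        raise DimensionError(
            f"conformation has {c.nrot} torsions, ligand has {flat.nrot}"
        )
    return GridScorer(flat, cache).energy_and_gradient(c.as_vector())[1]


def entropy_weighted_score(einter: float, nrot: int, w: float = NROT_WEIGHT) -> float:
    """Final reported affinity: intermolecular energy damped by 1/(1 + w·Nrot)."""
    return einter / (1.0 + w * nrot)


def export_grid(cache: GridCache, atype: str) -> str:
    """Plain-text dump of one type's map: header + one value per line."""
    if atype not in cache.maps:
        raise TypingError(f"no grid map for atom type {atype!r}")
    d = cache.dims
    header = (
        f"# origin {cache.origin[0]:.6f} {cache.origin[1]:.6f} {cache.origin[2]:.6f}\n"
        f"# spacing {cache.spacing:.6f}\n"
        f"# dims {d[0]} {d[1]} {d[2]}\n"
        f"# type {atype}\n"
    )
    body = "\n".join(f"{v:.6e}" for v in cache.maps[atype].ravel())
    return header + body + "\n"
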