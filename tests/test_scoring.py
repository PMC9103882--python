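"""Pair potential, grid cache, trilinear interpolation, energy and gradient."""

import numpy as np
import pytest

import mcdock as m
from mcdock.errors import ResourceError, TypingError
from mcdock.pdbqt import AtomRecord, DockingBox, LigandTree, Receptor
from mcdock.scoring import (
    CUTOFF,
    DirectScorer,
    GridCache,
    GridScorer,
    export_grid,
)


def _atom(serial, xyz, atype="C"):
    return AtomRecord(serial, f"X{serial}", atype, np.asarray(xyz, float))


def _single_atom_ligand(atype="C"):
    return m.flatten_tree(LigandTree([_atom(1, [0.0, 0.0, 0.0], atype)]))


class TestPairPotential:
    def test_zero_beyond_cutoff(self):
        for pair in [("C", "C"), ("N", "OA"), ("A", "S")]:
            assert m.pair_potential(*pair, 8.0) == 0.0
            assert m.pair_potential(*pair, 11.0) == 0.0

    def test_cc_contact_value_from_independent_arithmetic(self):
        # hand-summed weighted terms at surface distance 0 for a C-C pair
        # (radii 1.9 + 1.9), including the shift that zeroes the cutoff
        def raw(d):
            v = -0.035579 * np.exp(-((d / 0.5) ** 2))
            v += -0.005156 * np.exp(-(((d - 3.0) / 2.0) ** 2))
            v += 0.840245 * (d * d if d < 0 else 0.0)
            v += -0.035069 * min(max((1.5 - d), 0.0), 1.0)  # both hydrophobic
            return v

        expected = raw(0.0) - raw(8.0 - 3.8)
        assert m.pair_potential("C", "C", 3.8) == pytest.approx(expected, abs=1e-12)

    def test_continuous_at_cutoff(self):
        # numeric sweep approaching the cutoff from below
        for pair in [("C", "C"), ("N", "OA")]:
            v = m.pair_potential(*pair, CUTOFF - 1e-7)
            assert abs(v) < 1e-6

    def test_hydrogens_are_inert(self):
        assert m.pair_potential("HD", "OA", 2.0) == 0.0
        assert m.pair_potential("C", "H", 1.0) == 0.0

    def test_unknown_type(self):
        with pytest.raises(TypingError):
            m.pair_potential("Xx", "C", 3.0)

    def test_repulsive_at_overlap(self):
        assert m.pair_potential("C", "C", 1.0) > 1.0


def _linear_cache(coeffs=(2.0, 3.0, 4.0), spacing=0.5, n=9):
    """Cache whose single map samples the trilinear field a·x + b·y + c·z."""
    origin = np.array([-1.0, -1.0, -1.0])
    ax = [origin[k] + spacing * np.arange(n) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    vals = coeffs[0] * gx + coeffs[1] * gy + coeffs[2] * gz
    box = DockingBox(origin + spacing * (n - 1) / 2, np.full(3, spacing * (n - 3)))
    return GridCache(origin, spacing, (n, n, n), {"C": vals}, box)


class TestInterpolation:
    def test_exact_at_lattice_nodes(self):
        cache = _linear_cache()
        for idx in [(0, 0, 0), (3, 1, 4), (8, 8, 8)]:
            point = cache.origin + cache.spacing * np.array(idx)
            assert m.interp_energy(cache, "C", point) == pytest.approx(
                cache.maps["C"][idx], abs=1e-12
            )

    def test_trilinear_field_reproduced_exactly(self):
        """A trilinear polynomial is in the interpolation space, so random
        interior points must be reproduced to 1e-10."""
        cache = _linear_cache()
        rng = np.random.default_rng(3)
        lo, hi = cache.origin, cache.hull_hi
        for _ in range(200):
            p = lo + rng.random(3) * (hi - lo)
            want = 2.0 * p[0] + 3.0 * p[1] + 4.0 * p[2]
            assert m.interp_energy(cache, "C", p) == pytest.approx(want, abs=1e-10)

    def test_constant_cell(self):
        cache = _linear_cache()
        flat_map = {"C": np.full((5, 5, 5), 7.25)}
        const = GridCache(cache.origin, 0.5, (5, 5, 5), flat_map, cache.box)
        center = const.origin + 0.25  # cell-center point
        assert m.interp_energy(const, "C", center) == pytest.approx(7.25, abs=1e-12)

    def test_unknown_type(self):
        with pytest.raises(TypingError):
            m.interp_energy(_linear_cache(), "OA", np.zeros(3))

    def test_outside_hull_penalized_and_continuous(self):
        cache = _linear_cache()
        edge = cache.hull_hi
        inside = m.interp_energy(cache, "C", edge - 1e-9)
        at = m.interp_energy(cache, "C", edge)
        outside = m.interp_energy(cache, "C", edge + np.array([0.5, 0, 0]))
        assert at == pytest.approx(inside, abs=1e-6)
        assert outside == pytest.approx(at + 1.0 * 0.5**2, abs=1e-9)


class TestBuildGridCache:
    BOX = DockingBox([0, 0, 0], [6.0, 6.0, 6.0])

    def test_distant_receptor_gives_zero_lattice(self):
        rec = Receptor((_atom(1, [100.0, 0, 0]),))
        cache = m.build_grid_cache(rec, self.BOX, {"C"}, spacing=0.75)
        assert np.all(cache.maps["C"] == 0.0)

    def test_node_value_matches_direct_pair_potential(self):
        rec = Receptor((_atom(1, [1.0, 2.0, 3.0], "OA"),))
        cache = m.build_grid_cache(rec, self.BOX, {"N"}, spacing=0.5)
        idx = (4, 5, 6)
        node = cache.origin + cache.spacing * np.array(idx)
        want = m.pair_potential("N", "OA", float(np.linalg.norm(node - [1, 2, 3])))
        assert cache.maps["N"][idx] == pytest.approx(want, abs=1e-12)

    def test_refinement_consistency_at_coincident_nodes(self):
        rec = Receptor((_atom(1, [0.5, 0.5, 0.5]),))
        coarse = m.build_grid_cache(rec, self.BOX, {"C"}, spacing=1.0)
        fine = m.build_grid_cache(rec, self.BOX, {"C"}, spacing=0.5)
        # origins differ by half a coarse cell (margin is one cell of each
        # spacing), so coarse node k coincides with fine node 2k - 1
        for k in [(1, 1, 1), (3, 5, 2), (7, 7, 7)]:
            node_c = coarse.origin + coarse.spacing * np.array(k)
            j = tuple(2 * np.array(k) - 1)
            node_f = fine.origin + fine.spacing * np.array(j)
            np.testing.assert_allclose(node_c, node_f, atol=1e-12)
            assert coarse.maps["C"][k] == pytest.approx(
                fine.maps["C"][j], abs=1e-12
            )

    def test_memory_guard(self):
        rec = Receptor((_atom(1, [0, 0, 0]),))
        with pytest.raises(ResourceError):
            m.build_grid_cache(rec, self.BOX, {"C"}, spacing=0.5, max_points=100)

    def test_lattice_covers_box_with_margin(self):
        rec = Receptor((_atom(1, [0, 0, 0]),))
        cache = m.build_grid_cache(rec, self.BOX, {"C"}, spacing=0.375)
        assert np.all(cache.origin <= self.BOX.lo - cache.spacing + 1e-12)
        assert np.all(cache.hull_hi >= self.BOX.hi + cache.spacing - 1e-12)


class TestScore:
    def test_single_atom_has_no_intra(self):
        flat = _single_atom_ligand()
        rec = Receptor((_atom(1, [3.9, 0, 0]),))
        box = DockingBox([0, 0, 0], [8, 8, 8])
        cache = m.build_grid_cache(rec, box, set(flat.types))
        c = m.Conformation(np.zeros(3), [1, 0, 0, 0], np.zeros(0))
        pose = m.score(flat, c, cache)
        assert pose.eintra == 0.0
        assert pose.e == pose.einter
        assert pose.e == pytest.approx(pose.einter + pose.eintra, abs=1e-12)

    def test_grid_score_matches_grid_free_oracle(self, planted12, prep12):
        """Grid interpolation agrees with direct receptor pair sums to within
        the trilinear error bound at 0.375 Å spacing.  The piecewise-linear
        hydrophobic/H-bond ramps have slope kinks, so per pair the error can
        reach ~slope·h/2 (≈0.16 kcal/mol for an H-bond pair at its kink);
        summed over the handful of contact pairs of this pocket the bound is
        ~0.6 kcal/mol."""
        rec, flat, cache = prep12
        gs = GridScorer(flat, cache)
        ds = DirectScorer(flat, rec)
        rng = np.random.default_rng(5)
        x = planted12.planted_pose.as_vector()
        for _ in range(10):
            xp = x.copy()
            xp[:3] += rng.uniform(-0.5, 0.5, 3)
            e_grid = gs.energy(xp)[0]
            e_direct = ds.energy(xp)[0]
            assert e_grid == pytest.approx(e_direct, abs=0.6)

    def test_receptor_symmetry_gives_equal_scores(self):
        # receptor symmetric under z -> -z: mirrored single-atom poses tie
        rec = Receptor((_atom(1, [0, 0, 2.0]), _atom(2, [0, 0, -2.0])))
        flat = _single_atom_ligand()
        box = DockingBox([0, 0, 0], [8, 8, 8])
        cache = m.build_grid_cache(rec, box, {"C"}, spacing=0.25)
        up = m.Conformation([0.3, 0.1, 1.0], [1, 0, 0, 0], np.zeros(0))
        dn = m.Conformation([0.3, 0.1, -1.0], [1, 0, 0, 0], np.zeros(0))
        assert m.score(flat, up, cache).e == pytest.approx(
            m.score(flat, dn, cache).e, abs=1e-6
        )

    def test_score_stable_under_reparse(self, planted12, prep12):
        rec, flat, cache = prep12
        flat2 = m.flatten_tree(m.read_ligand(planted12.ligand_text))
        c = planted12.planted_pose
        assert m.score(flat, c, cache).e == m.score(flat2, c, cache).e


class TestGradient:
    def test_matches_finite_differences(self, planted12, prep12):
        _, flat, cache = prep12
        gs = GridScorer(flat, cache)
        rng = np.random.default_rng(11)
        h = 1e-5
        for _ in range(10):
            x = m.random_conformation(planted12.box, flat.nrot, rng).as_vector()
            _, g = gs.energy_and_gradient(x)
            fd = np.empty_like(g)
            for k in range(len(x)):
                xp, xm = x.copy(), x.copy()
                xp[k] += h
                xm[k] -= h
                fd[k] = (gs.energy(xp)[0] - gs.energy(xm)[0]) / (2 * h)
            err = np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1.0)
            assert err < 1e-4

    def test_uniform_field_has_zero_position_gradient(self):
        flat = _single_atom_ligand()
        box = DockingBox([0, 0, 0], [6, 6, 6])
        maps = {"C": np.full((9, 9, 9), 3.0)}
        cache = GridCache(np.array([-4.0, -4.0, -4.0]), 1.0, (9, 9, 9), maps, box)
        c = m.Conformation(np.zeros(3), [1, 0, 0, 0], np.zeros(0))
        g = m.gradient(flat, c, cache)
        np.testing.assert_allclose(g[:3], 0.0, atol=1e-12)

    def test_zero_at_symmetric_minimum(self):
        # single atom at the center of an octahedral cage: position gradient
        # vanishes by symmetry; orientation/torsion blocks are trivially zero
        d = 3.9
        atoms = tuple(
            _atom(i + 1, xyz)
            for i, xyz in enumerate(
                [[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d]]
            )
        )
        rec = Receptor(atoms)
        flat = _single_atom_ligand()
        box = DockingBox([0, 0, 0], [4, 4, 4])
        ds = DirectScorer(flat, rec)
        c = m.Conformation(np.zeros(3), [1, 0, 0, 0], np.zeros(0))
        _, g = ds.energy_and_gradient(c.as_vector())
        assert np.linalg.norm(g) < 1e-4


def test_entropy_weighting_only_scales_reported_score():
    assert m.entropy_weighted_score(-8.0, 0) == -8.0
    assert m.entropy_weighted_score(-8.0, 5) == pytest.approx(
        -8.0 / (1 + 0.05846 * 5)
    )


def test_export_grid_roundtrip():
    cache = _linear_cache(n=4)
    text = export_grid(cache, "C")
    lines = text.splitlines()
    assert lines[0].startswith("# origin")
    assert lines[2] == "# dims 4 4 4"
    vals = np.array([float(v) for v in lines[4:]])
    np.testing.assert_allclose(vals, cache.maps["C"].ravel(), rtol=1e-6)
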