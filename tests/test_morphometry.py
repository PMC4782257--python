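"""GPA, bending energy, semi-landmark sliding and tangent projection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import morphoevo as me
from morphoevo.errors import DegenerateGeometryError, InvalidArgumentError
from morphoevo.morphometry import _slide_one, bending_energy

from conftest import opa_distance, random_configs


def similarity_copy(points, theta, scale, shift):
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return points @ R.T * scale + np.asarray(shift)


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert me.centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_similarity_behaviour(self, seed):
        """Invariant to rotation/translation; doubling coordinates doubles size."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(7, 2))
        cs = me.centroid_size(pts)
        moved = similarity_copy(pts, rng.uniform(0, 2 * np.pi), 1.0, rng.normal(size=2))
        assert me.centroid_size(moved) == pytest.approx(cs, rel=1e-10)
        assert me.centroid_size(2 * pts) == pytest.approx(2 * cs, rel=1e-12)

    def test_single_point(self):
        assert me.centroid_size(np.array([[3.0, 4.0]])) == 0.0


class TestGPA:
    def test_identical_configs_zero_distance(self, cranium):
        cfgs = [
            me.LandmarkConfiguration(f"s{i}", cranium.points.copy()) for i in range(3)
        ]
        s = me.gpa_align(cfgs)
        d = np.linalg.norm(s.shapes[0] - s.shapes[1])
        assert d <= 1e-12

    def test_similarity_invariance(self, cranium):
        base = cranium.points
        cfgs = [
            me.LandmarkConfiguration("a", base.copy()),
            me.LandmarkConfiguration("b", similarity_copy(base, np.pi / 2, 3.0, [10, -4])),
        ]
        s = me.gpa_align(cfgs)
        assert np.linalg.norm(s.shapes[0] - s.shapes[1]) <= 1e-10

    def test_output_invariant_to_input_similarity_and_order(self, cranium):
        cfgs = random_configs(cranium, 12, noise=0.02, seed=3, with_nuisance=False)
        rng = np.random.default_rng(0)
        disguised = [
            me.LandmarkConfiguration(
                c.specimen_id,
                similarity_copy(
                    c.points, rng.uniform(0, 2 * np.pi), rng.uniform(0.2, 5), rng.normal(size=2)
                ),
            )
            for c in cfgs
        ]
        a = me.gpa_align(cfgs)
        b = me.gpa_align(disguised)
        np.testing.assert_allclose(a.shapes, b.shapes, atol=1e-8)
        order = rng.permutation(len(cfgs))
        c = me.gpa_align([cfgs[i] for i in order])
        np.testing.assert_allclose(
            a.shapes[order], c.shapes, atol=1e-8
        )

    def test_pairwise_distance_matches_brute_force(self):
        """GPA of a pair equals the brute-force 1-D rotation-search
        full Procrustes distance, for three random 4-point shapes."""
        rng = np.random.default_rng(42)
        shapes = [rng.normal(size=(4, 2)) for _ in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                s = me.gpa_align(
                    [
                        me.LandmarkConfiguration("a", shapes[i]),
                        me.LandmarkConfiguration("b", shapes[j]),
                    ]
                )
                got = np.linalg.norm(s.shapes[0] - s.shapes[1])
                want = opa_distance(shapes[i], shapes[j])
                assert got == pytest.approx(want, abs=1e-6)

    def test_collinear_configuration_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5)])
        cfgs = [
            me.LandmarkConfiguration("a", line + [0, 1e-16]),
            me.LandmarkConfiguration("b", line * 2 + [3, 0]),
        ]
        with pytest.raises(DegenerateGeometryError):
            me.gpa_align(cfgs)

    def test_needs_two_configs(self, cranium):
        with pytest.raises(InvalidArgumentError):
            me.gpa_align([me.LandmarkConfiguration("a", cranium.points)])


class TestBendingEnergy:
    def test_affine_annihilation(self, cranium):
        B = me.bending_energy_matrix(cranium.points)
        k = cranium.k
        np.testing.assert_allclose(B @ np.ones(k), 0, atol=1e-10)
        np.testing.assert_allclose(B @ cranium.points[:, 0], 0, atol=1e-10)
        np.testing.assert_allclose(B @ cranium.points[:, 1], 0, atol=1e-10)

    def test_positive_semidefinite(self, cranium, mandible):
        for tmpl in (cranium, mandible):
            B = me.bending_energy_matrix(tmpl.points)
            assert np.linalg.eigvalsh(B).min() >= -1e-10

    def test_affine_deformation_costs_nothing(self):
        ref = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.3]])
        B = me.bending_energy_matrix(ref)
        A = np.array([[1.2, 0.3], [-0.1, 0.9]])
        target = ref @ A.T + [0.4, -0.2]
        assert bending_energy(target, B) == pytest.approx(0.0, abs=1e-10)

    def test_collinear_reference_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            me.bending_energy_matrix(np.column_stack([np.arange(5.0), np.arange(5.0)]))


class TestSliding:
    def test_already_at_minimum_fixed_point(self, cranium):
        """Similarity copies of the reference have zero bending energy;
        sliding must not move anything."""
        cfgs = [
            me.LandmarkConfiguration(
                f"s{i}", similarity_copy(cranium.points, 0.3 * i, 1 + 0.2 * i, [i, -i])
            ).with_roles(cranium)
            for i in range(4)
        ]
        s = me.gpa_align(cfgs)
        slid = me.slide_semilandmarks(s)
        assert slid.sliding_info["max_displacement"] <= 1e-8

    def test_descent_property(self, cranium):
        """Within one iteration (fixed reference) sliding never increases
        bending energy."""
        cfgs = random_configs(cranium, 15, noise=0.02, seed=7)
        s = me.gpa_align(cfgs)
        slid = me.slide_semilandmarks(s, max_iter=4)
        for e_pre, e_post in slid.sliding_info["energy"]:
            assert e_post <= e_pre + 1e-12

    def test_single_free_semilandmark_matches_scalar_oracle(self, cranium):
        """With one semi-landmark free, the slide equals a 1-D brute-force
        minimisation of the bending energy along the tangent."""
        rng = np.random.default_rng(11)
        ref = cranium.points
        B = me.bending_energy_matrix(ref)
        pts = ref + rng.normal(0, 0.02, ref.shape)
        free = 16  # 1-based index of the only sliding point
        semi0 = np.array([free - 1])
        curves0 = {free - 1: tuple(v - 1 for v in cranium.curves[free])}
        slid, _ = _slide_one(pts, B, semi0, curves0)

        a, b = curves0[free - 1]
        u = pts[b] - pts[a]
        u = u / np.linalg.norm(u)

        def energy(t):
            q = pts.copy()
            q[free - 1] += t * u
            return bending_energy(q, B)

        ts = np.linspace(-0.5, 0.5, 20001)
        t_star = ts[np.argmin([energy(t) for t in ts])]
        # refine by golden section
        lo, hi = t_star - 1e-4, t_star + 1e-4
        gr = (np.sqrt(5) - 1) / 2
        for _ in range(100):
            m1, m2 = hi - gr * (hi - lo), lo + gr * (hi - lo)
            if energy(m1) < energy(m2):
                hi = m2
            else:
                lo = m1
        t_star = 0.5 * (lo + hi)
        got_t = float((slid[free - 1] - pts[free - 1]) @ u)
        assert got_t == pytest.approx(t_star, abs=1e-6)

    def test_coincident_neighbours_rejected(self, cranium):
        pts = cranium.points.copy()
        pts[14] = pts[16 - 1 - 1]  # make semi-landmark 16's neighbours coincide
        pts[16] = pts[14]
        cfgs = [
            me.LandmarkConfiguration("a", pts + 1e-9 * np.arange(38).reshape(19, 2)).with_roles(cranium),
            me.LandmarkConfiguration("b", cranium.points).with_roles(cranium),
        ]
        s = me.gpa_align(cfgs)
        s.shapes[0][14] = s.shapes[0][16]  # force zero-length tangent post-GPA
        with pytest.raises(DegenerateGeometryError):
            me.slide_semilandmarks(s)


class TestTangentSpace:
    def test_projection_idempotent_and_fixes_mean(self, cranium):
        cfgs = random_configs(cranium, 10, noise=0.02, seed=5)
        s = me.gpa_align(cfgs)
        once = me.tangent_project(s)
        s2 = me.AlignedSample(
            shapes=once.reshape(s.n, s.k, 2),
            centroid_sizes=s.centroid_sizes,
            mean_shape=s.mean_shape,
            tangent_coords=once,
            specimen_ids=s.specimen_ids,
        )
        twice = me.tangent_project(s2)
        np.testing.assert_allclose(once, twice, atol=1e-12)
        m = s.mean_shape.reshape(-1)
        s_mean = me.AlignedSample(
            shapes=m.reshape(1, s.k, 2),
            centroid_sizes=np.ones(1),
            mean_shape=s.mean_shape,
            tangent_coords=np.empty((1, 2 * s.k)),
            specimen_ids=["m"],
        )
        np.testing.assert_allclose(me.tangent_project(s_mean)[0], m, atol=1e-12)

    def test_small_deviation_distance_agreement(self, cranium):
        """Tangent distances track full Procrustes distances within 1% for
        distances below 0.05."""
        rng = np.random.default_rng(17)
        base = cranium.points
        cfgs = [me.LandmarkConfiguration("ref", base)]
        for i in range(6):
            cfgs.append(
                me.LandmarkConfiguration(f"d{i}", base + rng.normal(0, 0.003, base.shape))
            )
        s = me.gpa_align(cfgs)
        for i in range(1, len(cfgs)):
            tangent_d = np.linalg.norm(s.tangent_coords[0] - s.tangent_coords[i])
            full_d = opa_distance(cfgs[0].points, cfgs[i].points)
            assert 0 < tangent_d < 0.05
            assert tangent_d == pytest.approx(full_d, rel=0.01)


class TestDisparity:
    def test_identical_shapes_zero(self, cranium):
        cfgs = [
            me.LandmarkConfiguration(f"s{i}", similarity_copy(cranium.points, i, 1 + i, [i, 0]))
            for i in range(3)
        ]
        s = me.gpa_align(cfgs)
        assert me.mean_sq_procrustes_distance(s) == pytest.approx(0.0, abs=1e-20)

    def test_two_point_case(self, cranium):
        rng = np.random.default_rng(23)
        cfgs = [
            me.LandmarkConfiguration("a", cranium.points),
            me.LandmarkConfiguration("b", cranium.points + rng.normal(0, 0.005, (19, 2))),
        ]
        s = me.gpa_align(cfgs)
        d = np.linalg.norm(s.tangent_coords[0] - s.tangent_coords[1])
        assert me.mean_sq_procrustes_distance(s) == pytest.approx(d**2 / 4, rel=1e-10)

    def test_invariant_to_specimen_order(self, cranium):
        cfgs = random_configs(cranium, 9, noise=0.02, seed=31)
        p2 = me.mean_sq_procrustes_distance(me.gpa_align(cfgs))
        rng = np.random.default_rng(1)
        order = rng.permutation(9)
        p2_perm = me.mean_sq_procrustes_distance(me.gpa_align([cfgs[i] for i in order]))
        assert p2 == pytest.approx(p2_perm, rel=1e-8)
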