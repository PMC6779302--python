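"""IB transfer operators and finite-element force assembly."""

import numpy as np
import pytest

from heartfsi import ibfe
from heartfsi.ibfe import (
    LagrangianMesh,
    OutOfDomainError,
    Region,
    TetherSet,
    delta_kernel,
    interpolate_velocity,
    spread_forces,
    tether_forces,
)

RNG = np.random.default_rng(2024)
N, L = 32, 8.0
H = L / N


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


if HAVE_HYPOTHESIS:

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_kernel_partition_of_unity_property(r):
        s = sum(delta_kernel(r - j) for j in range(-3, 4))
        assert abs(s - 1.0) < 1e-13

    @given(
        st.floats(min_value=0.5, max_value=7.5),
        st.floats(min_value=0.5, max_value=7.5),
        st.floats(min_value=-10.0, max_value=10.0),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_spreading_conserves_any_point_force(x, y, fx, fy):
        f = spread_forces(np.array([[fx, fy]]), np.array([[x, y]]), N, L)
        total = f.sum(axis=(1, 2)) * H**2
        assert abs(total[0] - fx) < 1e-12 and abs(total[1] - fy) < 1e-12


class TestDeltaKernel:
    def test_compact_support(self):
        r = np.array([-3.0, -2.0, 2.0, 2.5, 10.0])
        np.testing.assert_array_equal(delta_kernel(r), 0.0)

    def test_value_at_origin(self):
        assert delta_kernel(0.0) == pytest.approx(0.5)

    def test_partition_of_unity(self):
        r = RNG.uniform(0.0, 1.0, 50)
        s = sum(delta_kernel(r - j) for j in range(-3, 4))
        np.testing.assert_allclose(s, 1.0, atol=1e-14)

    def test_even_symmetry(self):
        r = RNG.uniform(0.0, 2.0, 20)
        np.testing.assert_allclose(delta_kernel(r), delta_kernel(-r))


class TestSpreadInterp:
    def test_zero_forces_zero_field(self):
        pts = RNG.uniform(1, 7, (10, 2))
        f = spread_forces(np.zeros((10, 2)), pts, N, L)
        np.testing.assert_array_equal(f, 0.0)

    def test_single_force_at_grid_node_stencil(self):
        # weights reproduce the tensor-product kernel stencil; cells sum to 1/h^d
        pts = np.array([[2.0, 3.0]])  # exactly on a grid node
        f = spread_forces(np.array([[1.0, 0.0]]), pts, N, L)
        assert f[0].sum() * H**2 == pytest.approx(1.0, abs=1e-14)
        i, j = int(2.0 / H), int(3.0 / H)
        # on-node spreading uses the 1-D stencil phi(-1),phi(0),phi(1)
        w = [delta_kernel(-1.0), delta_kernel(0.0), delta_kernel(1.0)]
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                assert f[0][i + a, j + b] * H**2 == pytest.approx(
                    w[a + 1] * w[b + 1], abs=1e-14
                )

    def test_total_force_conserved(self):
        pts = RNG.uniform(0.5, 7.5, (40, 2))
        F = RNG.standard_normal((40, 2))
        f = spread_forces(F, pts, N, L)
        np.testing.assert_allclose(f.sum(axis=(1, 2)) * H**2, F.sum(axis=0), atol=1e-12)

    def test_first_moment_conserved(self):
        # torque about the domain centre matches the point-force torque
        pts = RNG.uniform(2.5, 5.5, (25, 2))  # away from the periodic seam
        F = RNG.standard_normal((25, 2))
        f = spread_forces(F, pts, N, L)
        x = np.arange(N) * H
        X, Y = np.meshgrid(x, x, indexing="ij")
        c = L / 2
        tz_grid = ((X - c) * f[1] - (Y - c) * f[0]).sum() * H**2
        tz_pts = ((pts[:, 0] - c) * F[:, 1] - (pts[:, 1] - c) * F[:, 0]).sum()
        assert tz_grid == pytest.approx(tz_pts, rel=1e-12)

    def test_linearity(self):
        pts = RNG.uniform(1, 7, (15, 2))
        F1 = RNG.standard_normal((15, 2))
        F2 = RNG.standard_normal((15, 2))
        lhs = spread_forces(2.0 * F1 - 3.0 * F2, pts, N, L)
        rhs = 2.0 * spread_forces(F1, pts, N, L) - 3.0 * spread_forces(F2, pts, N, L)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_constant_field_interpolated_exactly(self):
        u = np.stack([np.full((N, N), 3.5), np.full((N, N), -1.25)])
        pts = RNG.uniform(0.0, 8.0, (30, 2))
        U = interpolate_velocity(u, pts, L)
        np.testing.assert_allclose(U, [[3.5, -1.25]] * 30, atol=1e-13)

    def test_linear_field_interpolated_exactly(self):
        # first-moment property: kernel reproduces affine fields away from seam
        x = np.arange(N) * H
        X, Y = np.meshgrid(x, x, indexing="ij")
        A = np.array([[0.4, -0.7], [0.3, 0.9]])
        u = np.stack([A[0, 0] * X + A[0, 1] * Y, A[1, 0] * X + A[1, 1] * Y])
        pts = RNG.uniform(2 * H, L - 3 * H, (30, 2))
        U = interpolate_velocity(u, pts, L)
        np.testing.assert_allclose(U, pts @ A.T, atol=1e-12)

    def test_adjointness(self):
        pts = RNG.uniform(0, 8, (35, 2))
        F = RNG.standard_normal((35, 2))
        u = RNG.standard_normal((2, N, N))
        lhs = np.sum(spread_forces(F, pts, N, L) * u) * H**2
        rhs = np.sum(F * interpolate_velocity(u, pts, L))
        assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_jit_and_numpy_paths_agree(self):
        pts = RNG.uniform(0, 8, (20, 2))
        F = RNG.standard_normal((20, 2))
        u = RNG.standard_normal((2, N, N))
        np.testing.assert_allclose(
            spread_forces(F, pts, N, L), spread_forces(F, pts, N, L, method="numpy"),
            atol=1e-13,
        )
        np.testing.assert_allclose(
            interpolate_velocity(u, pts, L),
            interpolate_velocity(u, pts, L, method="numpy"),
            atol=1e-13,
        )

    def test_out_of_domain_rejected(self):
        with pytest.raises(OutOfDomainError):
            spread_forces(np.ones((1, 2)), np.array([[100.0, 1.0]]), N, L)
        with pytest.raises(OutOfDomainError):
            interpolate_velocity(np.zeros((2, N, N)), np.array([[np.nan, 1.0]]), L)


class TestDeformationGradients:
    def test_rigid_translation_gives_identity(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        mesh.chi = mesh.X + np.array([0.3, -0.2])
        F2, lam = ibfe.element_deformation_gradients(mesh)
        np.testing.assert_allclose(F2 - np.eye(2), 0.0, atol=1e-12)
        # chord stretches are measured against the (slack) rest lengths and
        # are invariant under rigid translation
        d = np.linalg.norm(mesh.X[mesh.chords[:, 1]] - mesh.X[mesh.chords[:, 0]], axis=1)
        np.testing.assert_allclose(lam, d / mesh._chord_L, atol=1e-12)

    def test_affine_map_exact(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        A = np.array([[1.08, 0.04], [-0.02, 0.94]])
        mesh.chi = mesh.X @ A.T
        F2, _ = ibfe.element_deformation_gradients(mesh)
        np.testing.assert_allclose(F2 - A, 0.0, atol=1e-11)

    def test_matches_finite_difference_of_map(self, channel_valve_mesh):
        # F at the (affine-element) quadrature point equals the FD gradient of
        # the interpolated map evaluated anywhere on the element
        mesh = channel_valve_mesh
        rng = np.random.default_rng(5)
        mesh.chi = mesh.X + 0.01 * rng.standard_normal(mesh.X.shape)
        F2, _ = ibfe.element_deformation_gradients(mesh)
        for e in rng.choice(len(mesh.tris), 5, replace=False):
            tri = mesh.tris[e]
            Xe, xe = mesh.X[tri], mesh.chi[tri]

            def interp_map(p):
                # barycentric interpolation of the element map
                T = np.column_stack([Xe[1] - Xe[0], Xe[2] - Xe[0]])
                lam12 = np.linalg.solve(T, p - Xe[0])
                lam = np.array([1 - lam12.sum(), *lam12])
                return lam @ xe

            p0 = Xe.mean(axis=0)
            eps = 1e-6
            Ffd = np.column_stack([
                (interp_map(p0 + [eps, 0]) - interp_map(p0 - [eps, 0])) / (2 * eps),
                (interp_map(p0 + [0, eps]) - interp_map(p0 - [0, eps])) / (2 * eps),
            ])
            np.testing.assert_allclose(F2[e], Ffd, atol=1e-8)

    def test_inverted_element_flagged_with_id(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        chi = mesh.X.copy()
        tri = mesh.tris[7]
        # collapse one triangle through itself
        chi[tri[0]] = chi[tri[1]] + 2.0 * (chi[tri[2]] - chi[tri[1]])
        mesh.chi = chi
        with pytest.raises(ibfe.InvertedElementError) as ei:
            ibfe.element_deformation_gradients(mesh)
        assert 7 in ei.value.element_ids


class TestAssembly:
    def test_reference_configuration_force_free(self, channel_valve_mesh, material_set):
        mesh = channel_valve_mesh
        mesh.chi = mesh.X.copy()
        f = ibfe.assemble_elastic_forces(mesh, material_set)
        assert np.max(np.abs(f)) < 1e-8

    def test_forces_are_negative_energy_gradient(self, channel_valve_mesh, material_set):
        mesh = channel_valve_mesh
        rng = np.random.default_rng(8)
        chi = mesh.X + 0.02 * rng.standard_normal(mesh.X.shape)
        mesh.chi = chi
        f = ibfe.assemble_elastic_forces(mesh, material_set)
        scale = np.max(np.abs(f))
        eps = 1e-6
        for i in rng.choice(mesh.n_nodes, 12, replace=False):
            for c in range(2):
                for sgn, store in ((1, "p"), (-1, "m")):
                    pert = chi.copy()
                    pert[i, c] += sgn * eps
                    mesh.chi = pert
                    val = ibfe.total_elastic_energy(mesh, material_set)
                    if store == "p":
                        Ep = val
                    else:
                        Em = val
                fd = -(Ep - Em) / (2 * eps)
                assert abs(fd - f[i, c]) / scale < 1e-4

    def test_free_body_self_equilibrium(self, channel_valve_mesh, material_set):
        mesh = channel_valve_mesh
        rng = np.random.default_rng(9)
        mesh.chi = mesh.X + 0.02 * rng.standard_normal(mesh.X.shape)
        f = ibfe.assemble_elastic_forces(mesh, material_set, T_active=30.0,
                                         chordae_C=9000.0)
        assert np.max(np.abs(f.sum(axis=0))) < 1e-10 * np.max(np.abs(f))

    def test_jit_matches_numpy_reference(self, chamber, material_set):
        mesh, _ = chamber
        rng = np.random.default_rng(10)
        mesh.chi = mesh.X + 0.02 * rng.standard_normal(mesh.X.shape)
        f_jit = ibfe.assemble_elastic_forces(mesh, material_set, T_active=80.0,
                                             chordae_C=9000.0, method="jit")
        f_np = ibfe.assemble_elastic_forces(mesh, material_set, T_active=80.0,
                                            chordae_C=9000.0, method="numpy")
        np.testing.assert_allclose(f_jit, f_np, rtol=1e-10, atol=1e-8)
        mesh.chi = mesh.X.copy()

    def test_active_tension_only_on_contractile_region(self, chamber, material_set):
        mesh, _ = chamber
        rng = np.random.default_rng(12)
        mesh.chi = mesh.X + 0.01 * rng.standard_normal(mesh.X.shape)
        f0 = ibfe.assemble_elastic_forces(mesh, material_set, T_active=0.0)
        f1 = ibfe.assemble_elastic_forces(mesh, material_set, T_active=100.0)
        contract_nodes = np.unique(mesh.tris[
            np.asarray([str(r) for r in mesh.tri_region]) == Region.WALL_CONTRACTILE.value
        ])
        changed = np.nonzero(np.max(np.abs(f1 - f0), axis=1) > 1e-9)[0]
        assert len(changed) and set(changed).issubset(set(contract_nodes))
        mesh.chi = mesh.X.copy()


class TestTethers:
    def _mesh_one_node(self):
        # minimal mesh: one free node embedded in a single far-away triangle
        X = np.array([[1.0, 1.0], [5.0, 1.0], [3.0, 5.0]])
        return LagrangianMesh(
            X=X, chi=X.copy(), tris=np.array([[0, 1, 2]]),
            tri_region=np.array([Region.WALL_PASSIVE.value], dtype=object),
            frame_f=np.array([[1.0, 0.0]]), frame_s=np.array([[0.0, 1.0]]),
            transmural=np.array([0.5]),
        )

    def test_zero_at_target(self):
        mesh = self._mesh_one_node()
        ts = TetherSet(nodes=[0], targets=mesh.X[:1], k=100.0)
        np.testing.assert_array_equal(tether_forces(mesh, [ts]), 0.0)

    def test_linear_below_cap(self):
        mesh = self._mesh_one_node()
        ts = TetherSet(nodes=[0], targets=mesh.X[:1], k=100.0, cap=0.6)
        d = np.array([0.3, -0.4])  # |d| = 0.5 < cap
        mesh.chi = mesh.X.copy()
        mesh.chi[0] += d
        f = tether_forces(mesh, [ts])
        np.testing.assert_allclose(f[0], -100.0 * d, rtol=1e-12)

    def test_hardening_beyond_cap(self):
        mesh = self._mesh_one_node()
        ts = TetherSet(nodes=[0], targets=mesh.X[:1], k=100.0, cap=0.6,
                       cap_hardening=20.0)
        mesh.chi = mesh.X.copy()
        mesh.chi[0] += [1.0, 0.0]
        f = tether_forces(mesh, [ts])
        expected = -(100.0 * 0.6 + 20.0 * 100.0 * 0.4)
        assert f[0, 0] == pytest.approx(expected)

    def test_vertical_mode_leaves_radial_free(self):
        mesh = self._mesh_one_node()
        ts = TetherSet(nodes=[0], targets=mesh.X[:1], k=100.0, mode="vertical")
        mesh.chi = mesh.X.copy()
        mesh.chi[0] += [0.5, 0.2]
        f = tether_forces(mesh, [ts])
        assert f[0, 0] == 0.0 and f[0, 1] == pytest.approx(-20.0)

    def test_static_equilibrium_under_constant_load(self):
        # explicit relaxation of a tethered node under constant force settles
        # at displacement F/k (closed-form spring equilibrium)
        k, Fx = 50.0, 10.0
        x, v = 0.0, 0.0
        dt, c, m = 1e-3, 15.0, 1.0
        for _ in range(20000):
            a = (Fx - k * x - c * v) / m
            v += dt * a
            x += dt * v
        assert x == pytest.approx(Fx / k, rel=1e-6)
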