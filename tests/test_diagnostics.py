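"""Flow-rate quadrature, cavity volume, pump metrics, fibre strain."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from heartfsi import diagnostics as D
from heartfsi import ibfe
from heartfsi.geometry import PlaneDef
from heartfsi.ibfe import LagrangianMesh, Region

N, L = 64, 16.0
H = L / N


def _grid_field(fn):
    x = np.arange(N) * H
    X, Y = np.meshgrid(x, x, indexing="ij")
    return fn(X, Y)


class TestFlowRate:
    PLANE = PlaneDef(x_left=5.0, x_right=7.0, y=8.0)

    def test_zero_velocity(self):
        u = np.zeros((2, N, N))
        assert D.flow_rate_across_plane(u, self.PLANE, L, depth=3.0) == 0.0

    def test_uniform_normal_velocity(self):
        u = np.stack([np.zeros((N, N)), np.full((N, N), 2.5)])
        q = D.flow_rate_across_plane(u, self.PLANE, L, depth=3.0)
        assert q == pytest.approx(2.5 * 2.0 * 3.0, rel=1e-12)

    def test_parabolic_profile_matches_fine_quadrature(self):
        xl, xr = self.PLANE.x_left, self.PLANE.x_right

        def profile(X, Y):
            s = np.clip((X - xl) / (xr - xl), 0, 1)
            return 4.0 * s * (1 - s)

        u = np.stack([np.zeros((N, N)), _grid_field(profile)])
        q = D.flow_rate_across_plane(u, self.PLANE, L, depth=1.0, n_quad=24)
        # fine-quadrature oracle over the same interpolated field
        fine = PlaneDef(x_left=xl, x_right=xr, y=8.0)
        pts = fine.quad_points(4000)
        Uy = ibfe.interpolate_velocity(u, pts, L)[:, 1]
        q_ref = np.sum(Uy) * (xr - xl) / 4000
        assert q == pytest.approx(q_ref, rel=1e-3)

    def test_plane_outside_grid_rejected(self):
        with pytest.raises(D.PlaneOutsideGridError):
            D.flow_rate_across_plane(np.zeros((2, N, N)),
                                     PlaneDef(x_left=-1.0, x_right=2.0, y=8.0), L, 1.0)


def _loop_mesh(points):
    n = len(points)
    # a dummy triangle keeps the mesh valid; the loop nodes are what matters
    X = np.vstack([points, [[100.0, 0.0], [101.0, 0.0], [100.0, 1.0]]])
    tris = np.array([[n, n + 1, n + 2]])
    return LagrangianMesh(
        X=X, chi=X.copy(), tris=tris,
        tri_region=np.array([Region.WALL_PASSIVE.value], dtype=object),
        frame_f=np.array([[1.0, 0.0]]), frame_s=np.array([[0.0, 1.0]]),
        transmural=np.array([0.5]),
    )


class TestCavityVolume:
    def test_circle_area(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 2.0
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        mesh = _loop_mesh(pts)
        v = D.cavity_volume(mesh, np.arange(len(pts)), depth=3.0)
        assert v == pytest.approx(np.pi * r**2 * 3.0, rel=1e-3)

    def test_translation_invariance(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th)], axis=1)
        mesh = _loop_mesh(pts)
        v1 = D.cavity_volume(mesh, np.arange(100), 1.0)
        mesh.chi[:100] += [5.0, -3.0]
        v2 = D.cavity_volume(mesh, np.arange(100), 1.0)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_star_polygon_matches_shoelace_oracle(self):
        rng = np.random.default_rng(4)
        th = np.sort(rng.uniform(0, 2 * np.pi, 60))
        r = 1.0 + 0.5 * rng.uniform(-1, 1, 60)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        mesh = _loop_mesh(pts)
        x, y = pts[:, 0], pts[:, 1]
        shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert D.cavity_volume(mesh, np.arange(60), 2.0) == pytest.approx(
            2.0 * shoelace, rel=1e-12
        )

    def test_negatively_oriented_loop_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        mesh = _loop_mesh(pts)
        with pytest.raises(ValueError):
            D.cavity_volume(mesh, np.arange(4), 1.0)


@dataclass
class _FakeResult:
    series: pd.DataFrame
    transition_times: dict


def _synthetic_cycle(av_pulse):
    """Build a result with prescribed AV flow during ejection."""
    t = np.round(np.arange(0.0, 1.2, 1e-3), 9)
    phase = np.where(t < 0.8, "DIASTOLE",
                     np.where(t < 0.85, "IVC", np.where(t < 1.05, "EJECTION", "IVR")))
    q_mv = np.where(t < 0.8, -100.0, 0.0)
    q_av = np.array([av_pulse(ti) if 0.85 <= ti < 1.05 else 0.0 for ti in t])
    v = np.full_like(t, 150.0)
    df = pd.DataFrame({
        "t": t, "phase": phase, "Q_mv": q_mv, "Q_av": q_av, "V_cav": v,
        "P_LV": 0.0,
    })
    return _FakeResult(df, {"IVC": 0.8, "EJECTION": 0.85, "IVR": 1.05})


class TestPumpMetrics:
    def test_rectangular_pulse_stroke_volume(self):
        res = _synthetic_cycle(lambda ti: 200.0)
        m = D.pump_metrics(res)
        # trapezoid on the phase-masked samples loses half a sample per edge
        assert m.stroke_volume == pytest.approx(200.0 * 0.2, rel=1e-2)
        assert m.filling_volume == pytest.approx(100.0 * 0.8, rel=1e-2)

    def test_triangular_pulse_half_of_rectangle(self):
        def tri(ti):
            s = (ti - 0.85) / 0.2
            return 200.0 * (1 - abs(2 * s - 1))

        m_tri = D.pump_metrics(_synthetic_cycle(tri))
        m_rect = D.pump_metrics(_synthetic_cycle(lambda ti: 200.0))
        assert m_tri.stroke_volume == pytest.approx(m_rect.stroke_volume / 2, rel=1e-2)

    def test_regurgitant_fraction_definition(self):
        # regurgitant volume of ~10% of filling gives a ~10% fraction
        res = _synthetic_cycle(lambda ti: 200.0)
        res.series.loc[res.series["phase"] == "IVC", "Q_mv"] = 160.0  # 8 mL over 50 ms
        m = D.pump_metrics(res)
        assert m.regurgitant_volume == pytest.approx(8.0, rel=0.05)
        assert m.regurgitant_fraction == pytest.approx(
            100.0 * m.regurgitant_volume / m.filling_volume
        )

    def test_durations_from_phase_log(self):
        m = D.pump_metrics(_synthetic_cycle(lambda ti: 200.0))
        assert m.ivc_duration == pytest.approx(50.0)
        assert m.ejection_duration == pytest.approx(200.0)

    def test_incomplete_cycle_rejected(self):
        res = _synthetic_cycle(lambda ti: 200.0)
        del res.transition_times["IVR"]
        with pytest.raises(D.IncompleteCycleError):
            D.pump_metrics(res)


class TestFibreStrain:
    def test_reference_state_zero(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        mesh.chi = mesh.X.copy()
        np.testing.assert_allclose(D.fibre_strain_field(mesh), 0.0, atol=1e-12)

    def test_uniform_stretch_along_fibres(self):
        # stretch everything 10% along x; elements with f0 = x report 0.1
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        mesh = LagrangianMesh(
            X=X, chi=X * [1.1, 1.0], tris=np.array([[0, 1, 2]]),
            tri_region=np.array([Region.WALL_PASSIVE.value], dtype=object),
            frame_f=np.array([[1.0, 0.0]]), frame_s=np.array([[0.0, 1.0]]),
            transmural=np.array([0.5]),
        )
        assert D.fibre_strain_field(mesh)[0] == pytest.approx(0.1)
        assert D.fibre_strain_field(mesh, kind="green")[0] == pytest.approx(
            0.5 * (1.1**2 - 1)
        )

    def test_matches_direct_invariant_oracle(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        rng = np.random.default_rng(6)
        mesh.chi = mesh.X + 0.02 * rng.standard_normal(mesh.X.shape)
        strain = D.fibre_strain_field(mesh)
        F2, _ = ibfe.element_deformation_gradients(mesh)
        for e in rng.choice(len(mesh.tris), 8, replace=False):
            C = F2[e].T @ F2[e]
            lam = np.sqrt(mesh.frame_f[e] @ C @ mesh.frame_f[e])
            assert strain[e] == pytest.approx(lam - 1.0, rel=1e-10)

    def test_relative_to_configured_reference(self, channel_valve_mesh):
        mesh = channel_valve_mesh
        ref = mesh.X * [1.05, 1.0]
        mesh.chi = ref.copy()
        np.testing.assert_allclose(
            D.fibre_strain_field(mesh, reference_chi=ref), 0.0, atol=1e-12
        )
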