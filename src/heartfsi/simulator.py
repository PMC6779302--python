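"""Coupled explicit time loop: structure forces -> spread -> fluid -> interpolate.

Each step assembles the Lagrangian forces (passive + active elasticity,
chordal tension with the phase-dependent modulus, tethers with the systolic
pull-back schedule, endocardial P_endo traction and tract-plane
pressure/plug forces), spreads them to the Eulerian grid, advances the
Navier-Stokes solver one step, interpolates velocities back and moves the
structure, then updates the circulation controller.

The tract planes are immersed 'plug' walls made of tethered marker points:
a blocked plane is a rigid target-point wall, an open plane exerts only its
scheduled pressure traction.  The inflow plane is one-way during diastole and
iso-volumetric contraction (it engages only against outward flow), which
implements the no-backflow condition while leaving filling unobstructed.

The time step follows the phase schedule (base dt0; 0.25 dt0 in early
systole, 0.125 dt0 for the remainder of systole), with dt0 automatically
reduced when explicit stability at the configured grid and stiffnesses
requires it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heartfsi import circulation as circ_mod
from heartfsi import diagnostics, fluid, geometry, ibfe, materials
from heartfsi.circulation import CirculationState, Phase, WindkesselState
from heartfsi.fluid import FluidState, Grid, SpectralProjector
from heartfsi.params import SimulationConfig
from heartfsi.units import KPA, MMHG


class SimulationDiverged(RuntimeError):
    """Non-finite fields encountered; carries a diagnostic state summary."""

    def __init__(self, msg: str, diagnostic: dict):
        self.diagnostic = diagnostic
        super().__init__(f"{msg}; diagnostic: {diagnostic}")


@dataclass
class PumpPlane:
    """Runtime state of one tract plane: fixed targets + advected markers."""

    targets: np.ndarray
    markers: np.ndarray
    ds: float
    engaged: bool = False
    vel: np.ndarray | None = None  # marker velocities (for plug damping)


@dataclass
class SimState:
    chi: np.ndarray
    fl: FluidState
    circ: CirculationState
    mv_plug: PumpPlane
    av_plug: PumpPlane
    t: float = 0.0
    n_steps: int = 0
    ejection_established: bool = False
    U_nodes: np.ndarray | None = None  # last interpolated node velocities
    q_mv_smooth: float = 0.0  # exponentially smoothed plane flows used by the
    q_av_smooth: float = 0.0  # controller (raw flows feed the Windkessel)


@dataclass
class SimulationResult:
    """Time series, phase log and derived pump metrics of one cycle."""

    series: pd.DataFrame
    transition_times: dict
    config: SimulationConfig
    final_chi: np.ndarray
    end_diastolic_chi: np.ndarray | None = None
    dt0: float = 0.0

    @property
    def metrics(self) -> diagnostics.PumpMetrics:
        return diagnostics.pump_metrics(self)


class CoupledModel:
    """Binds geometry, materials, fluid solver and circulation for one config."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.mesh, self.apparatus = geometry.build_lv_chamber(
            config.geometry, config.tethers
        )
        self.grid = Grid(n=config.grid_n, L=config.fluid.box_size)
        self.projector = SpectralProjector(self.grid)
        self.mats = ibfe.MaterialSet(
            anterior=config.anterior,
            posterior=config.posterior,
            chordae=config.chordae,
            myocardium=config.myocardium,
            numerics=config.numerics,
        )
        self.free = ~self.mesh.pinned_mask
        self.depth = config.geometry.depth
        self._probe_mask = self._disc_mask(self.apparatus.probe_center, config.probe_radius)
        self._ref_mask = self._disc_mask(self.apparatus.reference_center, config.probe_radius)
        h = self.grid.h
        self._k_plug = config.tethers.k_tract * config.plug_penalty_scale
        n_mark = max(6, int(np.ceil(self.apparatus.mv_plane.width / (0.5 * h))))
        self.apparatus.mv_plane.markers = self.apparatus.mv_plane.quad_points(n_mark)
        n_mark_av = max(6, int(np.ceil(self.apparatus.av_plane.width / (0.5 * h))))
        self.apparatus.av_plane.markers = self.apparatus.av_plane.quad_points(n_mark_av)
        self._mv_quad = self.apparatus.mv_plane.quad_points(24)
        self._av_quad = self.apparatus.av_plane.quad_points(24)
        # dashpots at a fraction of critical for each target-point set
        m_eff = config.fluid.rho * (2.0 * h) ** 2
        for ts in self.apparatus.tethers:
            ts.damping = config.tethers.damping_ratio * 2.0 * np.sqrt(ts.k * m_eff)
        self._c_plug = config.tethers.damping_ratio * 2.0 * np.sqrt(self._k_plug * m_eff)
        self.dt0 = self._stable_dt0()

    # ------------------------------------------------------------------
    def _disc_mask(self, center: np.ndarray, radius: float) -> np.ndarray:
        X, Y = self.grid.coords()
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2

    def _stable_dt0(self) -> float:
        """Largest safe base step for the explicit coupling at this resolution."""
        cfg = self.config
        h = self.grid.h
        # fluid inertia dragged per node: the four-point kernel couples a
        # footprint of radius ~2h, so the effective mass is rho*(2h)^2
        m_eff = cfg.fluid.rho * (2.0 * h) ** 2
        mesh = self.mesh
        # elastic stiffness scale per triangle: bulk penalty dominates
        p = mesh.X[mesh.tris]
        e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]], axis=1)
        L_min = np.min(np.linalg.norm(e, axis=2), axis=1)
        mod = (cfg.numerics.beta_s + 4.0 * cfg.anterior.C1) * KPA
        k_tri = float(np.max(4.0 * mod * mesh._area_ref / L_min**2))
        k_chord = 0.0
        if len(mesh.chords):
            k_chord = float(np.max(
                4.0 * cfg.chordae.C_systole * KPA * cfg.chordae.cross_section / mesh._chord_L
            ))
        k_teth = max(
            cfg.tethers.k_tract, cfg.tethers.k_basal,
            cfg.tethers.k_valve_soft * cfg.tethers.cap_hardening, self._k_plug,
        )
        k_max = max(k_tri, k_chord, k_teth)
        dt_lim = 2.0 * np.sqrt(m_eff / k_max)
        return float(min(cfg.numerics.dt0, cfg.numerics.stability_safety * dt_lim))

    def dt_schedule(self, t: float, phase: Phase) -> float:
        num = self.config.numerics
        t_ed = self.config.phases.t_diastole
        if phase == Phase.DIASTOLE:
            return self.dt0
        if phase in (Phase.IVC, Phase.EJECTION):
            if t < t_ed + num.early_systole_duration:
                return num.early_systole_factor * self.dt0
            return num.late_systole_factor * self.dt0
        return self.dt0

    # ------------------------------------------------------------------
    def initial_state(self) -> SimState:
        ap = self.apparatus
        circ = CirculationState(
            wk=WindkesselState(
                Pp=self.config.phases.P_aorta_init, Pao=self.config.phases.P_aorta_init
            )
        )
        return SimState(
            chi=self.mesh.X.copy(),
            fl=FluidState.quiescent(self.grid),
            circ=circ,
            mv_plug=PumpPlane(
                targets=ap.mv_plane.markers.copy(), markers=ap.mv_plane.markers.copy(),
                ds=ap.mv_plane.width / len(ap.mv_plane.markers),
            ),
            av_plug=PumpPlane(
                targets=ap.av_plane.markers.copy(), markers=ap.av_plane.markers.copy(),
                ds=ap.av_plane.width / len(ap.av_plane.markers),
                engaged=True,  # the aortic valve is closed at rest
            ),
        )

    # ------------------------------------------------------------------
    def structure_forces(self, state: SimState, T_active: float) -> np.ndarray:
        """All Lagrangian mesh-node forces (dyn per cm depth)."""
        cfg = self.config
        mesh = self.mesh
        mesh.chi = state.chi
        phase = state.circ.phase
        C_ch = circ_mod.chordae_stiffness(
            phase, cfg.chordae.C_diastole, cfg.chordae.C_systole
        )
        f = ibfe.assemble_elastic_forces(mesh, self.mats, T_active, chordae_C=C_ch)
        f += ibfe.tether_forces(
            mesh, self.apparatus.tethers, self._valve_k_scale(state.t),
            velocities=state.U_nodes,
        )
        P_endo_cgs = state.circ.P_endo * MMHG
        if P_endo_cgs > 0.0:
            f += self._endo_traction(state.chi, P_endo_cgs)
        return f

    def _valve_k_scale(self, t: float) -> float:
        """Systolic pull-back schedule for the capped valvular tether."""
        tp = self.config.tethers
        t_ed = self.config.phases.t_diastole
        if t <= t_ed:
            return 1.0
        ramp = min((t - t_ed) / tp.pullback_duration, 1.0)
        return 1.0 + (tp.systole_stiffening - 1.0) * ramp

    def _endo_traction(self, chi: np.ndarray, P: float) -> np.ndarray:
        """Uniform normal traction P on the contractile endocardial surface."""
        chain = self.apparatus.endo_chain
        pts = chi[chain]
        tang = np.diff(pts, axis=0)
        ds = np.linalg.norm(tang, axis=1, keepdims=True)
        # chain runs clockwise around the cavity; outward normal = (-ty, tx)
        n_out = np.stack([-tang[:, 1], tang[:, 0]], axis=1) / ds
        f_edge = P * ds * n_out  # force per edge, pushing the wall outward
        forces = np.zeros_like(chi)
        np.add.at(forces, chain[:-1], 0.5 * f_edge)
        np.add.at(forces, chain[1:], 0.5 * f_edge)
        return forces

    # ------------------------------------------------------------------
    def plane_forces(self, state: SimState) -> tuple[np.ndarray, np.ndarray]:
        """(positions, forces) of the tract-plane markers to spread this step."""
        cfg = self.config
        phase = state.circ.phase
        pts, frc = [], []

        # inflow plane: atrial pressure traction while filling is allowed
        mv = state.mv_plug
        P_in = state.circ.P_inflow * MMHG
        if phase in (Phase.DIASTOLE, Phase.IVC) and not mv.engaged and P_in > 0.0:
            pts.append(mv.targets)
            frc.append(np.tile([0.0, -P_in * mv.ds], (len(mv.targets), 1)))
        if mv.engaged:
            pts.append(mv.markers)
            f_mv = -self._k_plug * (mv.markers - mv.targets)
            if mv.vel is not None:
                f_mv -= self._c_plug * mv.vel
            frc.append(f_mv)

        # outflow plane: plug unless ejecting; afterload traction when open
        av = state.av_plug
        if phase == Phase.EJECTION:
            Pao = state.circ.wk.Pao * MMHG
            pts.append(av.targets)
            frc.append(np.tile([0.0, -Pao * av.ds], (len(av.targets), 1)))
        else:
            pts.append(av.markers)
            f_av = -self._k_plug * (av.markers - av.targets)
            if av.vel is not None:
                f_av -= self._c_plug * av.vel
            frc.append(f_av)

        if not pts:
            return np.zeros((0, 2)), np.zeros((0, 2))
        return np.concatenate(pts), np.concatenate(frc)

    # ------------------------------------------------------------------
    def measure(self, state: SimState) -> dict:
        u = state.fl.u
        L = self.grid.L
        q_mv = diagnostics.flow_rate_across_plane(u, self.apparatus.mv_plane, L, self.depth)
        q_av = diagnostics.flow_rate_across_plane(u, self.apparatus.av_plane, L, self.depth)
        p = state.fl.p
        p_lv = (float(p[self._probe_mask].mean()) - float(p[self._ref_mask].mean())) / MMHG
        self.mesh.chi = state.chi
        v_cav = diagnostics.cavity_volume(self.mesh, self.apparatus.cavity_loop, self.depth)
        return {"Q_mv": q_mv, "Q_av": q_av, "P_LV": p_lv, "V_cav": v_cav}

    # ------------------------------------------------------------------
    def step(self, state: SimState, dt: float | None = None) -> SimState:
        """One explicit coupled step; raises on CFL violation or divergence."""
        cfg = self.config
        phase = state.circ.phase
        if dt is None:
            dt = self.dt_schedule(state.t, phase)
            dt = min(dt, fluid.advective_dt_limit(state.fl.u, self.grid.h, 0.9))

        T_active = materials.twitch_tension(state.t, cfg.active)
        f_nodes = self.structure_forces(state, float(T_active))

        pos_m, frc_m = self.plane_forces(state)
        pos_all = np.concatenate([state.chi[self.free], pos_m])
        frc_all = np.concatenate([f_nodes[self.free], frc_m])
        f_grid = ibfe.spread_forces(frc_all, pos_all, self.grid.n, self.grid.L)

        fl_new = fluid.ns_step(
            state.fl, f_grid, dt, cfg.fluid, self.grid, self.projector,
            filter_strength=cfg.filter_strength,
        )
        if not np.isfinite(fl_new.u).all():
            raise SimulationDiverged(
                "non-finite velocity field",
                {"t": state.t, "phase": phase.value, "n_steps": state.n_steps},
            )

        # fused interpolation: structure nodes, plane quadrature, plug markers
        n_chi = len(state.chi)
        pts = [state.chi, self._mv_quad, self._av_quad]
        if state.mv_plug.engaged:
            pts.append(state.mv_plug.markers)
        if state.av_plug.engaged:
            pts.append(state.av_plug.markers)
        U_all = ibfe.interpolate_velocity(fl_new.u, np.concatenate(pts), self.grid.L)
        U = U_all[:n_chi]
        k = n_chi
        nq = len(self._mv_quad)
        q_mv = float(np.sum(U_all[k:k + nq, 1])) * (
            self.apparatus.mv_plane.width / nq) * self.depth
        k += nq
        nq2 = len(self._av_quad)
        q_av = float(np.sum(U_all[k:k + nq2, 1])) * (
            self.apparatus.av_plane.width / nq2) * self.depth
        k += nq2

        chi_new = state.chi.copy()
        chi_new[self.free] += dt * U[self.free]

        if state.mv_plug.engaged:
            mv_vel = U_all[k:k + len(state.mv_plug.markers)]
            mv_markers = state.mv_plug.markers + dt * mv_vel
            k += len(state.mv_plug.markers)
        else:
            mv_markers, mv_vel = state.mv_plug.targets.copy(), None
        mv_plug = PumpPlane(state.mv_plug.targets, mv_markers,
                            state.mv_plug.ds, state.mv_plug.engaged, mv_vel)
        if state.av_plug.engaged:
            av_vel = U_all[k:k + len(state.av_plug.markers)]
            av_markers = state.av_plug.markers + dt * av_vel
        else:
            av_markers, av_vel = state.av_plug.targets.copy(), None
        av_plug = PumpPlane(state.av_plug.targets, av_markers,
                            state.av_plug.ds, state.av_plug.engaged, av_vel)

        p = fl_new.p
        p_lv = (float(p[self._probe_mask].mean()) - float(p[self._ref_mask].mean())) / MMHG

        t_new = state.t + dt
        alpha = min(dt / 0.003, 1.0)  # ~3 ms smoothing for controller decisions
        state_new = SimState(
            chi=chi_new, fl=fl_new, circ=state.circ, mv_plug=mv_plug,
            av_plug=av_plug, t=t_new, n_steps=state.n_steps + 1,
            ejection_established=state.ejection_established, U_nodes=U,
            q_mv_smooth=state.q_mv_smooth + alpha * (q_mv - state.q_mv_smooth),
            q_av_smooth=state.q_av_smooth + alpha * (q_av - state.q_av_smooth),
        )
        self._update_circulation(state_new, dt, q_mv, q_av, p_lv)
        return state_new

    def _update_circulation(
        self, state: SimState, dt: float, q_mv: float, q_av: float, p_lv: float
    ) -> None:
        cfg = self.config
        meas = {"Q_mv": q_mv, "Q_av": q_av, "P_LV": p_lv}
        circ = state.circ
        phase_before = circ.phase

        # windkessel while ejecting
        if phase_before == Phase.EJECTION:
            circ.wk = circ_mod.windkessel_step(
                max(meas["Q_av"], 0.0), circ.wk, cfg.windkessel, dt
            )
            if state.q_av_smooth > 5.0:
                state.ejection_established = True

        # ejection-end detection only after forward flow was established
        q_for_controller = state.q_av_smooth
        if phase_before == Phase.EJECTION and not state.ejection_established:
            q_for_controller = max(q_for_controller, 1.0)

        circ = circ_mod.phase_update(
            circ, state.t, meas["P_LV"], q_for_controller, cfg.phases
        )

        # plug engagement by phase (one-way at the inflow plane): the plug
        # wall engages against outward (regurgitant) plane flow and releases
        # once the pressure difference favours inflow again
        mv, av = state.mv_plug, state.av_plug
        if circ.phase in (Phase.DIASTOLE, Phase.IVC, Phase.EJECTION):
            if not mv.engaged and state.q_mv_smooth > 2.0:
                mv.engaged = True
                mv.markers = mv.targets.copy()
            elif mv.engaged and circ.P_inflow - meas["P_LV"] > 0.5:
                mv.engaged = False
        else:  # IVR: hard closed
            if not mv.engaged:
                mv.engaged = True
                mv.markers = mv.targets.copy()
        want_av = circ.phase != Phase.EJECTION
        if want_av and not av.engaged:
            av.engaged = True
            av.markers = av.targets.copy()
        elif not want_av and av.engaged:
            av.engaged = False
        state.circ = circ
        state._meas = meas  # cached for recording

    # ------------------------------------------------------------------
    def run_cycle(self) -> SimulationResult:
        cfg = self.config
        state = self.initial_state()
        rows = []
        t_end = cfg.phases.t_cycle
        next_out = 0.0
        ed_chi = None
        guard = 0
        while state.t < t_end - 1e-12:
            if state.t >= next_out:
                rows.append(self._record(state))
                next_out += cfg.output_dt
            state = self.step(state)
            if ed_chi is None and state.circ.phase != Phase.DIASTOLE:
                ed_chi = state.chi.copy()
            guard += 1
            if guard > 5_000_000:
                raise SimulationDiverged("step-count guard exceeded", {"t": state.t})
        rows.append(self._record(state))
        series = pd.DataFrame(rows)
        return SimulationResult(
            series=series,
            transition_times=dict(state.circ.transition_times),
            config=cfg,
            final_chi=state.chi.copy(),
            end_diastolic_chi=ed_chi,
            dt0=self.dt0,
        )

    def _record(self, state: SimState) -> dict:
        meas = getattr(state, "_meas", None)
        if meas is None:
            meas = self.measure(state)
        else:
            self.mesh.chi = state.chi
            meas = dict(meas)
            meas["V_cav"] = diagnostics.cavity_volume(
                self.mesh, self.apparatus.cavity_loop, self.depth
            )
        return {
            "t": state.t,
            "phase": state.circ.phase.value,
            "Q_mv": meas["Q_mv"],
            "Q_av": meas["Q_av"],
            "V_cav": meas["V_cav"],
            "P_LV": meas["P_LV"],
            "Pao": state.circ.wk.Pao,
            "P_inflow": state.circ.P_inflow,
            "P_endo": state.circ.P_endo,
            "T_active": float(materials.twitch_tension(state.t, self.config.active)),
            "mv_plug": state.mv_plug.engaged,
            "av_plug": state.av_plug.engaged,
        }


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def run_cycle(config: SimulationConfig | None = None) -> SimulationResult:
    """Integrate one full cardiac cycle; deterministic given the config."""
    cfg = config or SimulationConfig()
    return CoupledModel(cfg).run_cycle()


def sweep_pendo(
    config: SimulationConfig | None = None,
    scales: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5),
) -> dict[float, SimulationResult]:
    """Re-run the cycle scaling the endocardial relaxation surrogate P_endo.

    EDP is held fixed; only P_endo_max is scaled, mirroring the
    myocardial-relaxation sensitivity experiment.
    """
    base = config or SimulationConfig()
    out: dict[float, SimulationResult] = {}
    for s in scales:
        cfg = copy.deepcopy(base)
        cfg.phases.P_endo_max = base.phases.P_endo_max * s
        out[s] = run_cycle(cfg)
    return out
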