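"""Parameter registry for the coupled MV-LV simulator.

Every tunable quantity lives in a small dataclass with physiological defaults.
Tissue moduli are in kPa, haemodynamic pressures in mmHg, lengths in cm, times
in s.  The whole registry round-trips to a plain YAML mapping whose keys mirror
the conventional material-table names (C1, a_v, b_v, C_chordae_systole, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class MVLeafletParams:
    """Incompressible fibre-reinforced leaflet law: W = C1(I1-3) + collagen term.

    ``bv`` is a dimensionless exponent (the collagen term is
    a_v/(2 b_v) * (exp[b_v (max(I4c,1)-1)^2] - 1)).
    """

    C1: float = 17.4  # kPa, anterior default
    av: float = 31.3  # kPa
    bv: float = 55.93  # dimensionless

    def __post_init__(self) -> None:
        if min(self.C1, self.av, self.bv) <= 0:
            raise ValueError("MV leaflet parameters must be positive")


ANTERIOR_LEAFLET = MVLeafletParams(C1=17.4, av=31.3, bv=55.93)
POSTERIOR_LEAFLET = MVLeafletParams(C1=10.2, av=50.0, bv=63.48)


@dataclass
class ChordaeParams:
    """Neo-Hookean chordal cables with a systole/diastole stiffness switch.

    The switch stands in for papillary-muscle contraction: taut, much stiffer
    chords while the valve is closed.
    """

    C_diastole: float = 540.0  # kPa
    C_systole: float = 9000.0  # kPa
    cross_section: float = 0.008  # cm^2 per chord (per unit depth in 2-D)

    def __post_init__(self) -> None:
        if not (self.C_systole > self.C_diastole > 0):
            raise ValueError("require C_systole > C_diastole > 0")
        if self.cross_section <= 0:
            raise ValueError("chord cross-section must be positive")


@dataclass
class HolzapfelOgdenParams:
    """Orthotropic exponential passive-myocardium law (I1, I4f, I4s, I8fs).

    Defaults are human-myocardium values from the literature the LV law derives
    from; they are not printed in the source material table and are flagged as
    such in the docs.  a-type moduli in kPa, b-type exponents dimensionless.
    """

    a: float = 0.2362
    b: float = 10.810
    af: float = 20.037
    bf: float = 14.154
    as_: float = 3.7245
    bs: float = 5.1645
    afs: float = 0.4108
    bfs: float = 11.300

    def __post_init__(self) -> None:
        vals = [self.a, self.b, self.af, self.bf, self.as_, self.bs, self.afs, self.bfs]
        if any(v < 0 for v in vals):
            raise ValueError("Holzapfel-Ogden parameters must be non-negative")


@dataclass
class ActiveTensionParams:
    """Phenomenological active-tension twitch.

    T(t) = 0 before onset t_act (end-diastole); afterwards a smooth
    rise-then-decay transient normalised so its peak equals T_ref.
    """

    T_ref: float = 225.0  # kPa
    t_act: float = 0.8  # s
    tau_rise: float = 0.06  # s
    tau_decay: float = 0.08  # s

    def __post_init__(self) -> None:
        if self.T_ref < 0:
            raise ValueError("T_ref must be non-negative")
        if min(self.tau_rise, self.tau_decay) <= 0:
            raise ValueError("twitch time constants must be positive")


@dataclass
class NumericalParams:
    """Bulk penalty and the phase-dependent time-step schedule.

    ``dt0`` is the base step used in diastole and iso-volumetric relaxation;
    early systole (first ``early_systole_duration`` after end-diastole) runs at
    ``early_systole_factor * dt0`` and the remainder of systole at
    ``late_systole_factor * dt0``.  The simulator additionally rescales dt0
    downward if explicit stability at the chosen grid/stiffness requires it.
    """

    beta_s: float = 1000.0  # kPa, incompressibility bulk penalty
    dt0: float = 1.22e-4  # s
    early_systole_factor: float = 0.25
    late_systole_factor: float = 0.125
    early_systole_duration: float = 0.1  # s
    stability_safety: float = 0.75

    def __post_init__(self) -> None:
        if self.beta_s <= 0 or self.dt0 <= 0:
            raise ValueError("beta_s and dt0 must be positive")
        if not (0 < self.late_systole_factor <= self.early_systole_factor <= 1):
            raise ValueError("invalid dt schedule factors")


@dataclass
class FluidProperties:
    """Blood-like Newtonian fluid on a periodic square box (CGS units)."""

    rho: float = 1.0  # g/cm^3
    mu: float = 0.04  # g/(cm s)
    box_size: float = 16.0  # cm

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0 or self.box_size <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class PhaseBCParams:
    """Cardiac-cycle pressure schedule.

    Atrial-side pressure ramps 0 -> EDP over diastole; the endocardial suction
    surrogate P_endo ramps 0 -> P_endo_max over [0, t_endo_peak] and back to 0
    at end-diastole.  The aortic pressure starts at the diastolic cuff value.
    """

    EDP: float = 8.0  # mmHg
    P_endo_max: float = 12.0  # mmHg
    t_endo_peak: float = 0.4  # s
    t_diastole: float = 0.8  # s
    t_cycle: float = 1.2  # s
    P_aorta_init: float = 85.0  # mmHg

    def __post_init__(self) -> None:
        if not (0 < self.t_endo_peak < self.t_diastole < self.t_cycle):
            raise ValueError("require 0 < t_endo_peak < t_diastole < t_cycle")


@dataclass
class WindkesselParams:
    """Three-element afterload: Rc in series with a parallel (Rp, Ca) pair.

    Units: resistances mmHg.s/mL, compliance mL/mmHg.  Defaults are a
    calibration giving 80-160 mmHg afterload for stroke-volume-scale pulses,
    not literature-reported values.
    """

    Rc: float = 0.05  # mmHg s/mL
    Rp: float = 1.1  # mmHg s/mL
    Ca: float = 1.3  # mL/mmHg

    def __post_init__(self) -> None:
        if min(self.Rc, self.Rp, self.Ca) <= 0:
            raise ValueError("Windkessel parameters must be positive")


@dataclass
class TetherParams:
    """Stiffnesses of the target-point constraints (dyn/cm per cm depth).

    The valvular region is soft in diastole with displacement saturating near
    ``valve_cap`` (6 mm); in systole its stiffness is ramped up by
    ``systole_stiffening`` over ``pullback_duration`` so the region is pulled
    back to its original position.  Tract walls and plane plugs are rigid.
    """

    k_tract: float = 2.0e6
    k_valve_soft: float = 2.0e4
    valve_cap: float = 0.6  # cm (6 mm)
    cap_hardening: float = 20.0  # stiffness multiplier beyond the cap
    systole_stiffening: float = 50.0
    pullback_duration: float = 0.1  # s after end-diastole
    k_basal: float = 2.0e6  # longitudinal-only penalty on the basal ring
    damping_ratio: float = 0.5  # dashpot fraction of critical, all tether sets


@dataclass
class GeometryConfig:
    """Idealized 2-D LVOT-view chamber with mounted valve (lengths in cm)."""

    center_x: float = 8.0
    center_y: float = 7.0
    short_axis: float = 3.0  # cavity semi-axis, horizontal
    long_axis: float = 4.0  # cavity semi-axis, vertical
    wall_thickness: float = 0.8
    basal_plane_y: float = 8.3
    gap_half_width: float = 2.65  # half-width of the basal opening
    tract_top_y: float = 12.8
    tract_wall_thickness: float = 0.5
    pillar_thickness: float = 0.8
    annulus_y: float = 9.8
    plane_y: float = 12.4  # MV/AV measurement+plug planes
    anterior_length: float = 2.4
    posterior_length: float = 1.4
    leaflet_thickness: float = 0.2
    n_chordae: int = 16
    ds_wall: float = 0.2  # target node spacing along bands
    ds_leaflet: float = 0.21
    n_wall_layers: int = 2
    depth: float = 3.6  # out-of-plane depth used to report mL
    seed: int = 0
    jitter: float = 0.0  # optional node jitter amplitude (cm)

    def __post_init__(self) -> None:
        if self.gap_half_width >= self.short_axis:
            raise ValueError("basal opening wider than the cavity")
        if self.anterior_length <= self.posterior_length:
            raise ValueError("anterior leaflet must be longer than posterior")
        if self.n_chordae % 2:
            raise ValueError("n_chordae must be even (split across leaflets)")
        for name in ("wall_thickness", "leaflet_thickness", "depth", "ds_wall"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationConfig:
    """Everything a run needs; deterministic given this object."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    anterior: MVLeafletParams = field(default_factory=lambda: dataclasses.replace(ANTERIOR_LEAFLET))
    posterior: MVLeafletParams = field(default_factory=lambda: dataclasses.replace(POSTERIOR_LEAFLET))
    chordae: ChordaeParams = field(default_factory=ChordaeParams)
    myocardium: HolzapfelOgdenParams = field(default_factory=HolzapfelOgdenParams)
    active: ActiveTensionParams = field(default_factory=ActiveTensionParams)
    numerics: NumericalParams = field(default_factory=NumericalParams)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    phases: PhaseBCParams = field(default_factory=PhaseBCParams)
    windkessel: WindkesselParams = field(default_factory=WindkesselParams)
    tethers: TetherParams = field(default_factory=TetherParams)
    grid_n: int = 64
    output_dt: float = 1.0e-3  # s, time-series cadence
    probe_radius: float = 0.8  # cm, LV pressure probe disc
    plug_penalty_scale: float = 1.0  # relative plug-wall stiffness
    filter_strength: float = 0.2  # grid-scale spectral filter per step
    seed: int = 0

    # -- plain-dict / YAML round trip -------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SUBTYPES:
                kwargs[f.name] = _SUBTYPES[f.name](**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def material_table(self) -> dict[str, float]:
        """Flat registry with the conventional material-table key names."""
        return {
            "C1_anterior": self.anterior.C1,
            "a_v_anterior": self.anterior.av,
            "b_v_anterior": self.anterior.bv,
            "C1_posterior": self.posterior.C1,
            "a_v_posterior": self.posterior.av,
            "b_v_posterior": self.posterior.bv,
            "C_chordae_systole": self.chordae.C_systole,
            "C_chordae_diastole": self.chordae.C_diastole,
            "a": self.myocardium.a,
            "b": self.myocardium.b,
            "af": self.myocardium.af,
            "bf": self.myocardium.bf,
            "as": self.myocardium.as_,
            "bs": self.myocardium.bs,
            "afs": self.myocardium.afs,
            "bfs": self.myocardium.bfs,
            "T_ref": self.active.T_ref,
            "beta_s": self.numerics.beta_s,
        }


_SUBTYPES = {
    "geometry": GeometryConfig,
    "anterior": MVLeafletParams,
    "posterior": MVLeafletParams,
    "chordae": ChordaeParams,
    "myocardium": HolzapfelOgdenParams,
    "active": ActiveTensionParams,
    "numerics": NumericalParams,
    "fluid": FluidProperties,
    "phases": PhaseBCParams,
    "windkessel": WindkesselParams,
    "tethers": TetherParams,
}
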