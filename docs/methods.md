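# Methods

`heartfsi` simulates one cardiac cycle of a coupled mitral-valve (MV) /
left-ventricle (LV) system by the immersed-boundary method with
finite-element elasticity (IB/FE): the blood is a viscous incompressible
fluid on a fixed periodic Eulerian grid, the tissue is a Lagrangian
triangulated structure whose hyperelastic first Piola-Kirchhoff (PK1) stress
is converted to an Eulerian body force by regularized-delta-function
spreading, and structure points move with the kernel-interpolated fluid
velocity.  This note records the models, the numerical choices, and what the
desk-scale configuration can and cannot show.

## Governing equations

Fluid (all CGS internally):

- momentum: rho (du/dt + u.grad u) = -grad p + mu lap u + f_s, with
  incompressibility div u = 0;
- f_s is the spread elastic/active/constraint force of the immersed
  structure; velocity interpolation uses the same four-point kernel, making
  spreading and interpolation exact adjoints.

Structure stress is split into a passive part everywhere plus an active part
on the contractile wall region only (the wall below the basal plane; the
valvular region, leaflets, chordae and tracts are passive).

## Constitutive laws (materials module)

* **MV leaflets** — incompressible fibre-reinforced solid,
  `W = C1 (I1 - 3) + a_v/(2 b_v) (exp[b_v (max(I4c,1) - 1)^2] - 1)` with one
  in-plane collagen family; anterior (C1, a_v, b_v) = (17.4 kPa, 31.3 kPa,
  55.93), posterior (10.2, 50, 63.48).  `b_v` is treated as a dimensionless
  exponent (an exponent cannot carry kPa).
* **Chordae tendineae** — 1-D incompressible neo-Hookean cables,
  `W = C (I1 - 3)`, `I1 = lam^2 + 2/lam`, nominal tension
  `t = 2C (lam - lam^-2)`, floored at zero for slack chords (the compressive
  response of a cable is not physical).  C switches from 540 kPa in diastole
  to 9000 kPa while the valve is closed (IVC + ejection), standing in for
  papillary-muscle contraction.
* **Myocardium** — Holzapfel-Ogden orthotropic law on (I1, I4f, I4s, I8fs)
  with the I4 terms clamped at 1 in compression.  The eight (a, b) moduli
  default to human-myocardium values from the literature this law family was
  fitted in (a = 0.2362 kPa, b = 10.810, a_f = 20.037 kPa, b_f = 14.154,
  a_s = 3.7245 kPa, b_s = 5.1645, a_fs = 0.4108 kPa, b_fs = 11.300); they are
  **not** values printed in the material table this package's defaults
  otherwise mirror, and are configurable.
* **Active stress** — `P_a = J T F f0 x f0`, rank one along the myofibre.
  T(t) is a phenomenological twitch, zero before end-diastole (t_act =
  0.8 s), then `(1 - exp(-s/tau_rise)) exp(-s/tau_decay)` normalised so its
  peak is exactly T_ref = 225 kPa (tau_rise = 60 ms, tau_decay = 80 ms).
  A myofilament ODE model would add calcium and length dependence; the
  twitch deliberately has neither (see Limitations).

**Zero stress at the reference state.** Each passive PK1 carries a
pressure-like correction chosen so the stress vanishes identically at F = I:
`-2 C1 F^-T` for the leaflet law and `-a F^-T` for the myocardium (the
coefficient follows from differentiating the isotropic energy term, and the
corrections are themselves gradients of `-C1 log I3` and `-(a/2) log I3`, so
the full PK1 remains an exact energy gradient — the basis of the
finite-difference oracles in the test suite).  Near-incompressibility is
enforced by the bulk penalty `beta_s log(I3) F^-T` with beta_s = 1000 kPa
(element Jacobians stay within about 5% of 1 in whole-cycle runs).

All tensor algebra is 3-D; 2-D runs embed F as plane strain with unit
out-of-plane stretch, so I1 = 3 at identity in either dimension.

## Discretization

* **Fluid**: collocated uniform grid, conservative (divergence-form)
  centered advection, centered five-point viscosity, midpoint (RK2) time
  stepping and an exact spectral projection built on the centered-difference
  symbol sin(kh)/h, so the centered discrete divergence of the velocity is
  zero to roundoff after every step.  Nyquist modes (the null space of that
  symbol) are annihilated.  An 8th-order exponential spectral filter
  (strength 0.2 per step) removes 2h-scale sawtooth modes that centered
  advection cannot damp at the high cell Reynolds numbers of blood-like
  viscosity; it leaves the resolved scales untouched to roundoff (the k = 1
  Taylor-Green mode passes through unchanged at machine precision) and
  preserves total momentum and the divergence-free property.  The
  Taylor-Green benchmark runs unfiltered and shows clean second-order
  convergence.
* **Structure**: linear triangles with one-point quadrature (exact for the
  elementwise-constant deformation gradients affine elements produce); nodal
  forces are assembled in weak form as the exact negative gradient of the
  discrete strain energy.  Chordae are 1-D segments with an explicit rest
  length (1.35x their mounted length, so they are slack in the open
  configuration and engage as the leaflets excurse toward closure).
* **Coupling**: classical four-point Peskin kernel; forces of pinned anchor
  nodes (papillary-head stand-ins, leaflet roots on the fixed annulus) are
  absorbed externally and not spread.
* **Constraints**: tract walls and housing are target-point tethered
  (k = 2e6 dyn/cm per cm depth); the valvular region uses a soft tether
  (2e4) that hardens 20x beyond a 6 mm excursion cap and is stiffened 50x
  over the first 100 ms of systole (the "pull-back" schedule); basal-ring
  nodes are penalized in the longitudinal component only, leaving radial
  motion free.  Every tether set carries a dashpot at 0.5 of critical
  damping (using the previous step's interpolated node velocity): the
  explicit spring/fluid coupling is otherwise neutrally stable and its
  oscillation grows through advection.  Damping changes no equilibrium.
* **Tract planes**: each tract's top plane is a row of marker points at
  half-grid spacing.  Open planes exert the scheduled pressure traction
  (atrial ramp at the inflow, Windkessel afterload during ejection) as a
  delta-spread pressure jump; blocked planes become rigid target-point
  "plug" walls.  The inflow plane is one-way in diastole/IVC: the plug
  engages when the (3 ms exponentially smoothed) plane flow turns outward
  and releases when the atrial-LV pressure difference favours inflow again.

## Cycle controller

Phases run DIASTOLE -> IVC -> EJECTION -> IVR exactly once per 1.2 s cycle.
The atrial pressure ramps 0 -> EDP = 8 mmHg over the 0.8 s diastole and is
held through IVC; the endocardial suction surrogate P_endo (myocardial
relaxation) ramps 0 -> 12 mmHg over 0.4 s and back to 0 at end-diastole,
applied as an outward normal traction on the contractile endocardium.  The
binary aortic valve opens when the probed LV pressure exceeds the aortic
pressure (initially 85 mmHg); ejection couples a three-element Windkessel
(Ca dPp/dt = Q - Pp/Rp, Pao = Q Rc + Pp) advanced by an exact exponential
update for piecewise-constant Q, and ends when forward flow stops (the
controller requires forward flow to have been established first, so the
opening transient cannot immediately re-close the valve).  The LV pressure
probe is the mean projection pressure over a 0.8 cm disc at the cavity
centroid, referenced to a far-field patch (pressure on a periodic box is
defined only up to a constant).

Time steps follow the phase schedule dt0 / 0.25 dt0 (first 100 ms of
systole) / 0.125 dt0 (remaining systole), with dt0 = min(1.22e-4 s, a
stability estimate from the stiffest element/tether and the kernel-footprint
fluid mass rho (2h)^2 at safety 0.75).  At the default 64^2 grid this gives
dt0 ~ 1.0e-4 s and ~30k steps per cycle.

## Synthetic geometry

The default chamber is an idealized 2-D long-axis (LVOT-view) section chosen
to preserve the topology of the imaged system at desk scale: an elliptical
wall band (semi-axes 3.0 x 4.0 cm, thickness 0.8 cm, two element layers)
open at the base; rule-based myofibres rotating -60 deg -> +60 deg from
endocardium to epicardium about the local circumferential direction; a
passive valvular/housing region above the basal plane; two vertical tract
channels (2.0 cm wide) separated by a pillar (the aorto-mitral continuity);
two unequal leaflets (anterior 2.4 cm, longer than the posterior 1.4 cm)
hanging from the annulus with 16 chordae running to two fixed papillary
stand-in anchors; and a binary valve plane at the top of the outflow tract.
Channel widths are sized several grid cells beyond the kernel half-width so
the effective orifice is not consumed by delta-function smearing.  A
valve-in-a-rigid-channel builder provides the valve-only test
configuration.  Meshes are deterministic given (config, seed); optional
node jitter is seeded.

Volumes and flows are reported in mL and mL/s using a configured
out-of-plane depth of 3.6 cm — a reporting convention that makes the 2-D
compartment (~138 mL at rest, ~175 mL at end-diastole) comparable to
physiological scales, not a physical claim.

## What the desk-scale runs show (and what they do not)

The configuration reproduces the *mechanisms* and *directions of effect* of
the full 3-D system: suction-dominated early filling with peak mitral inflow
~200 mL/s, a closed iso-volumetric contraction (cavity volume constant to
<1%), pressure-triggered valve opening, Windkessel-loaded ejection with peak LV
pressure ~177 mmHg against an afterload loading up from 85 mmHg, and a
P_endo sweep in which filling volume, peak
inflow and ejection fraction increase strictly while iso-volumetric
contraction shortens — the qualitative content of the relaxation-impairment
experiment.  Absolute magnitudes are not comparable to the 3-D
patient-specific values: a 2-D ring cannot lengthen or twist, so its
compliance and ejection fraction (~19% here) are several-fold smaller than
an imaged ventricle's, closure regurgitation is largely suppressed by the
one-way plane, and leaflet closure geometry is only cartoon-faithful.
IVC shortening with stronger suction arises here purely from the higher
passive recoil pressure stored at the larger end-diastolic volume; the
length-dependent activation that amplifies this effect in myofilament
models is deliberately out of scope.

## Numerical choices and degenerate inputs

* Inverted elements (det F <= 0) raise an error naming the element; CFL
  violations name the admissible dt; non-finite fields abort with a
  diagnostic state summary.
* The aortic-valve pressure comparison keeps the previous state on exact
  ties (no chattering).
* Windkessel defaults Rc = 0.05, Rp = 1.1 mmHg s/mL, Ca = 1.3 mL/mmHg are a
  calibration placing afterload in the 80-160 mmHg band for
  stroke-volume-scale pulses, not literature values.
* Fluid rho = 1.0 g/cm^3, mu = 0.04 g/(cm s) are conventional blood values,
  also not from the mirrored material table.
* The compiled (numba) assembly and transfer kernels duplicate the
  vectorized reference implementations in scalar plane-strain form; the test
  suite asserts agreement to roundoff between both paths.

## Problem sizes used in the shipped checks

Tests and the acceptance script run the default 2-D chamber at the 64^2
grid (~480 structure nodes, ~650 triangles, 16 chords, one cycle in ~30-40 s
on one core); the P_endo sweep is 4 such runs.  The Taylor-Green benchmark
uses 64^2 and 128^2 grids to t = 1 s.  These sizes were chosen so the whole
verification suite completes in minutes while every qualitative property
above is resolved.
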