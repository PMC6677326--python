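# Methods

`circwave` simulates the whole circulation by coupling three layers: a
distributed vascular model (transmission-line trees for the large systemic
arteries and veins), lumped nonlinear windkessel beds for the peripheral
microcirculation, and a contractile heart with valves, pericardium and a
pulmonary windkessel. This note documents the governing models, the
numerical choices, the calibration strategy, and the limits of what the
test suite demonstrates.

## Vascular transmission lines

Each vessel is a 1D tube governed by the telegrapher's equations,

    -dq/dz = C dp/dt,
    -dp/dz = L(α0) dq/dt + R(α0) q,

the linearized 1D reduction of mass and momentum balance once convective
acceleration is neglected and wall shear is estimated from an approximate
oscillatory velocity profile. The per-unit-length inertance and resistance

    L = g(α0) ρ / A0,      R = h(α0) 8πη / A0²

carry profile-correction factors evaluated at the characteristic Womersley
number α0 = r0 √(ρω0/η) (ω0 = 2π/T). We compute g and h from exact
Womersley oscillatory-flow theory — the Bessel-function longitudinal
impedance of a rigid tube at ω0 — with series and scaled-Bessel branches
for numerical robustness. The classical boundary-layer approximations to
these factors agree with this choice to within a few percent over their
validity range; using the exact forms removes one approximation while
keeping the quasi-linear "one frequency, one profile" treatment: R and L
are frozen at the reference geometry, while compliance follows the
nonlinear wall law beat by beat.

The wall law is a power law with a collapse term,

    p_trans(A) = -p_ext + p0 [ (1+b)(A/A0)^{1+k/3} - b A0/A ],

so that p_trans(A0) = p0 - p_ext exactly, stiffness rises with pressure
(exponent controlled by k), and transmural pressure diverges to -∞ as the
lumen closes (b = 0.02 throughout). Compliance per unit length is the
analytic derivative C = dA/dp_trans. A useful property: at the reference
state the inviscid wave speed c = √(A dp/dA / ρ) depends only on (p0, k, b),
not on the calibre, so stiffness coefficients translate directly into
wave speeds.

Derived wave quantities use the weak-loss, frequency-independent
approximation of the propagation constant: c = 1/√(LC), Zc = √(L/C),
attenuation a = R/(2Zc) (the first-order expansion of √((R+iωL)(iωC))).

## Discretization and time stepping

Trees are read from CSV tables, validated (tree topology, terminal
specifications, flow fractions summing to one) and chopped into elements of
nominal length Δz = 0.02 m (ceiling rule, linear taper in radius). The TL
solver is a ladder network: one flow unknown per element
(L dq/dt + R q = Δp) and one pressure unknown per node
(C_node dp/dt = net inflow, with C_node the sum of adjacent half-element
compliances at the current nodal pressure). Junctions are ideal — a single
nodal pressure, exact flow conservation, no loss coefficients.

Time integration is a one-step θ-scheme solved implicitly as a single
sparse linear system per step (elements, nodes, windkessel beds and all
coupling conductances together), with the pressure-dependent coefficients
frozen at the start-of-step state. θ = 0.5 (trapezoidal) is used for open
benchmark domains; the closed loop uses θ = 0.55, whose mild high-frequency
dissipation suppresses node-scale ringing excited by valve events in the
stiff leg arteries while remaining second-order accurate in practice.
Δt = 1 ms throughout; halving Δt and Δz changes the mid-aortic systolic
pressure by well under 0.5 mmHg (checked on the open benchmark domain,
where the refinement costs a few seconds; the refinement physics —
discretization insensitivity of the vascular solver — is the same as in
the closed loop).

**Conservative volume update.** A semi-implicit compliance C(p⁰)·Δp does
not exactly equal the wall-law volume change over a step; integrated around
a cardiac cycle this quadrature bias acts like a slow leak (several
ml/cycle in early versions, enough to prevent periodic convergence, since
the venous pool recharges through R_p with a ~40 s time constant). The
solver therefore treats volume as the conserved state: the node equation
guarantees C·(p¹-p⁰) equals the discrete net inflow, so stored volumes are
advanced exactly and pressures are re-derived from the wall law (a
two-iteration Newton per node, with the stored volume pinned to machine
precision). Windkessel beds and the pulmonary windkessel carry volume
states the same way. With this, closed-loop volume drift per converged
cycle is at round-off (≪ 0.1 ml).

## Terminal windkessel beds

Each terminal artery drains through a nonlinear three-element windkessel
into its terminal vein: wave impedance in series, compliance to ground on
both the arterial and venous side, peripheral resistance in between.
Compliance and impedance are re-derived from the local wall law every step:

    C_AV = l_AV dA/dp,      Z_wave = ρ c / A = √(ρ (dp/dA) / A),

with l_AV = 6 q_AV^{1/3} (SI units; 0.26 m for the whole systemic flow of
85 ml/s) and q_AV the bed's share of the systemic flow per the fixture
fraction table (regional split 21% head / 47% abdomen / 18% pelvis+legs /
14% arms). The square-root grouping of Z_wave is the dimensionally
consistent reading of the bed impedance (Pa s m⁻³) and coincides with the
characteristic impedance of the attached tube end.

R_p is fixed per scenario from the calibration R_p = (p_art - p_ven)/q_AV
applied at the bed's own nodes: the arterio-venous difference is taken
between the scenario's *operating* mean arterial pressure and the venous
reference, net of the series wave impedances. The operating mean is
parametrized as a fraction of the wall-law reference pressure
(`map_factor`, 0.88 in normotension and 0.95 in hypertension), pinned so
the closed loop reproduces the published pressure indices; this resolves
the underdetermined terminal parameter set (see Calibration). Because the
hypertensive scenario raises p0 (and with it every R_p) without touching
the windkessel machinery, large changes in haemodynamic load need no
manual re-tuning of terminal parameters.

## Heart

Chambers are one-fibre contractile cavities: with homogeneous myofibre
stress σ_f in a thick wall of volume Vw around a cavity of volume V,

    p_trans = (σ_f / 3) ln(1 + Vw/V).

Sarcomere length derives from the one-fibre kinematic measure
(V + Vw/3)^{1/3}; total stress is an active raised-cosine twitch scaled by
a linear sarcomere-length dependence plus a power-law passive component
(titin/ECM in parallel). Atria activate at cycle start, ventricles 170 ms
later. The LV and RV are separate one-fibre chambers coupled through the
pericardium — a compliant bag with p ∝ (V_heart/V_ref)^{10} — rather than
through an explicit three-wall septal force balance; septal interaction is
secondary for the systemic pressure/wave quantities this package computes.
Valves follow the unsteady Bernoulli equation with a phenomenological
orifice (instant opening on a positive gradient, exponential closure to a
small leak area, τ = 3 ms). The pulmonary circulation is a single
nonlinear 3WK between the pulmonary valve and the left atrium, reusing the
terminal-bed machinery.

The heart advances by ten semi-implicit sub-steps inside each vascular Δt.
The aortic valve sees the root's characteristic impedance as a load line
around the step-start operating point — this represents the wave the
ejected flow launches into the aorta and is what keeps the staggered
heart/network coupling stable. Boundary flows are exchanged with exact
volume bookkeeping (the vena-cava return computed by the network is
committed to the right atrium verbatim).

A per-cycle circulating-volume controller (the pressure–flow regulation
idea familiar from closed-loop whole-heart models) injects or withdraws
volume at the venous root in proportion to the mean-flow error until the
systemic flow equals 85 ml/s *and* is stationary, then freezes; the final
recorded cycles are therefore strictly closed. The venous tree starts
2.5 mmHg above its reference pressure, near its working point, which
shortens the slow venous-pool charging transient.

## Reference PWP solver

The benchmark comparator solves the same equations and wall law with a
deliberately different discretization: pressure *and* flow on grid nodes
(flow duplicated per branch at junctions), two-point trapezoidal element
integrals in space, BDF2 in time (backward-Euler startup). Boundary
conditions (half-sinusoid root inflow: peak 350 ml/s, duration 0.3 s,
period 0.85 s; identical 3WK terminations to fixed venous pressure) match
the TL run exactly, so residual disagreement measures discretization only.
On the aorta + left-arm domain the two solvers agree to δ_p ≲ 0.1% and
δ_q ≲ 0.4% per tube — comfortably inside the published tolerance band
(≤ 2.9% / ≤ 5.6%), which also covered a delay-line attenuation
approximation that this ladder implementation does not need to make.

## Analysis layer

* **Error metrics**: per-tube RMS and relative errors over one converged
  cycle at the mid-tube element; pressure errors normalized pointwise by
  the reference, flow errors by the reference maximum.
* **Foot detection / PWV**: the foot is the maximum of the second time
  derivative within the systolic upstroke (window found by walking back
  from the steepest-rise point; earliest sample on curvature ties; optional
  moving-average smoothing for noisy signals). PWV divides the fixed
  along-tree path difference between the carotid and femoral terminal
  nodes by the foot-to-foot transit time. The path is the *difference* of
  root distances — the distance the wavefront actually travels between the
  two feet; a through-path would double-count the shared arch.
* **Wave intensity**: time-derivative convention,
  dI± = ±(dp/dt ± ρc dU/dt)²/(4ρc), so dI = dI⁺ + dI⁻ = (dp/dt)(dU/dt)
  in W m⁻² s⁻². Velocity is q/A with q co-located to the pressure node by
  averaging the two adjacent element flows (a half-element offset acts
  like a deliberate p/U misalignment and corrupts the decomposition); c is
  the local wall-law wave speed at the probe's mean pressure. The BCW
  onset is defined from the trough of |dI⁻| between ejection onset
  (aortic-valve opening, read exactly from the orifice-area channel) and
  the BCW peak: the onset is the last sample within 1% (of the
  trough-to-peak span) of that baseline. A plain 1%-of-peak threshold
  misfires when residual diastolic backward content does not decay to
  zero before ejection.
* **Dicrotic notch**: a local aortic-pressure minimum with a > 0.5 mmHg
  rebound within 100 ms of aortic valve closure. Present in the
  distributed (TL) afterload, absent when the systemic circulation is
  lumped into a single 3WK.

## Fixture tables and calibration

The packaged vessel tables (`*_synthetic.csv`) are synthetic
reconstructions, not transcriptions: they follow the published
human-network literature in style (Reymond-type arterial geometry,
Müller–Toro-type venous calibres at 1.4× the arterial radius, capped at
12 mm), with cerebral and coronary sub-trees excluded, legs at k = 30,
veins at k = 10 and compound benchmark tubes "1+2"/"19+27". The
undocumented degrees of freedom — aortic/arm stiffness coefficients,
terminal calibres, the operating-mean fraction, and the cardiac
parameters — were calibrated once so the normotensive closed loop
reproduces the published haemodynamic indices (aortic 128/75 mmHg at
85 ml/s mean flow, carotid-femoral PWV 5.5 m/s) and then frozen; the
hypertensive scenario (p0 105→135 mmHg, k+6 on all systemic arteries) is
run with the identical heart and machinery. Aortic k ≈ 1.1 with a
reference-state aortic wave speed of ≈ 4.3 m/s and a total arterial
compliance of ≈ 1.7 ml/mmHg (tree + beds) at the operating point are the
result of that calibration, all physiologically sensible for a young
adult. A small myocardial viscosity (600 Pa·s) damps the beat-to-beat
mechanical alternans that an undamped one-fibre chamber develops at
hypertensive afterload.

Problem sizes: the closed loop discretizes ~6 m of arteries and ~6 m of
veins into 634 elements (≈1300 unknowns) and converges in 30–50 cycles of
0.85 s at Δt = 1 ms (about 2 s wall-clock per cycle); the benchmark domain
is 83 elements and runs both solvers in under a minute.

## What the tests do and do not show

The suite verifies the numerics (profile factors against an independent
finite-difference Womersley solve, wall-law derivatives against central
differences, d'Alembert transport on a matched lossless tube, exact
volume conservation, cross-solver agreement, grid-refinement
insensitivity, bit-identical determinism) and the published study
conditions (pressure indices, PWV, wave-timing and venous pulsatility
bands). Because the vessel tables are reconstructions, agreement with the
published haemodynamic indices demonstrates that the model class
reproduces those operating points under calibration — not that the
original network was recovered. Quantities that depend most strongly on
the lost inputs (notably the absolute backward-wave intensity, which is
set by terminal reflection strength) are the least transferable; wave
*timing* (BCW delay ordering and magnitudes) is robust.

## Known limitations

Convective acceleration, junction loss coefficients, vessel
viscoelasticity, venous valves and the skeletal-muscle pump are not
modelled; cerebral and coronary trees are excluded; the one-fibre chambers
omit explicit septal mechanics and force-velocity dependence, so
isovolumic pressure transients are somewhat idealized. The lumped
single-3WK afterload mode exists only for the qualitative dicrotic-notch
comparison.
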