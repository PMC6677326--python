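# circwave

Closed-loop heart–vessel simulation with the large systemic arteries and
veins modelled as trees of nonlinear transmission lines.

## What this is for

Pulse waves launched by the ejecting ventricle travel along the arterial
tree, reflect at branch points and peripheral beds, and return to shape the
central pressure waveform — the physics behind clinical indices such as
carotid-femoral pulse wave velocity (PWV), pressure augmentation and wave
intensity. Lumped (windkessel-only) circulation models cannot represent any
of this. `circwave` targets researchers studying heart–vessel interaction:
it couples a distributed vascular model to a contractile whole-heart model
so that both the cardiac and the wave-transmission side of questions like
"what changes in hypertension?" can be simulated in seconds per heartbeat
on a laptop.

## The model in brief

* **Vessels** — every segment obeys the telegrapher's equations
  `-∂q/∂z = C ∂p/∂t`, `-∂p/∂z = L(α₀) ∂q/∂t + R(α₀) q`, with inertance
  `L = g(α₀)ρ/A₀` and resistance `R = h(α₀)8πη/A₀²` corrected for the
  oscillatory velocity profile at the characteristic Womersley number α₀,
  and a nonlinear pressure–area wall law
  `p = p₀[(1+b)(A/A₀)^{1+k/3} − bA₀/A]` whose derivative supplies the
  pressure-dependent compliance (and a collapse branch for veins).
* **Peripheral beds** — each terminal artery drains into its terminal vein
  through a nonlinear three-element windkessel whose compliance
  `C = l_AV·dA/dp` and wave impedance `Z = ρc/A` are re-derived from the
  local wall law every millisecond (`l_AV = 6 q_AV^{1/3}`).
* **Heart** — four one-fibre contractile chambers
  (`p = σ_f/3 · ln(1+V_w/V)`), unsteady-Bernoulli valves, a compliant
  pericardial bag, and a pulmonary windkessel close the loop.
* **Numerics** — implicit θ-scheme on the whole ladder system at
  Δt = 1 ms / Δz = 2 cm, with volume as the exactly conserved state.
* **Verification** — an independent 1D pulse-wave-propagation solver
  (nodal p/q, trapezoidal-in-space, BDF2-in-time) runs the same equations
  on the same benchmark domain; the two solvers cross-validate to a small
  fraction of a percent.

Scenarios: `REF` (normotension, p₀ = 105 mmHg), `HYP` (hypertension,
p₀ = 135 mmHg and stiffness k+6 in all systemic arteries), and `BENCH`
(open aorta + left-arm domain driven by a half-sinusoid inflow, both
solvers). Vessel geometry ships as editable CSV tables (synthetic
reconstructions of published human networks — see `docs/methods.md`).

## Worked example

```bash
circwave run --scenario ref --out runs/ref
```

runs the normotensive closed loop to periodic convergence (~50 cycles,
about two minutes) and prints, among other entries:

```
"p_sys_mmhg": 128.4,
"p_dia_mmhg": 77.0,
"p_pulse_mmhg": 51.4,
"pwv_m_s": 5.5,
"mean_systemic_flow_ml_s": 85.1,
```

i.e. an aortic pressure of ~128/77 mmHg at a cardiac output of 85 ml/s and
a carotid-femoral PWV of 5.5 m/s — a healthy young adult. The same command
with `--scenario hyp` yields ~188/91 mmHg and PWV 7.9 m/s: raised mean and
pulsatile pressure with a stiffened, earlier-reflecting arterial tree.
`runs/ref/` also contains the pressure/flow traces (`traces.csv`), the
carotid wave-intensity decomposition (`wia.csv`: forward compression wave,
backward compression wave from reflections, end-systolic forward expansion
wave) and the valve state channel. The benchmark comparison,

```bash
circwave run --scenario bench --out runs/bench
```

prints the per-tube error table between the transmission-line and the
reference pulse-wave-propagation solver (RMS and relative errors for
pressure and flow at each mid-tube element).

The same functionality is available as a library:

```python
from circwave import ScenarioConfig
from circwave.scenarios import run_closed

out = run_closed(ScenarioConfig.ref())
print(out["indices"])        # p_sys/p_dia/p_pulse [mmHg], PWV [m/s]
print(out["wia_features"])   # BCW delay, FCW/BCW/FEW peak intensities
```

## Layout

| module | contents |
|---|---|
| `circwave.constitutive` | wall law, Womersley profile factors, TL coefficients |
| `circwave.network` | vessel-table I/O, validation, discretization |
| `circwave.tl_solver` | implicit transmission-line solver (open & closed loop) |
| `circwave.pwp_solver` | independent reference 1D solver (benchmark) |
| `circwave.windkessel` | nonlinear terminal beds |
| `circwave.heart` | chambers, valves, pericardium, pulmonary bed |
| `circwave.analysis` | error metrics, foot detection, PWV, wave intensity |
| `circwave.scenarios` | REF/HYP/BENCH configuration and orchestration |
| `circwave.cli` | `circwave run` / `circwave report` |

`docs/methods.md` documents the model equations, numerical design
decisions, the fixture calibration and known limitations.
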