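# Methods

This note records the model equations as implemented, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the formulation was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1D pulse-wave model

Each vessel segment carries the area/flow form of the 1D blood-flow
equations

    A_t + Q_x = 0
    Q_t + (α Q²/A)_x + (A/ρ) P_x = − C_f Q/A

with density ρ = 1060 kg/m³. Pressure closes through the algebraic
tube law `P = P_ext + β(√A − √A0)` with
`β(A0) = √π h E / ((1−ν²) A0)`; the printed form of this constitutive
relation in the source literature is typeset without the square roots,
which is dimensionally inconsistent, so the standard square-root form of
the 1D solver lineage is used. Wall defaults h = 0.945 mm,
E = 1.41 MPa, ν = 0.5, P_ext = 0 give a quasi-rigid vessel at coronary
pressures; an optional `stiffness_multiplier` lets tests push into the
truly rigid limit. The characteristic wave speed is
`c = √(β√A/(2ρ))` (≈ 20 m/s at the 3.9 mm ostial diameter).

Friction: the momentum sink is −C_f Q/A with the *kinematic*
coefficient `C_f = 22π µ/ρ` (m²/s). The pairing α = 1.1 with 22πν
corresponds to a blunted polynomial velocity profile; the exact α, C_f
values used in the original experiments are not published, so both are
config-exposed (`BloodProperties(alpha=..., mu0_cP=...)`). Dynamic
viscosity derives from hematocrit, µ = µ0/(1−φ), µ0 = 1.2 cP plasma.

## Numerical scheme

Interior nodes advance with a MacCormack predictor–corrector: the
predictor uses forward spatial differences of the fluxes [Q, αQ²/A] and
of P, the corrector backward differences of the predicted values; sweep
directions are fixed (not alternated) — the literature does not pin the
variant down, so the choice is documented here and backed by a
grid/time refinement test (halving Δx and Δt moves the last-cycle mean
distal pressure by < 0.5%). In mass-conservation form the scheme's
numerical flux is F_{i+1/2} = (Q_{i+1} + Q*_i)/2, which the
closed-domain volume-conservation test exploits (volume conserved to
round-off with reflective ends).

Boundary and coupling nodes close the system through Riemann
invariants W± = u ± 4c extracted at the adjacent interior node:

* **Inlet**: prescribed Q(t) from the inflow waveform; the inlet area
  solves u − 4c(A) = W⁻ by scalar Newton.
* **Bifurcation**: six boundary unknowns (A, Q at the parent end and
  the two child starts) constrained by mass conservation, continuity of
  total pressure P + ½ρ(Q/A)² across all three ends, and three outgoing
  characteristic invariants. Eliminating each Q through its invariant
  reduces the system exactly to a 3×3 Newton in the three areas
  (analytic Jacobian, damped to keep areas positive, relative update
  tolerance 10⁻¹³, ≤ 60 iterations).
* **Stenosis interface**: a zero-length internal interface splitting
  the host segment at the lesion center — the element is an integral
  model, so meshing a narrowed throat would double-count the loss. Flow
  continuity plus a total-pressure jump equal to
  ΔP_s(Q) = aQ + b|Q|Q + d·dQ/dt, with a = µK_v/(2π r_u³),
  b = ρK_t(A_u/A_s − 1)²/(2A_u²), d = ρK_u L_s/A_u, and dQ/dt by
  first-order backward difference (matching the boundary order of the
  scheme). Reduces to a 2×2 Newton in the two interface areas.
* **Terminal**: 2-element Windkessel C dP/dt = Q − P/R_p integrated by
  implicit Euler, coupled through the forward characteristic; scalar
  Newton in the terminal area.

Grid: uniform per-segment spacing ≤ 500 µm (default), node count
⌈L/Δx⌉+1 so end nodes sit exactly on segment boundaries. Time step
10⁻⁵ s by default; `dt_s=None` picks the largest step satisfying a 0.9
CFL number with margin, and the CFL ratio is monitored every step
(startup violations refuse to run and report the maximum stable Δt).

**Initialization.** Cycles to convergence are expensive, so the state
starts from a nonlinear resistor-network solve: per-part viscous
resistances ∫22πµ/A0² dx, linearized stenosis elements a + b|Q|
(5 fixed-point sweeps), terminal R_p; node pressures march down from
the implied ostial pressure and areas follow the inverse tube law.
Typical runs then converge in 3–6 cycles.

**Convergence.** After every cycle the relative L2 difference of the
distal-pressure waveform (the probe used for FFR; the quantity of
clinical interest) against the previous cycle is computed; converged
means < 10⁻³, with a hard cap of 20 cycles and a minimum of 3 (2 for
the scaled-down UQ runs).

**Area deformation.** Reported as the mean over nodes and time of
|A − Ā_node|/Ā_node on the final cycle, i.e. pulsatile wall motion
about the local cycle mean. Deformation relative to the zero-pressure
reference A0 would be dominated by static pressurization (~2% at
90 mmHg) rather than by wall motion, which is not what a quasi-rigid
claim is about; the healthy-tree check asserts < 2% at the default
wall.

## Boundary conditions and personalization

Ostial mean flow = cardiac output × coronary fraction × dominance
split. The coronary fraction (4%) and splits (left:right 70:30
right-dominant, 80:20 left-dominant, 75:25 co-dominant) are
physiological conventions, config-exposed, since only "a fraction of
cardiac output via flow dominance" is specified upstream. Hyperemia
multiplies the left inflow by 4, the right by 3, and every terminal
resistance by 0.22; both scalings are applied simultaneously (the model
is deliberately over-determined this way — inflow is prescribed, so the
Windkessel sets the pressure level rather than the flow).

Terminal resistances follow R_i = (P_mean/Q_ostial)·Σ_j r_j³/r_i³ with
Q_ostial the *resting* ostial flow; the parallel combination equals
P_mean/Q_ostial identically (asserted to 10⁻¹²). Compliance is constant
at 9 µcm⁴s²g⁻¹ = 9·10⁻¹¹ m³/Pa per terminal (≈ 0.012 mL/mmHg).

Cardiac output enters twice — as the inlet-flow scale and as Q_ostial
in the resistance rule — and the two roles are separable
(`PatientRecord.co_inlet_Lmin` / `co_resistance_Lmin`): the streamlined
analysis generalizes the inlet role and keeps the resistance role
patient-specific, and the UQ perturbation applies only to the
resistance role.

Inflow waveforms: two analytic, unit-mean, two-phase shapes (systole =
35% of the period), the left diastolic-dominant (≥ 60% of the
flow-time integral in diastole, reflecting systolic compression of the
left coronary bed), the right more balanced. The measured canonical
waveform shapes are not published as data, so these are parameterized
stand-ins; any sampled waveform can be supplied instead
(`build_inflow(shape=...)`). Time-averaged FFR is insensitive to the
shape details — only the mean and the gross systolic/diastolic split
matter — which is also why waveform shape is generalized from the
outset in the streamlined variants.

## FFR extraction

FFR = (cycle-mean distal pressure)/(cycle-mean ostial pressure) from a
converged hyperemic run; ≤ 0.80 classifies as ischemic (ties
inclusive). Pa is the *simulated* ostial pressure, mirroring the
invasive Pd/Pa measurement, not the clinical MAP input. The distal
probe walks the requested arc length downstream from the stenosis
distal end, following the larger-radius child at bifurcations (the
main-branch continuation a physician would interrogate); requests
beyond the tree report the maximum reachable length. Results refuse to
compute from non-converged runs.

## Uncertainty quantification

Design: second-order Saltelli, blocks [A, B, AB_i…, BA_i…], n(2k+2)
rows, built on a scrambled Sobol sequence in 2k dimensions mapped
through the normal inverse CDF; deterministic per seed. Estimators:
Saltelli-2010 for main effects S_i, Jansen for total effects S_Ti,
Saltelli-2002 for closed second-order effects. The reported S_ij is the
*pure* interaction, closed_ij − S_i − S_j (the index that vanishes for
additive models); the closed index itself is recoverable by adding the
main effects back. Percentile bootstrap (B = 1000 by default) over base
rows gives 95% CIs; the index set counts as converged when every
main/total CI width is below 10% of the largest index, and inputs with
max(S_i, S_Ti) > 0.05 count as significant.

Input transforms: `value` replaces (distal location), `factor`
multiplies (CO, MAP), `addition` shifts percentage points (degree).
Normal tails produce non-physical values, so degree is clipped to
[0, 99.5]%, factors to ≥ 0.05, and sampled distal locations to the
reachable downstream length; degree perturbations hold the measured
minimal luminal radius r_s fixed and re-derive the reference radius r_u
(the estimation direction used clinically). Indices aggregate over
cases by concatenating per-case blocks, so between-case variability
enters V[Y] while the pairing structure is preserved. Failed
simulations are logged and their base rows dropped; more than 1%
failures aborts the campaign.

Reclassification study: per case, m standard-normal draws are fixed
once and scaled by the SD multiplier (nested design), perturbing only
the CO factor and the degree addition; distal location and MAP stay at
baseline. The curve reports the mean within-case FFR range per level
and the reclassification proportion *cumulatively* over increasing
multipliers — a case, once its classification has flipped at some
level, stays counted — which makes the proportion non-decreasing by
construction and matches the nested-draw semantics.

## Diagnostic evaluation

Positive = reference FFR ≤ 0.80. Rates are percentages with exact
Clopper–Pearson 95% CIs (small counts make Wald intervals misleading);
Pearson correlation by least squares; Bland–Altman differences
(predicted − reference) with ±1.96 SD limits. ROC sweeps all empirical
cutpoints (classify at pred ≤ c), AUC by trapezoid — identical to the
Mann–Whitney U normalization, which the tests assert — and the optimal
threshold maximizes Youden's J, reported as the interval between the
achieving cutpoint and the next larger predicted value (any threshold
inside classifies identically).

Model variants: baseline (all patient-specific); semi-streamlined
(generalized MAP 87.3 mmHg, HR 70.8 bpm, hematocrit 39.2%, inlet-CO
4.5 L/min, waveform, ostial diameter 3.9 mm; patient-specific
resistance-CO, stenosis, tree, distal location); streamlined
(additionally distal location 30 mm).

## Synthetic data

Trees are strictly bifurcating with Murray's law r_p³ = r_maj³ + r_min³
(asymmetry γ = r_min/r_maj = 0.85 by default), constant radius per
segment, lengths = 18 radii with mild seeded jitter, pruned in pairs
below 0.5 mm radius (the angiographic reconstruction limit). The
default cohort tree has depth 3 (7 segments) with the focal lesion
mid-segment on the *major child* of the root: a proximal main-branch
lesion past the first bifurcation, so part of the ostial flow bypasses
it as in a real left coronary tree. Cohort scalars: CO N(4.5, 1.5)
L/min, HR N(70.8, 13.7) bpm, SBP/DBP N(125.8, 25.8)/N(67.1, 12.7) mmHg
with MAP = (SBP + 2·DBP)/3, hematocrit N(39.2, 4.0)% (no published SD;
a typical adult spread), degree N(55.6, 17.2)% truncated to [20, 95],
lesion length N(10, 3) mm truncated to [3, 20] (no published
distribution; typical focal lesions), dominance 79.6/12.2/8.2%
right/left/co-dominant, distal location U(5, 65) mm clamped to the
reachable downstream length of the generated tree.

What the generator does **not** emulate: angiographic tortuosity,
eccentric or diffuse plaque, taper within segments, ostial/bifurcation
lesions, serial stenoses, collateral flow, autoregulation, per-patient
hyperemic response. Tests passing on this material validate the
numerics, the couplings and the statistical machinery — not clinical
accuracy on real anatomy, which requires reconstructed patient
geometries and invasive reference measurements.

## Problem sizes used by the test suite

Simulation tests run single vessels or 3-segment trees at the default
500 µm / 10⁻⁵ s resolution. The input-importance campaign uses two
synthetic cases at Saltelli n = 64 (1280 simulations) with 1.5 mm
spacing, CFL-limited time step and a 12-cycle cap — a deliberately
scaled-down version of the full campaign, which at production scale
runs > 10⁶ simulations and is exposed through the same
`uq_pipeline(n=..., cases=...)` interface. The reclassification test
uses 4 cases × 6 draws × 3 non-zero SD levels.

## Known limitations

* Elastic (not rigid) walls with a single global wall law; no
  viscoelasticity, no per-vessel stiffness.
* Prescribed inflow means no autoregulation: severe lesions raise
  ostial pressure rather than reducing flow, pushing FFR lower than
  physiology would allow. Monotonicity and orderings are unaffected.
* Junction losses beyond total-pressure continuity are not modeled;
  trifurcations must be pre-split into two bifurcations.
* The MacCormack variant (fixed sweep direction, first-order boundary
  closures) is one of several defensible choices; refinement tests
  quantify, rather than eliminate, the discretization error.
* Sensitivity of FFR to the velocity-profile parameters (α ∈ [1.0,
  1.33] and the paired friction coefficient) is exposed through
  configuration but not asserted, since the source values are
  unpublished.
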