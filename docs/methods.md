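# Methods

`vqsim` simulates ventilation–perfusion (V/Q) matching in a single lobe of a
rat lung. Four sub-models are coupled: a synthetic 2-D pulmonary vascular
network, lumped-parameter (0D) vessel hemodynamics, compartmental oxygen
transport with Hill hemoglobin binding, and an empirical hypoxic pulmonary
vasoconstriction (HPV) controller that closes the loop from alveolar oxygen
back onto arterial tone. This note records the model equations as
implemented, the parameter choices that matter, the design decisions taken
where the formulation was genuinely open, the numerical strategy, and what
the synthetic setting does and does not say about real lungs.

## Vascular network synthesis (`netgen`)

A lobe-shaped polygon (~9 mm across) is meshed with a jittered grid of
points (default spacing 300 µm). The tree grows distributively: each
iteration finds the mesh point farthest from the current network (node-wise
distance), attaches a new node to the nearest network node that still has
fewer than two daughters (the root keeps a single trunk), and steps a fixed
grow distance Δg toward that point (Δg = 50 µm, K = 1000 nodes by default).
Ties break deterministically (lowest point index, then lowest node id), so a
network is a pure function of (mesh, root, K, Δg).

Maximal node chains between branch points become vessel segments; the
venous tree mirrors the arterial topology, lengths and radii exactly.
Each mesh point is assigned to the nearest terminal segment (distal-node
distance by default), defining perfusion zones with area fractions
`a_j = points_in_zone / total_points` (uniform area weight per point since
no finite-element cell areas exist here).

Terminal design flows are `a_j · QP*` with QP* = 0.66 ml/s, summed up the
tree. Radii then solve Poiseuille's law under a closure relating pressure
drop to flow. Four closures are implemented:

- **constant wall shear** (default): `8 µ(r) q / (π r³) = τ_w`, the
  Murray-type design rule, radii ≈ q^(1/3);
- **constant velocity**: `q/(π r²) = v*`;
- **constant gradient**: `ΔP = l/k_p`, radii ≈ q^(1/4);
- **as-printed**: `ΔP = q l / k`, in which flow and length cancel and the
  tree is taperless (kept for reference).

The constant-shear default was chosen because it is the only implemented
closure under which the HPV tone differential can redistribute flow between
zones (resistance concentrates distally, where tone is zone-specific); under
the constant-gradient closure every path's resistance is essentially
proportional to its length at design flow and simulated HPV *increases*
flow heterogeneity, contrary to the phenomenon being modeled. τ_w = 3.2 mmHg
is calibrated once so the dilated whole-organ resistance of generated
networks falls in the isolated-perfused rat lung range (~25–30 mmHg·s/ml at
the design flow); this gives root radii ≈ 230 µm and terminal radii
≈ 50–60 µm. Apparent viscosity follows the in vitro diameter/hematocrit law
(Fahraeus–Lindqvist minimum near 7 µm, large-tube asymptote 3.2 at Hct
0.45) scaled by a 1.2 cP plasma viscosity.

Vessels are classified by diameter-defined Strahler ordering: a classic
Strahler pass, then iterative reassignment against per-order diameter
mean ± SD bounds (≤ 30 iterations), constrained so a parent's order is
never below its daughters'. Generated 1000-node trees span ≥ 4 orders with
monotone mean diameters.

## Vessel mechanics (`mechanics`, `engine`)

Each segment is a two-state RLC element with a visco-elastic (Voigt) wall:

    C dP_v/dt = q_in − q_out
    L dq_in/dt = P_in − P_out − R q_in
    P_out = P_alv + P_v + R_D (q_in − q_out),   R_D = v/C

with Poiseuille `R0 = 8µl/(πr⁴)`, thin-wall compliance `C0 = 2πr³l/(hE)`
(the body-text form; the factor-2 variant is configurable), inertance
`L = ρl/(πr²)`, wall thickness `h = r(a e^{br} + c e^{dr})` (r in mm), and
units mmHg–ml–s (1 mmHg = 133.322 Pa). Resistance is volume-dependent,
`R = R0 (V0/V)²` with `V = C P_v`.

**Reference volume.** `V0` is the segment volume at the baseline steady
state (tone 1, 25 mmHg drop), not the geometric volume `πr²l`: with the
printed `V = C P_v` and these wall stiffnesses, `πr²l / C0 = hE/2r ≈ 1.7e3`
mmHg, so a geometric reference would inflate every resistance ~10⁴-fold at
physiological pressures and produce micro-flows. With the equilibrium
reference, `R = R0` exactly at baseline, and vasoconstriction (C → C0/T at
roughly constant wall pressure) raises resistance ≈ T³ — the amplification
required by the whole-organ numbers (see tone semantics). Capillary
reference volumes are the unstressed volumes (compliance × the 1 mmHg
design drop). A config switch restores the geometric convention.

Junctions are resolved algebraically inside the right-hand side:
bifurcations share the parent outlet pressure and sum daughter inflows;
venous confluences split the confluent inflow between partner segments by
the two-equation pressure/flow balance (the split conserves flow
identically); terminal arterioles, capillaries and venules chain by
pressure/flow continuity; the primary vein's outflow is closed against the
fixed venous outlet pressure through its own wall resistance. Capillaries
take `R0` and `L` from their feeding arterial terminal and compliance
`C = 0.7 a_j V_cap,Total / 1 mmHg`, where `V_cap,Total = 2π Σ r_i² l_i`
(half of pulmonary blood is capillary; 70% of it unstressed).

**Tone semantics.** Tone T multiplies `R0`, divides `C0`, and re-derives
`R_D = v/C`. Three scenario modes:

- `no_hpv`: a *global dilated baseline* tone `T_baseline = 0.5` on arterial
  and venous segments — the papaverine-like maximally dilated state of the
  whole-organ pressure–flow calibration;
- `uvc`: uniform vasoconstriction, global tone `T* = 0.8`;
- `hpv`: dynamic per-segment arterial tones (below), venous side at
  baseline.

The dilated baseline is the only reading under which uniform
vasoconstriction at `T* = 0.8` *reduces* flow, and it reproduces the
published UVC/no-regulation resistance ratios almost exactly
((0.8/0.5)³ ≈ 4.1 via the T³ mechanism, vs 3.8–4.2 reported across three
networks); the fitted lower tone bound (~0.49) coincides with it.

## Oxygen transport (`gas_transport`)

Breathing is a prescribed sinusoid: bulk airflow `QV* sin(2πR_R t)`
(QV* = 2.97 ml/s, R_R = 1.17 s⁻¹) and external alveolar pressure
`0.75 sin(2πR_R t)` mmHg. Two fixed-volume airway compartments (proximal
airway and dead-space mixing chamber, 0.15 ml each — rat anatomical dead
space, well below the 1.6 ml tidal volume) advect O2 partial pressure
piecewise by flow direction. Each zone's alveolus has volume
`dV/dt = w_i Q_air` (w_i = a_j under uniform ventilation; occluded zones get
w_i = 0 with the remainder renormalized so bulk airflow is held) and O2
moles `dM/dt = q_i β P_adv − αD_O2(P_alv − P_cap)`, with
`P_alv = M/(βV)`. β = 5.95e-5 is read as a gas capacitance in mol/(L·mmHg)
(≈ 1/RT), the only dimensionally consistent reading; an explicit 10⁻³ L/ml
factor bridges ml-based flows with molar concentrations throughout.

Blood oxygen combines Henry solubility and Hill binding,
`C = αP + Hct·C_Hb·Pⁿ/(Pⁿ + P50ⁿ)` (n = 2.6, P50 = 36 mmHg, capacity
Hct·C_Hb = 8.5e-3 mol/L). The inverse P(C) is computed by a monotone
interpolant polished with two Newton steps (|ΔP| < 1e-9 mmHg over the
physiological range); a bracketed scalar inversion is also exposed.
Capillary concentrations follow advection + alveolar diffusion; venous
segments mix their upstream inflows. Two stabilizations of the printed
balances: advection is upwind (reversed-flow excursions must not
anti-diffuse concentrations), and venous mixing volumes are floored at the
anatomical volume `πr²l` (the compliance-distension volume of a stiff small
vein is ~10⁻⁸ ml, which would impose meaningless 10⁴ s⁻¹ mixing rates).

**Inflow oxygen.** The default mixed-venous input concentration is the
Hill-curve content at 40 mmHg (4.8924e-3 mol/L ≈ 11 vol%). An
arterial-level input (e.g. 7.84e-3 mol/L ≈ 92% saturation, ≈ 86–91 mmHg)
would bound every steady venous tension above ~86 mmHg — no hypoxic venous
state could ever be simulated, and the two-condition calibration target
under FiO2 0.10 (49 mmHg, below the 71 mmHg inspired tension) would be
unreachable. Inspired tension is `FiO2 (760 − 47)` mmHg.

## HPV controller (`hpv_control`)

Each zone emits `S = exp(−P_alv,O2/P_HPV)` with `P_HPV = 80/ln 2 = 115.42`
mmHg (half-signal at 80 mmHg, the tension below which pulmonary resistance
measurably rises). The signal conducts upstream with exponential decay
`exp(−l/λ)` (λ = 100 mm — far longer than the lobe, so effectively
undecayed; retained as published). The target tone of arterial segment j is
the **mean** over its downstream zones of the decayed signals, mapped onto
`[T_min, T_max]`; the mean keeps the target inside the stated bounds for
any zone count (a raw sum exceeds 1 for any segment feeding ≥ 3 zones and
would clamp most of the tree at T_max, erasing the spatial differential —
the raw-sum-with-clamping variant is available as a config option).
Instantaneous tone relaxes with first-order kinetics (τ = 30 s by default;
τ = 2 s is used for calibration and steady-state studies — the fixed point
is τ-independent, which is tested). Tone applies to arterial segments only
and initializes at 1.

## Scenario engine and numerics (`engine`)

The full state stacks (P_v, q_in) for every arterial, capillary and venous
segment, capillary and venous O2 concentrations, per-zone alveolar
(volume, moles), two airway pressures, and per-arterial-segment tones in
hpv mode (a 1-zone toy network has 13 states; a 1000-node lobe ≈ 1000–1500).
Boundary conditions are either a fixed arterial–venous pressure drop
(default 25 mmHg above a 7 mmHg venous outlet) or a prescribed constant
root inflow (the root flow equation is frozen).

The system is stiff (wall time constants `R_D C = v = 0.01` s next to
~10⁻⁸ s flow relaxation) and integrated with a BDF stepper and a sparse
finite-difference Jacobian whose structure is assembled from the couplings
(including the numerically large tone←alveolar and dead-space←alveolar
entries; M is in mol, so these are O(10²–10⁵) in raw units). Two
idiosyncrasies required care. First, the Voigt term `R_D(q_in − q_out)`
amplifies solution-level flow error into outlet pressures, which makes the
right-hand side effectively rough at tolerance level; a multistep solver
occasionally wedges (step size collapses through its own history) and is
restarted from the current state when progress stalls — a one-step restart
recovers immediately and the integration statistics are recorded. Second,
the hard inspiratory/expiratory switch at `Q_air = 0` is blended with a
tanh over 10⁻³ QV*, which is physically negligible and removes
step-controller thrashing at flow reversal.

Runs proceed cycle by cycle (rtol 1e-6, per-block absolute tolerances).
Initial conditions come from a damped fixed-point solve of the nonlinear
resistor network plus an algebraic cycle-averaged gas steady state
(per-zone ventilation/diffusion/advection balance with a dead-space
rebreathing fixed point); this removes a slow alveolar-store transient that
would otherwise creep below any per-cycle convergence threshold and bias
venous oxygen upward. Periodic steady state is declared when the
cycle-to-cycle change of primary-vein O2 falls below 3e-4 (plus tone drift
< 2e-3 in hpv mode) with a minimum of 8 cycles; summaries use trapezoidal
means over the final two cycles. The 120-cycle default budget is a cap,
not a requirement.

## Analysis (`analysis`) and calibration (`calibration`)

Heterogeneity is the population CV (σ/µ) of per-zone cycle-averaged
quantities. Zone ventilation magnitude uses the mean-of-half-sine
convention `w_i QV* (2/π)` (any fixed convention rescales all V/Q ratios
uniformly). Transit times sum segment volume/flow along each
arterial→capillary→venous path, weighted by the flow carried; the
flow-weighted mean obeys Little's law (total perfused volume / total flow)
to < 1%. Densities are Gaussian KDEs (Silverman bandwidth) clipped to
non-negative support and renormalized. One-at-a-time ±10% sensitivities
report the percent change of primary-vein O2.

Calibration fits (D_O2, T_max, T_min) to two-condition venous O2 targets
(normoxia/hypoxia at prescribed inflows) with a real-coded GA: tournament
selection, BLX-0.5 crossover, Gaussian mutation, elitism; D_O2 is searched
on a log scale over [0.01, 100] ml/s, T_max in [1, 3], T_min in [0.05, 1]
with ordering enforced in the decoder. The final population's
per-parameter SDs and pairwise correlations are reported as the
uncertainty summary. A caveat: the often-assumed ill-conditioning along
the tone-bound difference (T_max and T_min entering the controller only
through T_max − T_min at each zone) is not a reliable feature of the
objective at small network sizes — on desk-scale lobes the venous O2 under
a prescribed inflow is nearly insensitive to both bounds, and where
sensitivity appears the equal-shift direction can be the steeper one — so
population correlations from small GA runs should not be over-read.

## Problem sizes used in the shipped checks

The acceptance script regenerates everything at the published scale:
six networks of 1000 nodes (Δg = 50 µm) under a fixed 25 mmHg drop,
integrated to periodic steady state with τ = 2 s. The test suite uses one
1000-node network for the full scenario suite and the occlusion series,
plus a second for the heterogeneity average; a ~400-node lobe carries the
sensitivity protocol, a ~150-node lobe the genetic-algorithm protocols
(with reduced generation/population budgets), and ~120-node networks the
conservation audits. The physics is scale-free in the properties tested
(directions, conservation laws, bounds); the heterogeneity statistics are
asserted only at full scale.

## What the synthetic setting does and does not show

The generator emulates a space-filling 2-D lobe with realistic branching
statistics and area-proportional design flows; it does not reproduce 3-D
geometry, gravity, cast-specific morphometry below ~50 µm, airway-tree
structure (ventilation is prescribed, uniform or occluded), capillary
sheet flow or recruitment, CO2/acid–base coupling, or chemoreflexes. Tests
passing on these networks demonstrate the internal consistency of the
coupled model and the direction and rough magnitude of HPV's effect on
flow heterogeneity and oxygenation — not quantitative prediction for any
real lung.

Known limitations worth flagging: total alveolar–capillary O2 flux at a
fixed pressure drop *falls* under HPV in this implementation (regulation
trades a ~4× flow reduction against a venous O2 gain capped by the
saturation plateau), although per-zone flux becomes more uniform and venous
oxygenation improves; compliance changes under dynamic tone exchange volume
with pressure instantaneously (the printed wall model conserves charge-like
volume only at fixed compliance); and the 2-D lobe's ~65 zones make all
heterogeneity statistics coarser than microsphere measurements with
thousands of samples.
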