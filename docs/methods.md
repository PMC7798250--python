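# Methods

## The modelling problem

A reaction whose reactants and products live in different compartments has
no single well-defined concentration rate: removing one molecule from a
2000 µm³ cytosol and adding it to a 300 µm³ nucleus changes the two
concentrations by different amounts. Amount-based (particle-flux) rates fix
the bookkeeping, but the question remains how the flux scales when the
geometry changes. `areakin` implements the three conventions side by side:

* **volume scaling** — ν = V₁·k_f·∏[S]ˢ − V₂·k_r·∏[P]ˢ, with V₁/V₂ the
  compartment volumes of the reactant/product side. First-order constants
  keep s⁻¹ units. This is what most published models and some tooling do
  implicitly.
* **area scaling** — ν = A·(k_af·∏[S]ˢ − k_ar·∏[P]ˢ), with A the membrane
  interface area. Flux across a membrane is proportional to the number of
  transporters, i.e. at constant transporter density to A; first-order
  constants become permeabilities with µm·s⁻¹ units.
* **single compartment** — all species share one pool whose volume is the
  sum of the member volumes; transport degenerates to interconversion and
  geometry cancels from the concentration dynamics entirely.

The state vector is always the vector of species **amounts** (unit:
µM·µm³ = 10⁻²¹ mol), so trans-compartment stoichiometry conserves mass by
construction; concentrations are derived views (amount / own compartment
volume). Units are fixed package-wide: µm, µm², µm³, µM, s.

Assumptions: compartments are well stirred and of constant volume during a
simulation (geometry changes are scenario comparisons, not dynamics);
transporter density is uniform, so area is a valid proxy for transporter
count; rate laws are mass action unless a model imports an opaque SBML
expression.

## Geometry

Nuclei are treated as perfect spheres. A measured nuclear cross-section is
read as the great-circle section, r = √(A_cs/π); volume (4/3 πr³), surface
(4πr²) and cross-section (πr²) are then mutually consistent, with
surface = 4 × cross-section exactly. The HeLa reference table is recomputed
this way from the measured cross-sections (155/200/245 µm²) and the
original model's nuclear volume (1.2·10⁴ µm³); the published surfaces
(619.28/800.23/979.79/2533.88 µm²) differ from the exact values by at most
~0.17%, which we attribute to intermediate rounding in the published
pathway. The implementation computes exactly and the tests allow 0.2%
relative; no attempt is made to replicate the unknown rounding path.

Root epidermis cells are idealized as cuboids with constant width and
depth (default 5 µm each, configurable): they elongate almost exclusively
in length, so the contact face with the axially adjacent cell (width ×
depth = 25 µm²) is constant while the volume is linear in length.

## Simulation and metrics

Time courses use LSODA (scipy's `solve_ivp` wrapper) on the amount ODEs,
the standard stiff/non-stiff switching choice for biochemical networks.
Defaults: rtol 1e-8, atol 1e-12 in amount units (the root-transport
comparison tightens these to 1e-10/1e-14 because one of its acceptance
properties asserts 1e-9 identity between trajectories).

"Time to equilibrium" is not standardized, so it is parameterized: the
time-to-fraction-f metric (default f = 0.95) is the first time at which a
species has closed fraction f of the gap between its initial and
equilibrium concentration, with linear interpolation between grid points.
Equilibrium concentrations are read from the final trajectory point only
after an equilibration guard: the last 5% of points must vary by less than
0.1% of the species' dynamic range, otherwise an explicit error advises a
longer horizon. Transient peaks are global maxima over the dense output
grid (≥1000 points where peak metrics are consumed; ties broken by the
earliest time). Steady states are found by integrating over geometrically
growing horizons until the trajectory settles, then polishing with damped
Newton iterations using a least-squares (minimal-norm) step — the
pseudo-inverse handles the singular Jacobians of closed, mass-conserving
systems without leaving the conserved subspace.

## The root-cell transport comparison

Four developmental transitions along the root axis are built from the zone
lengths {8, 30, 90, 220} µm. The two printed anchors are the extremes (8
and 220 µm); the intermediate values are fixture defaults chosen to give
a roughly geometric progression through the transition and elongation
zones, and are configurable. Transport runs from the older (larger) cell
into the younger one, giving (upstream, downstream) length pairs
(30, 8), (30, 30), (90, 30) and (220, 90). X₁ starts at 1 µM; X₂ at 0 (its
initial value is otherwise unspecified, and 0 makes the relaxation fully
visible). The default transport constants are symmetric, k_af = k_ar =
1 µm·s⁻¹, a mid-range small-molecule permeability that gives convenient
tens-of-seconds relaxation times.

Calibration anchors all three implementations at scenario 1:

* volume model: k_f = k_af·A/V₁, k_r = k_ar·A/V₂ evaluated at the
  scenario-1 geometry. With these constants the volume- and area-scaled
  amount rates are identical at *every* state — but only at that geometry —
  so both species' trajectories coincide at scenario 1 and diverge as the
  cells grow.
* pooled model: a one-pool model cannot reproduce both species'
  concentrations of a two-compartment model with V₁ ≠ V₂ (pooling loses the
  volume split: the X₂ views differ by the factor V₁/V₂). The pooled
  constants are therefore matched on the tracked species X₁, whose
  reference trajectory is a single exponential: k_f + k_r reproduces the
  area model's relaxation rate λ = A(k_af/V₁ + k_ar/V₂) and
  k_r/(k_f + k_r) its equilibrium fraction, making the X₁ curves exactly
  identical. The calibration verifies this pointwise to 1e-6.

With the constants then left untouched, the three implementations separate
in characteristic ways: the area model's time to equilibrium grows
strictly with cell size (the same 25 µm² face has to fill ever larger
volumes) and its equilibrium concentrations equalize (amounts split as
V₁:V₂); the pooled model is bit-for-bit geometry-blind; the volume model
keeps its relaxation rate λ = k_f + k_r in every scenario but shifts its
equilibrium concentration ratio as [X₁]/[X₂] = (V₂/V₁)·(k_r/k_f). Note the
pinned quantities: the volume model's [X₁]_eq = k_r/(k_f+k_r) is itself
geometry-free and (for symmetric permeabilities) numerically equal to the
pooled value, so mode divergence must be probed on X₂, on the ratio, or on
the timescale. These signatures are parameter-free properties of the
scaling modes and are property-tested over random constants and geometry
draws, not just at the defaults.

## Scaled sensitivities

Scaled (logarithmic) sensitivities (p/y)·∂y/∂p are estimated by central
differences on a multiplicative perturbation,
[y(p(1+δ)) − y(p(1−δ))]/(2δ·y(p)), with δ = 10⁻³ by default: central
differences are O(δ²) and exact for outputs linear in p. Every perturbed
evaluation re-solves the model from scratch. Outputs with y(p) = 0 are
recorded as undefined, never silently NaN. Several parameters can be
perturbed concomitantly by the same factor (a "group"), which is the
natural probe for robustness against rescaling all transport steps at
once; since scaled coefficients are log-derivatives, the coefficient of a
ratio output is the difference of the species coefficients.

The shuttle template (`fixtures.make_shuttle_model`) is a linear
RanGTP-like cycle: nuclear production of the GTP-form (0.5 s⁻¹), diffusive
area-scaled export (0.01 µm·s⁻¹ across the ~2535 µm² envelope of a
1.2·10⁴ µm³ nucleus), cytosolic hydrolysis (1 s⁻¹, 6·10³ µm³ cytosol) and
area-scaled re-import of the GDP-form (0.02 µm·s⁻¹). The permeabilities
are deliberately transport-limited (A·k ≪ V·k_conversion), the regime in
which the steady-state nuclear GTP-form level — the quantity that carries
the nucleocytoplasmic gradient, since the conversion steps pin the
counter-species — is strongly sensitive to either permeability alone
(coefficients ≈ ∓0.2) yet nearly invariant under concomitant scaling of
both (≈ −0.006, i.e. ~3% of the single coefficients). The steady state of
this cycle has a series-resistance closed form against which the numerics
are tested.

## SBML rescaling

`read_sbml` supports SBML L2/L3 single-model documents with mass-action or
opaque kinetic laws, assignment rules and (expanded) function definitions;
events, rate/algebraic rules, constraints and initial assignments raise an
explicit unsupported-feature error naming the construct. Kinetic laws are
parsed into sympy expressions against a closed symbol table — any
identifier that is not a declared entity is rejected rather than guessed.

The volume→area rewrite only touches laws that *structurally* factor as
(compartment size) × expression, where the factor is the size identifier
itself or a numeric literal equal to a declared size within 1e-9 relative;
which compartment's volume the law used is taken from the matched factor,
never assumed. The factor is replaced by a fresh area parameter (value
A_ref, unit annotation µm²; emitted as a plain parameter rather than a 2-D
compartment for broad tool compatibility) and the kinetic constants inside
the remaining expression are multiplied by V_ref/A_ref — valid exactly when
the expression is homogeneous of degree 1 in those constants, which is
verified symbolically (true for mass action and permeability-type laws;
anything else is refused). Globals shared with untouched reactions are
localized under a new name before scaling. The rewrite is numerically exact
at the reference geometry (verified on a test trajectory to 1e-6) and
arithmetically involutive: rescaling back divides the constants by the same
factor, recovering them to floating-point round-off (≤1e-12 relative).

Geometry scenarios multiply compartment sizes and (in the area-scaled
model only — the original has no area parameter, which is precisely its
blind spot) the area parameters: e.g. a 50% radius increase is volumes
×1.5³ and areas ×1.5²; a pure surface increase (wrinkled or multinucleated
morphologies) is areas ×1.5 at fixed volumes. Species initial
concentrations are preserved under size changes (amount-specified species
are rescaled with their compartment). Documents are never fetched from the
network; BioModels accessions must be supplied as local files.

## What the synthetic fixtures do and do not show

The generators reproduce the *structure* of the study inputs: the
root-cell series with its constant interface, the HeLa sphere conversions,
two-compartment SBML documents with nuclear-volume-scaled transport laws
(the form found in published shuttling models — the dual-volume form
V₁k_f[S] − V₂k_r[P] does not factor as a single size × expression and is
deliberately not generated as a rescale target), and the shuttle cycle.
They are linear or near-linear small systems with exact closed forms, which
is what makes the oracle tests sharp. Passing them demonstrates the
correctness of the machinery — rate assembly, integration, calibration,
rewriting — not that any particular biological model is quantitatively
right; real case studies (e.g. the RanGTP and TGF-β/Smad2 BioModels
entries) bring saturating kinetics, many species and experimentally fitted
constants, and enter only through the SBML pipeline with a locally supplied
file.

## Numerical choices and problem sizes

* Comparison horizons are set to 18 closed-form relaxation times (residual
  e⁻¹⁸ ≈ 1.5·10⁻⁸), so equilibrium read-offs are good to well below the
  1e-6 bands they are tested against; the equilibration guard catches any
  run that still drifts.
* The oracle sweep uses 200 random two-compartment exchanges (volumes
  10–5000 µm³, areas 1–500 µm², permeabilities 0.05–5 µm·s⁻¹) against
  `scipy.linalg.expm`; relaxation rates are recovered by a log-linear fit
  over the first five relaxation times.
* The rescaling round trip runs on five random fixture documents per
  invocation, alternating reversible/irreversible templates.
* Degenerate inputs fail loudly: non-positive geometry, zero membrane area
  in a lookup, negative amounts passed to the public rate evaluator,
  non-equilibrated metrics requests, non-factorable kinetic laws.

## Known limitations

* Only deterministic ODE semantics: no stochastic or spatial (PDE)
  formalisms; membrane transport is a flux across a static interface.
* Mass action plus opaque imported expressions; saturating laws get no
  dedicated builder (they pass through the expression path).
* The SBML subset excludes events and rate rules; models using them must be
  simplified upstream.
* Compartment volumes are constant within a simulation; growth is explored
  through scenario grids, not as a dynamic variable.
* The pooled-model calibration matches the tracked species exactly but
  cannot represent the second species' concentration at unequal volumes —
  an inherent property of the one-compartment idealization, reported here
  rather than hidden.
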