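# Methods

## Model

The package estimates fractional flow reserve (FFR) — the ratio of the
pressure distal to a coronary stenosis to the aortic pressure under maximal
hyperemia — from a geometric description of the coronary tree and a handful
of patient-level scalars, without any invasive measurement. The epicardial
tree is reduced to a resistive network: steady, laminar, Newtonian flow
(μ = 0.0035 Pa·s, ρ = 1050 kg/m³) in rigid vessels, so each segment obeys
the Ohm analogy ΔP = R·Q with the Poiseuille resistance

    R = 8 π μ L / A²,   A = (A_inlet + A_outlet) / 2.

For a uniform tube this is the textbook 128 μ L/(π d⁴). Each outlet drains
through a lumped microcirculation resistance to a venous pressure taken as
zero. Pulsatility, vessel compliance and turbulence are all neglected;
for FFR, which is a ratio of time-averaged pressures, these effects are
secondary to the resistive balance the model does capture.

### Boundary conditions

1. **Resting flow.** Total coronary flow is 4% of cardiac output (an
   empirical clinical statistic; configurable). It is distributed over the
   tree top-down with the allometric power law Q ∝ D^(7/3): at a junction,
   daughter k receives the share D_k^(7/3) / Σ_m D_m^(7/3). Because the
   power law relates each daughter to the parent independently, the raw
   ratios need not sum to one; shares are normalized per junction so mass
   is conserved exactly (the conservation-based reading of the scaling
   law). The daughter's *effective diameter* is its proximal diameter by
   default (`effective_diameter="mean"` switches to the mean of the two
   ends); the literature leaves the choice open and the difference is small
   for short junction-adjacent segments. Resting distribution always reads
   the healthy geometry: epicardial lesion severity does not alter minimal
   microvascular resistance.

2. **Microcirculation calibration.** Walking each root→outlet path
   proximal→distal with the healthy geometry, the accumulated epicardial
   drop gives the microcirculation inlet pressure
   P_i = P_MBP − Σ R_seg·Q_seg, with P_MBP = (P_sys + 2 P_dia)/3 and Q_seg
   the conserved through-flow (sum over descendant outlets — the only
   reading consistent with mass conservation on branched paths). Then
   R_i = P_i/Q_i. By construction, solving the resting network with these
   R_i returns the resting flows exactly; the test suite asserts this
   inversion to 1e-10 relative.

3. **Hyperemia.** Adenosine-induced maximal hyperemia is imposed through
   two clinical statistics: the inlet mean pressure falls by 12%
   (P0 = 0.88·P_MBP) and each microcirculation resistance falls to
   R_j = 0.23·R_i. Both coefficients are configuration values with the
   clinical numbers as defaults. In the limit of negligible epicardial
   resistance the hyperemic/resting flow ratio is therefore
   0.88/0.23 ≈ 3.83, a closed form the tests pin.

### The coupled fixed point

Under hyperemia the outlet flows are unknown because stenotic (epicardial)
resistance, microcirculation resistance and inlet pressure interact. The
solver iterates, with under-relaxation factor α (default 0.3):

    Q_j ← (1 − α) Q_j + α P_j / R_j
    P_j ← outlet pressure from the network solve at the new flows

until the dimensionless residual max_j |P_j − Q_j R_j| / P0 ≤ 1e-4
(defaults; both configurable). Since P_j = P0 − Σ path drops, the stopping
rule is exactly the physical matching condition: epicardial drops plus the
microcirculatory drop balance the inlet pressure at every outlet.

A literal damped pressure update of the form
P ← P + α(P0 − P + Q R_j) is retained behind the `eq10_literal` flag for
comparison; its stationary point (P = P0 + Q R_j) is inconsistent with the
matching condition above, so it never converges to the physical solution
and the package treats the network re-evaluation as the authoritative
update. Iteration order over outlets is sorted ids, initialization is the
resting flow pattern (positive and physiologically close), transiently
negative iterates are clipped to 1e-12 m³/s with a warning, and α is halved
(floor 1e-4) whenever the residual makes no net progress over 10
iterations — which catches both divergence and the period-2 oscillation
that a strong stenosis can induce. For the linear resistance model the same
fixed point is a linear system (path-overlap matrix plus diagonal R_j),
solved directly by `direct_solve_linear`; the suite verifies fixed-point /
direct agreement to 1e-6 relative over 100 randomized trees. With α below
the spectral bound 2/(1 + λ_max(D⁻¹(M − D))) the residual decays
geometrically; the suite asserts monotone decay for α = 0.3 after a short
burn-in.

### Stenoses and FFR extraction

Stenoses are explicit annotations (lesion diameter = reference diameter ×
(1 − severity)) that override the local diameter profile, so severity
sweeps do not touch the geometry. Segment resistance is integrated
piecewise over the modified profile — the same two-point-mean-area form
applied per interval — which reduces exactly to the closed form for a flat
profile and localizes the lesion's contribution. An optional nonlinear
mode adds a sudden-expansion loss ΔP = K_t·ρ/(2A₀²)·(A₀/A_s − 1)²·Q² per
lesion (K_t = 1.52, the classical empirical expansion coefficient),
folded in as an equivalent resistance ΔP/Q; it vanishes as Q → 0. The
default is the linear model, which keeps the direct-solve oracle exact;
the nonlinear term documents (but does not calibrate away) the gap to a
fully three-dimensional pressure-loss computation.

FFR_U = P_d/P0, with P_d sampled 3 cm of centerline arc length past the
lesion's distal shoulder, staying on the lesion's own segment; if less
than 3 cm of vessel remains, the most distal point of that segment is used
and the result is flagged (`fallback=True`). P_a is the hyperemic inlet
pressure P0, since the ratio is formed inside the simulated hyperemic
field.

### The diameter-flow comparator (FFR_D)

The comparator fixes the total hyperemic flow from patient scalars,
distributes it over the *healthy* tree by the same power law, and performs
a single forward pressure pass — no stenosis–flow coupling. Its empirical
total-flow formula is not published; the package ships a documented
stand-in, resting flow = 4.0·M^0.75 mL/min (M = myocardial mass in g),
scaled to hyperemia by 0.88/0.23. The constant 4.0 was fixed once so that
the cohort-mean mass (142.5 g) reproduces the 4%-of-cardiac-output resting
flow at the cohort-mean cardiac output (4.2 L/min); it is a configuration
value recorded in every result's metadata and must not be read as the
original method's constant. The inlet pressure is the mean aortic pressure
by default (`inlet_pressure="diastolic"` switches, since the source
description is ambiguous on this point). Because the comparator pushes the
healthy flow through the lesion, it overestimates the pressure drop of
severe stenoses — FFR_D < FFR_U there, an ordering the tests assert.

## Synthetic cohort

`synthetic_cohort` generates the study conditions end to end. Trees are
rooted binary trees: daughter diameters satisfy the Murray relation
D_parent³ = Σ D_daughter³ with an asymmetry ratio drawn uniformly from
[0.6, 1.0]; root diameters uniform in [3.0, 4.5] mm; segment length = 8 ×
diameter; branching depth 3–5, stopping below the 1 mm reconstruction
limit. Each vessel receives one focal 5 mm lesion with severity uniform in
[0.2, 0.8] and a physiology draw centred on the clinical cohort statistics
(diastolic 80 ± 8 mmHg, pulse pressure 45 ± 10 mmHg — mean pressure ≈ 95
mmHg —, cardiac output 4.2 ± 1.6 L/min, heart rate 68 ± 24 bpm, myocardial
mass 142.5 ± 46.6 g, all clipped to physiological ranges). The reference
("invasive") FFR is the exact direct-solve pipeline value plus additive
Gaussian noise on the FFR scale (sd 0.02, the order of pressure-wire
error), clipped to (0, 1]. Everything derives from one seed and is
byte-reproducible.

What the generator does *not* emulate: real anatomical statistics of the
three major vessels, eccentric/serial/diffuse lesion morphology, CT
segmentation error, or any systematic bias between model and wire
measurement. Passing the end-to-end tests therefore shows internal
consistency of the pipeline under idealized geometry and noise — not
clinical accuracy, which only patient data can establish. The default
cohort size (86 vessels) matches the clinical comparison the diagnostic
statistics are designed around; it runs in seconds, so no scaled-down
problem sizes are needed anywhere in the suite.

## Evaluation statistics

Positive class is reference FFR ≤ 0.8 (ties positive). Sensitivity,
specificity, PPV, NPV and accuracy are percentages; zero-denominator cells
are reported as not-available rather than zero. Bland–Altman agreement is
summarised as the mean difference and limits of agreement mean ± 1.96 sd
(sd with n−1); the published ±-intervals behave as limits of agreement,
and they are labelled as such here. AUC is the Mann–Whitney pair
probability computed from average ranks (ties 0.5), with estimates negated
so that lower FFR scores as more diseased; a seeded bootstrap (2000
resamples, percentile) provides the optional CI. Patient-level aggregation
takes the worst (minimum-FFR) lesion per patient — an assumption, flagged
in the output, since the aggregation rule for multi-vessel patients is not
standardized.

## Numerical choices and limitations

* Units: SI internally; 1 mmHg = 133.322 Pa; clinical units at the I/O
  boundary with explicit declarations.
* The residual is normalized by P0 so the 1e-4 tolerance is dimensionless.
* Degenerate inputs: zero-length or zero-diameter segments are validation
  errors; a calibration that drives any microcirculation inlet pressure
  non-positive raises naming the outlet; an unconverged solve returns a
  flagged result rather than raising.
* Sub-millimetre branches are *not* pruned on load (configurable upstream
  by the caller; the reconstruction limit is a property of the imaging
  pipeline, not of the network mathematics).
* The network is zero-dimensional: it cannot resolve eccentric or
  irregular lesion shapes; the piecewise-Poiseuille + optional expansion
  loss is a deliberate, documented simplification of the full 3-D pressure
  field.
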