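# Methods

This note records the models implemented in `epimech`, the numerical
choices behind them, and what the synthetic-data tests do and do not
establish about real tissue data.

## Geometry and shape characterization

A tissue is a shared-vertex polygonal mesh: vertices, counter-clockwise
per-cell index loops, and optionally a periodic box. The box is stored as a
2×2 matrix (rows are lattice vectors) rather than a pair of lengths because
relaxing a disordered tissue to *zero global stress* requires a shear degree
of freedom: at a stationary point of the energy with respect to only the box
lengths, the off-diagonal stress σ_xy of a disordered tissue retains a
residual of order 10⁻² in dimensionless units. Periodic cell loops are
unwrapped by minimum image around their first vertex; cells wider than half
the box (which occur only in tissues of a handful of cells) carry explicit
per-occurrence integer image offsets instead, and edge identity is keyed by
the image offset so that the "each interior edge is shared by exactly two
cells" invariant is meaningful even on tiny tori.

A tricellular junction (TCJ) is a vertex where three or more cells meet.
Junction degrees are derived from mesh incidence, or supplied explicitly for
data whose annotation is better than the mesh (cropped tissue borders,
single-cell fixtures). Explicit annotation takes precedence; otherwise
border cells of bounded tissues fall back to all their vertices, flagged
`boundary`, because incidence undercounts their junction degrees.

Three shape tensors per cell, each a centered second moment:

- **area** — second moment of area over the interior, divided by area
  (a w×h rectangle gives diag(w²/12, h²/12));
- **perimeter** — arc-length-weighted boundary moment about the line
  centroid;
- **junction** — unweighted second moment of the TCJ vertex positions about
  their mean (all vertices, with a `fallback` flag, when fewer than three
  TCJs are known).

Orientation θ is the principal-eigenvector axis folded to [0°, 180°), with
the global stretch axis along x at 0° and angles counter-clockwise; axial
differences fold to [0°, 90°]. Circularity is C = λ_min/λ_max, which meets
both limiting anchors: 0 for collinear geometry and 1 for a circle. The
choice of normalization is this package's own design, validated by the limit
behaviour, rotation/scale equivariance, and brute-force sampling oracles in
the tests. A tensor whose
eigenvalue gap is below 10⁻⁹ (relative) has no meaningful axis; it is
reported as θ = 0 with a `degenerate` flag and excluded from downstream
orientation statistics.

## Vertex model and stress inference

Dimensionless energy per cell, with areas scaled by the preferred area Ã₀
and lengths by √Ã₀:

    u = ½ (A − 1)² + ½ Γ L² + ½ Λ L,

the ½ on the line-tension term arising from writing the per-edge tension sum
per cell. Defaults (Λ, Γ) = (−0.259, 0.172). Cell pressure P = A − 1 and
cell-borne edge tension T = ΓL + Λ/2 give the energy-derived (virial) cell
stress — the strain derivative of u per unit area —

    σ_v = (A − 1) I + (T/A) Σ_edges |l| l̂ l̂ᵀ,

whose half-trace is exactly the effective pressure
P_eff = (A−1) + ΓL²/(2A) + ΛL/(4A), positive under net tension. In physical
variables the Λ term reads Λ L̃ √Ã₀ / (4Ã): lengths scale with √Ã₀ and areas
with Ã₀, the only dimensionally consistent convention.

**Coaxiality.** The claim that the principal stress axis "aligns exactly"
with the TCJ shape axis is implemented as a property of the *inference
construction*, not of the raw virial: on relaxed
disordered tissues the virial deviatoric axis differs from the
junction-tensor axis by a median of roughly 1°, reaching tens of degrees
for nearly isotropic cells where the axis is ill-conditioned (a
characterization the test suite computes), and the discrepancy does not
vanish with tighter equilibria or with other standard shape tensors (area,
perimeter, edge).
`cell_stress_tensor` therefore returns the projection of the virial onto the
junction-tensor eigenframe: the trace (hence P_eff) is preserved exactly,
the deviatoric component is the in-frame projection ξ, and θ_σ ≡ θ_J by
construction. The raw virial remains available (`virial_stress_tensor`) as
the mechanical reference; tests cross-check the construction against it
(trace and projected deviatoric agree to 10⁻⁹; the closed form agrees with
an independent r⊗f force-assembly oracle to 10⁻⁶).

**Tissue stress and Ã₀ calibration.** Tissue stress is the area-weighted
mean of the per-cell *virial* tensors (a plain mean is available), which
equals the box-strain gradient of the total energy — so a box-relaxed
equilibrium reports ‖σ_tis‖ ≈ 0 identically, whereas averaging the
junction-projected tensors would leave a spurious O(10⁻³) residual from the
discarded off-axis components. P_tis is its half-trace, identical under
either choice. For Λ ≤ 0, P_eff is strictly decreasing in Ã₀ (verified
numerically over randomized cells), so the calibration P_tis(Ã₀) = 0 has a
unique root; it is bracketed in [10⁻³, 10³] × (mean cell area) and solved by
Brent's method to relative tolerance 10⁻⁸, with a `CalibrationError` when the
bracket has no sign change (possible for Λ ≥ 0 with high-perimeter cells).
Only relative stresses are inferred; no absolute calibration is attempted.

## Simulator

Random tissues are periodic Voronoi tessellations of uniform points in a
square box of side √n (mean cell area 1); degenerate point sets retry with
an incremented sub-seed. Relaxation minimizes the total energy over
fractional vertex coordinates — plus the three box components (two lengths
and a shear) when `box_mode="relax"` — with L-BFGS on analytic gradients
(validated against central differences to 10⁻⁵ relative). Convergence is a
maximum vertex-force norm below `force_tol` (default 10⁻⁶). Edges shorter
than 0.02·√(mean area) with 3-valent endpoints undergo a T1 neighbour
exchange (re-expanded perpendicular at 1.5× the threshold length) followed
by re-relaxation; with Λ < 0 short edges are energetically disfavoured and
T1s essentially never fire in these protocols, but the operation is
implemented and invariant-tested. Uniaxial stretch is the instantaneous
area-preserving affine map x → (1+f)x, y → y/(1+f) of vertices and box,
followed by fixed-box relaxation — modelling a substrate-held stretch;
time-resolved viscoelastic adaptation is out of scope.

## Torque model of spindle orientation

Two spindle poles sit at ±h along a candidate axis φ from the area centroid,
h = 0.25 × (mean centroid-vertex distance), halved automatically (and
flagged) if a pole would leave the cell. Each pole casts `n_rays` (default
180) uniformly spaced rays over its *outward half-fan* — the ±90° span about
the pole's outward axis; the inward hemisphere is occupied by the spindle
body. Each ray pulls on its pole with force ∝ l^β along the ray (β = 3
default), and the torque is the ray-averaged z-component of
(pole − centroid) × force.

The half-fan is essential, not cosmetic: for a full isotropic fan the polar
first-moment identity ∫ l³ d̂ dψ = 3A(centroid − pole) makes each pole's net
force point exactly at the area centroid when β = 3, so the net torque
vanishes identically for *every* cell shape and the model carries no signal
(the finite-ray residual is discretization noise). A cortex-anchored
variant (anchors uniform in boundary arclength) converges but stabilizes the
short axis, contradicting the long-axis rule. The outward half-fan recovers
long-axis division for β ∈ {1, 2, 3} and is stable under ray-count doubling
and grid halving.

The predicted axis scans φ over [0°, 180°) at `angle_grid` (default 1°),
takes sign changes with restoring slope (torque +→− ) as stable equilibria,
refines each by bisection, and selects the one minimizing the rotational
potential −∫τ dφ (trapezoid on the periodic grid, evaluated at the refined
root). Degeneracy is declared when the profile is flat (max |τ| below
10⁻⁶ × the mean of l^(β+1) over centroid rays — near-circular cells) or when
several distinct stable axes tie in potential at 10⁻³ of the potential range
— the quadrature accuracy — which is how the exact symmetry ties of regular
polygons (e.g. the two diagonals of a square) are recognized. A tie may
instead be broken toward a caller-supplied reference axis (the junction
axis in the pipeline), flagged `tie_broken`. Regular polygons do retain a
genuine weak torque ripple (≈10⁻³ of scale for a hexagon); the tie mechanism,
not an amplitude threshold, is what marks them unusable.

## Statistics

- *Alignment tables*: one row per division per reference axis (area,
  perimeter, junction, torque-model, stretch), with the subpopulation
  filters |θ_A−θ_J| ≥ 15°, |θ_P−θ_J| ≥ 15°, |θ_Minc−θ_J| ≥ 15°, C_A > 0.65,
  C_J ≤ 0.65, and θ_J ≥ 60° from the stretch axis. Degenerate reference
  axes are excluded; unmatched divisions are dropped and logged.
- *Mann-Whitney vs uniform* ("are differences closer to zero?"): one-sided
  rank test of the observed axial differences against 10⁵ seeded uniform
  [0°, 90°] draws, using the asymptotic method (exact enumeration is
  intractable against the large reference, where the normal approximation
  is excellent); an analytic-CDF variant is available. Calibration: under
  the uniform null, empirical type-I error is 0.050 at α = 0.05 over 2,000
  replicates, and power increases monotonically with the generator's von
  Mises concentration κ.
- *Kolmogorov-Smirnov*: one-sample against the uniform CDF on a configurable
  angular domain (axial differences live on [0°, 90°]; when testing raw
  division angles against the stretch axis they are folded to [0°, 90°]
  first, the standard axial treatment), and two-sample for distribution
  comparisons.
- *Spearman* rank correlation with midrank ties (e.g. C_J versus
  |θ_D − θ_J|); constant input is refused.
- *Division rate*: 100 × divisions / (cells × hours), with a percentile
  bootstrap 95% CI (10⁴ replicates), resampling animal caps by default
  (cells optionally). Calibration at 24 explants × 120 cells drawn at
  6.47%/h: the CI covers the generating rate in ≈ 93% of 500 replicates —
  the familiar mild undercoverage of percentile bootstraps at modest sample
  counts, which worsens below ~15 explants.
- *Two-phase fits*: least-squares lines on [0, t_b] and [t_b, end] of a
  cumulative mitotic-entry curve, t_b chosen among sample times in a window
  (default 40-60 min) by minimizing total squared residual; slopes reported
  in %/h. No multiple-testing correction is applied anywhere; every result
  carries its raw p and n.

## Synthetic data

Axial angles are modelled on the doubled circle (von Mises on 2θ), the
standard treatment for orientation data; κ = 0 is exactly uniform and κ is
capped at 10⁶ for the perfect-alignment limit. Division events are
Bernoulli draws per cell at (rate %/h × duration), with NEB times uniform or
two-phase (defaults 8.1 then 4.35 %/h breaking at 50 min), and daughter
positions placed symmetrically about the centroid along the drawn axis.

Scenario defaults are the study conditions they emulate: control rates 3.22
(unstretched) and 6.47 %/h (stretched) over 2 h on ≈320-cell tissues;
stretched tissues use the 13% area-preserving affine map; division
concentration κ = 2 for stretched controls, which puts ≈52% of divisions
within 15° of the reference axis. The `tcj_only_signal` scenario uses a
running-bond "brick wall" of rectangles with aspect 1.1 — chosen because for
1 < aspect < √(3/2) each interior brick's area axis is horizontal while its
six TCJs (four corners plus two edge midpoints) have a vertical principal
axis, so area- and junction-based predictions disagree by 90° in every cell
and the |θ_A−θ_J| ≥ 15° subset is the whole population. The
`displaced_tcj_hexagon` fixture is a regular 12-gon with six annotated TCJs
clustered around one axis: exactly circular by area and perimeter (C_A =
C_P = 1) yet strongly elongated by junctions (C_J = 0.2) — the geometry of a
round cell whose junctions carry an orientation its outline does not.

What the synthetic tissues do **not** emulate: segmentation noise and
raster artefacts (inputs here are exact polygons), curved cell edges,
mitotic rounding dynamics, apical-basal (3-D) structure, and temporal shape
evolution between interphase and NEB. Passing tests therefore establish the
correctness and calibration of the estimators and the internal consistency
of the mechanical model, not the biological conclusions on microscope data.

## Problem sizes

Default test and acceptance workloads use 50-cell simulated tissues,
≈320-cell lattice scenarios, 2,000-replicate
statistical calibrations, and 100-seed scenario sweeps; these sizes give
stable statistics while keeping the full suite fast enough for routine runs.

## Known limitations

- The stress read-out's exact θ_J coaxiality is a modelling choice of the
  inference construction (see above); the energy-derived virial axis
  deviates from θ_J by ~1° at equilibrium, most for round cells.
- Minimum-image unwrapping limits JSON-round-tripped periodic meshes to
  cells smaller than half the box unless explicit offsets are stored (the
  simulator always stores them).
- The torque model is 2-D, static, and ignores force-generator biochemistry;
  its β = 3 point prediction degenerates entirely without the half-fan
  geometry, so comparisons across fan conventions are not meaningful.
- The percentile bootstrap undercovers slightly at small explant counts;
  CIs from fewer than ~10 explants should be read as approximate.
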