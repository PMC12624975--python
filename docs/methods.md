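# Methods

`arraystrain` couples three layers: a nonlinear finite-element model of
micromotion-induced tissue strain around a bed-of-needles (Utah-style)
microelectrode array, a strain summarization over each electrode's
recording volume, and a recording-performance pipeline with rank-based
strain-performance statistics exercised on synthetic recordings.  This
note records the models, the numerical choices, and what the desk-scale
defaults do and do not establish.

## Mechanical model

**Geometry.**  A planar array of `rows x cols` silicon shanks (400 um
pitch) on a base substrate.  Each shank tapers from a 150 um square at the
base to a 10 um-diameter circle at 1.49 mm, capped by a revolved
quarter-ellipse tip (major radius 10 um along the axis, minor radius 5 um);
total shank length 1.5 mm.  The square-to-circle loft is represented
implicitly as a superellipse cross-section whose exponent interpolates
from a square-like value at the base (default 12) to 2 at the taper end.
The surrounding cortical tissue is a rectangular prism extending a
configurable margin beyond the tips and laterally outward from the base
(full-scale values: 1 mm and 2 mm).  Coordinates: base underside in the
z = 0 plane, origin at the base center, shanks along -z; lengths in um,
stresses in Pa (forces in pN).

**Materials.**  Tissue is a one-term Ogden solid,

    Psi = (mu1/alpha1) (l1^-a1 + l2^-a1 + l3^-a1 - 3) + (1/d1)(J - 1)^2,

with the cortical parameters mu1 = 150.5 Pa, alpha1 = 19,
d1 = 6.65e-5 1/Pa (ground state: shear modulus mu = mu1*alpha1/2 ~
1.43 kPa, bulk modulus kappa = 2/d1 ~ 30 kPa, so nu ~ 0.477).  Two stretch
conventions are implemented.  Taken literally on raw principal stretches,
the negative-exponent form carries a spurious hydrostatic stress
-mu1 * I at the reference state (d/dl of l^-a1 does not vanish at l = 1);
the `isochoric` convention, which applies the deviatoric term to
lbar_i = J^(-1/3) l_i as the one-term Ogden of the major commercial
solvers does, is stress-free at identity and is the default for solves.
The `raw` convention is retained for the energy-level formula checks.
Silicon is isotropic elastic (200 GPa, nu = 0.278); because the stiffness
mismatch with tissue is ~8 orders of magnitude, the default "rigid" mode
eliminates the silicon degrees of freedom and prescribes the full driven
displacement on every node bonded to the array.  An "elastic" mode
(St. Venant-Kirchhoff silicon) is retained for fidelity checks.

**Boundary conditions.**  The bottom tissue face is fixed; the array is
displaced in the XY plane by magnitude * (sin th, cos th, 0) with the
angle measured from +Y.  Static only: no inertia, viscoelasticity,
insertion pre-strain, or contact separation (the bonded interface shares
mesh nodes, which reproduces tied kinematics exactly).

## Discretization and solver

**Meshing.**  A coarse structured background grid over the tissue +
base block is split into Kuhn tetrahedra and refined by Rivara
longest-edge bisection against a spatial size field until every element
obeys it; bisection keeps the mesh conforming at every step.  The size
field combines (a) a tip term — edges at most `tip_max_edge` inside the
sphere of influence around each tip, growing linearly with distance
outside — and (b) a shank-wall term proportional to the local shank
half-width in a band around the wall.  A post-pass re-refines any element
that still violates the exact tip-sphere predicate, so the constraint
"all edges <= tip_max_edge within the sphere" holds verbatim.  Vertices
near the implicit shank surface are snapped onto it (guarded against
element inversion); the mesh is then promoted to 10-node tetrahedra by
edge-midpoint insertion, with midside bookkeeping kept for the multigrid
transfer below.  The array solid is immersed (element region tags by
centroid) rather than boundary-fitted; with snapping, the interface is
piecewise-linear on the shank surface where it matters (near the tips).

**Finite elements.**  Total-Lagrangian quadratic tetrahedra, 4-point
Gauss rule, straight-sided elements (constant Jacobian).  The Ogden
first Piola-Kirchhoff stress is assembled in the principal frame of C;
the material tangent is a forward finite difference of the stress (the
assembled matrix is symmetrized; the residual itself is the exact energy
gradient, which the tests verify to 1e-5).  Newton iteration uses
adaptive load stepping with a consistent linear predictor for each
boundary-condition increment (K du = -(r + K_fc dg)), chord-style
tangent reuse while the residual contracts faster than a threshold, a
backtracking line search on the residual norm, and automatic step
bisection on failure.  Convergence is declared on the true nonlinear
residual (relative tolerance per study, absolute floor 1e-6 pN).

**Linear solver.**  scipy's sparse direct solver cannot factorize these
quadratic-tet systems beyond roughly 10^5 unknowns within a desktop
memory budget, and incomplete-LU preconditioning stalls on the nearly
incompressible operator.  The package therefore ships a two-level
p-multigrid preconditioner: the coarse space is the linear (corner
vertex) subspace — midside dofs interpolate as edge-endpoint averages,
so the prolongation is exact — with the coarse operator factorized once
by sparse LU (~7x smaller) and Chebyshev-Jacobi smoothing (degree 2,
applied in single precision; the outer CG runs in double).  The
preconditioner is frozen across Newton iterations and refreshed when CG
iteration counts degrade.

**Global-local submodeling.**  Resolving every tip at 1-3 um edges on a
multi-shank mesh is out of reach of a single CPU (a 4x4 grid at 3 um tips
is ~1.5M unknowns), so per-electrode ROI metrics are computed on fine tip
submodels: a box (default half-width 55-90 um) around each tip is meshed
at the requested tip edge, its outer boundary carries Dirichlet data
interpolated from the coarse global solution, nodes bonded to the array
carry the full driven displacement, and the local nonlinear problem is
re-solved.  The mesh-convergence sweep reuses one global solve and varies
only the submodel tip edge, isolating the tip discretization error.  The
magnitude sweep is one continuation solve with intermediate load states
captured at the requested magnitudes.

**Strain post-processing.**  F is evaluated at the ten nodes of each
element and volume-weighted averaged across elements sharing a node; the
logarithmic (Hencky) strain follows from the principal decomposition of
C, and the von Mises equivalent strain is
(1/(1+nu_eff)) sqrt(0.5 sum (e_i - e_j)^2) on the principal logarithmic
strains with nu_eff = 0.5 (the large-deformation post-processing
convention; configurable).  ROI summaries use all tissue nodes within
50 um of the tip, averaged in half-open 2.5 um radial bins, with bin
means weighted by ideal spherical-shell volumes (mesh-density unbiased);
the maximum is the largest nodal value in the sphere.  Electrodes group
into concentric rings by grid distance from the array edge, with the
four corners as their own group; a three-way corner / edge (outermost
ring minus corners) / interior split feeds the ordering ANOVA.

## Synthetic recordings

The clinical and NHP datasets behind the in-vivo correlations are not
public, so the recording pipeline is exercised on synthetic data whose
ground truth is monotonically linked to a per-electrode strain map:

- impedance Z_e = z0 exp(beta_Z s~_e) eta (lognormal noise), default
  z0 = 300 kOhm, beta_Z = -0.8, sigma = 0.25;
- spike peak-to-peak amplitude A_e = a0 exp(beta_A s~_e) eta, default
  a0 = 120 uV, beta_A = -0.7, sigma = 0.15;
- evoked firing-rate gain g_e = g0 (1 + beta_G s~_e), default g0 = 1.5,
  beta_G = 1 in the "v4" regime;

with s~ the within-array min-max normalized strain.  The "motor" regime
(beta_Z, beta_A < 0) emulates the negative strain-impedance/PTPV/SNR
structure; "v4" the positive evoked-SNR link; "null" sets all slopes to
zero for type-I calibration.  Traces are white Gaussian noise (default
6 uV SD) plus Poisson spike trains (20 Hz, 2 ms refractory) convolved
with a fixed biphasic difference-of-Gaussians template (1.5 ms support,
unit peak-to-peak, scaled per electrode); sessions carry multiplicative
lognormal factors (sd 0.08); dead electrodes get impedances a few-fold
above the screening threshold; an optional shared-noise block mixes a
common noise source into a chosen electrode set (insulation-failure
emulation).  Randomness is numpy PCG64; per-session/trial substreams are
spawned from the master seed, so datasets are bit-reproducible.

What this generator does *not* emulate: biophysical spike shapes and
their diversity, 1/f and line noise (a 1/f flag exists but is off by
default), LFP, electrode drift, and any causal tissue response linking
strain to performance over time.  Passing recovery tests therefore show
that the pipeline measures what it claims and has calibrated error rates
— not that the in-vivo correlation magnitudes are reproduced.

## Recording-to-metric pipeline

Impedance screening (strictly above 1 MOhm for SIROF, 2 MOhm for
platinum excludes the electrode) -> 2nd-order Butterworth 300-5000 Hz
bandpass, zero-phase by default (causal single-pass by flag) -> negative
threshold crossings at mean - 4.5 RMS (RMS over the full filtered trace)
with a 1 ms lockout; snippets span 0.5 ms before to 1 ms after the
crossing, edge-clipped snippets discarded -> representative PTPV = mean
of the largest ceil(2% N) snippet peak-to-peak voltages (minimum one)
-> noise floor = 2 SD of the trace with snippet windows excised; SNR =
PTPV / noise floor -> neighbor correlation = mean Pearson correlation of
the filtered trace with its 3-8 Moore-adjacent connected neighbors ->
eMUA = 500-5000 Hz bandpass, full-wave rectification, 200 Hz low-pass,
resampled to 1 kHz (all four parameters configurable); evoked SNR =
(peak trial-averaged stimulation-window eMUA - mean baseline) / SD of
baseline.  Metrics are averaged across sessions, then min-max normalized
within the array over functional electrodes only (x' = (x - min) /
max(x - min), guaranteed [0, 1]); screened-out electrodes never touch the
min/max, and electrodes without detected events propagate as missing
values, never zeros.  Session-to-session variability is the per-electrode
SD across sessions.

Where the underlying reports are silent, the defaults are package
choices, not attributions: zero-phase filtering, the 1 ms lockout, the
ceil rounding of the top-2% count, the shifted-maximum normalization
denominator, and the standard envelope recipe for eMUA.

## Statistics

Spearman rank correlation with average ranks and pairwise deletion;
exact permutation p-values for n <= 9, the t approximation otherwise;
two-sided throughout.  Kruskal-Wallis H with tie correction; Dunn's
post-hoc z-tests on pooled ranks with Holm adjustment by default (raw p
also reported).  One-way ANOVA with Tukey HSD via the studentized-range
distribution.  All three are cross-checked against brute-force rank
computations and scipy/statsmodels in the tests.

## Desk-scale study conditions

The shipped studies preserve the full-scale shank geometry, material
parameters, boundary conditions and 400 um pitch, and scale down only
the bulk problem size:

- strain ordering: 4x4 grid, tissue margins 250 um, coarse global mesh
  (32 um tip edges, shank walls at ~8x local half-width), per-tip
  submodels at 3 um tip edges within a 2 um sphere of influence and a
  55 um box (all 16 submodels share one translated mesh/problem template
  and warm-start from the previous tip's solution); driven displacement
  10 um in Y;
- magnitude sweep: one continuation solve to 50 um with states captured
  at 1, 5, 10, 20, 50 um; angle runs at 22.5 and 45 degrees;
- mesh convergence: single shank, same margins; submodels at tip edges
  3, 2, 1, 0.5 um against one 12 um global solve;
- recordings: 10x10 grid with unconnected corners (96 electrodes) for
  the motor regime, 3-4 s sessions; 8x8 for the evoked regime with
  15-50 trials of 0.25-0.5 s windows; 200/500 seeds for the
  recovery/null calibrations.

The sphere-of-influence radius for the fine meshes (2 um, scaled to
the tip minor radius) and the reduced margins are desk-scale choices:
the volume-weighted ROI average is dominated by the outer shells of the
50 um sphere (r^2 weighting), so its mesh sensitivity concentrates
within a few um of the tip, which the sweep resolves.  Known
limitations: the immersed (staircase-plus-snapping) interface perturbs
the strain field within roughly one element of the wall; the ordering
and monotonicity claims are robust to this, absolute near-wall maxima
less so.  Flat cortical surface, no insertion damage, no gyral
curvature, no electrode coating geometry.
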