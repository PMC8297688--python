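# Methods

This note documents the models, numerical schemes, defaults and known
limitations of `cvep`.  Nothing here reports an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Governing model

Tissue electrophysiology is the monodomain reaction–diffusion equation
coupled to the Courtemanche–Ramirez–Nattel (CRN) human atrial cell model:

    ∂V/∂t + I_ion(V, w, c) = ∇·(D ∇V) + I_app(t),   D∇V·n = 0 on ∂Ω,
    dw/dt = H(V, w),   dc/dt = G(V, w, c),

with V the transmembrane potential, w the 15 gating variables and c the 5
ionic concentrations of CRN.  The cell model runs in its published
physical units (mV, ms, pA/pF, mM); total ionic current in pA/pF equals
mV/ms on the membrane since the CRN capacitance normalizes out.  A
normalized potential u = (V + 84)/100 (span 100 mV) exists for I/O and
for interpreting stimulus amplitudes quoted in 1/s: an applied current of
200 1/s on u corresponds to 20 mV/ms on V.

The diffusivity tensor is built per element from an orthonormal fiber
frame (f0, s0, n0):

    D = σ_l f0⊗f0 + σ_t s0⊗s0 + σ_n n0⊗n0,
    σ_l = C_l · CV²,
    σ_t = σ_n = C_l · CV²  (CV < 0.4 m/s),   C_tn  (CV ≥ 0.4 m/s),

with C_l in seconds so that σ is a diffusivity in m²/s — the membrane
surface-to-volume ratio χ and capacitance C_m are absorbed into the
coefficient (the config accepts physical χ, C_m and rescales if a user
supplies them).  Internally the solver works in mm and ms, so σ is
converted with 1 m²/s = 10³ mm²/ms.  Both shipped coefficient presets —
baseline (C_l = 3.0e-4 s, C_tn = 0.48e-4 s) and progressed
(C_l = 2.0e-4 s, C_tn = 0.32e-4 s) — satisfy C_tn = 0.16·C_l exactly,
which makes the transversal law continuous at the 0.4 m/s threshold.

Electrical remodeling follows the piecewise-linear fraction

    I_CV(x) = clamp((CV(x) − cv_lo) / (cv_hi − cv_lo), 0, 1),

with cv_lo = 0.25 m/s and cv_hi = 1.25 m/s for the baseline variant and
cv_lo = 0.5 m/s for the progressed variant, scaling the maximal
conductances g_to, g_CaL, g_Kur by (0.5 + 0.5·I_CV), (0.3 + 0.7·I_CV),
(0.5 + 0.5·I_CV).  No other CRN parameter is modified (in particular
I_K1 and I_Na are untouched; see Limitations).

## Numerics

**Space.**  Bilinear quadrilaterals (2D sheets) and trilinear hexahedra
(3D slabs) on structured grids; Galerkin mass and stiffness matrices with
2×2(×2) Gauss quadrature (exact for these integrands).  The mesh size
parameter `h` is the grid spacing (equal to the mean longest element
edge).  Element CV is the arithmetic mean of its nodal values.

**Time.**  BDF of order 1–3 with matching-order extrapolation and a
BDF1→2→3 startup ramp.  The segregated step advances the ionic model
first: gate ODEs are linear in the gate given the extrapolated potential,
so the BDF update is solved in closed form (unconditionally stable,
gates clamped to [0,1]); concentrations use the BDF combination with the
right-hand side evaluated at (V_EXT, w^{n+1}, c_EXT) and are floored at
1e-12 mM.  The potential equation then solves

    (α/Δt M + A) V^{n+1} = (1/Δt) M V_BDF − I_ion + I_app

with I_ion assembled by state-variable interpolation (SVI): V_EXT, w, c
are interpolated to the quadrature points with the element basis, the
current is evaluated there and tested against the basis functions.  A
Rush–Larsen exponential gate update exists as a config option (default
off).  The linear system is solved by sparse LU factorization (reused
across steps; one factorization per BDF order in the ramp); a Jacobi-
preconditioned CG path with relative tolerance 1e-8 is available — any
solver meeting the residual contract is conforming.

**Performance.**  Voltage-dependent gate kinetics and current
coefficients are tabulated on a 0.05 mV grid over [−120, 80] mV with
linear interpolation inside the numba kernels; the exact-math path is
retained and the test suite bounds the table error below 2e-4 relative.
Saturating sigmoid arguments in the SR-release gates are clamped at ±300
to keep exponentials finite.  Removable singularities in the CRN rate
expressions are evaluated by their analytic limits within a ±1e-6 mV
guard band.

**Determinism.**  All kernels are single-threaded and every generator is
seeded; identical inputs give bitwise-identical activation maps (tested).

## CV estimation

For each map point: neighbors within a 7.1 mm ball are projected onto a
total-least-squares tangent plane (normal = smallest principal axis; the
in-plane axes are the projections of the global axes, which makes patch
orientation deterministic); points within the 1 cm × 1 cm tangent-plane
square are kept (≥ 6 required); activation time is fitted with a degree-2
polynomial (coordinates centered/scaled; condition number above 1e8
rejects the fit); velocity is ∇T/‖∇T‖² at the center, lifted back to 3D.
Speeds outside [0, 2] m/s, flat gradients (< 1e-6 ms/mm, wavefront
collisions) and rank-deficient patches are invalidated, never clamped;
mesh projection uses the nearest *valid* donor (lowest index on ties).
Wavefront curvature biases the fitted speed by O((patch/2r)²): for a
centrifugal wave this is a few percent 1–2 cm from the source, which the
tests assert quantitatively (median < 2%, max < 5% for r ∈ (12, 20) mm).

## Synthetic data

The generators define the study conditions:

- **Sheets/slabs**: structured meshes with uniform or circular fiber
  patterns.  The 5×5 cm disease fixtures use fibers along +y so that the
  sinus-style activation from the y=0 edge propagates mainly along
  fibers, as physiological activation does.
- **CV fields**: a smooth Gaussian background — white noise on a control
  lattice with spacing equal to the smoothing length (default 8 mm),
  bicubic-spline interpolated — plus, for persistent-like substrates,
  three radius-6 mm patches blended down to 0.15 m/s with a radial
  smoothstep.  The field is a pure function of (spec, domain, seed), so
  nested refinements sample the identical field.  The spatial mean is
  pinned by a fixed-lattice fixed-point shift applied to the background
  *before* patch blending, so patch centers always reach their floor and
  the paroxysmal-persistent mean gap is 0.40 m/s by construction
  (paroxysmal mean 1.00, persistent mean 0.60, noise sd 0.25 before
  smoothing; the smoothed pointwise sd is ~0.16–0.19).  Paroxysmal fields
  are clipped below at 0.30 m/s (no severe slow zones), all fields to
  [0.05, 2.0] m/s.
- **Eikonal maps**: Dijkstra shortest travel time on the mesh edge graph
  including both element diagonals (metric overestimate bounded by
  sec(π/8) − 1 ≈ 8.2% on uniform fields), edge weight = length × mean
  slowness of its endpoints; subsampled to ~2.5 mm to mimic
  mapping-catheter spacing.

What the generators do **not** emulate: atrial anatomy and wall
thickness, rule-based fiber architecture, mapping noise and fractionated
electrograms, respiratory/contact artifacts, and spatial correlation
between slow conduction and fiber disarray.  Tests passing on these
substrates show the pipeline is self-consistent and numerically correct,
not that it reproduces any specific patient.

## Protocols and analysis defaults

- Baseline activation: three spheres (radius 6 mm; 7 mm in the
  paroxysmal variant), amplitude 200 1/s, 5 ms, at 1.82 Hz with delays
  0/10/20 ms recurring every cycle; on synthetic sheets the landmarks sit
  along the y=0 edge spaced 1.5 cm.  Trigger: one cube of side 6 mm at
  8.26 Hz in the opposite corner, starting at t=0 together with the
  baseline (configurable).  Overlapping impulses superpose.
- Activation time: argmax over steps of |α V^{n+1} − V_BDF|/Δt (computed
  on the fly each step); nodes whose maximal slope is below 10% of the
  global median or below 1 mV/ms never depolarized and are invalid.  Map
  error: norm-1 relative error on the reference nodes after interpolating
  the coarse map with the element basis, restricted to the intersection
  of the valid sets.
- Dominant frequency: spectral peak of the detrended, Hann-windowed
  probe trace, zero-padded to ≤ 0.25 Hz resolution, searched in
  0.5–30 Hz; traces with < 1 mV of activity are flagged silent.
- Phase singularities: φ = atan2(u(t−τ) − ū, u(t) − ū) with τ = 8 ms and
  ū the node's temporal mean; a singularity is an element whose corner
  phases wind by ±2π.  Tips are linked greedily across frames (same
  chirality, jump ≤ 6 mm per 2 ms frame).  A rotor is *anchored* if its
  bounding radius is < 5 mm and it lives > 1 s, *wandering* if it drifts
  wider but survives > 1 s, else *terminated*; a trajectory aspect ratio
  > 3 flags a functional line of block (this quantitative criterion is
  ours — the underlying phenomena are usually identified visually).
- S1–S2 scans: planar S1 from the left edge, disc S2 (radius 8 mm) at
  the sheet center, classification per coupling interval: *early* if S2
  elicits no wave beyond 12 mm of its support, *reentry* if a phase
  singularity persists longer than two rotation periods (2 × 150 ms)
  after S2, *late* otherwise; the vulnerable window is the contiguous
  reentry range (non-contiguity is reported with a warning, not forced).

## Problem sizes used by the shipped experiments

Desk-scale choices, recorded here for reproducibility: the acceptance
script's refinement ladder runs the full 5×5 cm fixture (reference
spacing 50/304 ≈ 0.164 mm, 93k nodes, Δt = 0.025 ms, 200 ms window); the
test suite runs the same ladder on a 2.5×2.5 cm quarter-size sheet with a
100 ms window.  Trigger-dominance runs use a 5×5 cm sheet at ~0.83 mm
spacing for 2.5 s at Δt = 0.1 ms.  Vulnerable-window scans use a
4.5×4.5 cm uniform 0.25 m/s sheet at 0.75 mm spacing, Δt = 0.1 ms, 10 ms
coupling-interval grid, with early termination once the tissue is
quiescent.  Cell-level runs use Δt = 0.05 ms (0.005–0.01 ms for
reference integrations).

## Known limitations and observed discrepancies

- **Wave-speed dispersion.**  Planar speed converges roughly first-order
  in the spacing (cable test, prescribed 1.0 m/s: 0.840/0.865/0.878/0.883
  m/s at h = 2/3, 1/3, 1/6, 1/12 mm).  Consequently the activation-map
  refinement error at (0.33 mm, 0.05 ms) against the (0.165 mm,
  0.025 ms) reference is ~0.02 and almost purely spatial; the ladder
  ordering (coarser is always worse) is robust.  Raising the SVI
  quadrature to 3×3 points does not move the speed — the bias is the
  linear-element dispersion itself, so only finer meshes reduce it.
- **Trigger following is ERP-limited.**  With CRN kinetics and the
  remodeling floors above, tissue ERP stays near 200–300 ms even fully
  remodeled, so propagated wavefronts cannot follow an 8.26 Hz (121 ms)
  trigger 1:1: on the uniform 0.7 m/s sheet the activation settles into
  exact 3:1 block (363 ms intervals, 2.75 Hz; a 2.5 s analysis window
  that includes the irregular onset reports ~3.5 Hz) — trigger-driven and
  far above the 1.82 Hz baseline, but not equal to the trigger rate.  Reproducing 1:1 distal following would
  require remodeling of additional currents (I_K1, I_Na) that shorten
  refractoriness, which is deliberately out of scope here.
- Reentry on desk-scale sheets is wavelength-limited: with APD ≈ 200 ms
  and CV ≈ 0.2 m/s the wavelength is ~4 cm, so sustained rotors on
  ≤ 5 cm sheets live hundreds of milliseconds before boundary
  annihilation; the S1–S2 classification thresholds are set for that
  regime.
- Single precision of the printed CRN constants is preserved verbatim;
  no parameter fitting of any kind is performed anywhere in the package.
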