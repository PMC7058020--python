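# Methods

## The physical model

`raftedge` computes elastic deformations of a two-leaflet lipid membrane
containing a straight boundary between a liquid-ordered (L_o) domain and
the surrounding liquid-disordered (L_d) phase, and the interaction of that
boundary with membrane inclusions.  The system is translationally
symmetric along the boundary, so all fields depend on a single lateral
coordinate x and every energy is an energy per unit boundary length
(k_B T/nm); multiplying by an inclusion's effective length along the
boundary gives absolute energies.

Each monolayer is described on its neutral surface (the head/tail
junction, where splay and stretching decouple) by a director field **n**
(average lipid orientation), the surface height H(x) and the monolayer
interface height M(x).  Directors and surface normals point towards the
monolayer interface.  The elastic energy per unit area of one leaflet is
the quadratic tilt–splay–stretch functional

    w = B/2 (div n + J0)^2 + Kt/2 t^2 + Ka/2 (α − α0)^2 + σ0/2 (∇H)^2

with splay modulus B, tilt modulus Kt, stretching modulus Ka, spontaneous
curvature J0 and lateral tension σ0 (per monolayer); α is the relative
area stretch and α0 = σ0/Ka its tension-imposed equilibrium value.  Local
volumetric incompressibility eliminates α in favour of the geometry:

    α_u = [h_u − (H_u − M) − (h_u²/2) div n_u] / h_u        (upper leaflet)
    α_l = [h_l − (M − H_l) − (h_l²/2) div n_l] / h_l        (lower leaflet)

where h is the relaxed hydrophobic monolayer thickness.  This shared M(x)
couples the two leaflets rigidly.  In the linearized 1D geometry

    splay = dn/dx,    t_u = n_u − dH_u/dx,    t_l = n_l + dH_l/dx.

The sign conventions follow from the downward/upward orientation of the
upper/lower directors; they are internally validated by the exact mirror
symmetry of the energy under a leaflet swap combined with L → −L, and
externally by the sign-sensitive spontaneous-curvature landscapes (a
thick stripe with J0 = +0.25 nm⁻¹ binds the boundary only at L = −3 nm).

Every density is renormalized by subtracting the flat-state density of
the local phase (B/2·J0² per leaflet), so uniform bulk phases contribute
zero and the total energy is a finite excess per unit boundary length.
Gaussian-curvature terms vanish by translational symmetry; thermal
fluctuations and large deformations are outside the model.

By convention the lower-leaflet phase boundary sits at x = 0 and the
upper-leaflet boundary at x = L (the interleaflet shift); the disordered
phase occupies x → −∞.  For |L| > 0 an intermediate strip with one
ordered and one disordered leaflet appears, across which the bilayer
thickness ramps from 2·h_s to 2·h_r.

## Default parameters

Internal units: k_B T and nm, with k_B T = 4×10⁻²¹ J for conversions
(1 mN/m = 0.25 k_B T/nm²).  The `default` preset:

| parameter | L_o (r) | L_d (s) | units |
|---|---|---|---|
| splay modulus B | 20 | 10 | k_B T |
| monolayer thickness h | 1.8 | 1.3 | nm |
| tilt modulus Kt | 40 | 40 | mN/m (10 k_B T/nm²) |
| stretching modulus Ka | 120 | 120 | mN/m (30 k_B T/nm²) |
| spontaneous curvature J0 | 0 | 0 | 1/nm |
| tension σ0 (per leaflet) | 0.025 | 0.025 | k_B T/nm² |

All inclusions default to width ΔL = 1.3 nm (one α-helix diameter).
Monolayers in the intermediate strip keep their bulk-phase constants.

## Inclusion boundary conditions

* **Shallow amphipathic peptide** — excluded span in its host leaflet; a
  director jump of magnitude |Δn| = ΔL/√((ΔL/2)² + (h/2)²) (interpolated
  through the fraction δ of the peptide embedded in the ordered leaflet
  when straddling the boundary) with negative x-projection (heads pushed
  apart); rigid rotation ties the neutral-surface offset between its
  edges to the free mean edge director, H(b) − H(a) = ΔL·(n₁+n₂)/2.  δ is
  computed as the geometric overlap fraction of the span with the ordered
  region, making |Δn|(X₀) continuous.
* **Deep / midplane hydrophobic peptide** — director jump of free
  magnitude with positive x-projection (tails pushed apart) across a
  single grid cell, neutral surface(s) continuous; midplane peptides act
  on both leaflets.
* **Transmembrane protein** — both leaflets excluded over the span;
  H_u − H_l = h₀ at both edges; edge directors fixed with the jump split
  symmetrically (n₁ = −Δn_x/2, n₂ = +Δn_x/2 per leaflet); one free
  vertical offset and no tilt (the edge heights are tied together —
  numerically this rigidity constraint turned out to be inactive for all
  cases computed).
* **Lipid stripe** — parameter substitution (B₀, J₀, h₀) on the span of
  one leaflet; directors and surfaces continuous automatically.  "GM1-
  like" means thick (h₀ = h_r), positively curved (J₀ = +0.25 nm⁻¹) and
  ordered-phase-stiff (B₀ = B_r): a lipid whose saturated chains match
  the ordered phase is naturally assigned its splay rigidity.

Free quantities at inclusion edges (mean rotation director, transmembrane
vertical offset) stay in the unknown vector and are resolved by the
minimization — natural boundary conditions rather than guessed values.

## Discretization and solver

The functional is discretized on a uniform grid with a staggered midpoint
scheme: each interval contributes dx × density(midpoint), first
derivatives are differences across the interval and undifferentiated
fields are nodal averages.  This makes the energy an exactly
positive-semidefinite sparse quadratic form in the stacked unknowns
(n_u, n_l, H_u, H_l, M per node) and is O(dx²) accurate.  A plain
trapezoid of nodal centered-difference densities was rejected because it
decouples odd and even sublattices (checkerboard zero modes).  The
midpoint scheme retains one benign O(dx²) artifact: in the far tails the
minimizer superposes a ~10⁻⁴ grid-scale zigzag on n that trades splay for
stretching within a cell; it vanishes under refinement and is invisible
to the energy (the convergence ladder changes W by < 10⁻⁴ relative
between dx = 0.05 and 0.00625 nm).

Constraints (far-field clamping of directors and thicknesses at the box
edges, the M(x_left) = 0 gauge pin removing the vertical-translation zero
mode, and the inclusion conditions above) are linear equalities; the
constrained minimizer solves the sparse KKT stationarity system with a
direct factorization (iterative refinement fallback; residual gate
10⁻⁸).  The energy is then recomputed by integrating the functional on
the minimizer, independently of the assembled quadratic form; the two
routes agree to < 10⁻⁶ k_B T/nm and are additionally cross-checked in the
tests against a finite-difference-reconstructed dense Hessian oracle and
against random feasible perturbations.

Defaults: dx = 0.025 nm (0.05 nm in the test/acceptance scans, already
converged to < 0.1%), half-width 20 nm beyond the outermost structure
(15 nm in scans).  `refine_until_converged` halves dx and widens the box
until W stabilizes (default 10⁻³ relative).

### Decay lengths and box sizing

The characteristic roots of the linearized bulk Euler–Lagrange system are
computed as a quadratic eigenvalue problem.  The structural
(thickness/tilt) roots are complex: decay lengths 1.80 nm (L_d) and
2.47 nm (L_o) with oscillation periods 2π/Im k ≈ 8–11 nm — these set the
required box and scan sizes.  Freezing the tilt (Kt → ∞) *lengthens* the
structural decay towards the closed-form root of
(B + Ka h²/4)k⁴ + (Ka − σ0)k² + Ka/h² = 0 (2.99 nm for L_d), because the
fast tilt channel is removed; the numerical spectrum matches this
analytic limit to four digits.  In addition the lateral tension admits a
soft bilayer-bending branch with decay length √(B_eff/σ_eff) ≈ 20–28 nm.
It carries little energy, but leaflet-asymmetric inclusions with a free
rotation (shallow/deep peptides) do work against it, so their *absolute*
bulk self-energies converge only in ~100 nm boxes.  Energy *differences*
(binding depths, gains, plateau differences) are insensitive to this
truncation and are converged in the default boxes; the
plateau-separability identity W_plateau = W_bare + W_self is verified in
a common 60 nm half-width box where both sides include the bending tail.

## Scans and landscape analysis

`boundary_energy_profile` scans W(L) (default ±6 nm, step 0.25 nm); the
equilibrium shift L₀ is the parabolically refined minimum, reported as
the positive member of the degenerate ±L₀ pair.  `inclusion_energy_
profile` scans W(X₀) at fixed L (default ±L₀ = ±3 nm, matching the
standard presentation; joint re-minimization over L is not performed).
Because the structural modes oscillate with an 8–11 nm period, the tails
flatten to the plateau gate (max slope 10⁻³ k_B T/nm² per unit of the
profile's dynamic range) only beyond |X₀| ≈ 15–30 nm; the default range
is ±20 nm and the acceptance scans use ±24 nm (±33 nm for the
amphipathic helix).  Plateaus are the means of the outer 10% of each
tail.  Local minima found on the coarse grid are re-sampled at 0.05 nm
before parabolic refinement: several wells are |x|-shaped cusps (they
occur where an inclusion edge crosses a leaflet phase boundary) and are
markedly sharper than the 0.25 nm scan step.

Each minimum's depth is stored against every useful reference (nearer
plateau, each plateau, lower/higher plateau).  When the two plateaus are
similar, the depth below the adjacent plateau is quoted; when they differ
strongly, the physically meaningful binding depth is measured from the
*lower* plateau — the bulk phase the inclusion would otherwise occupy.
Boltzmann enrichment factors are exp(ΔW·l_eff/k_BT) with the effective
lateral length l_eff of the inclusion supplied by the caller.

## Degenerate inputs, tolerances, tie-breaks

Excluded spans narrower than two grid cells are rejected (no silent
smearing).  Constraints referencing positions outside the box, scan
ranges that end before the plateaus, non-positive refinement tolerances
and unknown families raise descriptive errors.  Minima shallower than
10⁻⁹ k_B T/nm against their neighbours are treated as noise.  A missing
gauge pin is detected before factorization by testing the translation
mode against the constraint matrix.

## Known limitations

* One-dimensional: straight boundaries only; valid for domains ≳10 nm.
* Small-deformation (quadratic) elasticity; director jumps of order 1
  (|Δn| ≈ 1.4 for a helix in the disordered leaflet) stretch the
  linearization and should be read qualitatively, as in the source
  analysis.
* No thermal undulations — the entropic interleaflet coupling channel is
  absent by construction.
* The intermediate "hybrid" strip keeps bulk-phase constants; simulation
  evidence suggests the true change is small but nonzero.
* Figure-derived reference values carry reading uncertainty; the two
  quantities of the short-barrel landscape reproduce at −15% (depth
  0.340 vs "≈0.4") and +14% (plateau difference 2.29 vs "≈2") with
  opposite signs, consistent with eyeballing noise rather than a model
  bias, while the sharper printed values (0.17, 0.2, 0.15, 1.1 pN, 7.4,
  1.5) reproduce to a few percent.
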