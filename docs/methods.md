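# Methods

This note records the model implemented by `rbeflow`, the numerical choices
behind it, and what the bundled studies do and do not demonstrate.

## Governing equations and discretization

We solve the incompressible Navier–Stokes equations for a Newtonian fluid
(density ρ_f, dynamic viscosity μ_f, CGS units throughout; the defaults
ρ_f = 1.06 g cm⁻³ and μ_f = 4·10⁻² g cm⁻¹ s⁻¹ are representative of
blood).  The viscous term is kept in strain-rate form, σ(u, p) =
2μ_f ε(u) − pI with ε(u) = (∇u + ∇uᵀ)/2, so the natural outflow condition
σn = 0 is the discrete do-nothing condition.  The working dimension is
d = 2; the spectral interface basis and the Taylor–Hood DOF accounting are
also provided for d = 3, but element assembly and the solvers are
two-dimensional.  The mass matrix is weighted by ρ_f, consistent with the
momentum balance.

Space: Taylor–Hood P2–P1 on triangles, assembled directly on the deformed
(physical) meshes with straight elements and a 7-point degree-5 rule —
exact for every bilinear form with P2 data, including the convective term.
The wall no-slip condition is eliminated strongly (the operators are
restricted to free DOFs); inlets are imposed weakly through multipliers
(below).  Mapping the mesh node-by-node through Φ commits a controlled
variational crime at P2 edge midpoints (the deformed midpoint is the
midpoint of the deformed edge, not the image of the reference midpoint);
this is an O(h²) geometric consistency error, below the element error at
the resolutions used.

Time: BDF of order σ ∈ {1, 2} with coefficients α = [1], β = 1 and
α = [4/3, −1/3], β = 2/3.  BDF2 self-starts with one backward-Euler step,
whose local O(Δt²) error does not degrade the global second order (verified
by the timestep-halving study).  Simulations start from rest with a cosine
flow-rate ramp Q(t) = Q₀[1 − cos((t − t_r)π/(t₀ − t_r))]/2 on [t_r, t₀].

The nonlinear step residual is R(Y) = HY − Σ_j α_j H Y_old,j − Δtβ F∘(t, Y)
over the coupled state Y = (W, Λ), solved by Newton–Raphson with relative
tolerance 10⁻⁶ (default, not dictated by the model; an absolute floor of
10⁻¹² guards steady states where the residual is already at rounding
level).  The exact tangent includes both convective derivatives
C(u) + C′(u); a frozen Stokes tangent is available and is the reduced
model's default.

## Building blocks and deformations

The block library: tubes T1/T2/T3 (unit diameter, axial length k diameters)
and a symmetric Y-bifurcation with 45° branches, trunk length 0.6 and
branch length 1.2 diameters.  Tube deformation χ is analytic — axial
scaling by the length ratio, linear radius taper from inlet to outlet,
circular-arc bending of the centreline with cross-sections kept normal —
with the closed-form Jacobian used everywhere (Piola, admissibility
checks).  The admissible box (length ratio 0.75–2, radius ratio 0.5–1.5,
bend ±0.4 rad) was fixed so that det Jχ > 0 on the whole box; the worst
case is a short tube with the widest taper and strongest bend.  The
bifurcation is deformed by rotating each outlet segment rigidly about its
own centre and extending the boundary displacement harmonically (one scalar
Laplace solve per component, Dirichlet at inlet/outlets, natural on walls);
its Jacobian is approximated by the identity, adequate for the small
rotations admitted (±0.3 rad).

Composition: interfaces are straight segments; two subdomains are glued
when their descriptors (centre, half-width, opposite normals) agree within
10⁻⁶ of the half-width.  The lower-indexed subdomain is the "+" side and
owns the canonical interface frame; the "−" side only flips the sign of the
multiplier.  So that randomly perturbed parameter sets always compose,
tubes inherit their inlet half-width from the upstream interface (a
transverse scale folded into χ), and the tube feeding a bifurcation is
tapered back to the reference half-width — the bifurcation's radii are not
parameters.  A tree of N blocks therefore always has N − 1 internal
interfaces.

## Spectral multiplier space

On the 3D reference interface (unit disk), the scalar modes are the ridge
polynomials P_k^n(x, y) = U_n(x cos ω + y sin ω), ω = kπ/(n+1), U_n the
Chebyshev polynomials of the second kind.  With unit normalization they are
orthonormal under the constant weight W = 1/π — the implementation fixes
the normalization by requiring the numerically evaluated Gram matrix to be
the identity (it is, to 10⁻¹⁵, with tensorized Gauss–Legendre quadrature of
order ≥ 2n + 2 in radius and a periodic rule in angle).  The 2D analogue
uses the interval [−1, 1] with the U_n themselves, orthonormal under
(2/π)√(1 − x²) (Gauss–Jacobi quadrature).  The vector basis is
component-major (all scalar modes times e₁, then e₂, …), degree-major
within a component; this fixed ordering makes coupling matrices bitwise
reproducible.  Counts: N_λ = d(n+1)(n+2)/2 (3D), d(n+1) (2D); default
degree n = 5.  Mapped to a physical interface by an affine map Θ whose
in-plane frame is derived deterministically from the stored normal, with
vector components carried in that frame on *both* sides, so the sign flip
realizes ξ⁻ = −ξ⁺ exactly.

Parameter counts per block: tubes have 3 nonaffine parameters in either
dimension; the bifurcation has one outlet-normal rotation per outlet in 2D
(2 total) and three Euler angles per outlet in 3D (6 total).

## Saddle-point solution strategy

The Newton tangent [[Ã, B̃ᵀ], [B̃, 0]] (Ã = H + ΔtβA block-diagonal over
subdomains, B̃ = ΔtβB) is solved either directly (sparse LU — the default
at the desk scales of the bundled studies, where it is both fastest and
simplest) or iteratively with the block preconditioner: the exact block-LDU
decomposition reduces the solve to per-subdomain applications of Ã⁻¹ plus
one dense solve with the multiplier Schur complement S = −B̃Ã⁻¹B̃ᵀ, which
is small (total multiplier count squared) and assembled by applying the
local inverse to the columns of B̃ᵀ.  Local-inverse policies: exact sparse
LU (the preconditioner is then the exact inverse and flexible GMRES
converges in one application), one SIMPLE sweep (momentum solve, pressure
Schur complement from diag(F)⁻¹, diagonal velocity correction), or inner
GMRES at tolerances 5·10⁻¹ / 10⁻². The outer method is a restarted
right-preconditioned *flexible* GMRES (restart 100, tolerance 10⁻⁸, chosen
below the Newton tolerance), required because the inner solves vary between
applications.  The Schur complement may be reused for n_reuse = 20
consecutive applications; the studies show this changes outer counts by at
most a couple of iterations.

## Offline phase

Snapshot campaigns solve the coupled FE problem on configurations drawn by
perturbing every block's parameters uniformly around the base values, with
half-widths ±10 % for ratios and ±10° for angles — values chosen as a
plausible anatomical variability; they are configuration options, not model
constants.  Draws falling outside the admissible box are redrawn.  Every
timestep of every successful run contributes one snapshot per subdomain
(stride configurable); failed configurations are skipped and counted.

Velocity snapshots are pulled back to the reference block with the Piola
transformation v̂(x̂) = |J_Φ(x̂)| J_Φ⁻¹(x̂) v(Φ(x̂)), evaluated DOF-wise
(the Jacobian at the reference DOF coordinate, the velocity at the matching
deformed DOF) — this preserves discrete divergence-freedom up to the
map-quadrature error, which the tests bound by the FE interpolation error
of an exactly solenoidal field.  J_Φ = Q·Jχ is the true Jacobian of
Φ = Qχ + t.  Pressure snapshots transfer by DOF identity.

POD per block: the method of snapshots (eigendecomposition of SᵀXS) when
snapshots are fewer than DOFs — the usual case — otherwise the explicit
Cholesky route (X = HᵀH, SVD of HS, modes H⁻¹Ũ); the two agree to rounding.
X is the H¹ matrix for velocity, the L² mass for pressure.  Truncation
keeps the smallest N with relative information content
Σ_{i≤N}σ_i²/Σσ_i² ≥ 1 − ε².  Mode signs are fixed (largest-magnitude entry
positive) for reproducibility.

Supremizers: for every pressure mode η, solve X̂_u ŝ = D̂ᵀη; for every
multiplier mode of every interface of the block (tubes: both ends;
bifurcation: all three faces — inlet-capable faces included, since any face
may be coupled or carry weak Dirichlet data in a composed geometry), solve
X̂_u ẑ = B̂ᵀe_l.  The union [POD | ŝ | ẑ] is re-orthonormalized against
X̂_u by modified Gram–Schmidt with re-orthogonalization; vectors whose
projected norm falls below 10⁻⁸ of their original norm are dropped as
dependent.  Enrichment provably raises the reduced pressure inf–sup
constant; the tests verify the increase numerically.

Archives store per-block bases and singular values in HDF5 plus a JSON
manifest (tolerances, seeds, snapshot provenance counts, mesh hashes); a
hash mismatch on reload fails loudly.

## Online phase

Per subdomain, the stored velocity basis is Piola-pushed onto the deformed
block (v = J v̂/|J| at DOFs, the exact inverse of the pullback) and all FE
operators of the deformed subdomain are projected by congruence.  The
multiplier space is never reduced — it is already small, and keeping it
intact preserves the interface physics (the multiplier approximates the
interface traction).  The reduced Newton tangent drops the convective term:
it is then constant over the whole simulation, so the per-block
factorizations and the reduced multiplier Schur complement are computed
once.  The convective residual is evaluated by direct projection
(assemble-and-project, robust default) or by contracting the precomputed
third-order tensor, truncated to N_c modes per subdomain; at N_c = N the
two paths agree to rounding, and the energy ordering of the POD makes
moderate truncation nearly free in accuracy.

Errors against the FOM are the time-integrated relative broken norms:
per-subdomain H¹ (velocity) and L² (pressure) squared norms summed over
subdomains, integrated trapezoidally in time, and divided by the same
functional of the FOM trajectory.

## Synthetic study conditions, and what the tests show

All studies are self-generated: there is no external dataset.  The bundled
conditions mirror the physical regime (blood-like ρ_f, μ_f, Δt =
2.5·10⁻³ s, BDF2, degree-5 multipliers, parabolic inflow ramped by the
cosine law) at desk scale: meshes of 4–6 elements across the vessel
diameter, horizons of 40–240 steps, chains of 2–8 blocks and a 9-block
tree, inflow Q₀ = 1 cm²/s giving a peak inlet speed of 1.5 cm/s and a
Reynolds number of order 40.  The ROM convergence study uses 5 perturbed
configurations of a 3-block chain, 40 timesteps each, and a 3×3 grid of
POD tolerances (ε_u ∈ {4·10⁻², 4·10⁻³, 4·10⁻⁴} × ε_p ∈ {10⁻², 10⁻³,
10⁻⁴}); snapshots are collected once and the bases are rebuilt per
tolerance pair.

What passing these studies shows: the discretization attains its nominal
orders; the weak coupling conserves mass and transmits tractions; the POD
satisfies its optimality identity; supremizer enrichment keeps every tested
reduced solve nonsingular; the reduced solution converges to the FE one as
the tolerances tighten, with e_u below 5 % at the tightest setting of the
self-consistent study.  What it does not show: performance at physiological
Reynolds numbers (pulsatile, 3D, Re ~ 10³), wall compliance, or accuracy on
anatomies outside the deformation family — the synthetic geometry family
has exactly matching interface segments by construction, whereas real
vessel junctions only approximately match the block library.

## Known limitations

- Element assembly and solvers are 2D; 3D support covers the interface
  basis and DOF accounting only.
- The bifurcation Jacobian is approximated by the identity in the Piola
  transformation; for rotations beyond ~0.3 rad this approximation, not the
  POD, would dominate the reduced-velocity divergence error.
- No hyper-reduction: the direct-projection convective path assembles a
  full-order operator per Newton iteration, so speed-ups at scale rely on
  the truncated tensor and the frozen tangent.
- The FOM default linear solver is a direct factorization; the block
  preconditioner is the intended path for large problems but has only been
  exercised at desk scale.
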