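# rbeflow

Reduced-basis element solver for unsteady incompressible flow in modular,
vessel-like geometries.

## The problem

Simulating blood flow in arteries with the full Navier–Stokes equations is
expensive: a resolved finite-element model of even a short vascular segment
carries 10⁵–10⁶ unknowns per heartbeat, which is prohibitive in multi-query
settings (uncertainty quantification, parameter sweeps, near-real-time
evaluation).  `rbeflow` implements a *reduced-basis element* strategy for
this problem: the vessel is approximated as a union of simple, deformed
**building blocks** — straight tubes with aspect ratios 1:1, 1:2, 1:3 and a
model symmetric bifurcation — and a reduced-order model is trained once per
*block*, not per geometry, so the same small bases serve any vessel
assembled from the library.

## The method

**Geometry.** Each subdomain is the image of a reference block under
Φ(x̂) = Q χ(x̂; μ) + t, with Q a rotation, t a translation, and χ a
parametrized nonaffine deformation (tubes: axial stretch, linear outlet
taper, circular-arc bending, with an exact Jacobian; bifurcation: harmonic
extension of rigid outlet-normal rotations).

**Full-order model.** Incompressible Navier–Stokes with density ρ_f and
viscosity μ_f, discretized with inf–sup-stable Taylor–Hood P2–P1 elements
per subdomain and marched with BDF(σ), σ ∈ {1, 2}.  Subdomain solutions are
glued *weakly*: velocity continuity across every interface Γ^[jm] is
enforced against a small spectral multiplier space — ridge polynomials
P_k^n(x, y) = U_n(x cos ω + y sin ω), ω = kπ/(n+1), built from
Chebyshev polynomials of the second kind and orthonormal on the reference
interface — times each canonic vector.  With maximum degree n the space has
N_λ = d(n+1)(n+2)/2 modes in 3D and N_λ = d(n+1) in 2D.  Both one-sided
coupling matrices B_pq = ∫_Γ ξ_p·φ_q are assembled on their own meshes, so
no interpolation ever crosses a (generally nonconforming) interface.  Inlet
Dirichlet data are imposed weakly the same way.  Each Newton step solves a
saddle system in Y = (W, Λ); a block preconditioner inverts it through the
dense Schur complement S = −B̃Ã⁻¹B̃ᵀ over the (small) multiplier space,
with exact, SIMPLE, or inner-GMRES local inverses inside flexible GMRES.

**Reduced-order model.** Offline, the coupled FE problem is solved on
randomly perturbed variants of a base geometry; velocity snapshots are
mapped to the reference blocks with the divergence-preserving Piola
transformation v̂(x̂) = |J_Φ| J_Φ⁻¹ v(Φ(x̂)) and compressed by POD,
orthonormal in the H¹ (velocity) and L² (pressure) norms, truncated at
relative information content 1 − ε².  The velocity basis is enriched with
supremizers (X_u s = Dᵀη per pressure mode, X_u z = Bᵀe_l per multiplier
mode) so the reduced saddle problem stays inf–sup stable.  Online, the
bases are Piola-pushed onto the actual deformed subdomains, all operators
are projected by congruence, the multiplier space is kept unreduced, and
time-stepping reuses the FE machinery on a system that is orders of
magnitude smaller.  The convective term is evaluated by direct projection
or by contracting a precomputed tensor T[i,l,m] = ∫ρ_f[(ζ_m·∇)ζ_l]·ζ_i,
optionally truncated to the first N_c modes.  Accuracy is measured by the
time-integrated relative broken-norm errors e_u (H¹) and e_p (L²).

## Worked example

`examples/04_offline_online_rom.py` trains on 5 perturbed three-tube chains
(40 timesteps each, Δt = 2.5·10⁻³ s) and evaluates on the unperturbed
geometry:

```
offline phase (5 perturbed configurations, 40 steps each): 7.7 s
  block T1: 30 POD modes + 18 pressure + 24 coupling supremizers -> 72 velocity basis functions, 18 pressure modes
  block T2: 15 POD modes + 13 pressure + 24 coupling supremizers -> 52 velocity basis functions, 13 pressure modes

FOM: 621 unknowns, 1.5 s;  ROM: 281 unknowns, 0.5 s
time-integrated broken-norm errors: e_u = 2.14e-03 (H1), e_p = 3.37e-05 (L2)
```

The ROM reproduces the coupled FE solution to 0.2% in the velocity H¹
broken norm on a geometry it never saw, using bases shared across blocks of
the same kind.  The other examples cover geometry composition
(`01_build_geometry.py`), the coupled FE solve and its conservation
properties (`02_coupled_fom.py`), preconditioner robustness in the number
of blocks (`03_block_preconditioner.py`), and convective-term truncation
(`05_convective_truncation.py`).

A thin CLI wraps the same pipeline for shell use:

```bash
rbeflow fixtures two_tube_2d --out cfg     # write a starter config
rbeflow run-fom cfg/two_tube_2d.yaml       # coupled FE solve -> VTU + tables
rbeflow run-offline cfg/two_tube_2d.yaml   # snapshots + POD -> basis archive
rbeflow run-online cfg/two_tube_2d.yaml --with-fom   # ROM + error report
```

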