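# Methods

## Problem and model

The study asks how the *turbulence* inlet boundary condition of a
truncated post-stenotic domain affects the accuracy of a steady RANS
simulation, using a full-domain solution as ground truth. The flow is
steady, incompressible and Newtonian (blood: ρ = 1060 kg/m³,
μ = 3.5 cP). The governing equations are the Reynolds-averaged
continuity and momentum equations,

    ∂U_i/∂x_i = 0
    ρ U_j ∂U_i/∂x_j = ∂/∂x_j [ −P δ_ij + 2 μ S_ij − ρ <u_i u_j> ],

with zero body force and the Boussinesq closure
−ρ<u_i u_j> = 2 μ_t S_ij − (2/3) ρ k δ_ij, where μ_t = ρ C_μ k²/ε.
k and ε follow the standard two-equation model with constants
C_μ = 0.09, C_ε1 = 1.44, C_ε2 = 1.92, σ_k = 1.0, σ_ε = 1.3.

**Production variant.** By default the production term uses the
Kato–Launder form P_k = μ_t S Ω (strain-rate magnitude × vorticity
magnitude) instead of μ_t S². The standard form spuriously generates
k under the strong, nearly irrotational straining inside the stenosis
contraction, which contaminates the cut-plane TKE profiles that the
whole study feeds on; the Kato–Launder form coincides with the
standard one in pure shear (the tests check this identity) and removes
only the irrotational-strain artifact. Production is additionally
capped at 10 ρ ε for iteration robustness. The standard form is one
configuration flag away (`kato_launder_production: false`).

## Geometry and meshing

The vessel is a straight channel of diameter D = 0.02 m carrying a
cosine-bump constriction (C¹ wall contour) that occludes 50% of the
diameter; the stenosis spans stations 6D–8D, the outlet run is 8D
(configurable; the downstream length is not a quantity the study
fixes). Cut planes for the three sub-models sit at the throat apex
(7D) and 0.5D / 1.0D distal to it; sub-model k (1, 2, 3) inherits cut
plane k, and the axial node spacing is chosen so every cut coincides
with a grid column — mapping then needs no geometric interpolation.

**Dimensionality.** The reference experiment is a 3-D bent pipe; this
desk-scale artifact is 2-D. The default mode is **axisymmetric**: a
planar channel halves the area-contraction ratio (2:1 instead of 4:1)
and therefore under-drives the jet (peak ≈ 1.4 m/s, peak TKE ≈ 0.05)
to the point where the cut-plane turbulence regime no longer resembles
the reference study, whereas the axisymmetric throat reproduces the
4:1 contraction, the ≈ 2.85 m/s jet and TKE of order 0.2 m²/s². The
planar mode remains available (it is also the natural host for the
optional in-plane swept bend; the 45° out-of-plane bend of the
reference geometry has no 2-D counterpart and the default is a
straight channel).

Grids are transfinite and body-fitted: uniform axial stations,
transverse geometric clustering toward the walls (ratio 1.15). The
default study grid is 6 axial cells per diameter × 20 cells across the
radius (≈ 40 across the diameter; 96×20 cells for the full model),
selected by the built-in refinement check — the throat peak velocity
moves < 2% under a 1.5× refinement — and by the need to run the
193-run study matrix sequentially in minutes. `--scale` multiplies the
resolution.

## Discretization and solution

Finite volumes on the colocated body-fitted grid. Convection:
first-order upwind implicitly plus a deferred-correction limited
second-order upwind (Barth–Jespersen limiter); diffusion: central with
explicit non-orthogonal (cross-diffusion) correction; gradients:
Green–Gauss using (φ_f − φ_P) differences, which keeps the operator
exact for constants on the r-weighted axisymmetric areas. Axisymmetric
volumes and face areas carry the full 2π revolution factor (exact via
Pappus / mid-radius rules); the radial momentum equation carries the
−μ_eff v/r² sink and the production its (v/r)² strain contribution.

Pressure–velocity coupling is SIMPLE with Rhie–Chow face fluxes;
under-relaxation 0.7 (momentum), 0.3 (pressure), 0.7 (turbulence and
eddy viscosity). Linear systems are solved with a sparse direct
factorization in a fixed ordering, so runs are bitwise deterministic.
Convergence is declared when every equation's normalized residual
|A x − b|₁ / (Σ|a_P x_P| + Σ|b|) falls below 1.0e-4 (the normalization
convention is this artifact's own fixed choice). Divergence and NaNs
raise typed errors carrying the residual history.

Boundary conditions: Dirichlet velocity/k/ε at the inlet; zero static
pressure with zero-gradient velocity at the outlet; no-slip walls with
equilibrium wall functions (κ = 0.41, E = 9.8): friction velocity from
the wall-cell k, log law above y⁺ ≈ 11.2 and the linear sublayer below,
wall-cell k production τ_w u*/(κy) in the log regime and zero in the
sublayer regime, wall-cell ε pinned to C_μ^{3/4} k^{3/2}/(κy). The same
wall drag coefficient is applied to both velocity components (the
wall-parallel decomposition is not separated; wall-normal velocity at
wall-adjacent cells is small). Wall functions trade sublayer fidelity
for desk-scale grids; because ground truth and all variants share the
wall treatment, the boundary-condition comparison is like-with-like.

Floors and clips: k clipped at 0, ε floored at 1e-12 m²/s³, μ_t capped
at 1e5 μ. ε in wall-adjacent cells is imposed by row replacement.

## Study protocol

1. **Ground truth** — full model, uniform inlet 0.66 m/s, turbulence
   intensity 5% (k = (3/2)(UI)² = 1.6335e-3 m²/s²), dissipation from
   mixing length 0.0014 m. Re = ρUD/μ ≈ 4.0e3.
2. **Profile extraction** — at each cut plane the plane-normal velocity
   is recovered from the converged face mass fluxes (the profile's
   integrated mass flux is then *identical* to the full model's), and
   the transverse velocity and k are distance-weighted cell averages.
   The transverse velocity is carried along with the normal component:
   at the 0.5D/1.0D planes the wall still diverges and dropping it
   would impose a spurious inlet defect on every mapped run.
3. **Mapped-exact sub-models** — velocity + k imposed directly;
   inlet ε rebuilt pointwise from the mapped k with the sub-model
   mixing length 0.000375 m (jet scale), since the measurement maps
   TKE, not dissipation.
4. **Intensity sub-models** — the velocity profile stays mapped and
   only the turbulence quantities are replaced: k = (3/2)(|u| I)² per
   inlet face from the *local* mean velocity (how flow solvers
   implement the intensity inlet), I ∈ {5, 10, 15}%. This isolates the
   turbulence boundary condition; a config switch restores fully
   uniform plug inlets with the correspondingly constant k.
5. **Degradation matrix** — each sub-model degrades its own plane:
   voxel averaging (edge = {1, 5, 10, 15}% of D, grid centred on the
   lumen, partial edge voxels averaged over their in-lumen portion;
   in axisymmetric mode the radial profile is mirrored into a
   diameter line first, as the scanner samples the whole lumen), then
   Gaussian noise with σ = max(TKE)/SNR, SNR ∈ {1, 5, 10, 30, 50},
   negatives clipped to zero (TKE is non-negative; clip counts are
   recorded). Three replicate noise realizations per cell; the
   realization is *paired across SNR levels* (common random numbers)
   so SNR trends are not masked by realization scatter, and
   independent across voxel sizes. All seeds derive from the root seed.
6. **Comparison** — velocity magnitude and k are interpolated
   (piecewise-linear, with boundary-value augmentation so the hull
   covers the walls) at a fixed 64×32 lattice spanning 0.1D–4D
   downstream of the sub-model inlet, full lumen; MAE, maximum error,
   and MAE as % of the ground-truth field maximum are reported per
   run. The 0.1D standoff keeps inlet-plane artifacts out of the ROI.

## What the emulator does and does not capture

The measurement stage reproduces the two statistical artifacts the
study varies — intravoxel averaging and additive Gaussian noise with
peak-referenced SNR — and nothing else: no MRI signal model, no
intravoxel dephasing, no velocity-encoding bias, no motion. Velocity
is passed through undegraded, as the study frames only the TKE data as
measured. Passing tests therefore demonstrate sensitivity of the RANS
solution to *these* degradations, not to scanner physics.

## Known limitations and observed deviations

* The mapped-exact TKE error of sub-model 2 (cut 0.5D past the apex)
  is ≈ 12% of the ROI TKE maximum, well above sub-models 1 and 3
  (≈ 3% and ≈ 1%) and above the 5% level the other two meet. The cause
  is structural, not numerical: the prescribed sub-model mixing length
  0.000375 m implies an inlet ε an order of magnitude below the true
  dissipation in the expanding annular shear layer, so the inlet eddy
  viscosity is too large and k overshoots just downstream (mapping the
  true ε instead brings the error under 2%; the error is unchanged
  from 96×20 to 160×32 grids). The same model ranking — model 2 worst
  by a factor of 2–3 — appears in the reference experiment.
* Degradation trends: the TKE error decays with SNR and grows with
  voxel size for fine voxels, but several coarse-voxel (10–15%) series
  are non-monotone: voxel averaging biases the wall-concentrated inlet
  TKE peak down while clipped noise biases it up, and the two
  compensate around the small mapped-exact bias floor. The
  inlet-plane reconstruction error itself is strictly monotone in SNR
  (tested); the non-monotonicity appears only after the solve.
* Single-phase steady RANS with wall functions on coarse 2-D grids:
  no transition modelling, no LES/DNS reference, no pulsatility, no
  non-Newtonian rheology, no wall compliance. Absolute error values
  are specific to this desk-scale configuration; the *orderings*
  (intensity monotonicity, mapped-beats-guessed) are the study's
  conclusions.
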