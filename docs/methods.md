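# Methods

`ecguq` quantifies how uncertainty in the *shape* of the moving pericardium
propagates into the forward and inverse problems of electrocardiography, on a
two-dimensional cross-section of the torso. This note records the model, the
numerical choices and their rationale, and what the synthetic study
conditions do and do not establish.

## Forward model

The torso cross-section is a homogeneous volume conductor `D` bounded by a
fixed chest contour `Γ` and a heartbeat-periodic pericardial contour `Σ(t)`.
With unit conductivity and no internal sources the extracellular potential
solves the mixed boundary value problem

    Δy = 0 in D,     ∂y/∂n = 0 on Γ,     y = u on Σ(t),

where `u(s, t)` is the prescribed pericardial potential in the material
(curvilinear) coordinate `s ∈ [0, 1)`. The problem is recast as a direct
boundary integral equation with the 2D Laplace kernel
`G(x, x′) = −log‖x − x′‖ / 2π`: single (`V`) and double (`K`) layer operators
restricted to the two boundary components form a 2×2 block system whose
unknowns are the chest trace `ρ0,Γ` and the pericardial normal derivative
`ρ1,Σ`. All normals are exterior to `D` — outward on the chest, pointing
*into* the cardiac cavity on the pericardium; the multi-component Gauss
identity `(½I + K_∂D)·1 = 0` is enforced as a test invariant rather than by
convention text.

Eliminating either unknown yields the discrete solution operator
`A: u ↦ ρ0,Γ` and the Poincaré–Steklov (Dirichlet-to-Neumann) operator
`B: u ↦ ρ1,Σ`. `A` and `B` are built by a single dense block solve with all
unit vectors; an explicit Schur-complement path is kept as a cross-check.
The Schur path requires `V_ΣΣ` to be invertible, which fails exactly when
the pericardium has unit logarithmic capacity (e.g. a circle of radius
1 in the working unit) — a property of the log kernel; the block path is
therefore the default.

### Collocation quadrature

Curves are truncated trigonometric polynomials, so all integrands are
analytic and Nyström collocation on equispaced nodes `s_i = i/n` converges
exponentially. Blocks coupling distinct curves use the plain trapezoidal
rule. On a single curve the single-layer kernel is split as

    G = −log(4 sin²(π(s−s′)))/4π  +  smooth remainder,

the periodic log part integrated by exact circulant spectral weights
(derived from `log(4 sin² πτ) = −2 Σ_k cos(2πkτ)/k`) and the remainder by
the trapezoidal rule; its diagonal limit is `−log(‖γ′(s)‖/2π)/2π`. The
same-curve double-layer diagonal is the curvature limit
`⟨γ″, n⟩ / (4π‖γ′‖²)`. Measured self-convergence on the concentric-circle
oracle is below `1e−13` at `n = 128` against `n = 512`.

Matrices act on physical boundary values: the arc-length weight
`‖γ′(s_j)‖/n` is folded into the quadrature, so `V·1 = −a log a` on a circle
of radius `a` and discrete operators compose with the diagonal trapezoidal
mass matrices `S_Φ = diag(‖γ′(s_i)‖/n_Φ)`.

## Inverse problem

Given noisy chest data `y_d`, the pericardial potential is recovered per
time step from the normal equations

    (Aᵀ S_Γ A + λ² M) u = Aᵀ S_Γ y_d,

the exact gradient of `½‖Au − y_d‖²_{S_Γ} + (λ²/2) uᵀMu`. The four penalty
matrices are

| kind | penalty | M |
|------|---------|---|
| `tik0` | L² of the Dirichlet data | `S_Σ` |
| `tik1` | L² of the Neumann data | `Bᵀ S_Σ B` |
| `h12` | H^{1/2} trace norm `⟨Bu, u⟩` | `(Bᵀ S_Σ + S_Σ B)/2` |
| `tv` | smoothed L¹ of the Neumann data | `Bᵀ W S_Σ B`, `W_ii = [2√((Bu₀)_i² + β)]⁻¹` |

Total variation is linearised exactly once (lagged diffusivity) around the
zero-order Tikhonov solution `u₀` at the same λ; no fixed-point iteration is
performed. `β = 1e−5` by default. For the H^{1/2} penalty the exact
symmetrised gradient form is the default; the one-sided variant
`S_Σ(Bᵀ + B)/2` is available behind a flag since the literature states the
derivative in that form — on our operators the two differ only when `S_Σ`
and `B` do not commute (non-circular pericardium).

Default regularisation parameters are λ = 1e−6 (tik0), 1e−3 (tik1),
1e−5 (h12), 1e−5 (tv) — the values the reference study selected on its
anatomy. Alternatively the L-curve criterion picks, per time step, the λ of
maximal finite-difference curvature of (log residual, log penalty) over a
log-spaced grid (default `1e−8 … 1`, 33 points; endpoints excluded, ties
towards larger λ), and the maximum over the heartbeat is used — a
deliberately conservative policy that suppresses oscillations at the cost
of possible over-regularisation at some instants.

Regularisation parameters do **not** transfer across anatomies: on the
synthetic geometry the fixed defaults above under-regularise badly (the
normal-equation spectrum depends on the geometry and mass-matrix scales),
while the L-curve procedure lands at λ ≈ 0.2–0.3 and 6–15 % relative L2
reconstruction error for all four penalties at the 1e−8 noise level. The
reconstruction-quality test therefore runs the selection procedure rather
than the fixed values; the fixed values are retained for the
regularity-ordering study below, whose subject is precisely the weakly
regularised, shape-sensitive regime.

## Shape uncertainty model

The uncertain pericardium is a random deformation of the reference contour:
at the space–time collocation points,

    χ(z, ξ) = E[χ](z) + Σ_k m_k(z) ξ_k,     ξ ∈ [−1, 1]^K iid uniform,

with weighted modes `m_k = √λ_k χ_k` from a pivoted Cholesky factorisation
of the covariance. The covariance is the product of a periodic sine-power
kernel in time, `k_SP(θ) = (cos θ + 1)/2` with `θ` the geodesic phase
distance on the heartbeat circle (`η = 2πt/T`), and Matérn kernels in space
of the Euclidean distance between reference positions: smoothness 5/2 for
the first displacement component and the Gaussian limit `ν → ∞` for the
second, both with correlation length ρ = 50 mm and variance σ² = 4/3 mm².
The two components are uncorrelated, so each is factorised separately and
the mode lists are merged by pivot magnitude — equivalent to a joint
factorisation of the block-diagonal covariance.

Uniform ξ on `[−1, 1]` has variance 1/3; the expansion is used literally,
without rescaling, so the per-point displacement standard deviation is
`√(Σ_k m_k²/3)` ≈ 0.67 mm per component at full variance. The 95 % shape
band is mean ± 1.96 of this field.

**Truncation tolerance.** The pivoted Cholesky stops at a trace residual of
1e−4. The library default interprets this *relative* to the initial trace
(the standard convention for the algorithm); an *absolute* residual is
available via configuration. The study configurations use the absolute
interpretation: on the emulated geometry at 500 collocation points it
truncates a single-instant expansion at K = 105 — the rank regime the
reference anatomy exhibits (K ≈ 100) — whereas the relative reading stops
near K = 38. At the reduced resolution n = 128 used by the acceptance study
the absolute reading gives K = 78.

**Admissibility.** A sampled deformation is accepted only if the deformed
contour has a non-degenerate parameterisation (minimal nodal speed above
1e−3 of the mean), is simple, and lies strictly inside the chest — the
discrete surrogate of the uniformity condition that keeps the boundary value
problem well posed. An inadmissible draw raises an error naming the instant;
quadrature never silently skips nodes, which would bias the moments.

## Moment quadrature

Moments `M_m y = ∫ y(·, ξ)^m ρ(ξ) dξ` over the uniform product density are
approximated by two rule families on `[−1, 1]^K`:

* **Anisotropic sparse Gauss–Legendre.** Combination-technique rule over the
  total-degree set `{k : Σ_j α_j k_j ≤ L}` with 1-D rule sizes
  `m(l) = l + 1`, realised by tensorising nested 1-D difference rules
  (no explicit combination coefficients; an independent brute-force
  combination construction is the test oracle). Anisotropy weights are
  decay-adaptive: `α_j = max(1, log₂(r_max/r_j))` with `r_j` the sup-norm of
  mode `j`. Exactly cancelled nodes are dropped, so the 1-D rule reduces
  bit-wise to Gauss–Legendre.
* **Halton quasi-Monte Carlo.** Unscrambled radical inverses in the first K
  primes starting at index 1, mapped to the cube, weights 1/N; Owen
  scrambling is available behind a seed.

All weights include the `2^{−K}` density, so every rule integrates constants
exactly. Convergence studies report relative sup-norm errors of `M₁` and
`M₂` against a Halton reference and fit the rate as the negative
least-squares slope of `log₁₀ error` vs `log₁₀ N`, per moment.

## Synthetic study conditions

No anatomical dataset ships with the package; `synthesize_torso` emulates
the reference study's cross-section at anatomical scale:

* chest: fixed oval, semi-axes 180 × 120 mm, with a small seeded low-order
  radial wobble (2 %);
* pericardium: smooth perturbed circle of mean radius 45 mm (≈ 100 mm
  extent) centred at (−40, 15) mm, with seeded radial harmonics (6 %);
* heartbeat: T = 690 ms sampled at 50 uniform instants; the contour radius
  is modulated by a two-harmonic periodic profile with its maximum exactly
  at t = 0 (diastole) and minimum at t = 270 ms (systole), amplitude 8 %;
* pericardial potential: a left-bundle-branch-block-like activation —
  two wavefronts leave s = 0 (right-ventricular free wall) and meet at
  s = 0.5 after 150 ms; each point follows a logistic upstroke (width 5 ms),
  a 250 ms plateau and a logistic downstroke (width 30 ms), amplitude 1,
  strictly T-periodic;
* chest data: forward solution plus iid Gaussian noise of variance 1e−8
  (≈ 40–46 dB SNR depending on the instant mix).

What this emulates: scale, topology, periodic motion, activation timing, and
the covariance model of the reference study. What it does not: the true
CMR-derived contour shapes (our pericardium is rounder and farther from the
chest than a real heart's left flank), heterogeneous conductivity, 3D
effects, or real segmentation noise. Consequently moments and convergence
behaviour reproduce *regimes and orderings*, not pointwise values: in
particular the emulated forward problem is less shape-sensitive than the
anatomical one, so absolute moment errors here are smaller than the
reference study reports at equal budgets.

### Problem sizes and instants used by the shipped studies

Single-instant studies fix the pericardium at one stored instant:

* the **forward** convergence study runs at mid-depolarisation (the instant
  nearest 75 ms, when half the pericardium is activated), where the chest
  potential carries the steep wavefront and is most shape-sensitive — the
  activation template has no PR-interval onset delay, so this phase plays
  the role the mid-QRS instant plays on a clinical timeline;
* the **inverse** regularity study runs at the plateau instant nearest
  189 ms, the instant the reference study analysed.

The forward study uses n = 128 collocation points per boundary, the
absolute-tolerance KL (K = 87 at this instant), sparse levels up to a few
times 1e4 nodes and a Halton reference of N = 1e5 (3e4 in the test suite).
The inverse study uses n = 64, sparse levels up to ~2e3 nodes and a
N = 2e4 reference. These sizes keep a full run in minutes on one core while
preserving the spectral accuracy of the spatial solver (machine precision
at n = 128 for these geometries).

**Rate fits.** Convergence-rate fits exclude budgets whose error is within
a factor 3 of the smallest observed error: those measure the reference's
own quasi-Monte-Carlo error (a flat floor), not the sparse rule. At least
three budgets are always kept. On the emulated geometry the sparse
quadrature reaches the reference floor within a few hundred nodes — the
forward map here is considerably less shape-sensitive than on the reference
anatomy — so the fitted forward rate (~0.4) characterises a shorter decay
range than the reference study's; the sparse-vs-QMC agreement at large
budgets (discrepancy a few 1e−6 at ~1.5e4 nodes, versus the 5e−5 scale of
the reference study) is correspondingly tighter.

## Numerical and degenerate-input choices

* Dense LU everywhere; problem sizes (≤ ~1000 unknowns) never justify
  iterative solvers.
* Block system condition is guarded by an LU pivot-ratio estimate (limit
  1e14); assembly rejects colliding collocation points.
* Trigonometric interpolation (FFT, balanced Nyquist) is used for curve
  construction from points and for periodic time interpolation of
  coefficient arrays; linear interpolation in time is rejected because it
  breaks C¹ periodicity.
* Curve orientation is normalised counterclockwise at load time; exterior
  normals are realised by a per-role sign, never by reversing the
  parameterisation.
* Pivoted Cholesky clips round-off negatives on the diagonal but aborts on
  indefiniteness beyond −1e−12 of the trace (checked *before* clipping).
* L-curve curvature uses central differences on the log-log grid; degenerate
  curves (zero residual or penalty) are rejected.
* CSV readers use round-trip float parsing so write∘read is bit-exact.
* Every random operation takes an explicit seed; the pipeline derives
  per-stage seeds from one global seed as `(seed·1009 + stage index) mod 2³¹`.

## Known limitations

* 2D only; the 3D kernel and surface quadrature are out of scope.
* The pericardial potential is prescribed, never simulated from ionic
  models; its closed form is a template with the documented timing
  properties, not a reproduction of any particular measured potential.
* TV is a single lagged-diffusivity linearisation — by design, not an
  iterated solver; its known lack of parametric smoothness limits sparse
  quadrature convergence (this is reproduced, not fixed).
* No temporal coupling in the inverse solve: each instant is regularised
  independently.
* The space–time KL under the absolute tolerance at full resolution is
  substantially larger than the reference study's printed rank (joint
  factorisation does not exploit the finite Fourier rank of the sine-power
  kernel); single-instant studies are unaffected.
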