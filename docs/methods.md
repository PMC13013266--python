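# Methods

This note documents the model, the numerical choices and the conventions the
package commits to, including the places where the design was genuinely open.

## Model and assumptions

The time-domain model couples the damped Westervelt equation for the acoustic
pressure fluctuation p with a volume-based Rayleigh–Plesset approximation for
the microbubble volume perturbation v about its equilibrium v₀ = (4π/3)R₀³:

    p_tt − c²Δp − bΔp_t = η (p²)_tt + c²ρ₀n₀ v_tt + h,
    v_tt + δω₀ v_t + ω₀² v = ζv² + ξ(2v v_tt + v_t²) − μ p,

with absorbing boundary condition βp_t + γp + ∇p·n = 0 (β, γ > 0) and
time-periodicity in t. The ODE holds pointwise in space (an effective-medium
description of the bubbly mixture: n₀ bubbles per unit volume, each
responding to the local pressure). Assumptions: constant medium properties;
volume perturbations small against v₀ (the quadratic ζ, ξ terms are a
second-order expansion); monodisperse bubbles; no subharmonics (only integer
multiples of the driving frequency are represented).

The solver computes time-periodic states — stable-cavitation regimes — not
transients or collapse.

## Parameters

All quantities SI; all frequencies angular (rad/s).

| symbol | meaning | default | unit |
|---|---|---|---|
| c | sound speed | 1500 | m/s |
| b | sound diffusivity (strong damping) | 1e−3 | m²/s |
| ρ₀ | mixture density | 1000 | kg/m³ |
| β_a | medium nonlinearity parameter | 3.5 | — |
| R₀ | equilibrium bubble radius | 2e−6 | m |
| n₀ | bubble number density | 1e12 | 1/m³ |
| P₀ | ambient (vapor) pressure | 100 | Pa |
| κ | adiabatic exponent | 1.4 | — |
| ν | kinematic viscosity | 8.9e−6 | m²/s |
| β, γ | boundary coefficients | 1/c, 1 | s/m, 1/m |
| a | source amplitude | 1e5 | source units |
| r_δ | source support parameter | 0.004 | m |
| ω | driving frequency | ω₀ (resonance) | rad/s |
| N | number of harmonics | 10 | — |
| h | mesh size | 0.003 | m |

Derived: ω₀ = √(3κP₀/(ρ₀R₀²)) ≈ 0.324 Mrad/s, δ = 4ν/(ω₀R₀²) ≈ 27.5,
μ = 4πR₀/ρ₀, ζ = (κ+1)ω₀²/(2v₀), ξ = 1/(6v₀), η = β_a/(ρ₀c²).

Two unit caveats the configuration surfaces explicitly:

* **n₀** is stored per cubic metre. Bubble densities are sometimes quoted per
  millilitre; both readings are selectable via the `[bubbles] n0` key. See
  "Regime caveats" below — the default 1e12 m⁻³ is far outside the weakly
  nonlinear regime of the volume oscillator at the default drive level.
* **ω₀ ≈ 0.324 "MHz"** as often quoted is an angular frequency
  (3.24·10⁵ rad/s). The codebase is uniformly angular.

## Multiharmonic reduction

With the half-spectrum Ansatz p ≈ Σ_{m=0}^{N} e^{imωt} pₘ(x) (time convention
e^{+imωt}; outgoing waves then behave as e^{−ikr}), the m-th pressure
harmonic satisfies the modified Helmholtz problem

    −(1 + iωmb/c²) Δpₘ − (k² + 𝔞) pₘ + i𝔟 pₘ = −k²hₘ − f_{p,v},  k = mω/c,

where, with αₘ = (−m²ω² + imδω₀ω + ω₀²)⁻¹ and D = (ω₀²−m²ω²)² + (mδω₀ω)²,

    𝔞 = μρ₀n₀ m²ω²(ω₀²−m²ω²)/D,    𝔟 = μρ₀n₀ m³ω³δω₀/D ≥ 0,

equivalently −(k²+𝔞)+i𝔟 = −m²ω²(1/c² + ρ₀n₀μαₘ). 𝔞 shifts the wavenumber
(sign flips at mω = ω₀), i𝔟 is bubble-induced dissipation. The volume
harmonic is always eliminated algebraically, vₘ = αₘ(−μpₘ + f_v); p₀ = 0
(the periodic pressure has zero mean), and v₀ is either pinned to zero or
updated from the difference-frequency balance ω₀²v₀ = (ζ/2)v₀² +
Σⱼ(ζ/2 − ξω²j²/2)|vⱼ|².

The quadratic couplings feed harmonic m with convolutions of lower harmonics:
η-weighted pressure products (sum-frequency Σ pₗp_{m−l}) and ζ/ξ-weighted
volume products, plus — in the real-field variants only — conjugate
(difference-frequency) products conj(u_{(k−m)/2}) u_{(k+m)/2} over stride-2
index ranges.

### Convolution-weight convention (an open design point, decided)

Two consistent Fourier-product conventions exist. In the **half-spectrum
(complex) convention** the coefficient of e^{imωt} in p² is Σₗ pₗp_{m−l}. In
the **real-field convention** p = Re Σ pₘe^{imωt}, the same product carries a
factor ½ on the sum-frequency convolution plus conjugate terms; the physical
second harmonic of the real dynamics is therefore half of what the complex
scheme predicts for the same coefficients. The package's time-domain ODE
oracle measures exactly this: the steady second-harmonic volume response is
0.5·α₂(ζ−3ξω²)v₁² (the test suite asserts the ½).

All five cascade variants in this package share the **half-spectrum
convolution weights** (η, ζ − ξω²(m−l)(2m−l), no halves), so that the real
variants reduce exactly to the complex ones when their conjugate sums are
dropped, and all variants agree with each other to the size of the
difference-frequency corrections (measured: ≤ 2·10⁻³ per harmonic for m ≤ 4
at h = 0.003, N = 5, bubble-free). The conjugate sums keep their natural
coefficients (ζ − ξω²(k²+3m²)/4 on the volume side, a factor −2 bracket on
the pressure side for m ≥ 2). Consequence to keep in mind: harmonic
amplitudes reported by every variant follow the complex convention and
overestimate the true real-field second harmonic by a factor that grows as
2^{m−1}; within-package comparisons and amplitude-scaling laws are unaffected.

### Algorithms

* `complex-linearized` — levels N′ = 1…N; level N′ solves harmonics 1…N′ with
  right-hand sides built from level N′−1. Returns all levels, so
  convergence-in-N studies are post-processing. Harmonic m stabilizes at
  level m (triangular structure); the audit hook records which (level,
  harmonic) pairs each right-hand side reads.
* `complex-coupled` — one sweep m = 1…N; the m-th right-hand side references
  only lower harmonics of the same solution. Identical to the stabilized
  linearized limit (asserted to 1e−8).
* `real-linearized`, `real-linearized-zero0` — as above plus conjugate
  convolutions and the v₀ update (or v₀ ≡ 0).
* `two-harmonic` — N = 2 with effective sound speeds 1/c̃ₘ² = 1/c² + ρ₀n₀μαₘ
  and effective nonlinearity β̃_a = c⁴ρ₀²n₀(ζ−3ξω²)μ²α₁²α₂; algebraically
  identical to `complex-coupled` at N = 2 (asserted to 1e−8).

The fully coupled real system (same-level conjugate couplings) is only
residual-evaluated, not solved: the fixed-point/linearized route is the
production path, and the residual evaluator reports per-harmonic weak-form
(PDE) and algebraic (ODE) residual norms for any supplied field.

## Discretization

* **Mesh.** Deterministic built-in disk mesher: nodes on concentric rings,
  circumferential spacing h and radial spacing (√3/2)h — the near-equilateral
  geometry frontal meshers target — with a golden-angle twist per ring and a
  seed-controlled rotation; Delaunay triangulation (disk is convex, so the
  inscribed polygon is covered exactly). Yields ≈ 0.146/h² · area nodes
  (e.g. 15081 nodes at h = 0.003125) and max edge ≤ 1.5h. Triangle-format
  and Gmsh MSH 2.2 import are provided so external meshes can be used.
* **Elements.** P1 on triangles; exact formulas for stiffness K, consistent
  mass M and boundary mass M_bnd. The Robin term enters the system matrix as
  D·robin·M_bnd (scaled by the complex diffusion D = 1 + iωmb/c², since the
  boundary integral arises from integrating the diffusion term by parts):
  A = D·K + R·M + D·robin·M_bnd with reaction R = −(k²+𝔞)+i𝔟.
* **Source.** Cosine monopole bump h(x) = a/(4r_δ)(1 + cos(π‖x−x₀‖/(2r_δ)))
  on ‖x−x₀‖ ≤ 2r_δ, assigned to the fundamental only by default (configurable
  per harmonic); this is what produces the clean a^{m−1} harmonic scaling.
  Load vectors use a fixed degree-4 (6-point) triangle quadrature, validated
  against the closed-form integral ∫h = a·r_δ(π − 4/π). Convolution sources
  (products of FE functions) are represented by nodal interpolation and
  integrated with M — consistent at P1 accuracy.
* **Linear solves.** Sparse direct LU (SuperLU), one factorization per
  harmonic reused across all cascade levels; accepted when the relative
  discrete residual is below 1e−10. A warning (not an error) is logged when
  the mesh provides fewer than 10 elements per wavelength at the highest
  harmonic.
* **Norms and time diagnostics.** L²(Ω) norms are mass-matrix weighted
  (√(uᴴMu)), matching the discretization. Time reconstruction is exact
  trigonometric evaluation; the L∞(0,T;L²) norm uses 256 uniform samples per
  period by default (≫ 2N+1; refining beyond changes the value by < 0.1%).
  Difference maps default to the t₀ = 0 snapshot, configurable.

### Accuracy and the pollution caveat

A manufactured-solution suite (smooth complex field, inhomogeneous Robin
datum built per boundary edge with the polygon's own edge normals, so only
the O(h²) domain approximation remains) verifies second-order L² convergence
of the kernel; the observed final-pair order is 2.0 in the resolved regime
kh < 1. At the default driving frequency the wavelengths of harmonics m ≥ 2
are only marginally resolved on the h = 0.003 mesh (≈ 10 elements per
wavelength at m = 1, 5 at m = 2), so harmonic-content ratios at that mesh are
not fully mesh-converged (r₂ changes by tens of percent between h = 0.006 and
h = 0.0015). Reported reference-setup numbers are therefore tied to the
stated discretization, and the package reports them at exactly that h.

## Reference oracles

* **ODE oracle.** Classical RK4 with 2¹⁰ fixed steps per period, started from
  rest; transients are discarded over max(50, ⌈10/(rate·T)⌉) periods, where
  rate is the slow decay rate of the damped oscillator (≈ ω₀/δ when
  overdamped); the final 4 periods are FFT-analyzed at bins m·4. The implicit
  v_tt dependence of the nonlinear ODE is resolved by the algebraic rewriting
  v_tt = (−δω₀v_t − ω₀²v + ζv² + ξv_t² − μp)/(1 − 2ξv), valid while
  2|ξ||v| < 1; leaving that region aborts with an amplitude report. The
  linear transfer test recovers αₘ to ≲ 1e−6 relative; integrator order 4 is
  confirmed by step-halving.
* **Manufactured Helmholtz suite** as above.

## Regime caveats and known limitations

* The quadratic ODE coefficients are enormous in SI terms (ζ ≈ 3.8e27,
  ξ ≈ 5e15) because v₀ ≈ 3.4e−17 m³; the oscillator is weakly nonlinear only
  while ζ|v|/ω₀² ≈ |v|/v₀ ≪ 1, i.e. pressure amplitudes ≲ 1 kPa at resonance
  with the default parameters. At the default n₀ = 1e12 m⁻³ and a = 1e5 the
  bubble-added nonlinearity exceeds the medium nonlinearity by ~4·10⁴
  (|β̃_a| ≈ 1.5·10⁻⁷·n₀ against β_a = 3.5) and the bubble dissipation
  dominates the wave operator (𝔟₁ ≈ 9·10⁻⁷·n₀ m⁻² against k² ≈ 4.7·10⁴ m⁻²,
  a 1.5 mm decay length). In that regime the computed harmonic content is a
  property of the formal cascade, not of a physically small-amplitude
  mixture, and the real-field fixed-point iteration diverges (its contraction
  condition requires small fields). For physically moderate bubble effects
  use n₀ ≲ 1e9 m⁻³ or reduce the drive amplitude; the package deliberately
  keeps the documented defaults and lets the configuration override them.
* The linearized cascades are exactly homogeneous in the source amplitude
  (pₘ ∝ aᵐ), so relative harmonic ratios obey rₘ ∝ a^{m−1} regardless of
  regime; absolute levels in the strongly coupled regime should not be read
  as physical.
* Subharmonics (ω/2, …), 3D domains, spatially varying β_a, curved boundary
  elements, adaptive refinement and Newton solvers for the fully coupled
  system are out of scope.
* The synthetic configuration (disk, centered monopole, monochromatic
  excitation at resonance) emulates a controlled transducer experiment in a
  homogeneous bubbly medium; it does not emulate tissue heterogeneity,
  polydisperse bubble populations, or transducer directivity — passing tests
  say nothing about those effects.
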