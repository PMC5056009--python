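# Methods

## Model

The package solves the SparseSENSE problem

```
min_x  Φ(x) = ||D x||_1 + (λ/2) ||A x − y||²,     x ∈ ℂ^{ny·nx}
```

* `A` stacks, per coil, pointwise multiplication by the sensitivity map
  `S_j` followed by the centered orthonormal 2-D DFT restricted to the
  sampled k-space locations.  All stored grids are DC-centered (zero
  frequency at `(ny//2, nx//2)`); FFT-layout shifts are internal to
  `fft2c`/`ifft2c`.  With sum-of-squares-normalised maps
  (`Σ_j |S_j|² = 1`) the operator norm satisfies `||A||² ≤ 1`.
* `D` is either the forward-difference gradient (TV, components
  `(∂₁x, ∂₂x)`, weights `(1,1)`) or a special second-order TGV
  (`(D₁₁x, D₂₂x, (D₁₂x+D₂₁x)/2)`, weights `(1,1,2)` so the weighted group
  magnitude is the Frobenius norm of the symmetric second-difference
  tensor).  Second differences are forward-forward compositions.  `||·||_1`
  is the isotropic group ℓ1 norm under those weights.
* Adjoints are conjugate transposes under the weighted inner product; this
  is required for the optimality condition `0 = Dᵀw + λAᴴ(Ax−y)` to be the
  true first-order condition for complex images.  Exactness to ~1e-16
  relative is enforced by tests for every (kind, boundary) combination.

Boundary rule: `periodic` by default — it makes `DᵀD` diagonal in the DFT
basis (symbol `4sin²(πu/ny) + 4sin²(πv/nx)`), which the BOS baseline's
x-solve requires; `neumann` (replicate-edge) is provided and is the
natural choice for TGV² experiments.

## Proximal maps

For a gradient field with pointwise weighted group magnitude `m`:

* shrinkage (prox of `γ||·||_{2,1}`): `v ↦ v·max(m−γ, 0)/m`;
* projection (prox of the conjugate): `v ↦ v·min(m/γ, 1)/m`, whose output
  groups have magnitude at most 1.

Groups with `m = 0` map to 0 (the continuous limit).  The Moreau
decomposition `v = shrink(v,γ) + γ·project(v,γ)` holds to machine
precision and is both tested directly and exploited to show the FBOSS and
FBOSP updates are algebraically identical.

## Iterations

FBOSS/FBOSP (one iteration, default rule):

```
z   = x − δ⁻¹ Aᴴ(Ax − y)
v   = γw + Dx
w⁺  = (v − shrink(v, γ))/γ          # FBOSS
w⁺  = project(v, γ)                 # FBOSP (identical by Moreau)
x⁺  = z − (1/(λδ)) Dᵀw⁺
δ⁺  = ||A(x⁺−x)||² / ||x⁺−x||²      # BB mode (constant mode keeps δ)
```

The printed coefficient "λδ⁻¹" on the dual step admits two parsings.  The
default `x_update_rule="inverse_product"` uses `1/(λδ)` together with the
plain gradient step above — the unique combination whose fixed points
satisfy `0 = Dᵀw + λAᴴ(Ax−y)`, i.e. solve the stated objective.  The
literal reading (`as_printed`: coefficient `λ/δ` on both the gradient and
the dual step) is also shipped for comparison; because the shared factor
cancels in the fixed-point equation, that mode effectively solves the
objective with unit data weight and is not the default.

BB degenerate case `x⁺ = x` (0/0): the previous δ is kept.
Initialisation: `x⁰ = Aᴴy` (zero-filled reconstruction), `w⁰ = 0`,
`δ₀ = 1`.  A non-finite iterate raises a divergence error carrying the
iteration index and history.  One "iteration" is one full update; history
rows record post-update quantities.

**BOS baseline** (fixed δ, parameter ρ): gradient-like `z`-step, groupwise
shrinkage with threshold `1/ρ` of `w + Dx`, exact x-solve of
`(ρDᵀD + λδI)x = ρDᵀ(s−w) + λz` by FFT (hence the periodic-TV
restriction), and multiplier update `w⁺ = w + Dx⁺ − s`.  The printed form
of these updates has ambiguous grouping; the implementation uses the
standard Bregman-operator-splitting form, validated two ways: an 8×8 dense
matrix solve reproduces the FFT x-solve to 1e-10, and the fixed-point
algebra recovers the model's optimality condition (starting BOS at an
independently computed optimum with the matched multiplier `w/ρ` leaves
the objective stationary).

**AM baseline** (parameter α, TV only): denoising split variable `v`
(an image), dual projection `w⁺ = Π_X(w + τ_k D v)` onto the unit group
ball, averaged `v`- and `x`-updates, and the same BB δ-rule.  Schedules
`τ_k = 0.2 + 0.08k` and `θ_k = (0.5 − 5/(15+k))/τ_k`; the index in the
second schedule is taken to be the iteration counter `k`.

Stopping: relative change `||x^k − x^{k−1}||/||x^k|| ≤ ε` (default 5e-5),
or `max_iter`.

## Parameters

| knob | default | meaning |
|---|---|---|
| λ | 1e3 | data-consistency weight, calibrated for 8-bit-scale data |
| γ | 1.0 | prox scale of the splitting (sensible range 0.1–10) |
| δ₀ | 1.0 | initial stepsize |
| ε | 5e-5 | relative-change stopping tolerance |
| ρ | 0.5 | BOS shrink/solve weight |
| δ (BOS) | 1.0 | BOS fixed stepsize |
| α | 1e2 | AM coupling weight |

γ does not move the fixed points (any γ > 0 yields the same optimality
system); it trades shrinkage aggressiveness against dual stepsize.

## Synthetic data and what it shows

`make_dataset` emulates a Cartesian multi-coil acquisition that is fully
acquired, artificially undersampled and corrupted by receiver noise:

* **Phantom** — standard ten-ellipse Shepp-Logan head phantom (purely
  real; magnitude in [0,1]), plus piecewise-constant `blocks` and
  `smooth_bumps` alternatives; an optional smooth phase ramp is off by
  default so the truth's total variation stays small and complex-phase
  handling is tested separately.
* **Amplitude** — the phantom is scaled to peak 255 (8-bit image
  convention).  The standard λ=1e3, the ε=5e-5 stopping rule and the PSNR
  peak constant 255 form a consistent parameter set only at this scale:
  on unit-scale data the same λ makes the dual correction `(1/(λδ))Dᵀw`
  order-one relative to the image, and the BB iteration becomes
  nonmonotone without ever meeting the stopping rule.
* **Coil maps** — Gaussian lobes centred on a circle of radius 1.1 (FOV
  units) with width 0.55, i.e. surface-coil-like penetration of about half
  the FOV, with smooth random linear phase; optional low-order complex
  polynomials.  `normalize=True` enforces `Σ|S_j|² = 1`, making the SoS
  reference exactly `|x|` and bounding `||A||² ≤ 1`.
* **Mask** — inclusion probability `(1 + r/r₀)⁻²` in k-space radius `r`
  with `r₀ = max(ny,nx)/4` (center-weighted, as in standard CS-MRI
  variable-density sampling), realised by keeping the top-scoring draws so
  the sample count is exactly `round(ny·nx/factor)`; DC is always
  sampled.  A variable-density whole-line scheme is also provided.
* **Noise** — i.i.d. complex Gaussian added at sampled locations only,
  with variance calibrated so the sampled-signal-to-noise energy ratio is
  `snr_db` (verified by Monte-Carlo to ±0.5 dB).

What passing tests show: operator and prox correctness to machine
precision, the FBOSS/FBOSP equivalence, convergence to the model's
first-order optimality system, and the qualitative speed ordering
(FBOSS/FBOSP ≪ BOS in iterations).  What they do not show: performance on
scanner data — real acquisitions have measured (imperfect) sensitivity
maps, structured noise, and much higher SNR than the 30 dB synthetic
default; absolute error levels here are therefore not comparable to
published scanner-data figures.

A known limitation follows: at the standard synthetic conditions (30 dB,
λ=1e3 at 8-bit scale) the converged TV reconstruction retains ≈ 0.12–0.19
relative error — λ=1e3 is weak regularisation at this scale and does not
suppress that much noise through the undersampled inversion.  The same
pipeline reaches 8e-4 on noiseless data and 0.03–0.05 at 40–50 dB, which
is the regime the published scanner-data error levels correspond to.  The
acceptance suite asserts the 5% recovery bound at 30 dB as specified and
that test is expected to fail; all other properties pass.

## Numerical choices

* Centered orthonormal DFT throughout storage; the BOS x-solve uses the
  plain-FFT layout internally (the `DᵀD` symbol is layout-invariant).
* Equivalence testing of FBOSS vs FBOSP uses the constant-stepsize mode:
  the iteration map is then nonexpansive and the two (algebraically
  identical) routes agree to ~1e-16.  Under BB stepsizes the nonmonotone
  dynamics amplify round-off by several orders of magnitude over 100
  iterations, so that mode is checked at a correspondingly looser 1e-6.
* The cross-solver agreement study uses a well-conditioned fixture
  (factor 2, 40 dB) so the slow baselines actually reach the common
  optimum within the iteration budget; solver speed is assessed
  separately on the harder standard fixture.
* Power iteration (`spectral_norm`) returns the largest eigenvalue of
  `opᴴop`, i.e. the squared operator norm.
* PSNR: the package's default formula `20log10(255/||x−x*||²)` uses the
  squared 2-norm; the conventional `20log10(255/RMSE)` is available as
  `formula="standard"`.  Both compare magnitude images after scaling the
  reference to [0, 255].  Relative error is `||x−x*||/||x*||` on
  magnitudes.
* Degenerate inputs: zero gradient groups map to zero in both prox maps;
  a zero reference is rejected in the metrics; masks always contain DC;
  the BB 0/0 case falls back to the previous stepsize.
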