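# Methods

This note documents the models implemented in `rhodomap`, the numerical
choices behind them, and what the synthetic phantom does and does not
validate.

## Physical model

Lipofuscin in the retinal pigment epithelium fluoresces under 488 nm
excitation. On its double path (excitation in, emission out) the light is
attenuated by macular pigment near the fovea and by unbleached rod
rhodopsin elsewhere; Beer–Lambert gives

    AF(Λ, λ, t) = I(Λ) Φ(Λ, λ) exp(−[D_MP(Λ) + D_MP(λ) + ϱ_rh(0)(k_rh(Λ)+k_rh(λ)) R(t)]),

where `R(t)` is the fraction of rhodopsin remaining under the steady
scanning illumination. `R` obeys the bleaching/regeneration balance
`dR/dt = −I R/L + (1−R)/K` with photosensitivity `1/L` and visual-cycle
time constant `K ≈ 700–1000 s`, whose closed form is

    R(t) = (L/K)/(I + L/K) + I/(I + L/K) · exp(−(1 + KI/L) t/K).

In cSLO imaging `I ≫ L/K` and `t ≪ K`, so `R(t) ≈ exp(−βt)` with
`β = I/L`, and each pixel's brightening collapses to the three-parameter
law

    AF(t) = α exp(−γ e^{−βt}),

with `α` the fully bleached amplitude (camera units — no radiometric
calibration is attempted), `β` the bleaching rate (1/s internally; the
conventional per-frame value 0.04 at 8 frames/s is 0.32 s⁻¹), and `γ`
the double-path rhodopsin optical density at time zero — the quantity
being mapped. A density of `γ = ln 2 ≈ 0.693` attenuates the initial
signal by 50%; at `β = 0.32 s⁻¹` bleaching is >98% complete after 40 s,
which sets the one-minute movie length.

Time is seconds everywhere internally; movies carry an explicit
timestamp grid, so a per-frame reading of a rate is always convertible.
`β` is stored as the single rate `I/L`: the fitter never needs `I` and
`L` separately.

## Macular pigment map

With zero-sum weights `ω_j` over `n` co-registered bands,

    D_MP(460) = Σ_j ω_j ln(AF_p(j)/AF_f(j)) / Σ_j ω_j (k_MP(Λ_j)+k_MP(λ_j)),

the unknown fluorescence-efficiency ratio cancels exactly. The
perifoveal reference `AF_p` is a scalar per band, the mean over a
6°-radius, 1°-wide annulus; a scalar reference is what guarantees the
cancellation argument. Weights `(1, −1)` over two bands reproduce the
classic two-wavelength estimate. Pixels with nonpositive intensity are
masked, never clamped (the formula lives in the log domain, clamping
would bias it); negative densities under noise are retained, with an
optional display clip. Self-consistency is assessed by recomputing the
map under alternative zero-sum weight sets and reporting the per-pixel
spread; "most self-consistent" is operationalized as the weight set with
the smallest summed squared deviation from the cross-set mean.

The extinction tables `k_MP` (normalized to 1 at 460 nm) and `k_rh`
(normalized at 500 nm, zero at and above 590 nm where rhodopsin
absorbance is negligible) ship as editable two-column CSVs with linear
interpolation; they are smooth templates of the published curve shapes,
not digitized datasets, and are user-overridable. Phantom generation and
inversion share whatever table is configured, so recovery tests are
exact regardless of the template details.

## Per-pixel fit

The fit minimizes the mean-square-log energy (p = ln a)

    E(p, b, c) = Σ_i |ln f(t_i) − p + c e^{−b t_i}|² Δt_i,

a left-Riemann quadrature on the timestamp grid (the last sample reuses
the final spacing, so `Σ Δt_i` plays the role of `T − T₀` in every
closed form, keeping the discrete Hessian identities exact). For fixed
`b > 0` the Hessian of `E` in `(p, c)` is positive definite — its
determinant vanishes only at `b = 0`, by Cauchy–Schwarz, which survives
discretization — so the unique critical point is the global minimum.

Minimization uses artificial-time gradient descent discretized
semi-explicitly: `p` and `c` are updated implicitly (closed forms), `b`
explicitly. Numerical choices:

- `τ_c = 0.1`, `τ_b = 0.01`. The explicit `b` update is the only
  conditionally stable one and dictates the small step.
- `τ_p` is auto-balanced to `τ_c · Σ e^{−2bt}Δt / (T−T₀)` so that the
  log-amplitude and density modes contract at matching linear rates. Any
  positive `τ_p` converges to the same minimizer; balancing matters
  because the iteration count `N(x, y)` doubles as the vessel detector's
  signal. With a large unbalanced `τ_p` the amplitude mode equilibrates
  almost immediately and `N` reflects only the density distance — on
  phantoms this halves the vessel/background contrast of the `N` map.
  An explicit `τ_p` is honored when configured.
- Convergence: max parameter change `< 1e−7`, cap 5000 iterations (the
  fixed-rate iteration is affine and contracts unconditionally, so the
  cap matters only for the three-parameter mode). Divergence of the
  explicit `b` update (`b < 0` or non-finite) flags the pixel instead of
  aborting the image.
- Pixels with any nonpositive sample after averaging are masked from
  fitting (the log is undefined) and handed to vessel detection as
  occlusion candidates.

Whole-image fitting holds `b` at a single global `b₀`: the bleaching
rate is a photochemical constant, spatially invariant. `b₀` comes from
the initialization protocol: (i) average the movie over a 5–8° annulus
and run a three-parameter fit on that low-noise curve (seeded by a
half-rise-time heuristic); (ii) run three-parameter fits on an annulus
subsample (≤1024 pixels) and take the mode of the Freedman–Diaconis
histogram of recovered rates; (iii) start the log-amplitude at the
annulus value, spatially modulated by the macular pigment map when one
is available (`p₀(x,y) = p₀ − D_MP(x,y)·(k_MP(Λ)+k_MP(λ))`). Before
fitting, every frame is averaged over its surrounding 8×8 pixels
(sliding window, reflected borders) to suppress sensor noise.

## Vessel detection

Vessel pixels see mostly dark noise and violate the bleaching model.
Two detectors fall out of the fit itself — the package deliberately uses
no generic vessel segmenter:

- Iteration count: the fixed-rate iteration contracts at a
  data-independent rate, so `N(x, y) ∝ log` distance between the shared
  initial values and the pixel's solution; vessels, whose solutions sit
  far from the retinal consensus, converge last. Default threshold: the
  95th percentile of `N`, plus all non-converged pixels.
- L1 residual `ΔAF = Σ_i |f(t_i) − â e^{−ĉ e^{−b̂ t_i}}|`, thresholded
  by rank. Default band: the worst decile (90–100). The 8×8 averaging
  smears each vessel over the window width, so the model-failure halo is
  roughly three times the raw vessel area; a 5% band cannot cover it.

The final occlusion Ω is the union of both detectors dilated by 2 px
(edge pixels are corrupted by eye micro-movements and registration
imprecision); a mask covering more than half the image raises rather
than silently inpainting the retina away. The smooth relaxation χ_Ω is
a clipped-linear ramp of the Euclidean distance to Ω (default width
3 px): the simplest monotone interface.

## Inpainting

The density map is quantized to 8 bits over a robust range — the 1st to
99th percentile, widened when necessary so that no value outside Ω
clips; only vessel garbage, which is being replaced anyway, may clip.
Each bit plane `g` is extended into Ω by minimizing

    E(u) = w_f ∫ χ_Ω |u−g|² + 1/(2εμ) ∫ u²(u−1)² + εμ |u|_B²,

where `|u|_B²` is a Besov(1,2,2)-type seminorm: the level-weighted
detail energy of an orthogonal wavelet expansion (Daubechies-4,
4 levels, periodized), weight `4^j` growing toward finer scales. The
descent treats the double well and fidelity explicitly and the Besov
term — diagonal in the wavelet domain — implicitly, so the quadratic
stiffness never limits the step; the step is set from the Lipschitz
bound of the explicit part. The relaxed solution is thresholded at 1/2.

Parameter balance is the critical choice: on trusted pixels the
fidelity weight must dominate the finest-scale Besov weight
(`εμ·4⁴ = 25.6` at the defaults `ε = 1`, `μ = 0.1`), otherwise the
descent redraws contours *outside* the occlusion. The default
`w_f = 200` pins trusted data (including most of the transition ring)
while holes, seeing only the well and Besov terms, fill smoothly.

The final map is a two-step product: three inpainted versions with
`(ε, μ)` scaled by {0.5, 1, 2} and transition widths {4, 3, 2} px are
averaged, then the average passes through adaptive per-level soft
wavelet thresholding (BayesShrink). The transition widths are paired
*inversely* with the regularization scales: giving the most aggressive
smoother the widest (weakest) trust transition lets it overwrite the
near-vessel ring, so the strong smoother gets the tight ring instead.
Deviation between the pre- and post-inpainting maps is reported outside
Ω as (a) max absolute deviation relative to the quantization range and
(b) mean squared deviation relative to mean squared signal.

## Phantom

The generator emulates the statistical structure the pipeline assumes:
per-pixel double-exponential brightening; a Gaussian foveal macular
pigment peak (default 0.5 at 460 nm, 1° width) folded into α through
the extinction tables; a rod-topology γ field
`γ(r, θ) = γ_max (1 − e^{−r/s(θ)})`, zero at the fovea center, with the
rise scale smallest on the superior vertical meridian (4°) and largest
on the nasal horizontal meridian (7°), matching the qualitative human
rod topography; random smooth vessel trees (default 6 branches, 3 px
wide — about 100 µm at the default 256 px / 30° scale) whose pixels are
replaced by model-free dark noise at ~8% of α; and additive Gaussian
sensor noise at 2% of α (movies are low-SNR; no published level exists,
2% reproduces visually plausible single-pixel curves). Defaults follow
the clinical acquisition: 30° field, 8 frames/s for 60 s, β = 0.04 per
frame.

Not emulated: eye motion and registration error (movies are perfectly
registered; the real pipeline assumes registration happened upstream),
image background (background removal is explicitly not a pipeline
stage — a `background` hook exists and defaults to subtracting
nothing), and intensity quantization of the camera. Passing phantom
tests therefore validates the mathematics — model inversion, detection
geometry, inpainting fidelity — not robustness to registration
artifacts or background structure, which on clinical data dominate the
error budget and keep the maps distributional rather than absolutely
quantitative.

## Problem sizes

The validation suite runs the full five-step pipeline once at the
clinical scale (256×256 pixels, 480 frames) and uses smaller phantoms
(~80–96 px, 15–30 s) for orchestration and property tests; brute-force
oracles (200×200 energy grids, exhaustive 2¹⁶ binary fills of a 4×4
hole, Runge–Kutta integration) are sized to stay exact yet quick.

## Known limitations

- Amplitudes are relative: α absorbs `I(Λ)Φ(Λ,λ)` and any uncorrected
  background, so γ maps are comparable within an image, not across
  instruments.
- The fovea mixes macular pigment and rhodopsin; with the MP map
  supplied the amplitude start is corrected there, but γ estimates
  inside ~1° remain the least constrained (little bleaching signal).
- The iteration-count detector assumes shared initial values; running
  it on fits initialized per-pixel from an oracle would erase its
  signal.
- Real vessel masks in the source imagery benefit from registration
  artifacts that make vessels even easier to detect than in the
  perfectly registered phantom.
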