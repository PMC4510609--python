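# rhodomap

Mapping rod rhodopsin optical density across the human retina from
standard clinical autofluorescence imaging.

## The problem

Rod photoreceptors carry rhodopsin, a visual pigment that strongly
absorbs blue-green light and "bleaches" (becomes transparent) under
illumination. In a 488 nm confocal scanning laser ophthalmoscope (cSLO)
movie of a dark-adapted retina, the lipofuscin autofluorescence of the
retinal pigment epithelium *brightens* over ~40 s as the overlying
rhodopsin bleaches away. The magnitude and kinetics of that brightening,
pixel by pixel, encode the local rhodopsin density — an early marker of
visual-cycle defects and rod loss. `rhodomap` turns a registered
one-minute AF movie (plus, optionally, a multi-spectral image set for
macular pigment) into a spatial map of rhodopsin optical density with
retinal vessels detected and inpainted away.

## The model

Beer–Lambert on the double light path, with the remaining-rhodopsin
fraction `R(t) ≈ e^{−βt}` under steady scanning light, gives the
per-pixel bleaching law

    AF(t) = α · exp(−γ · e^{−βt}),

- `α` — fully bleached AF amplitude (absorbs source power, fluorescence
  efficiency and macular pigment attenuation
  `e^{−D_MP(460)(k_MP(Λ)+k_MP(λ))}`),
- `β = I/L` — bleaching rate, a photochemical constant held spatially
  uniform (≈0.04 per frame at 8 frames/s),
- `γ` — double-path rhodopsin optical density at time zero: the map.

Each pixel's curve `f(t₁..t_m)` is fitted by minimizing the
mean-square-log energy `E(p,b,c) = Σᵢ |ln f(tᵢ) − p + c e^{−btᵢ}|² Δtᵢ`
(p = ln a) with a semi-explicit gradient-descent scheme whose fixed-rate
iteration provably reaches the global minimum. Macular pigment density
comes first from the zero-sum multi-wavelength log-ratio formula
`D_MP(460) = Σ ω_j ln(AF_p/AF_f) / Σ ω_j (k_MP(Λ_j)+k_MP(λ_j))`.
Vessels are detected from the fit's own diagnostics (iteration-count map
and L1 model residual) and filled by bit-plane-wise wavelet
Ginzburg–Landau inpainting with a smooth occlusion mask. A synthetic
retinal phantom with full ground truth makes the whole pipeline testable
without clinical data. See `docs/methods.md` for the details and
numerical choices.

## Worked example

```python
import numpy as np
from rhodomap import (PhantomSpec, SpectralBand, OpticalCoefficients,
                      generate_movie, generate_mp_set, run_pipeline)

spec = PhantomSpec(shape=(128, 128), duration=30.0, seed=42)
movie, truth = generate_movie(spec)
coeffs = OpticalCoefficients.default()
bands = [SpectralBand(460, 600), SpectralBand(480, 600),
         SpectralBand(510, 600), SpectralBand(530, 600)]
mpset, _ = generate_mp_set(spec, bands, (1, 1, -1, -1), coeffs, noise_sigma=0.5)

res = run_pipeline(movie, mp_set=mpset, coeffs=coeffs)

print(f"bleaching rate b0      : {res.init.b0:.4f} 1/s "
      f"({res.init.b0 / spec.frame_rate:.4f} per frame)")
print(f"vessel mask fraction   : {res.mask.omega.mean():.1%}")
s = res.inpaint.deviation_stats
print(f"inpainting deviation   : {s['amplitude_pct']:.2f}% amplitude, "
      f"{s['mse_pct']:.4f}% relative MSE (outside mask)")
sel = ~truth.vessel_field
r = np.corrcoef(res.final.gamma[sel], truth.gamma_map[sel])[0, 1]
print(f"gamma map vs truth     : Pearson r = {r:.3f} (off-vessel)")
```

prints

```
bleaching rate b0      : 0.3200 1/s (0.0400 per frame)
vessel mask fraction   : 17.2%
inpainting deviation   : 0.22% amplitude, 0.0001% relative MSE (outside mask)
gamma map vs truth     : Pearson r = 0.986 (off-vessel)
```

The histogram-mode estimate recovers the generating bleaching rate
exactly (0.04 per frame); the vessel tree plus its blur halo occupies
17% of the field and is masked; removing it perturbs the map outside the
mask by 0.22% of its dynamic range at worst; and the final density map
tracks the ground-truth rod topology at r = 0.99.

`run_pipeline(..., outdir=...)` persists every intermediate (MP map,
â/b̂/ĉ fields, iteration counts, vessel mask, final map, stripe-averaged
profiles). The same five steps are scriptable from the shell:

```sh
rhodomap simulate --seed 1 --out phantom/
rhodomap run-all --movie phantom/movie.tif --out maps/
```

The estimator classes (`MacularPigmentMapper`, `BleachModelFitter`,
`VesselDetector`, `WGLInpainter`) follow scikit-learn conventions
(`get_params`/`set_params`, fitted attributes with trailing
underscores) and compose with sklearn tooling.

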