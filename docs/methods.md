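# Methods

## Model

`patchfuse` fuses two co-registered single-channel images A and B (think
CT and MR of the same slice; registration is assumed, not performed). The
pipeline is fully deterministic: all randomness lives in the synthetic
phantom generator and is seed-controlled.

1. Both images are decomposed with a K-level separable DWT (default
   `db3`, K = 3, symmetric half-sample extension). Symmetric extension
   with PyWavelets' extended coefficient layout gives a perfectly
   invertible filter bank, so `reconstruct(decompose(I)) == I` to
   floating-point accuracy; this is asserted in the tests rather than
   assumed.
2. The approximation bands are merged as k₁·A + k₂·B, k₁ + k₂ = 1.
3. Each of the 3K detail bands is merged per coefficient as
   ω·A + (1−ω)·B with ω = φ_A/(φ_A + φ_B), where φ is the structure-tensor
   coherence of *that band*, computed independently for each sub-band,
   level and source.
4. The fused pyramid is inverted and the output clipped to [0, 1]
   (reconstruction of a convex-combined pyramid can overshoot the input
   range slightly).

The coherence pipeline per band: centered-difference gradient → initial
tensor J₀ = ∇I∇Iᵀ → NLM filtering of the three tensor planes with one
shared weight set per pixel → closed-form eigenvalues → φ = (μ₁ − μ₂)².
Sharing a single weight set across the planes keeps the filtered tensor
symmetric and PSD (it is a convex combination of PSD matrices); weights
are computed from the band being filtered, which plays the role of the
intensity signal in the standard NLM formulation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `wavelet_name` | `db3` | — | analysis/synthesis filter pair |
| `levels` | 3 | — | pyramid depth |
| `k1`, `k2` | 0.75, 0.25 | — | low-band affine weights (must sum to 1) |
| `search_radius` | 5 | px | NLM search window 11×11 |
| `patch_radius` | 2 | px | similarity patch 5×5 |
| `h` | 0.15 | intensity | NLM decay; ≈15% of the [0, 1] range, a standard NLM heuristic, exposed for tuning |
| `rho` | `patch_radius / 2` | px | Gaussian patch taper G_ρ, so ~2σ spans the patch; 0.5 for point patches |

The wavelet/window defaults are the reference experimental protocol; `h`
and `rho` have no canonical published values, so the defaults above are
the package's own choices and both are plain config fields.

## Numerical choices

* **Gradient**: central differences, `gx` along columns (x), `gy` along
  rows (y). Symmetric, zero-bias on linear ramps.
* **Boundaries**: mirror reflection (edge sample not repeated) everywhere
  — gradients, patch extraction, Gaussian smoothing, the WA activity
  window. One convention keeps the brute-force oracles simple.
* **Search window**: the NLM normalizer Z(X) runs over the search window
  only, clipped to the image domain at borders (and hence automatically
  clipped when a coarse sub-band is smaller than the window). Window
  radii are held fixed across pyramid levels.
* **Eigenvectors**: v₁ ∥ (J₁₁ − J₂₂ + √disc, 2J₁₂). Where disc < 1e-12
  the tensor is treated as isotropic and the pair is pinned to the
  coordinate axes — any orthonormal pair is valid there; pinning makes
  runs bit-reproducible. The anisotropic-diagonal corner case
  (J₁₂ = 0, J₂₂ > J₁₁) falls back to the y-axis explicitly.
* **Degenerate weights**: ω = φ_A/(φ_A+φ_B) and the WA activity ratio
  both fall back to 0.5 when numerator and denominator vanish — the
  symmetric, continuous limit.
* **CGM ties** select source A, making the rule deterministic.
* **Low-band rule shared by all schemes**: the `wa` and `cgm` baselines
  replace only the detail-band rule, so EOG differences between schemes
  isolate the high-frequency rule.

## Design choices where the design was open

* **Coherence on sub-bands, not sources.** φ is indexed per sub-band and
  level, so the tensor pipeline runs on each detail plane at its own
  scale rather than on the full-resolution sources. This is the reading
  implemented; it also makes the cost independent of source resolution
  beyond level 1.
* **WA activity measure.** "Adaptive weighted average" fixes no formula;
  the implementation uses the mean squared coefficient over a 3×3 window,
  the canonical activity measure in the wavelet-fusion literature, with
  ω = s_A/(s_A+s_B).
* **CGM on band gradients.** The gradient deciding the choose-max is the
  gradient of the detail band itself, matching the per-coefficient scope
  of the other rules.
* **EOG definition.** EOG = (1/HW)·Σ(gx² + gy²) on [0, 1]-normalized
  intensities. Published EOG tables rarely state the normalization (sum
  vs mean, intensity scale), so absolute values are not comparable across
  conventions — only the ordering of schemes on one input pair is, and
  that ordering is invariant to the normalization.
* **k₁ > k₂ privileges image A's approximation band**; which source is
  "A" is the caller's decision, so the weights are config, not semantics.

## Synthetic data

`make_phantom_pair` emulates the statistical structure multimodal fusion
exploits, not anatomy: image A has a bright elliptical rim (dense bone
analogue, default intensity 0.9) over a flat interior; image B shares the
identical, pixel-exact geometry with a dim rim and a textured interior
(band-limited Gaussian noise, σ = 2 px smoothing, amplitude 0.35, plus
three seed-jittered elliptical inclusions). Both carry additive Gaussian
noise (default σ = 0.01, light acquisition noise). The pair is
complementary by construction — gradient energy concentrates on the rim
in A and in the interior in B — and the generator asserts nothing about
MR physics, partial-volume effects, bias fields or mis-registration.
Passing tests therefore demonstrate the pipeline's contracts
(reconstruction, convexity, ordering of schemes on complementary
sources), not clinical image quality.

Problem sizes in the test suite — 128×128 phantoms, ≤16×16 oracle
instances, 20 random trials per oracle — were chosen so the whole suite
runs in seconds while every code path, including the full three-level
fusion, is exercised end to end.

## Known limitations

* 2-D, single-channel, two sources only; no registration, no color, no
  volumes.
* The NLM filter is exact but O(window² · patch²) per pixel; for large
  images at level 1 this is the dominant cost.
* φ computed on coarse sub-bands of very small images degenerates toward
  the 0.5 tie-break as the bands approach the window size.
* EOG is a no-reference sharpness proxy; it rewards retained gradient
  energy, including artifacts a human reader would penalize (see the
  `cgm` scores).
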