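# patchfuse

Multimodal medical image fusion driven by a **patch-based (nonlocal-means
filtered) structure tensor**.

Clinical imaging modalities are complementary: CT renders dense structure
(bone, implants) with high contrast but flat soft tissue, while MR renders
soft-tissue detail the CT misses. Given two co-registered grayscale slices,
`patchfuse` merges them into a single image that keeps the salient detail of
both, and quantifies the result with the energy-of-image-gradient (EOG)
sharpness metric.

## Method

The per-pixel **structure tensor** of an image *I* is the outer product of
its gradient, J₀ = ∇I ∇Iᵀ, a symmetric PSD 2×2 matrix with eigenvalues
|∇I|² and 0. Plain Gaussian averaging of J₀ (the linear structure tensor)
stabilizes it against noise but blurs edges. Here J₀ is instead averaged
with **nonlocal-means weights**: for pixels X, Y the weight

&nbsp;&nbsp;ω(X, Y) = exp(−d(X, Y)/h²) / Z(X),&nbsp;&nbsp;
d(X, Y) = Σₒ G_ρ(o) · (I[X+o] − I[Y+o])²

compares whole (2r+1)×(2r+1) patches under a Gaussian taper G_ρ, so
similar structures reinforce each other regardless of distance. The
filtered tensor J_NLM = NLM(J₀) has closed-form eigenvalues

&nbsp;&nbsp;μ₁,₂ = ½ [J₁₁ + J₂₂ ± √((J₁₁ − J₂₂)² + 4 J₁₂²)],

whose gap classifies local geometry (μ₁ ≈ μ₂: homogeneous; μ₁ ≫ μ₂ ≈ 0:
edge; μ₁ ≥ μ₂ ≫ 0: corner). The squared gap **φ = (μ₁ − μ₂)²** is the
local coherence measure.

Fusion runs in a K-level discrete wavelet frame (default `db3`, 3 levels,
symmetric extension):

* **low band**: W_L^F = k₁·W_L^A + k₂·W_L^B with (k₁, k₂) = (0.75, 0.25);
* **each detail band**: W^F = ω·W^A + (1−ω)·W^B with
  ω = φ_A/(φ_A + φ_B), φ computed per sub-band per level through the
  tensor pipeline (ω = ½ where both vanish).

The inverse transform yields the fused image. Two classical rules —
adaptive weighted average (`wa`) and choose-gradient-max (`cgm`) — are
implemented in the same frame for comparison.

## Worked example

```bash
patchfuse phantom ct.png mr.png --size 128 --seed 0   # registered pseudo-CT/MR pair
patchfuse fuse ct.png mr.png fused.png --scheme patch
patchfuse metrics ct.png mr.png
```

The `metrics` command fuses the pair under every scheme and prints:

```
scheme         eog
patch_tensor   0.0122697
wa             0.011454
cgm            0.0131352
```

EOG is the mean squared gradient magnitude of the [0, 1]-normalized fused
image — higher means more retained detail. The coherence-weighted scheme
(`patch_tensor`) outscores the weighted average (`wa`), which smooths
detail away wherever both sources are active; `cgm` scores highest on this
synthetic pair because hard coefficient selection maximizes gradient
energy at the price of switching artifacts near edges. For reference, the
inputs score 0.0132 (pseudo-CT) and 0.0042 (pseudo-MR).

Everything is also available as a library:

```python
import patchfuse as pf

A, B = pf.make_phantom_pair(pf.PhantomSpec(seed=0))
fused = pf.fuse_images(A, B, pf.FusionConfig(scheme="patch_tensor"))
print(pf.eog(fused))
```

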