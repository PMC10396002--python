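# Methods

## Model

The pipeline treats fusion as a two-scale problem in the spatial domain.
Each source image is separated into a large-scale *base* layer and
residual *detail* layers, and the separation of one modality is steered by
the other ("information clustering"): the base layer of image I is the
weighted median filter of I whose weights derive from a guidance map
f = 0.5·(J/255) built from the partner image J. Wherever J is flat the
affinity between the centre pixel and its neighbours is uniform and the
filter smooths aggressively; wherever J has an edge, neighbours across the
edge get exponentially small weight and the structure survives into the
base. The detail layers of the two sources are therefore aligned with a
shared edge geometry before any fusion rule is applied, which is the
method's central assumption: *co-registered* inputs whose meaningful
structure is mutually visible. Misregistered pairs violate it; the package
performs no alignment.

Recombination is purely algebraic. The base layers are fused through their
pixelwise extrema weighted by global standard deviations; detail layers
are scaled by one adaptive coefficient k and added/subtracted. All σ
quantities and the branching threshold (30) live on the 8-bit 0–255
intensity scale; inputs of other bit depths are rescaled on ingest.

## Filter parameters

| parameter | default | units / scale | role |
|---|---|---|---|
| `radius` | 5 | pixels | window (2r+1)², smoothing strength |
| `ni` | 256 | bins | intensity quantization; 256 is lossless on 8-bit data |
| `nf` | 32 | bins | guidance quantization for the joint histogram |
| `bandwidth` | 0.1 | [0,1] guidance units | affinity decay scale |
| `sigma_threshold` | 30 | 8-bit intensity σ | enhancement/attenuation switch |
| `weight_mode` | `auto` | — | branch choice (`positive`/`negative`/`fixed` for overrides) |
| `radical_grouping` | `grouped` | — | √(σ₁+σ₂) (default) vs √σ₁+√σ₂ in the k rule |
| `sigma_source` | `extrema` | — | σ₃, σ₄ from I_Bmax/I_Bmin (default) or each source's own base |

The affinity bandwidth and the window radius are free parameters of the
method; the defaults were picked once as moderate smoothing for 8-bit
scenes (an 11×11 window; bandwidth 0.1 means a guidance contrast of ~10 %
of full scale reduces a neighbour's influence by e⁻¹) and every value is
exposed in `FusionConfig` and on the CLI.

## Numerical choices

- **Quantization.** Intensities map to bins by `floor(v·ni/256)`, guidance
  by `floor(f·nf)`, out-of-range values clamp to edge bins (logged).
  Affinities are evaluated between the *bin centre* of the neighbour's
  guidance and the exact guidance value of the centre pixel — required so
  the per-window weight sums factor through the joint histogram.
- **Cut-point decision.** Both backends decide the median bin through the
  balance statistic b(c) = Σ_f (2·#{i≤c at f} − n_f)·g_f, computed with
  `math.fsum` over identical integer-count × weight products. Since fsum
  is correctly rounded and order-independent, the naive and accelerated
  backends agree bit-for-bit — an invariant the acceptance suite checks on
  random inputs.
- **Ties.** The median bin is the *smallest* cut with b ≥ 0 (stable
  ascending order); the output value is the lower median of the window's
  original values inside that bin. With `ni = 256` on 8-bit data the bin
  holds a single value, so the filter is selection-exact.
- **Borders.** Windows are truncated at the image edge: no padding values
  are invented, and every output pixel is one of its window's input values
  (selection property).
- **Cut propagation.** The accelerated backend slides the joint histogram
  and balance box column-wise along each row and restarts at each row
  start — the simplest scheme that preserves exactness.
- **Detail clipping.** The raw bright/dark residuals are negatives of one
  another; the layers are stored as the clipped positive/negative parts
  (nonnegative, disjoint support). Because the same k weights both layers,
  the fused output is algebraically identical under clipped and unclipped
  conventions — asserted as a test rather than assumed.
- **Degenerate inputs.** Flat base extrema (σ₃+σ₄ = 0) give k = 1;
  `min(σ₁,σ₂)` exactly at the threshold defines the sign term as 0 (k = 1);
  flat extrema images fuse with weights ½/½; fused output is clamped to
  [0, 255] with the clamp count logged.
- **Reconstruction exactness.** `base + bright − dark = I` is bit-exact for
  images with whole 8-bit intensity levels (the base is drawn from the
  image's own values, so the residual arithmetic is exact). For
  continuous-valued inputs the identity holds to one rounding of the
  residual (~1 ulp).

## Design decisions

- The printed affinity model degenerates to `exp(−f(p)−f(q))`, which is
  neither symmetric nor maximal at equality; the implemented affinity
  `exp(−|Δf|/h)` restores both properties and adds the missing scale h.
- The grouping of the radical in the k rule is ambiguous in the source
  material; the grouped form is the default because it reduces to the
  clean `k = √((σ₁+σ₂)/(σ₃+σ₄))` on the positive branch and reproduces the
  worked σ examples (k ≈ 1.0177 for a high-contrast pair, k ≈ 0.155 for a
  low-contrast one). The per-term reading is selectable, never mixed.
- σ₃, σ₄ default to the standard deviations of I_Bmax/I_Bmin; taking each
  source's own base σ instead is config-selectable (`sigma_source`), with
  the pair sorted so the pipeline stays symmetric under input swap.
- The Petrovic preservation model uses the published sigmoid constants
  (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22,
  σ_α = 0.8), strength ratio min/max with ratio 1 at equal gradients, and
  orientation α = arctan(S_y/S_x) (vertical convention at S_x = 0). Loss
  accumulates per-source unpreserved information where the fused gradient
  is weaker than that source's; artifacts accumulate it where the fused
  gradient exceeds both sources. Under these edge-strength-bounded
  definitions Q, L, N all lie in [0, 1] and no Q+L+N = 1 identity holds or
  is imposed.

## Synthetic data

`synthdata.make_pair` emulates the *structure* of co-registered
two-modality captures: a shared smooth scene field rendered twice —
modality A with strong structure amplitude plus fine texture
(visible-like), modality B with a flattened, extra-smoothed version of the
same geometry plus bright elliptical targets (thermal-like), Gaussian
sensor noise, and quantization to whole 8-bit levels. Structure fields are
standardized before amplitude scaling, so the `high` preset yields source
σ well above the branching threshold and the `low` preset well below it
for every seed — both branches of the adaptive weight are exercised by
construction. Targets carry full contrast inside the returned mask with a
blurred halo outside, and a reduced (30 %) contrast share in modality A,
mimicking objects faintly visible to both sensors.

What the generator does **not** emulate: real sensor transfer functions,
structured/thermal noise, parallax or misregistration, saturation bloom,
and natural image statistics (1/f spectra, occlusions). Passing tests
demonstrate the algebraic and branching behaviour of the pipeline on
controlled scenes, not field performance on TNO-like imagery.

## Problem sizes

The pipeline is pure Python/NumPy; the accelerated backend makes the
default test scales comfortable: backend-equivalence checks run on 16×16
random pairs across radii 1–3, decomposition identities on 40×40 pairs,
and the end-to-end checks on ten 96×96 pairs at the default radius 5
(about 2 s per fusion). The acceptance script uses one 96×96 pair per
branch.

## Known limitations

- O(w·h·(r + N_f)) per filter pass in interpreted Python; large frames
  (≥ 512²) are slow. The joint-histogram design would admit a compiled
  kernel without changing results.
- Single-channel only; RGB inputs are collapsed to luminance on ingest.
- Exactly two sources; no multi-exposure stacks.
- The σ-threshold rule is global: scenes mixing high- and low-contrast
  regions get one k for the whole frame.
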