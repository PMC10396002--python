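# icif — multimodal image fusion via information clustering

`icif` fuses two co-registered single-channel images — an infrared and a
visible-light frame, a CT and an MRI slice, or two multi-focus shots —
into one image that keeps the salient bright targets of one modality and
the fine texture of the other. It is aimed at surveillance, medical and
computational-photography pipelines that need a deterministic, training-free
fusion step, plus the standard metric suite to score the result.

## Method

The core operator is *information clustering* IC(·): a weighted median
filter in which the weights for smoothing one modality come from the
**other** modality. For a pixel p with window R(p), a neighbour q
contributes weight

    w_pq = exp(-|f(p) - f(q)| / h),        f = 0.5 · (other image / 255),

and the output is the weighted median of the window (smallest value whose
cumulative weight reaches half the total). Because the guidance map f is
built from the opposite sensor, the extracted layers of the two sources
stay mutually consistent. Each source I is decomposed as

    base   = IC(I),
    bright = max(I - base, 0),     dark = max(base - I, 0),

an exact three-layer split (I = base + bright − dark). The two bases are
fused through their pixelwise extrema I_Bmax, I_Bmin weighted by standard
deviations (the larger weight on I_Bmin), and the details are added back
with one adaptive weight

    ρ = (√(σ₁+σ₂) − √(σ₃+σ₄)) / √(σ₃+σ₄)
    k = 1 + sgn(min(σ₁,σ₂) − 30) · ρ
    I_F = I_BF + k·(bright₁+bright₂) − k·(dark₁+dark₂),

where σ₁, σ₂ are the source standard deviations and σ₃, σ₄ those of the
base extrema (8-bit scale). High-contrast pairs get detail enhancement
(k > 1), low-contrast pairs attenuation (k < 1).

The filter ships two backends that agree pixel-exactly: a brute-force
per-window reference and an accelerated backend using a sliding joint
histogram over (intensity bin, guidance bin), incremental
balance-counting-box cut-point tracking, and a necklace table that skips
empty histogram columns.

The metric suite implements AG (average gradient), H (entropy, bits), SD,
SF (spatial frequency), EI (Sobel edge intensity) and the
gradient-preservation triple Q^AB/F (fusion quantity), L^AB/F (fusion
loss), N^AB/F (fusion artifacts).

## Worked example

Generate a synthetic co-registered pair (visible-like modality A,
thermal-like modality B with bright blob targets) and fuse it:

```sh
icif synth -o demo --seed 7 --height 48 --width 48
icif fuse demo/mod_a.png demo/mod_b.png -o demo/fused.png --metrics --radius 3 -v
```

The log reports the adaptive weighting actually used:

```
INFO fusion weights: sigma1=52.111 sigma2=49.418 sigma3=53.331 sigma4=41.924 k=1.0324 branch=positive
```

Both source σ exceed the threshold 30, so the positive (enhancement)
branch fires with k ≈ 1.03: detail layers are slightly amplified.
`demo/fused_report.json` contains the quality metrics of the result, e.g.

```
"k": 1.032408281048516, "branch": "positive",
"q_abf": 0.6183717181094962, "ag": 9.832369687948768
```

— about 62 % of the sources' edge information is preserved in the fused
image (Q^AB/F), whose mean gradient (AG ≈ 9.8) exceeds that of either
input. `icif decompose` writes the six layers, and `icif metrics` scores
any existing fusion result. The same pipeline is available as a library:

```python
from icif import FusionConfig, fuse_images
fused, weights = fuse_images(img_a, img_b, FusionConfig())
```

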