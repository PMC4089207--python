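# ultraspeckle

Structure-based speckle reduction for ultrasound images.

Ultrasound images carry speckle — granular interference noise that is well
modeled as multiplicative — which roughens homogeneous tissue regions and
blurs the boundaries clinicians rely on. Plain linear smoothing removes
speckle but also removes the boundaries; plain median filtering preserves
more structure but oversmooths and can leave artifacts. This package
despeckles by first asking, at every pixel, *what kind of structure is
here*, and only then choosing a filter matched to that structure.

## The method

At each pixel the 2×2 Hessian of intensity (the local diffusion tensor)

```
H = [[Ixx, Ixy],
     [Ixy, Iyy]]
```

is computed by Gaussian-derivative convolution (scale σ = 1.4 px). Its
eigenvalues λ₁, λ₂ (|λ₁| ≥ |λ₂|) and eigenvectors describe the strength and
orientation of local intensity spreading: the major eigenvector points
across a curvilinear structure, the minor along it. After normalizing the
eigenvalues by their global maximum magnitude, two responses

```
T1 = λ₁² + λ₂²,    T2 = (|λ₂| + ε) / (|λ₁| + ε)
Cl = T1·(1 − T2),  Cs = T1·T2
```

measure feature strength, linearity (Cl) and spot-ness (Cs), and each pixel
is labeled **uniform** (T1 ≤ β), **linear** (bright ridge, λ₁ ≤ 0),
**boundary** (dark valley, λ₁ > 0), **spot** (T1 ≥ α, Cs > Cl), or
**unknown**, with β = 0.12 and α = 0.45. A refinement pass then walks all
spot/unknown pixels and relabels those whose neighbors along the minor
eigenvector are linear or boundary pixels — reconnecting curve segments
broken by weak echoes. Finally each pixel is filtered by the tool that fits
its label: a 9-sample oriented 1D Gaussian "stick" along the curve tangent
(linear/boundary), a 9×9 median (uniform/unknown), or a σ = 1 2D Gaussian
(spot). The whole pipeline is iterated; two passes are the usual
cost-effective setting.

The package also ships the evaluation machinery: a multiplicative
Rayleigh-shaped speckle model, PSNR and SSIM metrics, Gaussian/median
baseline filters, a labeled phantom generator, and a benchmark driver — so
the full experimental protocol runs on synthetic data with no downloads.

## Worked example

```python
import ultraspeckle as us

# a 256x256 phantom: flat bands, bright ridges, a dark curve, four spots
clean, truth = us.make_phantom(us.default_phantom_spec(seed=1))
noisy = us.multiplicative_rayleigh(clean, us.NoiseSpec(sigma=0.3, seed=1))

cfg = us.PipelineConfig(passes=1, equalize_each_pass=False)
pass1, _ = us.despeckle(noisy, cfg)
pass2, _ = us.despeckle(pass1, cfg)

for name, img in [("noisy", noisy), ("pass 1", pass1), ("pass 2", pass2)]:
    print(f"{name:7s} PSNR {us.psnr(clean, img):5.2f} dB   "
          f"SSIM {us.ssim(clean, img):.4f}")
```

prints

```
noisy   PSNR 17.41 dB   SSIM 0.1490
pass 1  PSNR 25.39 dB   SSIM 0.6402
pass 2  PSNR 27.97 dB   SSIM 0.8404
```

i.e. the first pass recovers ~8 dB of fidelity over the speckled input and
the second pass adds ~2.6 dB more, with structural similarity rising from
0.15 to 0.84 — the multi-pass payoff expected at this noise level.

From the shell, the same pipeline runs as

```
despeckle input.png -o output.png --passes 2 --save-typemap maps/ -v
```

where `--save-typemap` writes per-pass structure maps (grey = uniform,
green = linear, dark green = boundary, red = spot, blue = unknown).

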