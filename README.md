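# spirecon

Single-pixel compressive fluorescence imaging, end to end in software:
learned bipolar sampling patterns, photon-level measurement simulation,
classical and deep-unrolled reconstruction, and a high-speed "zoom"
(pattern merge/unmerge) sampling mode.

## Who this is for

Confocal laser scanning is slow and phototoxic because it builds an image
point by point under strong excitation.  Single-pixel imaging (SPI)
instead measures inner products between the scene and a sequence of
modulation patterns shown on a digital micromirror device (DMD), recorded
by a bucket detector — here a photon-counting PMT — and reconstructs the
image computationally.  With `m ≪ N` patterns the acquisition is
compressed: at a DMD refresh rate `R` the differential (±1) sampling mode
images at `F = R/(2m)` frames per second.  This package is for people who
want to study, prototype or teach that computational pipeline — pattern
design, photon statistics, and reconstruction — without an instrument:
everything runs on synthetic fluorescent phantoms (microsphere, nucleus,
and filament scenes).

## The model

Acquisition: `y = A x + n`, with `x ∈ R^N` the scene (`N = H×W`),
`A ∈ R^{M×N}` bipolar patterns with entries `±1/√N` realized optically as
complementary binary pattern pairs, and photon counting modeled as
independent Poisson draws on each binary exposure, differenced and
normalized.

Patterns are learned by minimizing `(1/N)‖AᵀA x − x‖²` over training
images with `A = Sign(Φ)/√N` and a straight-through gradient for `Sign`.

Reconstruction solves `min_x ½‖Ax − y‖² + λR(x)` either by proximal
gradient descent (ℓ₁ or TV prox) or by a ratio-conditioned unrolled
network: `K` stages, each an *exact* gradient step
`z = x − ρ_k Aᵀ(Ax − y)` on an image-domain anchor followed by a small
learned convolutional prox, trained with an ℓ₁ loss and random
measurement-subset augmentation so one model serves every sampling ratio
`m/N ≤ M/N`.  In zoom mode, patterns average-pooled `z×z` (and
re-bipolarized) are used for sampling while their nearest-neighbor
upscalings are fed to the network, which then reconstructs at source
resolution from ultra-low sampling ratios.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
conventions.

## Worked example

```python
import spirecon as sr
from spirecon.evaluation import (AcquisitionSpec, frame_rate, psnr,
                                 sampling_ratio, throughput)
from spirecon.forward_model import photon_budget
from spirecon.recon_classical import ReconSpec, pgd_reconstruct
from spirecon.synthetic_data import default_spec, gen_scene, photon_scale_for_total

# acquisition arithmetic for a 128x128 field, m = 5 differential patterns
spec = AcquisitionSpec(dmd_refresh_hz=15_000, n_measurements=5, n_pixels=128 * 128)
print(f"sampling ratio: {sampling_ratio(5, 128 * 128):.2f}%")
print(f"frame rate:     {frame_rate(spec):.0f} fps")
print(f"throughput:     {throughput(spec):.2f} Mpix/s")

# single-photon-level acquisition of a microsphere phantom
scene = gen_scene(default_spec("microspheres", 128, seed=0))
scale = photon_scale_for_total(scene, 400.0)   # ~400 photons per pattern
op = sr.random_operator(60, 128, 128, seed=1)
rec = sr.measure_photons(op, scene, scale, seed=2)
print(f"valid pixels:   {scene.n_valid()}")
print(f"photon budget:  {photon_budget(rec, scene):.2f} photons/pixel")

# reconstruct a 32x32 scene from a 20% noiseless acquisition by PGD
small = gen_scene(default_spec("nucleus", 32, seed=3))
op32 = sr.random_operator(200, 32, 32, seed=4)
rec32 = sr.measure(op32, small)
est, info = pgd_reconstruct(rec32, op32, ReconSpec(
    max_iters=400, step_size=0.5, reg_weight=0.001, regularizer="l1"))
print(f"PGD iterations: {info['iterations']},  PSNR {psnr(est, small.intensities):.2f} dB")
```

Output:

```
sampling ratio: 0.03%
frame rate:     1500 fps
throughput:     24.58 Mpix/s
valid pixels:   996
photon budget:  0.40 photons/pixel
PGD iterations: 400,  PSNR 13.38 dB
```

The first block is the speed arithmetic of the differential sampling mode:
5 patterns on a 16384-pixel field is a 0.03% sampling ratio, and a 15 kHz
DMD showing two binary exposures per pattern yields 1500 fps, i.e.
24.58 megapixels per second.  The photon block reproduces the single-photon
operating point: ~400 detected photons per pattern spread over ~1000
sample-occupied pixels is ~0.4 photons per pixel per measurement.  The last
line is a baseline iterative reconstruction; the trained unrolled network
(see `spirecon.recon_net.train` or the pipeline below) substantially
improves on sparse-measurement quality.

A full provenance-stamped pipeline — generate scenes, learn patterns,
simulate, train, sweep PSNR/SSIM over sampling ratios — runs from a YAML
config:

```sh
echo "preset: desk" > run.yaml
spirecon pipeline --config run.yaml
```

The `paper`-scale preset (128×128, M=5000, K=9, C=128) exists but is
guarded behind `--allow-large`; training it is a multi-day job.

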