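# punctakit

Quantification of fluorescent puncta and organelle positioning in
single-cell microscopy, with a synthetic ground-truth scene generator
that makes every stage of the pipeline testable without raw image data.

The package targets the image-analysis workflow of organelle-positioning
studies — lysosome repositioning to the Golgi region, autophagic flux
with tandem reporters, organelle–organelle interactions in time-lapse,
FRAP dynamics of cytoplasmic puncta, and lysosome/Golgi proximity in
electron micrographs. It is intended for cell biologists and image
analysts who need these statistics as reproducible, scriptable code
rather than a chain of GUI plugin steps.

## What it computes

**Perinuclear percentage.** Fluorescence is integrated over `n` = 70
concentric equal-width rings centred on the Golgi, covering 15 µm. With
ring intensities `I_k`,

```
perinuclear % = 100 · Σ_{k<35} I_k / Σ_{k<70} I_k
```

A uniform distribution gives (35/70)² = 25%; a cell is called
"perinuclear" above a configurable threshold (default 50%).

**Autophagic flux (AL/AP ratio).** With a tandem mCherry–GFP reporter
every punctum is red; a green component marks an autophagosome (AP) and
its absence an autolysosome (AL, GFP quenched by the acidic lumen).
Red spots are labelled AP by a green spot within 3 px (greedy
one-to-one, nearest pair first) or a green intensity above threshold at
the red position; the flux readout is `n_AL / n_AP`.

**Interaction events and joint speed.** Puncta are detected per frame
(single-scale Laplacian-of-Gaussian, subpixel quadratic refinement),
linked by greedy nearest-neighbour assignment, and a red/green track
pair interacting means center distance ≤ 3 px for ≥ 3 consecutive
frames (30 s at 10 s/frame). Joint speed is the mean instantaneous
speed of the pair centroid, in µm/min.

**FRAP recovery.** Normalized traces are fitted with
`F(t) = F_inf − (F_inf − F_bleach)·exp(−t/τ)`, reporting τ, half-time
`τ·ln 2` and mobile fraction `(F_inf − F_bleach)/(1 − F_bleach)`.

**EM proximity ratio.** From point/polygon annotations of micrographs:
lysosomes within 1.5 µm of any Golgi stack, divided by the number of
stacks sampled.

**Synthetic scenes.** `punctakit.scenes` builds cells (cytoplasm
annulus, nucleus, Golgi focus) with spread or perinuclearly concentrated
puncta, Brownian and jointly drifting pairs, Poisson + read-noise
rendering through a Gaussian PSF, single-exponential FRAP traces and
EM-style annotations — all with complete ground truth, which is how the
test suite verifies every statistic above.

## Worked example

```python
import punctakit as pk

p = pk.SceneParams(rng_seed=42)                      # 12 µm cell, 0.1 µm/px
rp = pk.RenderParams(psf_sigma=1.5, background=20.0, rng_seed=42)
amp = pk.amplitude_for_snr(5.0, rp)                  # peak SNR 5 spots
scene = pk.make_scene(p, [pk.PunctaPopulation(
    n_spots=200, spatial_mode="perinuclear", decay_length=2.0,
    amplitude_mean=amp)])
img = pk.render(scene, rp)

cfg = pk.RadialConfig(center=p.golgi_center, background_subtract=True)
prof = pk.radial_profile(img, p.pixel_size, cfg, mask=p.cytoplasm_mask())
res = pk.perinuclear_percentage(prof, cfg)
print(f"{res.perinuclear_pct:.1f}% -> {res.classification}")
# 64.3% -> perinuclear

fit = pk.fit_recovery(pk.make_frap_trace(0.1, 0.8, 40.0,
                                         noise_sd=0.02, seed=42))
print(f"tau={fit.tau:.1f}s mobile={fit.mobile_fraction:.2f}")
# tau=38.7s mobile=0.78
```

The rendered cell concentrates 96.5% of its puncta within 7.5 µm of the
Golgi, and the intensity-based ring statistic scores it at 64.3% —
well above both the 25% uniform baseline and the 50% classification
cut, so the cell is called perinuclear. The FRAP fit recovers the
simulated τ = 40 s to within the noise of a single trace.

The same pipeline is available from the shell:

```
punctakit simulate scene --out sim --seed 5
punctakit detect --input sim/scene.tif --out det --seed 5
punctakit perinuclear --input sim/scene.tif --center 177.5 127.5 --out peri --seed 5
```

Each command emits `results.json` with a config hash and seed, from
which the run is bit-exactly reproducible.

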