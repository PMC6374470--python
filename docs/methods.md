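# Methods

This note documents the models, algorithms and design choices behind
punctakit, in the spirit of a methods supplement: what each statistic
assumes, which parameters matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Coordinate and unit conventions

All modules share one convention: x = column, y = row, 0-based,
positions refer to pixel centers. Physical distance = pixel distance ×
`pixel_size` (µm/px); time = frame index × `frame_interval` (s). All
physical outputs are in µm and seconds, except speeds, which are
reported in µm/min — the customary scale for organelle motility. The
calibration is always explicit (argument, YAML config, or the JSON
sidecar written next to every TIFF); a missing pixel size is a hard
error rather than a silent default, because a wrong calibration
corrupts every distance, speed and ring radius downstream.

## Synthetic scenes

The generator emulates a single adherent cell imaged by confocal
microscopy: a disc-shaped cell (default radius 12 µm, a typical
HeLa-scale footprint) with a concentric nucleus (5 µm) and a Golgi
focus at the nuclear rim; the cytoplasm is the annulus between nucleus
and cell boundary. Defaults: 256×256 px at 0.1 µm/px, 10 s frame
interval.

Puncta are point emitters (all structures quantified here —
lysosomes, LC3/p62 puncta, lipid droplets — are near diffraction
limited, so no extended-object rendering is attempted):

- *Spread* populations are uniform over the cytoplasm.
- *Perinuclear* populations draw their Golgi-centred radial distance
  from an exponential of scale `decay_length` (default 2 µm),
  truncated to the reachable radius and rejected to the cytoplasm.
  When the Golgi sits at the cell center the accepted distance is
  exactly a doubly truncated exponential, which gives the closed-form
  quantiles used by the sampling tests.
- Brownian motion uses per-axis steps of sd √(2·D·Δt); steps leaving
  the cytoplasm are rejected and resampled (up to 100 attempts, then
  the spot stays put), which confines trajectories without strongly
  biasing the radial density.
- Interacting red/green pairs share a drift of speed `drift_velocity`
  during their prescribed interval, at a fixed separation of half the
  vicinity; outside the interval the members diffuse independently at
  a separation kept above 1.25× the vicinity by step rejection, and the
  frames adjacent to the interval are placed at 2× the vicinity. This
  guard is what makes the interaction ground truth *exactly*
  recoverable by a brute-force distance scan — the defining property
  the interaction tests rely on — at the cost of slightly
  non-independent motion near the vicinity boundary.

Rendering: each spot contributes amplitude × `photon_scale` photons
through a pixel-integrated isotropic Gaussian PSF (sd `psf_sigma`,
default 1.5 px ≈ 150 nm at the default calibration); pixel values are
Poisson(background + signal) plus Gaussian read noise, clipped to the
bit depth. Noise streams are seeded per (frame, channel), so rendering
is bit-reproducible and order-independent. SNR is defined as expected
peak spot signal over background noise sd; `amplitude_for_snr` inverts
the definition and is how test scenes are pinned at SNR 5.

Not emulated: 3D structure, photobleaching outside FRAP, chromatic
effects, spectral bleed-through, non-circular cell shapes, and
heterogeneous backgrounds. Tests passing on these scenes therefore
establish correctness of the *algorithms* under the stated noise model,
not robustness to every artefact of real acquisitions; in particular
real images need their detection threshold chosen against their own
background noise.

## Spot detection

Single-scale scale-normalized Laplacian of Gaussian (response
`−σ²·∇²G_σ∗I`), local maxima above `response_threshold` with maxima
closer than `min_separation` resolved in favour of the stronger,
subpixel refinement by a 1-D parabolic fit per axis on the 3×3
response neighbourhood (clipped to ±0.5 px). The threshold is in
response units; for the synthetic study conditions (background 20
photons) the noise-floor response sd is ≈1.2, and the default of 5–6
sits at ≈5 noise sd, half the response of an SNR-5 spot. Photometry:
integrated intensity = disc sum (radius `intensity_radius`) minus disc
area × median of the 2–3× radius annulus; the annulus median is robust
to a neighbouring punctum intruding into the background region. Cell
segmentation is deliberately out of scope — analyses accept an optional
mask (from the synthetic truth, or hand-drawn for real data), matching
the practice of quantifying hand-selected single cells.

## Radial perinuclear statistic

70 equal-width rings over 15 µm, Golgi-centred; the inner 35 rings are
perinuclear. The description of the ring partition that this module
follows states 70 circles but 35 inner + 36 outer; 35 + 36 = 71, so
the outer count is treated as an off-by-one and the partition is
35 + 35 of 70, both counts configurable. Pixels are assigned by
center-to-center distance with half-open bins [k·w, (k+1)·w), distance
≥ r_max excluded — the identical rule as the per-pixel brute-force
oracle, which is why the two agree to floating-point rounding rather
than approximately.

The classification threshold (50%) is a design choice: double the 25%
uniform-disc baseline. It is configurable, and on the synthetic study
conditions (200 puncta/cell, decay 2 µm vs spread, SNR 5, cytoplasm
mask, background subtraction) the two populations score ≈65% vs ≈33%,
so classification accuracy is insensitive to the cut anywhere in
roughly 40–60%.

Background subtraction (image median, clipped at zero) defaults to off
for the statistic itself but matters whenever the camera background is
a substantial part of total intensity — on the synthetic scenes it is
enabled, since the flat 20-photon background otherwise dilutes the
ring contrast. A spot-based variant (`radial_profile_from_spots`)
feeds detected puncta instead of raw intensity into the same rings.

## Autophagy flux

Red puncta are classified by a dual criterion: geometric matching of
independently detected green spots (greedy, nearest pair first,
deterministic tie-break by distance then spot index, one-to-one) *or*
measured green intensity at the red position above
`green_intensity_threshold`. The intensity route is the natural one for
a tandem reporter (both emissions come from the same molecule) but
requires a positive threshold — raw images always measure slightly
positive through noise, so a non-positive threshold disables the route
rather than labelling everything AP. On the synthetic flux scenes the
threshold is set at half the expected integrated spot signal, ≈5 noise
sd above zero. Unmatched green-only spots are reported but excluded
from the AL/AP ratio. The per-cell rule for "has autophagosomes" is
≥ `min_ap_puncta_per_cell` (default 3) AP puncta, configurable, with a
monotone threshold sweep available as a sensitivity check.
Colocalization is object-based (fraction of set A with a B neighbour
within radius) because the quantified structures are discrete puncta;
pixel-correlation measures (Pearson/Manders) are out of scope.

## Tracking and interactions

Linking is greedy nearest-neighbour per frame transition (closest pair
first, each spot used once, links longer than `max_displacement`
forbidden, no gap closing) — adequate at the puncta densities of
interest and fully deterministic; LAP/Kalman tracking is a documented
non-goal. An interaction is a maximal run of ≥ `min_frames` consecutive
co-observed frames with center distance ≤ `vicinity` (defaults 3 px,
3 frames = 30 s at the default 10-s interval). "Vicinity" is read as
center-to-center distance, and the duration as consecutive frames — a
single far frame breaks the run. Joint speed is the centroid speed of
the pair during the event (the average of the two members' positions,
differentiated per frame and scaled to µm/min); per-member speeds are
available via `instantaneous_speed`. No correction for chance proximity
is applied; a permutation baseline would be the natural extension.

## FRAP

Traces are normalized to the pre-bleach mean; time is rebased so the
first post-bleach sample is t = 0. The recovery is fitted by bounded
least squares in the parametrization (F_bleach, ΔF = F_inf − F_bleach,
τ), which keeps F_inf ≥ F_bleach structurally; bounds F_bleach ∈ [0,1],
ΔF ∈ [0,1.2], τ ∈ (0, 10·t_max], parameter tolerance 1e-8.
Initialization: F_bleach from the first post-bleach point, F_inf from
the last three, τ from the first half-recovery crossing (t_half/ln 2).
A flat trace (ΔF below 1e-9) is flagged `tau_identifiable=False` with
mobile fraction 0 instead of being fitted; non-convergence returns the
initialization with its residual and `converged=False`. Acquisition
bleaching correction defaults off (simple pre-bleach normalization);
synthetic bleach depths default to F_bleach ≈ 0.1, consistent with
90–95% bleaching protocols.

## EM proximity

Annotations are points (or polygons for extended Golgi areas; interior
distance 0 via shapely). The ratio's denominator is the number of
sampled Golgi stacks, pooled across fields; per-field ratios with
mean ± SEM are also emitted since per-experiment summaries are the
common reporting style. Morphological identification of endo-lysosomes
is the annotator's task — the module consumes coordinates only.

## Problem sizes and numerical choices

The test and acceptance workloads use 256² scenes, 20–200 puncta per
cell, ≤ 12 tracks per channel over ≤ 50 frames, 20-scene flux
replicates, and 100 FRAP replicates — sizes at which every brute-force
oracle (all-pairs distances, all-windows scans, per-pixel ring sums)
is exact and fast, so oracle equivalence can be asserted rather than
sampled. Seeds thread from a single integer through
`numpy.random.default_rng`; all randomized behaviour is reproducible
bit-for-bit.

## Known limitations

Greedy linking fragments tracks at high density or fast motion; the
LoG detector merges puncta closer than `min_separation`; the radial
statistic assumes a meaningful Golgi center supplied by the caller;
the EM ratio performs no stereological correction; and 2D positions
understate 3D distances for thick samples.
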