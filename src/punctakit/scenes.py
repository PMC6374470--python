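"""Synthetic fluorescence-microscopy scenes with known ground truth.

Every quantification stage in this package (spot detection, radial
perinuclear statistics, autophagy-flux classification, tracking and
interaction detection, FRAP fitting, EM proximity ratios) is validated
against scenes generated here: single cells with a circular cytoplasm,
a central nucleus and an off-centre Golgi focus, populated by point-like
puncta that are either spread uniformly through the cytoplasm or
concentrated perinuclearly with an exponential radial density around the
Golgi.  Puncta may diffuse (Brownian motion), and designated red/green
pairs undergo joint drift during a prescribed interaction interval.

Coordinate convention (shared by all modules): x = column, y = row,
0-based, positions refer to pixel centers; physical distance =
pixel distance x pixel_size (um/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .em import EMAnnotation
from .frap import FRAPTrace

CHANNELS = ("red", "green")

_MAX_PLACEMENT_ATTEMPTS = 10_000
_MAX_STEP_ATTEMPTS = 100


# ---------------------------------------------------------------------------
# scene parameters
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Geometry and acquisition parameters of a synthetic cell.

    The cell is a disc of radius ``cell_radius`` (um) centred at
    ``cell_center`` (px, (x, y)); the nucleus is a concentric disc of
    radius ``nucleus_radius``; the cytoplasm is the annulus between them.
    The Golgi focus defaults to the nuclear rim on the +x side.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W) px
    pixel_size: float = 0.1                   # um/px
    n_frames: int = 1
    frame_interval: float = 10.0              # s
    cell_center: Optional[tuple[float, float]] = None   # (x, y) px
    cell_radius: float = 12.0                 # um
    nucleus_radius: float = 5.0               # um
    golgi_center: Optional[tuple[float, float]] = None  # (x, y) px
    golgi_radius: float = 1.5                 # um
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.cell_center is None:
            self.cell_center = ((w - 1) / 2.0, (h - 1) / 2.0)
        if self.golgi_center is None:
            cx, cy = self.cell_center
            self.golgi_center = (cx + self.nucleus_radius / self.pixel_size, cy)
        if not (self.cell_radius > self.nucleus_radius > 0):
            raise ValueError("require cell_radius > nucleus_radius > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        r_px = self.cell_radius / self.pixel_size
        cx, cy = self.cell_center
        if (cx - r_px < -0.5 or cx + r_px > w - 0.5
                or cy - r_px < -0.5 or cy + r_px > h - 0.5):
            raise ValueError("cell does not fit inside the image bounds")

    # geometry helpers -----------------------------------------------------
    def in_cytoplasm(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised point-in-cytoplasm test; ``xy`` is (..., 2) in px."""
        xy = np.asarray(xy, dtype=float)
        d = np.hypot(xy[..., 0] - self.cell_center[0],
                     xy[..., 1] - self.cell_center[1]) * self.pixel_size
        return (d <= self.cell_radius) & (d >= self.nucleus_radius)

    def cytoplasm_mask(self) -> np.ndarray:
        """Boolean pixel mask of the cytoplasm annulus."""
        h, w = self.image_size
        yy, xx = np.mgrid[0:h, 0:w]
        return self.in_cytoplasm(np.stack([xx, yy], axis=-1))


@dataclass
class PunctaPopulation:
    """A population of identical puncta sharing channels and dynamics.

    ``channel_profile`` is one of ``red_only``, ``green_only`` or
    ``red_and_green`` (a tandem-reporter punctum visible in both
    channels).  ``spatial_mode='perinuclear'`` draws the Golgi-centred
    radial distance from an exponential with scale ``decay_length`` (um),
    truncated to the cytoplasm; ``'spread'`` is uniform over the
    cytoplasm.  ``diffusion_coeff`` is the Brownian diffusion constant in
    um^2/s; amplitudes are Gaussian with floor at 10% of the mean.
    """

    n_spots: int = 50
    channel_profile: str = "red_only"
    spatial_mode: str = "spread"
    decay_length: float = 2.0      # um
    diffusion_coeff: float = 0.0   # um^2/s
    amplitude_mean: float = 200.0
    amplitude_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.channel_profile not in ("red_only", "green_only", "red_and_green"):
            raise ValueError(f"unknown channel_profile {self.channel_profile!r}")
        if self.spatial_mode not in ("spread", "perinuclear"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        if self.spatial_mode == "perinuclear" and self.decay_length <= 0:
            raise ValueError("decay_length must be positive in perinuclear mode")
        if not self.label:
            self.label = self.spatial_mode

    @property
    def channels(self) -> tuple[str, ...]:
        return {"red_only": ("red",),
                "green_only": ("green",),
                "red_and_green": ("red", "green")}[self.channel_profile]


@dataclass
class InteractionTruth:
    """Ground truth for one red/green pair undergoing joint drift.

    During frames ``[start_frame, start_frame + duration)`` the pair
    moves with a shared drift of speed ``drift_velocity`` (um/s) and
    stays within ``vicinity_px`` of each other; outside the interval the
    members separate beyond the vicinity and diffuse independently.
    ``pair_ids`` (red spot id, green spot id) is assigned by
    :func:`make_scene`.
    """

    start_frame: int = 0
    duration: int = 3
    drift_velocity: float = 0.05   # um/s
    vicinity_px: float = 3.0
    pair_ids: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1 frame")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")


@dataclass
class RenderParams:
    """Image-formation model: Gaussian PSF, Poisson shot noise, Gaussian
    read noise, clipped to the sensor bit depth.

    Expected photons per pixel = ``background`` + ``photon_scale`` x sum
    over spots of amplitude x (pixel-integrated unit Gaussian of sd
    ``psf_sigma``).  ``shot_noise=False`` returns the noise-free
    expectation (useful for oracle tests).
    """

    psf_sigma: float = 1.5        # px
    background: float = 20.0      # photons
    photon_scale: float = 1.0     # photons per unit amplitude
    read_noise_sd: float = 0.0    # counts
    bit_depth: int = 16
    shot_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class TruthSpot:
    """One ground-truth punctum: channels, population label and its
    full per-frame subpixel trajectory (n_frames, 2) in px (x, y)."""

    spot_id: int
    channels: tuple[str, ...]
    population: int      # population index; -1 for interaction-pair spots
    label: str
    amplitude: float
    positions: np.ndarray


@dataclass
class SceneTruth:
    """Complete ground truth of a synthetic scene — the oracle that
    recovery tests compare against."""

    params: SceneParams
    spots: list[TruthSpot] = field(default_factory=list)
    interactions: list[InteractionTruth] = field(default_factory=list)

    @property
    def channels(self) -> tuple[str, ...]:
        present = {c for s in self.spots for c in s.channels}
        return tuple(c for c in CHANNELS if c in present)

    def spots_in_channel(self, channel: str) -> list[TruthSpot]:
        return [s for s in self.spots if channel in s.channels]

    def positions(self, frame: int, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """(spot ids, (n, 2) array of (x, y) px) for one frame/channel."""
        sel = self.spots_in_channel(channel)
        ids = np.array([s.spot_id for s in sel], dtype=int)
        if not sel:
            return ids, np.zeros((0, 2))
        return ids, np.stack([s.positions[frame] for s in sel])

    def perinuclear_fraction(self, r_inner: float = 7.5, frame: int = 0,
                             channel: Optional[str] = None) -> float:
        """Amplitude-weighted fraction of puncta within ``r_inner`` um of
        the Golgi centre — the ground-truth perinuclear statistic."""
        sel = self.spots if channel is None else self.spots_in_channel(channel)
        if not sel:
            raise ValueError("scene has no spots")
        gx, gy = self.params.golgi_center
        amps = np.array([s.amplitude for s in sel])
        pos = np.stack([s.positions[frame] for s in sel])
        d = np.hypot(pos[:, 0] - gx, pos[:, 1] - gy) * self.params.pixel_size
        return float(amps[d <= r_inner].sum() / amps.sum())

    def to_table(self):
        """Long-format ground-truth table (one row per frame x channel x
        spot), matching the CSV sidecar written next to rendered stacks."""
        import pandas as pd

        rows = []
        for s in self.spots:
            for ch in s.channels:
                for f in range(self.params.n_frames):
                    rows.append((f, ch, s.spot_id, s.positions[f, 0],
                                 s.positions[f, 1], s.amplitude,
                                 s.population, s.label))
        return pd.DataFrame(rows, columns=["frame", "channel", "spot_id",
                                           "x_px", "y_px", "amplitude",
                                           "population", "label"])


# ---------------------------------------------------------------------------
# position sampling
# ---------------------------------------------------------------------------

def _sample_spread(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    r_px = params.cell_radius / params.pixel_size
    cx, cy = params.cell_center
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        xy = rng.uniform(-r_px, r_px, size=2) + (cx, cy)
        if params.in_cytoplasm(xy):
            return xy
    raise RuntimeError("could not place a spot inside the cytoplasm")


def _sample_perinuclear(params: SceneParams, decay_length: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Radial distance from the Golgi centre ~ Exp(decay_length) truncated
    to the farthest cytoplasm point; angle uniform; rejected to the
    cytoplasm annulus."""
    gx, gy = params.golgi_center
    d_gc = math.hypot(gx - params.cell_center[0],
                      gy - params.cell_center[1]) * params.pixel_size
    r_max = d_gc + params.cell_radius  # um; upper bound on reachable radius
    trunc = -math.expm1(-r_max / decay_length)
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        r = -decay_length * math.log1p(-rng.uniform() * trunc)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        xy = np.array([gx + r / params.pixel_size * math.cos(theta),
                       gy + r / params.pixel_size * math.sin(theta)])
        if params.in_cytoplasm(xy):
            return xy
    raise RuntimeError("could not place a perinuclear spot inside the cytoplasm")


def _brownian_walk(start: np.ndarray, n_frames: int, step_sd_px: float,
                   params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Brownian trajectory confined to the cytoplasm by step rejection
    (after 100 failed proposals the spot stays put for that frame)."""
    pos = np.empty((n_frames, 2))
    pos[0] = start
    for f in range(1, n_frames):
        cur = pos[f - 1]
        if step_sd_px == 0.0:
            pos[f] = cur
            continue
        for _ in range(_MAX_STEP_ATTEMPTS):
            prop = cur + rng.normal(0.0, step_sd_px, size=2)
            if params.in_cytoplasm(prop):
                pos[f] = prop
                break
        else:
            pos[f] = cur
    return pos


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _pair_trajectories(tr: InteractionTruth, params: SceneParams,
                       diffusion_coeff: float, rng: np.random.Generator,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Red/green trajectories realising one interaction: joint drift with
    separation vicinity/2 during the interval, separation 2 x vicinity
    (well beyond the criterion) outside it."""
    n = params.n_frames
    s, d = tr.start_frame, tr.duration
    if s + d > n:
        raise ValueError("interaction interval extends past the last frame")
    v_px = tr.drift_velocity * params.frame_interval / params.pixel_size
    step_sd = math.sqrt(2.0 * diffusion_coeff * params.frame_interval) / params.pixel_size
    near = 0.5 * tr.vicinity_px
    far = 2.0 * tr.vicinity_px

    # anchor + drift direction such that the whole drift path stays inside
    for _ in range(_MAX_STEP_ATTEMPTS):
        anchor = _sample_spread(params, rng)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        drift = v_px * np.array([math.cos(phi), math.sin(phi)])
        path = anchor + np.arange(d)[:, None] * drift
        if params.in_cytoplasm(path).all():
            break
    else:
        raise RuntimeError("could not fit the interaction drift path in the cytoplasm")

    red = np.empty((n, 2))
    green = np.empty((n, 2))
    off_phi = rng.uniform(0.0, 2.0 * math.pi)
    near_off = near * np.array([math.cos(off_phi), math.sin(off_phi)])
    red[s:s + d] = path
    green[s:s + d] = path + near_off

    def _offset_dir(base: float) -> np.ndarray:
        a = rng.uniform(0.0, 2.0 * math.pi)
        return base * np.array([math.cos(a), math.sin(a)])

    # frames after the interval: independent Brownian, separation kept > vicinity
    for f in range(s + d, n):
        red[f] = _confined_step(red[f - 1], step_sd, params, rng)
        for _ in range(_MAX_STEP_ATTEMPTS):
            if f == s + d:
                prop = red[f] + _offset_dir(far)
            else:
                prop = _confined_step(green[f - 1], step_sd, params, rng)
            if (params.in_cytoplasm(prop)
                    and np.hypot(*(prop - red[f])) > 1.25 * tr.vicinity_px):
                green[f] = prop
                break
        else:
            green[f] = red[f] + _offset_dir(far)
    # frames before the interval: backward walk, separation kept > vicinity
    for f in range(s - 1, -1, -1):
        red[f] = _confined_step(red[f + 1], step_sd, params, rng)
        for _ in range(_MAX_STEP_ATTEMPTS):
            if f == s - 1:
                prop = red[f] + _offset_dir(far)
            else:
                prop = _confined_step(green[f + 1], step_sd, params, rng)
            if (params.in_cytoplasm(prop)
                    and np.hypot(*(prop - red[f])) > 1.25 * tr.vicinity_px):
                green[f] = prop
                break
        else:
            green[f] = red[f] + _offset_dir(far)
    return red, green


def _confined_step(cur: np.ndarray, step_sd: float, params: SceneParams,
                   rng: np.random.Generator) -> np.ndarray:
    if step_sd == 0.0:
        return cur.copy()
    for _ in range(_MAX_STEP_ATTEMPTS):
        prop = cur + rng.normal(0.0, step_sd, size=2)
        if params.in_cytoplasm(prop):
            return prop
    return cur.copy()


def make_scene(params: SceneParams,
               populations: Sequence[PunctaPopulation],
               interactions: Sequence[InteractionTruth] = (),
               *,
               interaction_diffusion_coeff: float = 0.005,
               interaction_amplitude: float = 200.0,
               no_chance_proximity: Optional[bool] = None,
               ) -> SceneTruth:
    """Build the full ground truth of a synthetic scene.

    Parameters
    ----------
    params
        Cell geometry and acquisition parameters; ``params.rng_seed``
        makes the scene bit-reproducible.
    populations
        Puncta populations (must be non-empty unless interactions are
        given).
    interactions
        Red/green pairs with prescribed joint-drift intervals.  Each pair
        adds one red and one green spot whose ids are written back into
        ``InteractionTruth.pair_ids``.
    interaction_diffusion_coeff
        Brownian diffusion (um^2/s) of pair members outside their
        interaction interval.
    no_chance_proximity
        When true (the default whenever interactions are present), any
        sampled position that would put a non-partner red/green pair
        within 1.25 x vicinity is resampled, so the interaction list is
        exactly recoverable from the positions.
    """
    if not populations and not interactions:
        raise ValueError("populations must be non-empty")
    if no_chance_proximity is None:
        no_chance_proximity = bool(interactions)
    guard_vic = 1.25 * max((tr.vicinity_px for tr in interactions), default=3.0)

    rng = np.random.default_rng(params.rng_seed)
    n = params.n_frames
    scene = SceneTruth(params=params)
    # per-frame occupied positions per channel, for the proximity guard
    occupied = {c: [np.zeros((0, 2)) for _ in range(n)] for c in CHANNELS}

    def _guard_ok(traj: np.ndarray, channels: tuple[str, ...]) -> bool:
        if not no_chance_proximity:
            return True
        for ch in channels:
            other = "green" if ch == "red" else "red"
            for f in range(n):
                occ = occupied[other][f]
                if len(occ) and np.hypot(*(occ - traj[f]).T).min() <= guard_vic:
                    return False
        return True

    def _register(traj: np.ndarray, channels: tuple[str, ...]) -> None:
        for ch in channels:
            for f in range(n):
                occupied[ch][f] = np.vstack([occupied[ch][f], traj[f]])

    next_id = 0
    for ip, pop in enumerate(populations):
        step_sd = (math.sqrt(2.0 * pop.diffusion_coeff * params.frame_interval)
                   / params.pixel_size)
        for _ in range(pop.n_spots):
            for _ in range(_MAX_STEP_ATTEMPTS):
                if pop.spatial_mode == "perinuclear":
                    start = _sample_perinuclear(params, pop.decay_length, rng)
                else:
                    start = _sample_spread(params, rng)
                traj = _brownian_walk(start, n, step_sd, params, rng)
                if _guard_ok(traj, pop.channels):
                    break
            else:
                raise RuntimeError("could not place population spot away from "
                                   "opposite-channel puncta")
            amp = max(float(rng.normal(pop.amplitude_mean, pop.amplitude_sd)),
                      0.1 * pop.amplitude_mean)
            scene.spots.append(TruthSpot(next_id, pop.channels, ip, pop.label,
                                         amp, traj))
            _register(traj, pop.channels)
            next_id += 1

    for tr in interactions:
        for _ in range(_MAX_STEP_ATTEMPTS):
            red, green = _pair_trajectories(tr, params,
                                            interaction_diffusion_coeff, rng)
            if _guard_ok(red, ("red",)) and _guard_ok(green, ("green",)):
                break
        else:
            raise RuntimeError("could not place interaction pair away from "
                               "other puncta")
        rid, gid = next_id, next_id + 1
        next_id += 2
        scene.spots.append(TruthSpot(rid, ("red",), -1, "interaction",
                                     interaction_amplitude, red))
        scene.spots.append(TruthSpot(gid, ("green",), -1, "interaction",
                                     interaction_amplitude, green))
        done = replace(tr, pair_ids=(rid, gid))
        scene.interactions.append(done)
        _register(red, ("red",))
        _register(green, ("green",))

    return scene


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_spot(expected: np.ndarray, x: float, y: float, photons: float,
              sigma: float) -> None:
    """Accumulate a pixel-integrated Gaussian of total ``photons``."""
    h, w = expected.shape
    half = int(math.ceil(5.0 * sigma))
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ex = np.arange(x0, x1 + 1) - 0.5 - x
    ey = np.arange(y0, y1 + 1) - 0.5 - y
    wx = np.diff(ndtr(ex / sigma))
    wy = np.diff(ndtr(ey / sigma))
    expected[y0:y1, x0:x1] += photons * np.outer(wy, wx)


def render(scene: SceneTruth, rp: RenderParams, frame: int = 0,
           channel: str = "red") -> np.ndarray:
    """Render one frame of one channel to a float32 image.

    Pixel values are Poisson(expected photons) plus Gaussian read noise,
    clipped to ``[0, 2**bit_depth - 1]``; with ``shot_noise=False`` and
    zero read noise the noise-free expectation is returned.  Noise is
    drawn from a stream seeded by ``(rp.rng_seed, frame, channel)``, so
    rendering is bit-reproducible and independent of call order.
    """
    if not (0 <= frame < scene.params.n_frames):
        raise IndexError(f"frame {frame} out of range")
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    h, w = scene.params.image_size
    expected = np.full((h, w), float(rp.background))
    for s in scene.spots_in_channel(channel):
        x, y = s.positions[frame]
        _add_spot(expected, x, y, s.amplitude * rp.photon_scale, rp.psf_sigma)

    rng = np.random.default_rng([rp.rng_seed, frame, CHANNELS.index(channel)])
    if rp.shot_noise:
        img = rng.poisson(expected).astype(np.float64)
    else:
        img = expected
    if rp.read_noise_sd > 0:
        img = img + rng.normal(0.0, rp.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 2.0 ** rp.bit_depth - 1).astype(np.float32)


def render_stack(scene: SceneTruth, rp: RenderParams,
                 channels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Render all frames/channels to a (T, C, H, W) float32 array."""
    chans = tuple(channels) if channels is not None else (scene.channels or ("red",))
    h, w = scene.params.image_size
    out = np.empty((scene.params.n_frames, len(chans), h, w), dtype=np.float32)
    for f in range(scene.params.n_frames):
        for c, ch in enumerate(chans):
            out[f, c] = render(scene, rp, f, ch)
    return out


def peak_signal(amplitude: float, rp: RenderParams) -> float:
    """Expected peak pixel value (above background) of a pixel-centred spot."""
    wc = ndtr(0.5 / rp.psf_sigma) - ndtr(-0.5 / rp.psf_sigma)
    return amplitude * rp.photon_scale * wc * wc


def background_noise_sd(rp: RenderParams) -> float:
    shot = rp.background if rp.shot_noise else 0.0
    return math.sqrt(shot + rp.read_noise_sd ** 2)


def amplitude_for_snr(snr: float, rp: RenderParams) -> float:
    """Spot amplitude whose rendered peak is ``snr`` x the background
    noise sd (SNR as used throughout the recovery tests)."""
    noise = background_noise_sd(rp)
    if noise == 0:
        raise ValueError("noise-free render params have no finite SNR amplitude")
    wc = ndtr(0.5 / rp.psf_sigma) - ndtr(-0.5 / rp.psf_sigma)
    return snr * noise / (rp.photon_scale * wc * wc)


# ---------------------------------------------------------------------------
# FRAP traces and EM annotations
# ---------------------------------------------------------------------------

def make_frap_trace(f_bleach: float, f_inf: float, tau: float,
                    t_max: float = 400.0, dt: float = 10.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    n_prebleach: int = 5) -> FRAPTrace:
    """Single-exponential FRAP recovery trace.

    F(t) = f_inf - (f_inf - f_bleach) * exp(-t / tau) for t >= 0 (first
    post-bleach sample at t = 0), preceded by ``n_prebleach`` samples at
    1.0; Gaussian noise of sd ``noise_sd`` on every sample.  The default
    sampling interval of 10 s matches a typical confocal FRAP protocol
    for slowly recovering puncta.
    """
    if not (0.0 <= f_bleach <= f_inf <= 1.2):
        raise ValueError("require 0 <= f_bleach <= f_inf <= 1.2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt <= 0 or t_max < dt:
        raise ValueError("need t_max >= dt > 0")
    rng = np.random.default_rng(seed)
    t_post = np.arange(0.0, t_max + dt / 2, dt)
    t_pre = -dt * np.arange(n_prebleach, 0, -1)
    f_post = f_inf - (f_inf - f_bleach) * np.exp(-t_post / tau)
    f_pre = np.ones_like(t_pre)
    t = np.concatenate([t_pre, t_post])
    f = np.concatenate([f_pre, f_post])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return FRAPTrace(t=t, F=f, n_prebleach=n_prebleach)


def make_em_annotation(n_golgi_stacks: int, lysosomes_per_stack: float,
                       radius_window: float = 1.5, field_size: float = 20.0,
                       seed: int = 0, n_background: int = 0,
                       poisson: bool = True,
                       field_id: str = "synthetic") -> EMAnnotation:
    """EM-style point annotation of Golgi stacks and lysosomes.

    Golgi stacks are uniform over the field (with a margin of
    ``radius_window`` so their windows fit); each stack receives a
    Poisson(``lysosomes_per_stack``) number of lysosomes uniform in its
    window (with ``poisson=False``, exactly ``round(lysosomes_per_stack)``
    — the deterministic construction used by exactness tests), plus
    ``n_background`` lysosomes placed outside every window.  Distances
    are in um.
    """
    if n_golgi_stacks < 0 or lysosomes_per_stack < 0 or n_background < 0:
        raise ValueError("counts and rates must be >= 0")
    rng = np.random.default_rng(seed)
    m = radius_window
    lo, hi = m, max(field_size - m, m)
    stacks = rng.uniform(lo, hi, size=(n_golgi_stacks, 2))
    lysosomes: list[tuple[float, float]] = []
    for sx, sy in stacks:
        k = (rng.poisson(lysosomes_per_stack) if poisson
             else int(round(lysosomes_per_stack)))
        r = radius_window * np.sqrt(rng.uniform(size=k))
        th = rng.uniform(0, 2 * np.pi, size=k)
        lysosomes.extend(zip(sx + r * np.cos(th), sy + r * np.sin(th)))
    placed = 0
    while placed < n_background:
        p = rng.uniform(0.0, field_size, size=2)
        if n_golgi_stacks == 0 or np.hypot(*(stacks - p).T).min() > radius_window:
            lysosomes.append((p[0], p[1]))
            placed += 1
    return EMAnnotation(golgi_stacks=[tuple(s) for s in stacks],
                        lysosomes=lysosomes, field_id=field_id)
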