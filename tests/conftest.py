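"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: event
scanning is a direct loop over all pairs and frames, matching is
exhaustive, and distances are recomputed from raw positions.
"""

from __future__ import annotations

import numpy as np
import pytest

import punctakit as pk


# ---------------------------------------------------------------------------
# oracle: interaction events by exhaustive scan
# ---------------------------------------------------------------------------

def brute_force_events(red_tracks, green_tracks, ic, pixel_size):
    """All maximal vicinity runs >= min_frames, by scanning every pair
    over every frame."""
    events = []
    for rt in red_tracks:
        for gt in green_tracks:
            rpos = dict(zip(rt.frames, zip(rt.xs, rt.ys)))
            gpos = dict(zip(gt.frames, zip(gt.xs, gt.ys)))
            all_frames = sorted(set(rpos) | set(gpos))
            if not all_frames:
                continue
            lo, hi = all_frames[0], all_frames[-1]
            near = {}
            for f in range(lo, hi + 1):
                if f in rpos and f in gpos:
                    dx = rpos[f][0] - gpos[f][0]
                    dy = rpos[f][1] - gpos[f][1]
                    near[f] = float(np.hypot(dx, dy)) <= ic.vicinity
                else:
                    near[f] = False
            f = lo
            while f <= hi:
                if near[f]:
                    start = f
                    while f <= hi and near[f]:
                        f += 1
                    length = f - start
                    if length >= ic.min_frames:
                        frames = list(range(start, start + length))
                        cents = np.array(
                            [((rpos[q][0] + gpos[q][0]) / 2,
                              (rpos[q][1] + gpos[q][1]) / 2) for q in frames])
                        if len(cents) > 1:
                            steps = np.hypot(*np.diff(cents, axis=0).T)
                            speed = float(np.mean(steps) * pixel_size
                                          / ic.frame_interval * 60.0)
                        else:
                            speed = float("nan")
                        events.append((rt.track_id, gt.track_id, start,
                                       length, speed))
                else:
                    f += 1
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return events


def events_as_tuples(events):
    return [(e.red_track_id, e.green_track_id, e.start_frame, e.n_frames,
             e.mean_joint_speed) for e in events]


def random_tracks(rng, n_tracks, n_frames, span=60.0, step=1.5, channel=""):
    """Random-walk tracks with random start frames and lengths."""
    tracks = []
    for tid in range(n_tracks):
        start = int(rng.integers(0, max(n_frames - 1, 1)))
        length = int(rng.integers(2, n_frames - start + 1))
        pos = rng.uniform(0, span, size=2)
        t = pk.Track(track_id=tid, channel=channel)
        for k in range(length):
            pos = pos + rng.normal(0, step, size=2)
            t.frames.append(start + k)
            t.xs.append(float(pos[0]))
            t.ys.append(float(pos[1]))
            t.intensities.append(1.0)
        tracks.append(t)
    return tracks


# ---------------------------------------------------------------------------
# oracle: one-to-one truth/detection matching for recall-precision
# ---------------------------------------------------------------------------

def match_truth(true_xy, det_xy, radius):
    """Greedy one-to-one matching by ascending distance; returns the
    number of matched pairs."""
    pairs = []
    for i, p in enumerate(np.atleast_2d(true_xy)):
        for j, q in enumerate(np.atleast_2d(det_xy)):
            d = float(np.hypot(*(p - q)))
            if d <= radius:
                pairs.append((d, i, j))
    pairs.sort()
    ui, uj = set(), set()
    n = 0
    for _, i, j in pairs:
        if i not in ui and j not in uj:
            ui.add(i)
            uj.add(j)
            n += 1
    return n


# ---------------------------------------------------------------------------
# scene builders (the study conditions used throughout the suite)
# ---------------------------------------------------------------------------

SNR = 5.0


def snr_render_params(seed=0, background=20.0, shot_noise=True):
    return pk.RenderParams(psf_sigma=1.5, background=background,
                           photon_scale=1.0, read_noise_sd=0.0,
                           bit_depth=16, shot_noise=shot_noise, rng_seed=seed)


def snr_amplitude(rp, snr=SNR):
    return pk.amplitude_for_snr(snr, rp)


def tracks_from_truth(scene, noise_px=0.0, rng=None):
    """Ground-truth positions as tracks (optionally with localization
    noise), one track per spot."""
    rng = rng or np.random.default_rng(0)
    out = {"red": [], "green": []}
    n = scene.params.n_frames
    for s in scene.spots:
        pos = s.positions + (rng.normal(0, noise_px, size=s.positions.shape)
                             if noise_px else 0.0)
        for ch in s.channels:
            out[ch].append(pk.Track(
                track_id=s.spot_id, channel=ch, frames=list(range(n)),
                xs=list(pos[:, 0]), ys=list(pos[:, 1]),
                intensities=[s.amplitude] * n))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
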