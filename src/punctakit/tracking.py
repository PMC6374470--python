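"""Frame-to-frame spot linking, speeds, and red/green interaction events.

Tracks are built by greedy nearest-neighbour assignment per frame
transition (closest pair first, deterministic tie-breaking, links longer
than ``max_displacement`` forbidden); unmatched spots open new tracks.
Instantaneous speed is the per-step Euclidean displacement converted to
um/min.  An interaction event between a red and a green track is a
maximal run of >= ``min_frames`` consecutive co-observed frames with
center-to-center distance <= ``vicinity`` px (defaults 3 px / 3 frames,
i.e. 30 s at a 10-s frame interval); its joint speed is the mean
instantaneous speed of the pair centroid over the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import Spot
from .flux import greedy_match


@dataclass
class LinkParams:
    max_displacement: float = 5.0  # px per frame
    allow_gaps: bool = False       # gap closing not implemented

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.allow_gaps:
            raise NotImplementedError("gap closing is not implemented")


@dataclass
class Track:
    track_id: int
    channel: str = ""
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def position(self, frame: int) -> Optional[np.ndarray]:
        try:
            i = self.frames.index(frame)
        except ValueError:
            return None
        return np.array([self.xs[i], self.ys[i]])

    def append(self, spot: Spot) -> None:
        if self.frames and spot.frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(spot.frame)
        self.xs.append(spot.x)
        self.ys.append(spot.y)
        self.intensities.append(spot.integrated_intensity)


@dataclass
class InteractionConfig:
    vicinity: float = 3.0        # px
    min_frames: int = 3
    frame_interval: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.vicinity <= 0:
            raise ValueError("vicinity must be positive")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")


@dataclass
class InteractionEvent:
    red_track_id: int
    green_track_id: int
    start_frame: int
    n_frames: int
    mean_joint_speed: float  # um/min; nan for single-frame events


def link_spots(spots: Sequence[Spot], lp: LinkParams = LinkParams()) -> list[Track]:
    """Link per-frame detections into tracks.

    Greedy nearest-neighbour assignment at each frame transition: all
    candidate links within ``max_displacement`` are taken closest first
    (ties broken by spot order), each spot used once; leftover spots
    start new tracks.  Every spot ends up in exactly one track.
    """
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    if not by_frame:
        return []
    frames = sorted(by_frame)
    tracks: list[Track] = []
    active: list[Track] = []

    def new_track(spot: Spot) -> None:
        t = Track(track_id=len(tracks), channel=spot.channel)
        t.append(spot)
        tracks.append(t)
        active.append(t)

    for s in by_frame[frames[0]]:
        new_track(s)
    for prev_f, cur_f in zip(frames, frames[1:]):
        cur = by_frame[cur_f]
        if cur_f != prev_f + 1 and active:
            active = []  # no gap closing: a missed frame ends every track
        ends = np.array([[t.xs[-1], t.ys[-1]] for t in active]).reshape(-1, 2)
        pos = np.array([[s.x, s.y] for s in cur]).reshape(-1, 2)
        matches = greedy_match(ends, pos, lp.max_displacement)
        matched_spots = set()
        still_active = []
        for it, isp in matches:
            active[it].append(cur[isp])
            matched_spots.add(isp)
            still_active.append(active[it])
        for i, s in enumerate(cur):
            if i not in matched_spots:
                new_track(s)
                still_active.append(tracks[-1])
        active = still_active
    return tracks


def instantaneous_speed(track: Track, pixel_size: float,
                        frame_interval: float) -> np.ndarray:
    """Per-step speeds in um/min (one per consecutive frame pair)."""
    if len(track) < 2:
        raise ValueError("need a track of length >= 2")
    xs, ys, fs = map(np.asarray, (track.xs, track.ys, track.frames))
    disp = np.hypot(np.diff(xs), np.diff(ys)) * pixel_size      # um
    dt = np.diff(fs) * frame_interval                           # s
    return disp / dt * 60.0


def _centroid_speed(red: Track, green: Track, frames: Sequence[int],
                    pixel_size: float, frame_interval: float) -> float:
    cents = np.array([(red.position(f) + green.position(f)) / 2.0
                      for f in frames])
    if len(cents) < 2:
        return float("nan")
    disp = np.hypot(*np.diff(cents, axis=0).T) * pixel_size
    return float(np.mean(disp / frame_interval * 60.0))


def detect_interactions(red_tracks: Sequence[Track],
                        green_tracks: Sequence[Track],
                        ic: InteractionConfig = InteractionConfig(),
                        pixel_size: float = 0.1) -> list[InteractionEvent]:
    """Find all red/green interaction events.

    For every track pair, maximal runs of consecutive co-observed frames
    with distance <= ``ic.vicinity`` are extracted; runs of length >=
    ``ic.min_frames`` become events.  Events are reported in (red id,
    green id, start frame) order.
    """
    events: list[InteractionEvent] = []
    for rt in red_tracks:
        rmap = {f: np.array([x, y]) for f, x, y in zip(rt.frames, rt.xs, rt.ys)}
        for gt in green_tracks:
            run: list[int] = []
            common = sorted(set(rt.frames) & set(gt.frames))
            for f in common + [None]:
                near = False
                if f is not None:
                    d = float(np.hypot(*(rmap[f] - gt.position(f))))
                    near = d <= ic.vicinity
                if near and (not run or f == run[-1] + 1):
                    run.append(f)
                    continue
                if len(run) >= ic.min_frames:
                    events.append(InteractionEvent(
                        red_track_id=rt.track_id,
                        green_track_id=gt.track_id,
                        start_frame=run[0], n_frames=len(run),
                        mean_joint_speed=_centroid_speed(
                            rt, gt, run, pixel_size, ic.frame_interval)))
                run = [f] if near else []
            # trailing run handled by the None sentinel above
    events.sort(key=lambda e: (e.red_track_id, e.green_track_id, e.start_frame))
    return events


def interaction_summary(events: Sequence[InteractionEvent],
                        n_red_tracks: Optional[int] = None) -> dict:
    """Event count and pooled joint-speed statistics for one cell."""
    speeds = np.array([e.mean_joint_speed for e in events
                       if np.isfinite(e.mean_joint_speed)])
    return {
        "n_events": len(events),
        "n_red_tracks": n_red_tracks,
        "mean_joint_speed": float(speeds.mean()) if speeds.size else float("nan"),
        "sd_joint_speed": (float(speeds.std(ddof=1)) if speeds.size > 1
                           else float("nan")),
        "speed_defined": bool(speeds.size),
    }
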