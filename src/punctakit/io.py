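"""Image and table I/O, configuration, and run metadata.

Images are plain grayscale multi-page TIFFs (8- or 16-bit), one page per
frame per channel in channel-major order, with the physical calibration
(um/px, s/frame) always supplied explicitly — via arguments, a YAML
config, or the JSON sidecar written next to every rendered stack.  There
is deliberately no silent default pixel size: a wrong calibration
corrupts every downstream distance and speed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__version__ = "0.1.0"

SPOT_COLUMNS = ["frame", "channel", "spot_id", "x", "y", "response", "intensity"]
TRACK_COLUMNS = ["track_id", "channel", "frame", "x", "y", "intensity"]
EVENT_COLUMNS = ["red_track_id", "green_track_id", "start_frame", "n_frames",
                 "mean_joint_speed_um_min"]


@dataclass
class ImageStack:
    """Calibrated multi-channel image stack, pixels indexed
    [frame][channel][row][col]."""

    pixels: np.ndarray
    pixel_size: float        # um/px
    frame_interval: float = 1.0  # s
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (T, C, H, W)")
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size (um/px) must be given and positive")
        if self.pixels.shape[0] > 1 and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive for time-lapse")
        if not self.channel_names:
            self.channel_names = [f"ch{c}" for c in range(self.pixels.shape[1])]
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("one name per channel required")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    def frame(self, f: int, channel) -> np.ndarray:
        c = (self.channel_names.index(channel) if isinstance(channel, str)
             else int(channel))
        return self.pixels[f, c]


def read_stack(path, pixel_size: Optional[float] = None,
               frame_interval: Optional[float] = None,
               n_channels: int = 1,
               channel_layout: str = "channel-major",
               channel_names: Optional[Sequence[str]] = None) -> ImageStack:
    """Read a grayscale multi-page TIFF into a calibrated stack.

    ``channel_layout`` declares the page order: ``channel-major`` (all
    frames of channel 0, then channel 1, ...) or ``frame-major`` (all
    channels of frame 0, then frame 1, ...).  Calibration missing from
    both the arguments and a ``<path>.json`` sidecar is a hard error.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    frame_interval = (frame_interval if frame_interval is not None
                      else meta.get("frame_interval", 1.0))
    n_channels = meta.get("n_channels", n_channels)
    channel_names = channel_names or meta.get("channel_names")
    if pixel_size is None:
        raise ValueError(f"no pixel_size for {path}: pass it explicitly or "
                         "provide a JSON sidecar")

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth {pages.dtype}; expected 8- or "
                         "16-bit grayscale")
    n_pages = pages.shape[0]
    if n_pages % n_channels:
        raise ValueError(f"{n_pages} pages not divisible by {n_channels} channels")
    n_frames = n_pages // n_channels
    if channel_layout == "channel-major":
        arr = pages.reshape(n_channels, n_frames, *pages.shape[1:])
        arr = np.swapaxes(arr, 0, 1)
    elif channel_layout == "frame-major":
        arr = pages.reshape(n_frames, n_channels, *pages.shape[1:])
    else:
        raise ValueError(f"unknown channel_layout {channel_layout!r}")
    return ImageStack(pixels=arr.copy(), pixel_size=float(pixel_size),
                      frame_interval=float(frame_interval),
                      channel_names=list(channel_names) if channel_names else [])


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a channel-major multi-page TIFF plus a JSON
    calibration sidecar; float pixel data is rounded to uint16."""
    path = Path(path)
    arr = stack.pixels
    if arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    pages = np.swapaxes(arr, 0, 1).reshape(-1, *arr.shape[2:])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "n_channels": stack.n_channels,
        "channel_names": stack.channel_names,
        "channel_layout": "channel-major",
    }, indent=2))
    return path


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def spots_to_frame(spots) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.frame, s.channel, s.spot_id, s.x, s.y, s.response,
          s.integrated_intensity) for s in spots],
        columns=SPOT_COLUMNS)


def spots_from_frame(df: pd.DataFrame):
    from .detection import Spot

    return [Spot(x=r.x, y=r.y, frame=int(r.frame), channel=str(r.channel),
                 response=float(r.response), integrated_intensity=float(r.intensity),
                 spot_id=int(r.spot_id))
            for r in df.itertuples()]


def tracks_to_frame(tracks) -> pd.DataFrame:
    rows = [(t.track_id, t.channel, f, x, y, i)
            for t in tracks
            for f, x, y, i in zip(t.frames, t.xs, t.ys, t.intensities)]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def tracks_from_frame(df: pd.DataFrame):
    from .tracking import Track

    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(track_id=int(tid),
                            channel=str(g.channel.iloc[0]),
                            frames=[int(f) for f in g.frame],
                            xs=list(g.x), ys=list(g.y),
                            intensities=list(g.intensity)))
    return tracks


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.red_track_id, e.green_track_id, e.start_frame, e.n_frames,
          e.mean_joint_speed) for e in events],
        columns=EVENT_COLUMNS)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(outdir, tables: Optional[dict] = None,
                  scalars: Optional[dict] = None,
                  config: Optional[dict] = None,
                  seed: Optional[int] = None) -> Path:
    """Write result tables as CSV and scalars as JSON under ``outdir``.

    The JSON embeds run metadata — config hash, seed and package version
    — so any run is reproducible from its emitted outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (tables or {}).items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    payload = {
        "results": _jsonable(scalars or {}),
        "metadata": {
            "version": __version__,
            "seed": seed,
            "config": _jsonable(config or {}),
            "config_hash": config_hash(config or {}),
        },
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_config(path) -> dict:
    """Load a YAML analysis config (parameter blocks keyed by stage)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of parameter blocks")
    return cfg
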