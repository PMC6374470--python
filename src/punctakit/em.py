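"""Lysosome-to-Golgi proximity from EM point/region annotations.

Electron micrographs are annotated by hand: each sampled field carries
the positions of Golgi stacks (points, or polygon outlines of the Golgi
area) and of endo-lysosomal structures (points).  The statistic of
interest is the number of lysosomes lying within a fixed window
(default 1.5 um) of any Golgi stack, divided by the number of Golgi
stacks sampled — a dimensionless lysosomes-per-stack ratio.  All
coordinates are in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

Point = tuple[float, float]
GolgiRegion = Union[Point, Sequence[Point]]  # point, or polygon vertex list


@dataclass
class EMConfig:
    window_radius: float = 1.5  # um

    def __post_init__(self) -> None:
        if self.window_radius <= 0:
            raise ValueError("window_radius must be positive")


@dataclass
class EMAnnotation:
    """One annotated EM field: Golgi stacks (points or polygons) and
    lysosome points, um coordinates."""

    golgi_stacks: list = field(default_factory=list)
    lysosomes: list = field(default_factory=list)
    field_id: str = ""

    def __post_init__(self) -> None:
        for g in self.golgi_stacks:
            arr = np.asarray(g, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite Golgi coordinates")
        if self.lysosomes:
            arr = np.asarray(self.lysosomes, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
                raise ValueError("lysosomes must be finite (x, y) points")


def _is_point(g) -> bool:
    arr = np.asarray(g, dtype=float)
    return arr.shape == (2,)


def _distance_to_stack(points: np.ndarray, g) -> np.ndarray:
    """Distance of each point to one Golgi stack; polygon interiors count
    as distance 0."""
    if _is_point(g):
        gx, gy = np.asarray(g, dtype=float)
        return np.hypot(points[:, 0] - gx, points[:, 1] - gy)
    from shapely.geometry import Point as ShPoint, Polygon

    poly = Polygon(np.asarray(g, dtype=float))
    return np.array([poly.distance(ShPoint(p)) for p in points])


def lysosomes_near_golgi(ann: EMAnnotation, cfg: EMConfig = EMConfig()) -> int:
    """Number of lysosomes within ``cfg.window_radius`` of the nearest
    Golgi stack (each lysosome counted once)."""
    if not ann.golgi_stacks:
        raise ValueError(f"field {ann.field_id!r} has no Golgi stacks")
    if not ann.lysosomes:
        return 0
    pts = np.asarray(ann.lysosomes, dtype=float)
    dmin = np.min([_distance_to_stack(pts, g) for g in ann.golgi_stacks], axis=0)
    return int(np.count_nonzero(dmin <= cfg.window_radius))


def lysosome_golgi_ratio(annotations: Sequence[EMAnnotation],
                         cfg: EMConfig = EMConfig()) -> dict:
    """Pooled lysosome/Golgi-stack ratio over the sampled fields.

    Returns the pooled ratio (total in-window lysosomes / total stacks)
    together with per-field ratios and their mean +/- SEM, since studies
    commonly report the statistic per experiment.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    counts = [lysosomes_near_golgi(a, cfg) for a in annotations]
    stacks = [len(a.golgi_stacks) for a in annotations]
    per_field = [c / s for c, s in zip(counts, stacks)]
    n = len(per_field)
    sem = float(np.std(per_field, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "ratio": float(sum(counts) / sum(stacks)),
        "n_lysosomes_in_window": int(sum(counts)),
        "n_golgi_stacks": int(sum(stacks)),
        "per_field_ratios": per_field,
        "per_field_mean": float(np.mean(per_field)),
        "per_field_sem": sem,
    }
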