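"""Tandem-reporter autophagy flux and object-based colocalization.

With a tandem mCherry-GFP-LC3 (or p62) reporter, every punctum is red
(mCherry is pH-insensitive); autophagosomes (AP) additionally show green
GFP fluorescence, while autolysosomes (AL) have lost it to the acidic
lumen.  Red puncta are therefore classified AP when they carry a green
component — either a detected green spot within a matching radius
(greedy one-to-one, nearest pair first) or a green-channel intensity at
the red position above a threshold — and AL otherwise.  The AL/AP count
ratio is the flux readout; object-based colocalization generalises the
same distance criterion to arbitrary spot sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detection import Spot, measure_intensity

AP = "AP"
AL = "AL"


@dataclass
class MatchParams:
    match_radius: float = 3.0            # px
    green_intensity_threshold: float = 0.0  # counts; used with a green image
    min_ap_puncta_per_cell: int = 3

    def __post_init__(self) -> None:
        if self.match_radius <= 0:
            raise ValueError("match_radius must be positive")


@dataclass
class FluxResult:
    n_AP: int
    n_AL: int
    n_green_unmatched: int = 0

    @property
    def n_red(self) -> int:
        return self.n_AP + self.n_AL


def greedy_match(pos_a: np.ndarray, pos_b: np.ndarray,
                 radius: float) -> list[tuple[int, int]]:
    """One-to-one greedy matching, nearest pair first.

    Candidate pairs within ``radius`` are taken in order of (distance,
    index a, index b) — the index tie-break makes the result independent
    of input ordering — and each point is used at most once.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    tree = cKDTree(pos_b)
    pairs = []
    for ia, p in enumerate(pos_a):
        for ib in tree.query_ball_point(p, radius):
            d = float(np.hypot(*(p - pos_b[ib])))
            pairs.append((d, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        out.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    return out


def classify_puncta(red_spots: Sequence[Spot], green_spots: Sequence[Spot],
                    mp: MatchParams = MatchParams(),
                    green_image: Optional[np.ndarray] = None,
                    intensity_radius: float = 4.0,
                    ) -> tuple[list[str], FluxResult]:
    """Label each red spot AP or AL.

    A red spot is AP when a green spot lies within ``mp.match_radius``
    (greedy one-to-one, nearest pair first) or, when ``green_image`` is
    given and ``mp.green_intensity_threshold`` is positive, when its
    measured green intensity at the red position exceeds the threshold
    (a non-positive threshold disables the intensity route — raw images
    always measure slightly positive through noise).  Green spots left
    unmatched are counted separately and excluded from the flux ratio.
    """
    frames = {s.frame for s in red_spots} | {s.frame for s in green_spots}
    if len(frames) > 1:
        raise ValueError("classify_puncta expects spots from a single frame")
    labels = [AL] * len(red_spots)
    pos_r = np.array([[s.x, s.y] for s in red_spots]).reshape(-1, 2)
    pos_g = np.array([[s.x, s.y] for s in green_spots]).reshape(-1, 2)
    matches = greedy_match(pos_r, pos_g, mp.match_radius)
    matched_g = {ib for _, ib in matches}
    for ia, _ in matches:
        labels[ia] = AP
    if green_image is not None and mp.green_intensity_threshold > 0:
        for i, s in enumerate(red_spots):
            if labels[i] == AL:
                g = measure_intensity(green_image, s.x, s.y, intensity_radius)
                if g > mp.green_intensity_threshold:
                    labels[i] = AP
    n_ap = labels.count(AP)
    res = FluxResult(n_AP=n_ap, n_AL=len(labels) - n_ap,
                     n_green_unmatched=len(green_spots) - len(matched_g))
    return labels, res


def al_ap_ratio(flux: FluxResult) -> float:
    """Autolysosome/autophagosome count ratio (requires n_AP > 0)."""
    if flux.n_AP <= 0:
        raise ValueError("AL/AP ratio undefined with no autophagosomes")
    return flux.n_AL / flux.n_AP


def pct_cells_with_autophagosomes(cells: Sequence[FluxResult],
                                  mp: MatchParams = MatchParams()) -> float:
    """Percentage of cells with at least ``min_ap_puncta_per_cell`` AP
    puncta."""
    if not cells:
        raise ValueError("no cells")
    n_pos = sum(c.n_AP >= mp.min_ap_puncta_per_cell for c in cells)
    return 100.0 * n_pos / len(cells)


def object_colocalization(spots_a: Sequence[Spot], spots_b: Sequence[Spot],
                          radius: float) -> float:
    """Fraction of ``spots_a`` with at least one ``spots_b`` neighbour
    within ``radius`` px (object-based colocalization)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not spots_a:
        raise ValueError("spots_a is empty")
    if not spots_b:
        return 0.0
    pos_a = np.array([[s.x, s.y] for s in spots_a])
    tree = cKDTree(np.array([[s.x, s.y] for s in spots_b]))
    d, _ = tree.query(pos_a, k=1)
    return float(np.count_nonzero(d <= radius) / len(spots_a))
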