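"""Morphometric, Sholl and topological analysis of dendritic trees.

The topological descriptor is the persistence barcode of the radial-
distance filtration: each bar is the (birth, death) radial span of one
dendritic component, merged by the elder rule at branch points, so the
number of bars equals the number of terminal tips.  Barcodes are
compared through Gaussian-kernel persistence images with a normalized
total-variation distance, which is guaranteed to lie in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import anderson_ksamp

from .cell.morphology import Morphology

__all__ = [
    "ShollProfile",
    "PersistenceBarcode",
    "PersistenceImage",
    "sholl",
    "persistence_barcode",
    "persistence_image",
    "persistence_image_distance",
    "sholl_compare",
    "morphometrics",
]


@dataclass
class ShollProfile:
    """Intersection counts on concentric spheres around the soma."""

    radii: np.ndarray  # ring radii [um], fixed step
    counts: np.ndarray

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def max_count(self) -> int:
        return int(np.max(self.counts)) if len(self.counts) else 0

    @property
    def argmax_radius(self) -> float:
        return float(self.radii[int(np.argmax(self.counts))])


@dataclass
class PersistenceBarcode:
    """Bars (birth, death) in radial distance [um]; one per tree component."""

    bars: List[Tuple[float, float]]

    def __len__(self):
        return len(self.bars)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bars, dtype=float).reshape(-1, 2)


@dataclass
class PersistenceImage:
    """Unit-mass Gaussian density of the persistence diagram on a grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        total = float(np.sum(self.density))
        if total > 0:
            self.density = self.density / total


def _soma_center(morph: Morphology) -> np.ndarray:
    return np.mean(morph.soma.points, axis=0)


def sholl(morph: Morphology, step: float = 10.0) -> ShollProfile:
    """Sholl analysis: dendritic crossings of spheres every ``step`` um.

    A crossing is a 3D sample segment whose endpoints straddle the
    sphere (Euclidean radial distance from the soma center).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    center = _soma_center(morph)
    rmax = 0.0
    seg_r = []  # (r_in, r_out) per sample segment
    for i in morph.sections_of("dend"):
        pts = morph.sections[i].points
        r = np.linalg.norm(pts - center, axis=1)
        if len(r) >= 2:
            seg_r.append(np.column_stack([np.minimum(r[:-1], r[1:]),
                                          np.maximum(r[:-1], r[1:])]))
            rmax = max(rmax, float(np.max(r)))
    nr = max(1, int(np.ceil(rmax / step)))
    radii = step * np.arange(1, nr + 1)
    counts = np.zeros(nr, dtype=int)
    if seg_r:
        segs = np.vstack(seg_r)
        for k, ring in enumerate(radii):
            counts[k] = int(np.sum((segs[:, 0] < ring) & (segs[:, 1] >= ring)))
    return ShollProfile(radii, counts)


def persistence_barcode(morph: Morphology) -> PersistenceBarcode:
    """Radial-distance persistence barcode of the dendritic tree.

    Elder-rule merging: leaves are processed by descending radial
    distance; at each branch point the younger component dies, the
    older persists; the root component spans [max leaf distance, 0].
    """
    center = _soma_center(morph)
    # Build the dendrite tree on section endpoints
    dend = morph.sections_of("dend")
    children: Dict[int, List[int]] = {i: [] for i in dend}
    roots = []
    for i in dend:
        par = morph.sections[i].parent
        if par in children:
            children[par].append(i)
        else:
            roots.append(i)

    bars: List[Tuple[float, float]] = []

    def tip_radius(i: int) -> float:
        pts = morph.sections[i].points
        return float(np.linalg.norm(pts[-1] - center))

    def base_radius(i: int) -> float:
        pts = morph.sections[i].points
        return float(np.linalg.norm(pts[0] - center))

    def process(i: int) -> float:
        """Return the birth (max leaf radius) of the component surviving
        through section i; emit death bars for the younger components."""
        kids = children[i]
        if not kids:
            return tip_radius(i)
        births = [process(k) for k in kids]
        order = np.argsort(births)[::-1]
        eldest = births[int(order[0])]
        death_r = tip_radius(i)  # branch point = distal end of this section
        for j in order[1:]:
            bars.append((births[int(j)], death_r))
        return eldest

    for r in roots:
        birth = process(r)
        bars.append((birth, 0.0))
    return PersistenceBarcode(bars)


def persistence_image(barcode: PersistenceBarcode, grid: int = 100,
                      bounds: Optional[Tuple[float, float]] = None,
                      bandwidth: Optional[float] = None) -> PersistenceImage:
    """Gaussian-kernel persistence image of a barcode.

    Grid 100x100 over the (birth, death) bounding box padded 10%;
    bandwidth defaults to 5% of the maximum radial extent; the image is
    normalized to unit mass.
    """
    arr = barcode.as_array()
    if bounds is None:
        hi = float(arr.max()) if len(arr) else 1.0
        lo = 0.0
        pad = 0.1 * (hi - lo + 1e-9)
        bounds = (lo - pad, hi + pad)
    if bandwidth is None:
        bandwidth = 0.05 * max(abs(bounds[1]), 1e-9)
    gx = np.linspace(bounds[0], bounds[1], grid)
    gy = np.linspace(bounds[0], bounds[1], grid)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    dens = np.zeros((grid, grid))
    inv2s2 = 1.0 / (2.0 * bandwidth * bandwidth)
    for b, d in arr:
        dens += np.exp(-((X - b) ** 2 + (Y - d) ** 2) * inv2s2)
    return PersistenceImage(gx, gy, dens)


def persistence_image_distance(a: PersistenceImage, b: PersistenceImage) -> float:
    """Normalized total-variation distance 0.5 * sum|A - B| in [0, 1].

    Requires both images on a common grid (each unit-normalized).
    """
    if a.density.shape != b.density.shape:
        raise ValueError("images must share one grid")
    return float(0.5 * np.sum(np.abs(a.density - b.density)))


def sholl_compare(profiles: Sequence[ShollProfile]):
    """Pairwise k-sample Anderson-Darling p-values on intersection counts.

    Returns a symmetric matrix with NaN on the diagonal (a profile is
    not tested against itself); p-values are not corrected for multiple
    comparisons and are capped to the tabulated range [0.001, 0.25].
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least two profiles")
    pmat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            a = profiles[i].counts.astype(float)
            b = profiles[j].counts.astype(float)
            if np.array_equal(a, b):
                p = 0.25
            else:
                with np.errstate(all="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = anderson_ksamp([a, b])
                p = float(np.clip(res.significance_level, 0.001, 0.25))
            pmat[i, j] = pmat[j, i] = p
    return pmat


@dataclass
class Morphometrics:
    max_radial_extent: float
    first_branch_distance: float
    n_trunks: int
    n_sections: int
    n_leaves: int
    total_length: float


def morphometrics(morph: Morphology) -> Morphometrics:
    """Basic per-neuron morphometrics of the dendritic arbor."""
    center = _soma_center(morph)
    dend = morph.sections_of("dend")
    children: Dict[int, int] = {i: 0 for i in dend}
    trunks = 0
    first_branch = np.inf
    rmax = 0.0
    total_len = 0.0
    for i in dend:
        sec = morph.sections[i]
        if sec.parent == 0:
            trunks += 1
        if sec.parent in children:
            children[sec.parent] += 1
        r = np.linalg.norm(sec.points - center, axis=1)
        rmax = max(rmax, float(np.max(r)))
        total_len += sec.length
    for i in dend:
        if children[i] >= 2:
            d = float(np.linalg.norm(morph.sections[i].points[-1] - center))
            first_branch = min(first_branch, d)
    leaves = sum(1 for i in dend if children[i] == 0)
    if not dend:
        first_branch = 0.0
    elif not np.isfinite(first_branch):
        first_branch = rmax
    return Morphometrics(rmax, first_branch, trunks, len(dend), leaves, total_len)
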