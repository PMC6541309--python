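"""Synthetic thalamocortical-like morphologies.

Random binary-branching dendritic trees calibrated to the measured
anatomy of ventrobasal relay cells: 3-7 principal trunks radiating from
the soma, maximum radial extent 120-200 um, first branch point 20-50 um
from the soma, and a dense proximal arbor whose Sholl profile peaks at
50-100 intersections between 50 and 80 um.  Diameters taper with
radial distance.  Trees are generated as section lists and can be
written to SWC.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ..cell.morphology import Morphology, Section

__all__ = ["MorphologyParams", "make_morphology", "make_morphologies"]


@dataclass
class MorphologyParams:
    """Generator defaults: the measured anatomical ranges."""

    # sampling ranges are kept ~2 um inside the anatomical bounds so the
    # discrete growth steps cannot overshoot them
    extent_range: tuple = (122.0, 198.0)  # um, max radial extent
    first_branch_range: tuple = (21.0, 47.5)  # um
    n_trunks_range: tuple = (3, 7)
    target_tips_range: tuple = (58.0, 92.0)  # total terminal tips per tree
    branch_zone_span_range: tuple = (28.0, 38.0)  # um of branching beyond first branch
    branch_zone_cap: float = 76.0  # um, branching never continues past this radius
    tip_radius_min_frac: float = 0.62  # tips end between this fraction and 1.0 of extent
    soma_radius_range: tuple = (7.0, 10.0)  # um
    trunk_diam: float = 2.8  # um
    tip_diam: float = 0.6  # um
    axon_length: float = 50.0  # um (truncated axon, as in reconstructions)
    point_spacing: float = 8.0  # um between 3D samples


def _unit(v):
    return v / np.linalg.norm(v)


def _jitter_direction(rng, d, angle_sd):
    """Rotate direction d by a random small angle (radians, sd given)."""
    perp = rng.standard_normal(3)
    perp -= perp @ d * d
    n = np.linalg.norm(perp)
    if n < 1e-9:
        return d
    perp /= n
    ang = abs(rng.normal(0.0, angle_sd))
    return _unit(np.cos(ang) * d + np.sin(ang) * perp)


def make_morphology(seed: int = 0, params: Optional[MorphologyParams] = None,
                    name: str = "") -> Morphology:
    """Generate one synthetic TC-like morphology (deterministic per seed)."""
    p = params or MorphologyParams()
    rng = np.random.default_rng(seed)
    extent = rng.uniform(*p.extent_range)
    first_branch = rng.uniform(*p.first_branch_range)
    n_trunks = int(rng.integers(p.n_trunks_range[0], p.n_trunks_range[1] + 1))
    soma_r = rng.uniform(*p.soma_radius_range)
    # branching must finish well before the earliest possible tip so the
    # Sholl profile peaks (at the tip count) inside the dense zone
    branch_end = min(
        first_branch + rng.uniform(*p.branch_zone_span_range),
        p.branch_zone_cap,
        p.tip_radius_min_frac * extent - 12.0,
    )
    # per-trunk branching depth targeting the total tip count
    target_tips = rng.uniform(*p.target_tips_range)
    base_level = max(1, int(np.floor(np.log2(target_tips / n_trunks))))
    extra = target_tips - n_trunks * 2**base_level
    n_upgraded = int(np.clip(round(extra / 2**base_level), 0, n_trunks))
    trunk_levels = [base_level + 1 if i < n_upgraded else base_level
                    for i in range(n_trunks)]
    rng.shuffle(trunk_levels)

    def diam_at(r):
        f = np.clip(r / extent, 0.0, 1.0)
        return p.trunk_diam + (p.tip_diam - p.trunk_diam) * f

    sections: List[Section] = [
        Section("soma", np.zeros((1, 3)), np.array([2.0 * soma_r]))
    ]
    # guarantee the max radial extent is realized by one marked path
    carry_extent = {0}

    def grow(start, direction, parent_idx, next_branch_r, levels_left, tip_tag):
        """Grow one branch segment; recurse at branch points."""
        r0 = np.linalg.norm(start)
        if levels_left > 0:
            target_r = min(next_branch_r, branch_end)
            target_r = max(target_r, r0 + 1.0)
            terminal = False
        else:
            tip_r = extent if tip_tag else rng.uniform(
                p.tip_radius_min_frac * extent, extent)
            target_r = max(tip_r, r0 + 5.0)
            terminal = True
        # advance along direction until radial distance reaches target
        pts = [start]
        pos = start.copy()
        d = direction
        guard = 0
        while np.linalg.norm(pos) < target_r and guard < 200:
            d = _jitter_direction(rng, d, 0.12)
            # bias outward so radial distance grows monotonically
            d = _unit(0.7 * d + 0.3 * _unit(pos if np.linalg.norm(pos) > 1e-6 else d))
            pos = pos + d * min(p.point_spacing, target_r - np.linalg.norm(pos) + 1.0)
            pts.append(pos.copy())
            guard += 1
        pts = np.array(pts)
        radii = np.linalg.norm(pts, axis=1)
        diams = diam_at(radii)
        sections.append(Section("dend", pts, diams, parent=parent_idx))
        idx = len(sections) - 1
        if not terminal:
            spread = rng.uniform(0.35, 0.55)
            r_here = np.linalg.norm(pos)
            step_r = max((branch_end - r_here) / max(levels_left, 1), 1.5)
            nb = r_here + step_r
            for k, sgn in enumerate((1.0, -1.0)):
                child_dir = _jitter_direction(rng, d, spread)
                child_dir = _unit(d + sgn * spread * (child_dir - d * (child_dir @ d)))
                grow(pos.copy(), child_dir, idx, nb, levels_left - 1,
                     tip_tag and k == 0)
        return idx

    for ti in range(n_trunks):
        # trunk directions roughly evenly distributed on the sphere
        z = rng.uniform(-1, 1)
        phi = rng.uniform(0, 2 * np.pi)
        d0 = np.array([np.sqrt(1 - z * z) * np.cos(phi),
                       np.sqrt(1 - z * z) * np.sin(phi), z])
        start = d0 * soma_r
        grow(start, d0, 0, first_branch, trunk_levels[ti], ti in carry_extent)

    # truncated axon stub (replaced by a standard stub at model build)
    ax0 = np.array([0.0, 0.0, -soma_r])
    ax1 = np.array([0.0, 0.0, -soma_r - p.axon_length])
    sections.append(Section("axon", np.vstack([ax0, ax1]),
                            np.array([1.2, 1.0]), parent=0))
    return Morphology(sections, name=name or f"synthTC_{seed}")


def make_morphologies(n: int, seed: int = 0,
                      params: Optional[MorphologyParams] = None) -> List[Morphology]:
    """Generate ``n`` synthetic morphologies with per-tree derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [make_morphology(int(s), params=params, name=f"synthTC_{seed}_{i}")
            for i, s in enumerate(seeds)]
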