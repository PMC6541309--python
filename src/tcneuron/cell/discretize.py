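"""Spatial discretization of a morphology into iso-potential compartments.

Each section is split into ``ceil(L / seg_len)`` equal-length
compartments (default segment length 40 um).  Membrane areas come from
truncated-cone frusta of the 3D sample points, axial resistances from
the integral of ``Ra / (pi r^2)`` along the same frusta, so total
membrane area is conserved exactly under re-discretization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from ..constants import UM2_TO_CM2
from .morphology import Morphology

__all__ = ["CompartmentGraph", "discretize"]

REGION_INDEX = {"soma": 0, "dend": 1, "axon": 2}


@dataclass
class CompartmentGraph:
    """Flat compartment tree (soma root at index 0, parent < child).

    ``gax`` [uS] is the axial conductance linking each compartment to
    its parent (0 for the root).  Areas are in cm^2.
    """

    parent: np.ndarray  # int, -1 for root
    area: np.ndarray  # cm^2
    length: np.ndarray  # um
    region: np.ndarray  # int codes per REGION_INDEX
    gax: np.ndarray  # uS
    section_of: np.ndarray  # morphology section index per compartment
    seg_len: float = 40.0
    comps_of_section: Dict[int, List[int]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def total_area(self) -> float:
        return float(np.sum(self.area))


def _frusta_profile(points: np.ndarray, diams: np.ndarray):
    """Cumulative arclength, radii at samples."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return arc, diams / 2.0


def _integrate(arc, radii, ra, s0, s1):
    """Membrane area [um^2] and axial resistance [MOhm] of the slice [s0, s1].

    Piecewise-linear radius profile; the axial integral over a frustum
    with radii r0->r1 is Ra * L / (pi r0 r1).
    """
    area = 0.0
    res = 0.0
    for i in range(len(arc) - 1):
        a, b = arc[i], arc[i + 1]
        lo, hi = max(a, s0), min(b, s1)
        if hi <= lo or b == a:
            continue
        t0 = (lo - a) / (b - a)
        t1 = (hi - a) / (b - a)
        r0 = radii[i] + (radii[i + 1] - radii[i]) * t0
        r1 = radii[i] + (radii[i + 1] - radii[i]) * t1
        dl = hi - lo
        # frustum lateral area with slant correction
        dr = r1 - r0
        area += math.pi * (r0 + r1) * math.sqrt(dl * dl + dr * dr)
        # axial resistance: Ra[Ohm cm] * L[um] / (pi r0 r1 [um^2]) * 1e-2 -> MOhm
        res += ra * dl / (math.pi * max(r0 * r1, 1e-12)) * 1e-2
    return area, res


def discretize(morph: Morphology, seg_len: float = 40.0, ra: float = 100.0) -> CompartmentGraph:
    """Build the compartment graph for a morphology.

    ``ra`` is the axial resistivity [Ohm cm].  The soma is always a
    single compartment; a spherical (single-sample) soma gets area
    4 pi r^2 and an equivalent-cylinder axial half-resistance.
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be > 0")
    parent: List[int] = []
    area: List[float] = []
    length: List[float] = []
    region: List[int] = []
    gax: List[float] = []
    section_of: List[int] = []
    comps_of_section: Dict[int, List[int]] = {}
    # Half resistances [MOhm] at the proximal/distal ends of each compartment
    half_prox: List[float] = []
    half_dist: List[float] = []
    last_comp_of_section: Dict[int, int] = {}

    soma = morph.soma
    if len(soma.points) < 2:
        r = soma.diams[0] / 2.0
        a_um2 = 4.0 * math.pi * r * r
        # axial half-resistance of an equivalent cylinder (L = 2r)
        hr = ra * r / (math.pi * r * r) * 1e-2
        soma_len = 2.0 * r
    else:
        arc, radii = _frusta_profile(soma.points, soma.diams)
        a_um2, res = _integrate(arc, radii, ra, 0.0, arc[-1])
        hr = res / 2.0
        soma_len = float(arc[-1])
    parent.append(-1)
    area.append(a_um2 * UM2_TO_CM2)
    length.append(soma_len)
    region.append(REGION_INDEX["soma"])
    gax.append(0.0)
    section_of.append(0)
    half_prox.append(hr)
    half_dist.append(hr)
    comps_of_section[0] = [0]
    last_comp_of_section[0] = 0

    for si, sec in enumerate(morph.sections):
        if si == 0:
            continue
        arc, radii = _frusta_profile(sec.points, sec.diams)
        L = float(arc[-1])
        nseg = max(1, math.ceil(L / seg_len)) if L > 0 else 1
        edges = np.linspace(0.0, max(L, 1e-9), nseg + 1)
        comps_of_section[si] = []
        prev = last_comp_of_section[sec.parent]
        for k in range(nseg):
            a_um2, res = _integrate(arc, radii, ra, edges[k], edges[k + 1])
            if a_um2 <= 0.0:  # zero-length section: nominal point compartment
                r0 = radii[0]
                a_um2 = math.pi * (2 * r0) * 1e-3
                res = 1e-6
            idx = len(parent)
            parent.append(prev)
            area.append(a_um2 * UM2_TO_CM2)
            length.append(edges[k + 1] - edges[k])
            region.append(REGION_INDEX[sec.stype])
            section_of.append(si)
            half_prox.append(res / 2.0)
            half_dist.append(res / 2.0)
            # axial conductance to parent: series half-resistances [MOhm] -> uS
            r_link = res / 2.0 + half_dist[prev]
            gax.append(1.0 / max(r_link, 1e-9))
            comps_of_section[si].append(idx)
            prev = idx
        last_comp_of_section[si] = prev

    return CompartmentGraph(
        parent=np.array(parent, dtype=np.int64),
        area=np.array(area),
        length=np.array(length),
        region=np.array(region, dtype=np.int64),
        gax=np.array(gax),
        section_of=np.array(section_of, dtype=np.int64),
        seg_len=seg_len,
        comps_of_section=comps_of_section,
    )
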