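"""Neuron morphologies: section trees and SWC input/output.

A :class:`Morphology` is a tree of unbranched sections (soma root,
dendrite and axon sections), each carrying 3D sample points and
diameters.  SWC (standard 7-column) is the interchange format; writing
is supported so synthetic morphologies round-trip through the same
reader.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

__all__ = ["Section", "Morphology", "read_swc", "write_swc", "replace_axon_with_stub"]

SWC_TYPE_TO_REGION = {1: "soma", 2: "axon", 3: "dend", 4: "dend"}
REGION_TO_SWC_TYPE = {"soma": 1, "axon": 2, "dend": 3}


@dataclass
class Section:
    """An unbranched neurite stretch between branch points.

    ``points`` is an (n, 3) array of sample coordinates [um], ``diams``
    the matching diameters [um].  ``parent`` indexes the parent section
    (-1 for the soma root); children attach at the parent's distal end.
    """

    stype: str  # soma | dend | axon
    points: np.ndarray
    diams: np.ndarray
    parent: int = -1

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.diams = np.atleast_1d(np.asarray(self.diams, dtype=float))
        if self.points.shape[0] != self.diams.shape[0]:
            raise ValueError("points and diams must have equal length")
        if np.any(self.diams <= 0):
            raise ValueError("diameters must be > 0")

    @property
    def length(self) -> float:
        """Arc length [um] along the sample points."""
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def area(self) -> float:
        """Membrane area [um^2]: frusta for chains, sphere for a point soma."""
        if len(self.points) < 2:
            r = self.diams[0] / 2.0
            return float(4.0 * np.pi * r * r)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        r = self.diams / 2.0
        slant = np.sqrt(seg**2 + np.diff(r) ** 2)
        return float(np.sum(np.pi * (r[:-1] + r[1:]) * slant))


@dataclass
class Morphology:
    """Tree of sections with exactly one soma root."""

    sections: List[Section] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        somas = [i for i, s in enumerate(self.sections) if s.stype == "soma"]
        if len(somas) != 1 or somas[0] != 0 or self.sections[0].parent != -1:
            raise ValueError("morphology must have exactly one soma root at index 0")
        for i, s in enumerate(self.sections[1:], start=1):
            if not (0 <= s.parent < i):
                raise ValueError(f"section {i}: parent must precede it (acyclic tree)")

    def sections_of(self, stype: str) -> List[int]:
        return [i for i, s in enumerate(self.sections) if s.stype == stype]

    @property
    def soma(self) -> Section:
        return self.sections[0]

    def total_length(self, stype: str = "dend") -> float:
        return sum(self.sections[i].length for i in self.sections_of(stype))

    def children_of(self, idx: int) -> List[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == idx]


def read_swc(path: Union[str, Path], name: Optional[str] = None) -> Morphology:
    """Read a standard 7-column SWC file into a Morphology.

    Soma samples are merged into a single root section; unbranched
    chains of same-type samples become one section each.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append(
            (
                int(parts[0]),
                int(parts[1]),
                float(parts[2]),
                float(parts[3]),
                float(parts[4]),
                float(parts[5]),
                int(parts[6]),
            )
        )
    if not rows:
        raise ValueError(f"{path}: empty SWC file")
    nodes: Dict[int, tuple] = {r[0]: r for r in rows}
    children: Dict[int, List[int]] = {}
    for r in rows:
        children.setdefault(r[6], []).append(r[0])

    soma_ids = [r[0] for r in rows if r[1] == 1]
    if not soma_ids:
        raise ValueError(f"{path}: no soma samples")
    soma_pts = np.array([[nodes[i][2], nodes[i][3], nodes[i][4]] for i in soma_ids])
    soma_diam = np.array([2.0 * nodes[i][5] for i in soma_ids])

    sections = [Section("soma", soma_pts, soma_diam, parent=-1)]
    soma_set = set(soma_ids)

    # Walk unbranched chains starting from every neurite sample whose
    # parent is a soma sample or a branch point.
    sec_of_node: Dict[int, int] = {i: 0 for i in soma_ids}

    def n_children(nid):
        return len(children.get(nid, []))

    starts = []
    for r in rows:
        nid, typ, _, _, _, _, par = r
        if typ == 1:
            continue
        if par in soma_set or par == -1 or nodes[par][1] == 1:
            starts.append(nid)
        elif n_children(par) > 1:
            starts.append(nid)

    # Process in order so parents are created first.
    pending = sorted(starts)
    for start in pending:
        chain = [start]
        cur = start
        while n_children(cur) == 1:
            nxt = children[cur][0]
            if nodes[nxt][1] == 1:
                break
            chain.append(nxt)
            cur = nxt
        par_node = nodes[start][6]
        parent_sec = sec_of_node.get(par_node, 0)
        stype = SWC_TYPE_TO_REGION.get(nodes[start][1], "dend")
        ids = chain
        pts = np.array([[nodes[i][2], nodes[i][3], nodes[i][4]] for i in ids])
        diams = np.array([2.0 * nodes[i][5] for i in ids])
        # prepend the parent sample as the proximal point (SWC convention)
        if par_node in nodes and nodes[par_node][1] != 1:
            p = nodes[par_node]
            pts = np.vstack([[p[2], p[3], p[4]], pts])
            diams = np.concatenate([[2.0 * p[5]], diams])
        sections.append(Section(stype, pts, diams, parent=parent_sec))
        idx = len(sections) - 1
        for i in ids:
            sec_of_node[i] = idx

    return Morphology(sections, name=name or Path(path).stem)


def write_swc(morph: Morphology, path: Union[str, Path]) -> None:
    """Write a Morphology as a standard SWC file."""
    lines = ["# SWC written by tcneuron"]
    next_id = 1
    last_node_of_sec: Dict[int, int] = {}
    soma = morph.soma
    soma_node_ids = []
    for j in range(len(soma.points)):
        par = -1 if j == 0 else soma_node_ids[-1]
        x, y, z = soma.points[j]
        lines.append(
            f"{next_id} 1 {x:.3f} {y:.3f} {z:.3f} {soma.diams[j] / 2:.3f} {par}"
        )
        soma_node_ids.append(next_id)
        next_id += 1
    last_node_of_sec[0] = soma_node_ids[0]
    for i, sec in enumerate(morph.sections):
        if i == 0:
            continue
        typ = REGION_TO_SWC_TYPE[sec.stype]
        par_node = last_node_of_sec[sec.parent]
        # skip the duplicated proximal point when the parent is a neurite
        start = 1 if (sec.parent != 0 and len(sec.points) > 1) else 0
        for j in range(start, len(sec.points)):
            x, y, z = sec.points[j]
            lines.append(
                f"{next_id} {typ} {x:.3f} {y:.3f} {z:.3f} {sec.diams[j] / 2:.3f} {par_node}"
            )
            par_node = next_id
            next_id += 1
        last_node_of_sec[i] = par_node
    Path(path).write_text("\n".join(lines) + "\n")


def replace_axon_with_stub(
    morph: Morphology, n_sections: int = 2, length: float = 30.0, diam: float = 1.0
) -> Morphology:
    """Replace any reconstructed axon with a short initial-segment stub.

    The stub is ``n_sections`` cylinders of ``length`` um and ``diam``
    um attached to the soma; dendrites are untouched.  Reconstructed
    axons are usually truncated, so a standardized stub makes models
    comparable across morphologies.
    """
    keep = [s for s in morph.sections if s.stype != "axon"]
    old_idx = [i for i, s in enumerate(morph.sections) if s.stype != "axon"]
    remap = {old: new for new, old in enumerate(old_idx)}
    sections = []
    for s in keep:
        parent = -1 if s.parent == -1 else remap[s.parent]
        sections.append(Section(s.stype, s.points.copy(), s.diams.copy(), parent))
    origin = sections[0].points[0]
    parent = 0
    for k in range(n_sections):
        z0 = origin + np.array([0.0, 0.0, -(k) * length])
        z1 = origin + np.array([0.0, 0.0, -(k + 1) * length])
        sections.append(
            Section("axon", np.vstack([z0, z1]), np.array([diam, diam]), parent)
        )
        parent = len(sections) - 1
    return Morphology(sections, name=morph.name)
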