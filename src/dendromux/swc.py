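"""Reading and writing SWC neuronal morphologies and mapping them onto
branch cables.

An SWC file lists samples ``id type x y z radius parent`` (coordinates and
radii in um).  Each maximal unbranched path is mapped onto one
:class:`~dendromux.cable.BranchCable`, ordered distal to proximal: every
sample-to-parent link becomes a cylindrical section whose length is the 3-D
Euclidean distance between the samples and whose diameter is twice the child
sample's radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List

from .cable import BranchCable, DendriteSection

__all__ = ["SWCNode", "read_swc", "write_swc", "swc_to_cables"]


@dataclass(frozen=True)
class SWCNode:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


def read_swc(path) -> Dict[int, SWCNode]:
    """Parse an SWC file into a node table keyed by sample id.

    Raises on malformed lines, non-positive radii, orphan parent references
    and cyclic parent chains.
    """
    nodes: Dict[int, SWCNode] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable SWC line") from exc
            if radius <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive radius")
            if nid in nodes:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {nid}")
            nodes[nid] = SWCNode(nid, ntype, x, y, z, radius, parent)
    for node in nodes.values():
        if node.parent != -1 and node.parent not in nodes:
            raise ValueError(f"sample {node.id} references missing parent {node.parent}")
    # cycle check by walking each node to a root
    for node in nodes.values():
        seen = set()
        cur = node
        while cur.parent != -1:
            if cur.id in seen:
                raise ValueError(f"cyclic parent chain at sample {cur.id}")
            seen.add(cur.id)
            cur = nodes[cur.parent]
    return nodes


def write_swc(nodes: Dict[int, SWCNode], path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(nodes):
            n = nodes[nid]
            fh.write(
                f"{n.id} {n.type} {n.x:.6f} {n.y:.6f} {n.z:.6f} {n.radius:.6f} {n.parent}\n"
            )


def _distance(a: SWCNode, b: SWCNode) -> float:
    return math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)


def swc_to_cables(
    nodes: Dict[int, SWCNode],
    r_m: float = 10_000.0,
    r_a: float = 100.0,
    c_m: float = 1.0,
) -> List[BranchCable]:
    """Map each maximal unbranched path of the morphology to a branch cable.

    Paths run from a tip or a bifurcation down to the next bifurcation or the
    root; sections within a cable are ordered distal to proximal.  Soma
    samples (type 1) are treated as the root region, not as cable sections.
    """
    children: Dict[int, list] = {nid: [] for nid in nodes}
    roots = []
    for n in nodes.values():
        if n.parent == -1:
            roots.append(n.id)
        else:
            children[n.parent].append(n.id)
    if not roots:
        raise ValueError("morphology has no root sample")

    def is_branch_point(nid: int) -> bool:
        return len(children[nid]) != 1 or nodes[nid].parent == -1 or nodes[nid].type == 1

    # A path's distal-most edge starts at a tip or at a bifurcation sample
    # (the bifurcation is the proximal endpoint of its daughter paths and the
    # distal endpoint of its own); walk distal -> proximal from each.
    cables: List[BranchCable] = []
    starts = [
        nid
        for nid in nodes
        if nodes[nid].type != 1
        and nodes[nid].parent != -1
        and len(children[nid]) != 1
    ]
    for start in sorted(set(starts)):
        sections = []
        cur = nodes[start]
        while cur.parent != -1:
            par = nodes[cur.parent]
            length = _distance(cur, par)
            if length > 0:
                sections.append(
                    DendriteSection(
                        length=length,
                        diameter=2.0 * cur.radius,
                        r_m=r_m,
                        r_a=r_a,
                        c_m=c_m,
                    )
                )
            if is_branch_point(par.id):
                break
            cur = par
        if sections:
            cables.append(BranchCable(tuple(sections), branch_id=f"swc_{start}"))
    if not cables:
        raise ValueError("morphology yields no dendritic cables")
    return cables
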