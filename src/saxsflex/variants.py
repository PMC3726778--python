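"""Rigidified variants of a hinged topology: the three model classes.

From a hinged declaration (rigid arms separated by a flexible hinge,
optionally with a flexible C-terminal tail) two rigid variants are
derived:

* ``linear``  — the hinge is replaced by a rigid helical spacer (1.5 A
  rise per residue) fusing the arms collinearly; the tail stays flexible.
* ``extended`` — everything is fused rigid and collinear, including the
  tail (modelled as a folded helical extension).
"""

from __future__ import annotations

import math

from .errors import TopologyError
from .topology import (BeadModel, Segment, SegmentTopology, build_topology,
                       fuse_collinear, make_toy_rigid_arm)
import numpy as np

#: axial rise per residue of an alpha-helical spacer, Angstrom
HELIX_RISE = 1.5


def helical_spacer(n_residues: int, rise: float = HELIX_RISE) -> BeadModel:
    """Rigid alpha-helix-like spacer: 3.8 A virtual bonds, given axial rise."""
    if n_residues == 1:
        return BeadModel(np.zeros((1, 3)))
    lateral = math.sqrt(3.8**2 - rise**2)
    # 100 deg turn per residue (3.6 residues/turn) fixes the radius
    radius = lateral / (2.0 * math.sin(math.radians(50.0)))
    return make_toy_rigid_arm(n_residues, rise * (n_residues - 1),
                              radius=radius, seed=0)


def _fused_segment(segments: list[Segment], label: str) -> Segment:
    parts = []
    for s in segments:
        if s.is_rigid:
            if s.template is None:
                raise TopologyError(f"rigid segment {s.label!r} lacks a template")
            parts.append(s.template)
        else:
            parts.append(helical_spacer(s.n_residues))
    fused = fuse_collinear(parts)
    return Segment("rigid", segments[0].start, segments[-1].end,
                   label=label, template=fused)


def make_linear_topology(topology: SegmentTopology) -> SegmentTopology:
    """Fuse everything from the first to the last rigid segment into one
    straight rigid body; flexible tails outside that span are kept."""
    segs = topology.segments
    rigid_idx = [i for i, s in enumerate(segs) if s.is_rigid]
    lo, hi = rigid_idx[0], rigid_idx[-1]
    fused = _fused_segment(segs[lo:hi + 1], label="linear core")
    new_segs = segs[:lo] + [fused] + segs[hi + 1:]
    return build_topology(new_segs, protein_label=f"{topology.protein_label} (linear)",
                          merge_adjacent_flexible=False)


def make_extended_topology(topology: SegmentTopology) -> SegmentTopology:
    """Fuse the entire chain into a single straight rigid body."""
    fused = _fused_segment(list(topology.segments), label="extended")
    return build_topology([fused],
                          protein_label=f"{topology.protein_label} (extended)",
                          merge_adjacent_flexible=False)
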