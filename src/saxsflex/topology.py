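"""Rigid/flexible segment architecture of a multidomain chain.

A chain is declared as an ordered list of segments, each spanning an
inclusive residue range and marked either ``rigid`` (moves as a unit,
backed by a one-bead-per-residue template) or ``flexible`` (resampled
for every conformer).  Coarse-graining is one bead per residue at the
Calpha position with unit scattering weight by default.

Residue numbering follows the source chain; all user-facing ranges are
inclusive.  Internal bead indexing is 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import GeometryError, TopologyError

logger = logging.getLogger(__name__)

#: Canonical virtual Calpha-Calpha bond length in Angstrom.
CA_BOND = 3.8

#: Allowed range for consecutive bead distances in chain-derived models.
CHAIN_BOND_RANGE = (2.8, 4.2)


# ---------------------------------------------------------------------------
# Bead models
# ---------------------------------------------------------------------------

@dataclass
class BeadModel:
    """Calpha-level bead model: one bead per residue.

    Parameters
    ----------
    coords
        ``(n, 3)`` array of bead positions in Angstrom.
    weights
        Per-bead scattering weight (dimensionless).  Defaults to 1.
    residue_ids
        Residue numbers in source-chain numbering.  Defaults to ``1..n``.
    """

    coords: np.ndarray
    weights: np.ndarray | None = None
    residue_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("bead model must contain at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.coords))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.coords),):
                raise ValueError("weights must have one entry per bead")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.coords) + 1)
        else:
            self.residue_ids = np.asarray(self.residue_ids)
            if self.residue_ids.shape != (len(self.coords),):
                raise ValueError("residue_ids must have one entry per bead")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def centroid(self) -> np.ndarray:
        """Weight-averaged centre of the model."""
        w = self.weights / self.weights.sum()
        return w @ self.coords

    def rg(self) -> float:
        """Mass-weighted root-mean-square distance from the centroid."""
        d2 = np.sum((self.coords - self.centroid()) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=self.weights)))

    def dmax(self) -> float:
        """Maximum pairwise bead distance."""
        from scipy.spatial.distance import pdist

        if self.n_beads < 2:
            return 0.0
        return float(pdist(self.coords).max())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "BeadModel":
        """Return a rigidly transformed copy (rotation applied first)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return BeadModel(coords, self.weights.copy(), self.residue_ids.copy())

    def validate_chain(self) -> None:
        """Check the virtual-bond invariant for chain-derived models."""
        if self.n_beads < 2:
            return
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        lo, hi = CHAIN_BOND_RANGE
        bad = np.where((d < lo) | (d > hi))[0]
        if bad.size:
            raise GeometryError(
                f"consecutive bead distance outside [{lo}, {hi}] A at "
                f"position(s) {bad.tolist()[:5]} (d={d[bad[0]]:.2f} A)")


def make_toy_rigid_arm(n_residues: int, length: float, radius: float = 0.0,
                       seed: int = 0, bond_length: float = CA_BOND) -> BeadModel:
    """Trace a rigid rod-like arm as a helix on a cylinder.

    Beads lie on a cylinder of the given ``radius`` whose axis is +x; the
    axial extent is exactly ``length`` and consecutive beads are
    ``bond_length`` apart.  The helical phase is randomized from ``seed``
    so distinct arms are not trivially superimposable.

    Raises
    ------
    GeometryError
        If ``length`` exceeds the fully extended chain, or the radius is
        too small to absorb the per-step lateral excursion.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    dz = length / (n_residues - 1)
    if dz > bond_length + 1e-9:
        raise GeometryError(
            f"length {length} A not reachable with {n_residues} beads at "
            f"{bond_length} A spacing (max {bond_length * (n_residues - 1)} A)")
    lateral = math.sqrt(max(bond_length**2 - dz**2, 0.0))
    x = np.arange(n_residues) * dz
    if lateral < 1e-6:
        coords = np.column_stack([x, np.zeros(n_residues), np.zeros(n_residues)])
        return BeadModel(coords)
    if radius <= 0 or lateral > 2 * radius:
        raise GeometryError(
            f"radius {radius} A too small for lateral step {lateral:.2f} A "
            f"(need radius >= {lateral / 2:.2f} A)")
    theta = 2.0 * math.asin(lateral / (2.0 * radius))
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    angles = phase + np.arange(n_residues) * theta
    coords = np.column_stack([x, radius * np.cos(angles), radius * np.sin(angles)])
    return BeadModel(coords)


def fuse_collinear(models: Sequence[BeadModel], gap: float = CA_BOND) -> BeadModel:
    """Fuse bead models end-to-end along a common +x axis.

    Each model is rotated so its first-to-last bead axis points along +x,
    then translated so its first bead sits ``gap`` Angstrom beyond the
    previous model's last bead along x.  Used to build rigid "linear"
    variants of hinged topologies.
    """
    if not models:
        raise ValueError("need at least one model")
    placed = []
    cursor = None
    for m in models:
        c = _align_axis_to_x(m.coords)
        if cursor is None:
            c = c - c[0]
        else:
            c = c - c[0] + cursor + np.array([gap, 0.0, 0.0])
        placed.append((c, m))
        cursor = c[-1]
    coords = np.vstack([c for c, _ in placed])
    weights = np.concatenate([m.weights for _, m in placed])
    return BeadModel(coords, weights)


def _align_axis_to_x(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates so the first->last bead vector points along +x."""
    coords = np.asarray(coords, dtype=float)
    axis = coords[-1] - coords[0]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return coords.copy()
    from scipy.spatial.transform import Rotation

    rot, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [axis / norm])
    return (coords - coords[0]) @ rot.as_matrix().T + coords[0]


# ---------------------------------------------------------------------------
# Segments and topologies
# ---------------------------------------------------------------------------

RIGID = "rigid"
FLEXIBLE = "flexible"


@dataclass
class Segment:
    """One stretch of chain, rigid or flexible, over an inclusive range."""

    kind: str
    start: int
    end: int
    label: str = ""
    template: BeadModel | None = None

    def __post_init__(self) -> None:
        if self.kind not in (RIGID, FLEXIBLE):
            raise TopologyError(f"segment kind must be rigid|flexible, got {self.kind!r}")
        if self.end < self.start:
            raise TopologyError(
                f"segment {self.label!r}: end {self.end} < start {self.start}")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def is_rigid(self) -> bool:
        return self.kind == RIGID


@dataclass
class SegmentTopology:
    """Ordered rigid/flexible segment architecture of one chain."""

    segments: list[Segment]
    protein_label: str = ""
    first_residue: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.segments:
            raise TopologyError("topology must contain at least one segment")
        if self.first_residue == 0:
            self.first_residue = self.segments[0].start
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        segs = self.segments
        if segs[0].start != self.first_residue:
            raise TopologyError(
                f"first segment starts at {segs[0].start}, expected "
                f"first_residue {self.first_residue}")
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end + 1:
                kind = "overlap" if b.start <= a.end else "gap"
                raise TopologyError(
                    f"{kind} between segments {a.label!r} [{a.start},{a.end}] "
                    f"and {b.label!r} [{b.start},{b.end}]")
        if not any(s.is_rigid for s in segs):
            raise TopologyError("topology must contain at least one rigid segment")
        for s in segs:
            if s.is_rigid:
                if s.template is not None and s.template.n_beads != s.n_residues:
                    raise TopologyError(
                        f"rigid segment {s.label!r} has template with "
                        f"{s.template.n_beads} beads but spans {s.n_residues} residues")
            elif s.template is not None:
                raise TopologyError(f"flexible segment {s.label!r} carries a template")

    # -- basic accessors --------------------------------------------------
    @property
    def last_residue(self) -> int:
        return self.segments[-1].end

    @property
    def n_residues(self) -> int:
        return sum(s.n_residues for s in self.segments)

    @property
    def rigid_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.is_rigid]

    @property
    def flexible_segments(self) -> list[Segment]:
        return [s for s in self.segments if not s.is_rigid]

    @property
    def hinge_length(self) -> int:
        """Total residue count of interior flexible segments.

        Interior means strictly between the first and last rigid segment;
        leading/trailing flexible tails do not count as hinge.
        """
        rigid_idx = [i for i, s in enumerate(self.segments) if s.is_rigid]
        lo, hi = rigid_idx[0], rigid_idx[-1]
        return sum(s.n_residues for s in self.segments[lo:hi] if not s.is_rigid)

    def bead_slices(self) -> list[slice]:
        """0-based bead index slice for each segment, in order."""
        out, pos = [], 0
        for s in self.segments:
            out.append(slice(pos, pos + s.n_residues))
            pos += s.n_residues
        return out

    def requires_templates(self) -> None:
        missing = [s.label for s in self.rigid_segments if s.template is None]
        if missing:
            raise TopologyError(f"rigid segment(s) missing templates: {missing}")


def build_topology(config: Iterable[Segment | dict], protein_label: str = "",
                   merge_adjacent_flexible: bool = True) -> SegmentTopology:
    """Validate a declarative segment list into a :class:`SegmentTopology`.

    ``config`` items are :class:`Segment` objects or dicts with keys
    ``kind, start, end`` and optionally ``label, template``.  Adjacent
    flexible segments are merged into one (they are indistinguishable to
    the sampler).
    """
    segs: list[Segment] = []
    for item in config:
        seg = item if isinstance(item, Segment) else Segment(**item)
        if (merge_adjacent_flexible and segs and not seg.is_rigid
                and not segs[-1].is_rigid and seg.start == segs[-1].end + 1):
            prev = segs.pop()
            seg = Segment(FLEXIBLE, prev.start, seg.end,
                          label=prev.label or seg.label)
        segs.append(seg)
    topo = SegmentTopology(segs, protein_label=protein_label)
    logger.info("built topology %r: %d residues, hinge length %d",
                protein_label, topo.n_residues, topo.hinge_length)
    return topo


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def load_pdb_as_beads(path: str | Path, chain_id: str | None = None) -> BeadModel:
    """Extract one bead per residue at the Calpha position from a PDB file.

    ATOM records only; first model of multi-model files; first altloc.
    Residues lacking a Calpha are skipped with a warning.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models in {path}") from None
    coords, resids = [], []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag.strip():  # HETATM / water
                continue
            if "CA" not in residue:
                logger.warning("residue %s%s has no CA atom; skipped",
                               residue.get_resname(), residue.id[1])
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                # keep the first altloc as it appears in the file
                first = sorted(atom.disordered_get_id_list())[0]
                atom = atom.disordered_get(first)
            coords.append(atom.get_coord())
            resids.append(residue.id[1])
    if not coords:
        raise ValueError(f"no Calpha atoms selected from {path}")
    return BeadModel(np.asarray(coords, dtype=float), residue_ids=np.asarray(resids))


def write_beads_pdb(models: BeadModel | Sequence[BeadModel], path: str | Path,
                    chain_id: str = "A") -> None:
    """Write bead model(s) as CA-only PDB; multiple models as MODEL blocks."""
    if isinstance(models, BeadModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for imod, m in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {imod:4d}\n")
            for i, (xyz, rid) in enumerate(zip(m.coords, m.residue_ids), start=1):
                fh.write(
                    "ATOM  {serial:5d}  CA  ALA {chain}{resseq:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    " C\n".format(serial=i % 100000, chain=chain_id,
                                  resseq=int(rid) % 10000, x=xyz[0], y=xyz[1],
                                  z=xyz[2], occ=1.0, b=0.0))
            fh.write("ENDMDL\n" if multi else "TER\n")
        fh.write("END\n")


def read_beads_pdb(path: str | Path) -> list[BeadModel]:
    """Read CA-only PDB file(s) written by :func:`write_beads_pdb`.

    Returns a list of models (one per MODEL block; single-model files
    yield a one-element list).
    """
    models: list[BeadModel] = []
    coords: list[list[float]] = []
    resids: list[int] = []

    def flush():
        nonlocal coords, resids
        if coords:
            models.append(BeadModel(np.asarray(coords),
                                    residue_ids=np.asarray(resids)))
        coords, resids = [], []

    with open(path) as fh:
        for line in fh:
            if line.startswith("ATOM") and line[12:16].strip() == "CA":
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
                resids.append(int(line[22:26]))
            elif line.startswith(("ENDMDL", "TER")):
                flush()
    flush()
    return models


# ---------------------------------------------------------------------------
# Topology config (YAML) I/O
# ---------------------------------------------------------------------------

def save_topology(topology: SegmentTopology, path: str | Path,
                  template_dir: str | Path | None = None) -> None:
    """Serialize a topology to a human-editable YAML file.

    Rigid templates are written as CA-only PDB files next to the config
    (or under ``template_dir``) and referenced by relative path.
    """
    path = Path(path)
    tdir = Path(template_dir) if template_dir else path.parent
    tdir.mkdir(parents=True, exist_ok=True)
    seg_dicts = []
    for i, s in enumerate(topology.segments):
        d: dict = {"label": s.label, "kind": s.kind,
                   "start": int(s.start), "end": int(s.end)}
        if s.template is not None:
            name = f"{s.label or f'segment{i}'}.pdb".replace(" ", "_")
            write_beads_pdb(s.template, tdir / name)
            d["template"] = str((tdir / name).relative_to(path.parent)) \
                if tdir != path.parent else name
        seg_dicts.append(d)
    doc = {"protein_label": topology.protein_label,
           "first_residue": int(topology.first_residue),
           "segments": seg_dicts}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_topology(path: str | Path) -> SegmentTopology:
    """Parse a topology YAML file written by :func:`save_topology`."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segs = []
    for d in doc["segments"]:
        template = None
        if d.get("template"):
            template = read_beads_pdb(path.parent / d["template"])[0]
        segs.append(Segment(d["kind"], d["start"], d["end"],
                            label=d.get("label", ""), template=template))
    return build_topology(segs, protein_label=doc.get("protein_label", ""),
                          merge_adjacent_flexible=False)
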