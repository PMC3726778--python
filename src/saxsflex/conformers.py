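"""Random conformer pool generation for rigid-arm / flexible-linker chains.

Rigid segments are placed as rigid transforms of their templates; flexible
segments are resampled for every conformer as virtual-bond Calpha chains
(3.8 A bonds, coil-like pseudo-bond-angle window, uniform torsions).  A
rigid body that follows a flexible segment is attached at the linker end
with a uniformly random orientation; a rigid body directly following
another rigid body is attached deterministically, continuing the chain
direction.  Hard-sphere excluded volume is enforced between all beads
except sequence-adjacent pairs and pairs within the same rigid template.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .errors import ClashError, TopologyError
from .topology import CA_BOND, BeadModel, SegmentTopology

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Sampling parameters for flexible-segment generation."""

    bond_length: float = CA_BOND
    pseudo_angle_range: tuple[float, float] = (80.0, 150.0)
    clash_radius: float = 3.0
    max_retries_per_conformer: int = 100
    #: also check clashes between different segments (arms vs arms/linkers),
    #: not only within each sampled linker
    check_global_clashes: bool = True

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.clash_radius >= self.bond_length:
            raise ValueError("clash_radius must be below bond_length")


@dataclass
class Descriptors:
    rg: float
    dmax: float
    end_to_end: float
    arm_angle: float | None
    shape_class: str | None


@dataclass
class Conformer:
    """A full-chain bead model plus its shape descriptors."""

    model: BeadModel
    rg: float
    dmax: float
    end_to_end: float
    arm_angle: float | None = None
    shape_class: str | None = None


@dataclass
class ConformerPool:
    """A pool of conformers sharing one topology, with cached curves."""

    conformers: list[Conformer]
    topology: SegmentTopology
    seed: int | None = None
    weights: np.ndarray | None = None
    #: set by saxs.compute_pool_curves: (q, intensity matrix (n_conf, n_q))
    curves: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.conformers)

    def descriptor(self, name: str) -> np.ndarray:
        return np.array([getattr(c, name) for c in self.conformers])

    def descriptor_table(self):
        """Per-conformer descriptor table (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame({
            "index": np.arange(len(self)),
            "rg": self.descriptor("rg"),
            "dmax": self.descriptor("dmax"),
            "end_to_end": self.descriptor("end_to_end"),
            "arm_angle": [c.arm_angle for c in self.conformers],
            "shape_class": [c.shape_class for c in self.conformers],
        })

    def subset(self, indices) -> list[Conformer]:
        return [self.conformers[i] for i in indices]


# ---------------------------------------------------------------------------
# Linker sampling
# ---------------------------------------------------------------------------

def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _unit3(v):
    return v / math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit3(_cross3(v, ref))


def _deflect(direction: np.ndarray, bond_angle_deg: float,
             torsion_rad: float) -> np.ndarray:
    """New bond direction given the pseudo-bond angle at the joint."""
    d = _unit3(direction)
    dev = math.pi - math.radians(bond_angle_deg)  # deviation from straight-on
    u = _perpendicular(d)
    w = _cross3(d, u)
    return (math.cos(dev) * d
            + math.sin(dev) * (math.cos(torsion_rad) * u
                               + math.sin(torsion_rad) * w))


def sample_linker(n_residues: int, anchor_position, anchor_direction,
                  config: GeneratorConfig, rng: np.random.Generator,
                  label: str = "linker") -> np.ndarray:
    """Sample a self-avoiding virtual-bond chain grown from an anchor.

    The first bead is placed ``bond_length`` from the anchor along
    ``anchor_direction``; subsequent bonds make pseudo-bond angles drawn
    uniformly from ``pseudo_angle_range`` with uniform torsions.  Beads
    separated by >= 2 positions must be at least ``clash_radius`` apart.

    Returns the ``(n_residues, 3)`` linker coordinates (anchor excluded).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    anchor = np.asarray(anchor_position, dtype=float)
    d0 = _unit3(np.asarray(anchor_direction, dtype=float))
    lo, hi = config.pseudo_angle_range
    r2 = config.clash_radius**2
    for _ in range(config.max_retries_per_conformer):
        angles = rng.uniform(lo, hi, size=n_residues)
        torsions = rng.uniform(0.0, 2.0 * math.pi, size=n_residues)
        pts = np.empty((n_residues, 3))
        pts[0] = anchor + config.bond_length * d0
        d = d0
        ok = True
        for i in range(1, n_residues):
            d = _deflect(d, angles[i], torsions[i])
            pts[i] = pts[i - 1] + config.bond_length * d
            if i >= 2:
                diff = pts[: i - 1] - pts[i]
                if (diff * diff).sum(axis=1).min() < r2:
                    ok = False
                    break
        if ok:
            return pts
    raise ClashError(
        f"could not sample clash-free segment {label!r} "
        f"({n_residues} residues) in {config.max_retries_per_conformer} attempts")


# ---------------------------------------------------------------------------
# Conformer assembly
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _assemble_chain(topology: SegmentTopology, config: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    coords_parts: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    prev_dir: np.ndarray | None = None
    prev_flexible = False
    for seg in topology.segments:
        if seg.is_rigid:
            tmpl = seg.template.coords
            if prev_end is None:
                part = tmpl.copy()
            elif prev_flexible:
                rot = _random_rotation(rng)
                attach = prev_end + config.bond_length * _random_unit(rng)
                part = (tmpl - tmpl[0]) @ rot.T + attach
            else:
                # rigid directly after rigid: deterministic continuation
                attach = prev_end + config.bond_length * prev_dir
                part = tmpl - tmpl[0] + attach
            prev_flexible = False
        else:
            if prev_end is None:
                prev_end = np.zeros(3)
                prev_dir = _random_unit(rng)
            part = sample_linker(seg.n_residues, prev_end, prev_dir, config,
                                 rng, label=seg.label)
            prev_flexible = True
        coords_parts.append(part)
        prev_end = part[-1]
        if len(part) >= 2:
            prev_dir = part[-1] - part[-2]
            prev_dir = prev_dir / np.linalg.norm(prev_dir)
        elif prev_dir is None:
            prev_dir = _random_unit(rng)
    return np.vstack(coords_parts)


def _clash_free(coords: np.ndarray, topology: SegmentTopology,
                config: GeneratorConfig) -> bool:
    n = len(coords)
    d = cdist(coords, coords)
    mask = np.ones((n, n), dtype=bool)
    idx = np.arange(n)
    # self and sequence-adjacent pairs are exempt
    mask[np.abs(idx[:, None] - idx[None, :]) <= 1] = False
    # template-internal geometry is fixed, not re-checked
    for seg, sl in zip(topology.segments, topology.bead_slices()):
        if seg.is_rigid:
            mask[sl, sl] = False
    return bool(d[mask].min() >= config.clash_radius) if mask.any() else True


def generate_conformer(topology: SegmentTopology,
                       config: GeneratorConfig | None = None,
                       rng: np.random.Generator | None = None) -> Conformer:
    """Generate one clash-free conformer of the topology.

    Raises :class:`ClashError` if the retry budget is exhausted.
    """
    config = config or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    topology.requires_templates()
    weights = np.concatenate([
        s.template.weights if s.is_rigid else np.ones(s.n_residues)
        for s in topology.segments])
    for _ in range(config.max_retries_per_conformer):
        coords = _assemble_chain(topology, config, rng)
        if not config.check_global_clashes or _clash_free(coords, topology, config):
            model = BeadModel(coords, weights)
            return conformer_from_model(model, topology)
    raise ClashError(
        f"no clash-free conformer in {config.max_retries_per_conformer} attempts")


def generate_pool(topology: SegmentTopology, n: int,
                  config: GeneratorConfig | None = None,
                  seed: int | None = None) -> ConformerPool:
    """Generate a pool of ``n`` conformers, reproducible from ``seed``.

    Each conformer uses an independent spawned RNG substream, so pools
    are order-independent under parallel evaluation.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    config = config or GeneratorConfig()
    children = np.random.SeedSequence(seed).spawn(n)
    conformers = []
    for i, child in enumerate(children):
        try:
            conformers.append(
                generate_conformer(topology, config, np.random.default_rng(child)))
        except ClashError as exc:
            raise ClashError(f"conformer {i}: {exc}") from exc
    return ConformerPool(conformers, topology, seed=seed)


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

#: shape-class thresholds on the inter-arm angle, degrees
CLASS_THRESHOLDS = {"U": 60.0, "L": 120.0}  # I above 120


def classify_angle(angle_deg: float) -> str:
    """Map an inter-arm angle to a qualitative shape class (U/L/I)."""
    if angle_deg < CLASS_THRESHOLDS["U"]:
        return "U"
    if angle_deg <= CLASS_THRESHOLDS["L"]:
        return "L"
    return "I"


def compute_descriptors(model: BeadModel,
                        topology: SegmentTopology) -> Descriptors:
    """Shape descriptors of a full-chain model.

    ``end_to_end`` is the distance from the first bead of the first rigid
    segment to the last bead of the last rigid segment.  ``arm_angle`` is
    the angle between the two outward arm vectors (pointing away from the
    hinge), so a straight chain scores 180 deg (class I) and a fully
    folded-back one 0 deg (class U); it is None when the topology has
    fewer than two rigid segments.
    """
    if model.n_beads != topology.n_residues:
        raise TopologyError(
            f"model has {model.n_beads} beads, topology spans "
            f"{topology.n_residues} residues")
    rg = model.rg()
    dmax = model.dmax()
    slices = [sl for seg, sl in zip(topology.segments, topology.bead_slices())
              if seg.is_rigid]
    first, last = slices[0], slices[-1]
    end_to_end = float(np.linalg.norm(
        model.coords[last.stop - 1] - model.coords[first.start]))
    if len(slices) < 2:
        return Descriptors(rg, dmax, end_to_end, None, None)
    v1 = model.coords[first.start] - model.coords[first.stop - 1]
    v2 = model.coords[last.stop - 1] - model.coords[last.start]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return Descriptors(rg, dmax, end_to_end, angle, classify_angle(angle))


def conformer_from_model(model: BeadModel,
                         topology: SegmentTopology) -> Conformer:
    d = compute_descriptors(model, topology)
    return Conformer(model, d.rg, d.dmax, d.end_to_end, d.arm_angle,
                     d.shape_class)


def rigid_segment_rmsd(conformer: Conformer,
                       topology: SegmentTopology) -> float:
    """Max deviation of any rigid segment's internal distance matrix
    from its template's (rigidity invariant check)."""
    worst = 0.0
    for seg, sl in zip(topology.segments, topology.bead_slices()):
        if not seg.is_rigid or seg.n_residues < 2:
            continue
        d_conf = pdist(conformer.model.coords[sl])
        d_tmpl = pdist(seg.template.coords)
        worst = max(worst, float(np.abs(d_conf - d_tmpl).max()))
    return worst
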