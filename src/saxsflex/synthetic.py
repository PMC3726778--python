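"""Ground-truth synthetic systems and experimental-style SAXS data.

Each scenario builds a two-arm toy chain (long rigid arm, flexible
hinge, short rigid arm, flexible tail), draws the inter-arm angle from a
declared distribution, and synthesizes a noisy ensemble-averaged Debye
curve — so every pipeline stage can be validated against known truth
without any external data.

Named scenarios emulate three qualitative phenotypes: a restricted
bent-arm ensemble (``L_shape``), a compact/extended two-state mixture
(``bimodal_UI``), a freely articulating hinge (``uniform_flexible``) and
a rigid straight rod (``rigid_linear``).

Noise model: counting-statistics-like,

    sigma(q) = noise_fraction * sqrt(I(q) * I(q_max)) + floor,

with floor = noise_fraction * I(q_max) / 10, so that relative errors are
smallest at low q and reach ~noise_fraction at the high-q end, as on a
real detector.  Intensities are perturbed with independent
Gaussian(0, sigma) noise and rare negative draws are resampled.  The
model is calibrated so that the true average curve scores a reduced
chi-square of ~1 against its own synthetic data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .conformers import (Conformer, ConformerPool, GeneratorConfig,
                         conformer_from_model, generate_conformer, sample_linker)
from .errors import GeometryError
from .saxs import DEFAULT_Q_GRID, ScatteringCurve, compute_pool_curves, write_curve
from .topology import (CA_BOND, BeadModel, Segment, SegmentTopology,
                       build_topology, make_toy_rigid_arm, save_topology,
                       write_beads_pdb)
from .variants import make_extended_topology

#: axial rise per residue of toy arms, Angstrom; chosen so the default
#: arms span the 200-250 A Dmax regime of tandem spectrin-repeat rods
ARM_RISE = 1.43
ARM_RADIUS = 8.0

SCENARIO_NAMES = ("L_shape", "bimodal_UI", "uniform_flexible", "rigid_linear")


# ---------------------------------------------------------------------------
# Angle distributions
# ---------------------------------------------------------------------------

@dataclass
class AngleDistribution:
    """Parametric distribution of the inter-arm angle in degrees."""

    kind: str  # point | two_point | uniform | truncnorm
    angles: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    low: float = 0.0
    high: float = 180.0
    mean: float = 90.0
    sd: float = 20.0

    def __post_init__(self) -> None:
        if self.kind == "two_point":
            if len(self.angles) != 2 or len(self.weights) != 2:
                raise ValueError("two_point needs 2 angles and 2 weights")
            if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
                raise ValueError("mixture weights must sum to 1")
        elif self.kind == "point" and len(self.angles) != 1:
            raise ValueError("point mass needs exactly one angle")

    @classmethod
    def point(cls, angle: float) -> "AngleDistribution":
        return cls("point", angles=(angle,))

    @classmethod
    def two_point(cls, angles, weights) -> "AngleDistribution":
        return cls("two_point", angles=tuple(angles), weights=tuple(weights))

    @classmethod
    def uniform(cls, low: float = 0.0, high: float = 180.0) -> "AngleDistribution":
        return cls("uniform", low=low, high=high)

    @classmethod
    def truncated_normal(cls, mean: float, sd: float, low: float = 0.0,
                         high: float = 180.0) -> "AngleDistribution":
        return cls("truncnorm", mean=mean, sd=sd, low=low, high=high)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.angles[0])
        if self.kind == "two_point":
            return rng.choice(self.angles, size=n, p=self.weights)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.kind == "truncnorm":
            from scipy.stats import truncnorm

            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                                 random_state=rng)
        raise ValueError(f"unknown angle distribution {self.kind!r}")


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Declarative description of one synthetic ground-truth system."""

    name: str
    arm1_residues: int = 120
    arm2_residues: int = 40
    hinge_residues: int = 9
    tail_residues: int = 20
    arm_angle_distribution: AngleDistribution = field(
        default_factory=lambda: AngleDistribution.uniform())
    noise_fraction: float = 0.02
    q_grid: np.ndarray = field(default_factory=lambda: DEFAULT_Q_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction <= 0:
            raise ValueError("noise_fraction must be positive")
        if self.arm1_residues < 2 or self.arm2_residues < 2:
            raise ValueError("arms need at least 2 residues")


def scenario_spec(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Build a named scenario preset.

    Presets: ``L_shape`` (point mass at 90 deg, short hinge),
    ``bimodal_UI`` (75/25 mixture of 20 and 170 deg, long 37-residue
    hinge), ``uniform_flexible`` (uniform angles, 8-residue hinge) and
    ``rigid_linear`` (single straight rigid rod).
    """
    presets = {
        "L_shape": dict(hinge_residues=9,
                        arm_angle_distribution=AngleDistribution.point(90.0)),
        "bimodal_UI": dict(hinge_residues=37,
                           arm_angle_distribution=AngleDistribution.two_point(
                               (20.0, 170.0), (0.75, 0.25))),
        "uniform_flexible": dict(hinge_residues=8,
                                 arm_angle_distribution=AngleDistribution.uniform()),
        "rigid_linear": dict(hinge_residues=9,
                             arm_angle_distribution=AngleDistribution.point(180.0)),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return ScenarioSpec(name=name, seed=seed, **kwargs)


@dataclass
class SyntheticExperiment:
    true_ensemble: ConformerPool
    data: ScatteringCurve
    scenario: ScenarioSpec


# ---------------------------------------------------------------------------
# Topology and true-ensemble construction
# ---------------------------------------------------------------------------

def make_scenario_topology(spec: ScenarioSpec) -> SegmentTopology:
    """Two toy rigid arms joined by a flexible hinge, plus a flexible tail.

    A hinge of length 0 fuses the arms into adjacent rigid segments.
    """
    a1, a2 = spec.arm1_residues, spec.arm2_residues
    arm1 = make_toy_rigid_arm(a1, ARM_RISE * (a1 - 1), ARM_RADIUS, seed=11)
    arm2 = make_toy_rigid_arm(a2, ARM_RISE * (a2 - 1), ARM_RADIUS, seed=22)
    segs: list[Segment] = []
    pos = 1
    segs.append(Segment("rigid", pos, pos + a1 - 1, label="arm1", template=arm1))
    pos += a1
    if spec.hinge_residues > 0:
        segs.append(Segment("flexible", pos, pos + spec.hinge_residues - 1,
                            label="hinge"))
        pos += spec.hinge_residues
    segs.append(Segment("rigid", pos, pos + a2 - 1, label="arm2", template=arm2))
    pos += a2
    if spec.tail_residues > 0:
        segs.append(Segment("flexible", pos, pos + spec.tail_residues - 1,
                            label="tail"))
    return build_topology(segs, protein_label=spec.name)


def _cone_vector(axis: np.ndarray, angle_deg: float, azimuth: float) -> np.ndarray:
    """Unit vector at a fixed angle from ``axis`` with given azimuth."""
    a = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, ref)
    u /= np.linalg.norm(u)
    w = np.cross(a, u)
    t = math.radians(angle_deg)
    return (math.cos(t) * a
            + math.sin(t) * (math.cos(azimuth) * u + math.sin(azimuth) * w))


def _conformer_at_angle(topology: SegmentTopology, angle_deg: float,
                        gen_config: GeneratorConfig,
                        rng: np.random.Generator) -> Conformer:
    """Build a conformer whose inter-arm angle equals ``angle_deg`` exactly.

    Arm 1 is kept in its template frame; the hinge is a random coil; arm 2
    is rotated so its bead axis realizes the target angle (with uniform
    azimuth on the cone and a uniform spin about its own axis); the tail
    is a random coil.
    """
    segs = {s.label: s for s in topology.segments}
    arm1, arm2 = segs["arm1"].template, segs["arm2"].template
    parts = [arm1.coords.copy()]
    end = arm1.coords[-1]
    direction = arm1.coords[-1] - arm1.coords[-2]
    hinge = segs.get("hinge")
    if hinge is not None:
        coil = sample_linker(hinge.n_residues, end, direction, gen_config, rng,
                             label="hinge")
        parts.append(coil)
        end = coil[-1]
    elif abs(angle_deg - 180.0) > 2.0:
        raise GeometryError(
            f"target angle {angle_deg} deg unrealizable with a 0-residue hinge "
            "(fused arms are collinear)")
    v1 = arm1.coords[0] - arm1.coords[-1]
    v1 = v1 / np.linalg.norm(v1)
    v2 = _cone_vector(v1, angle_deg, rng.uniform(0.0, 2.0 * math.pi))
    t2 = arm2.coords[-1] - arm2.coords[0]
    t2 = t2 / np.linalg.norm(t2)
    align, _ = Rotation.align_vectors([v2], [t2])
    spin = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * math.pi) * v2)
    rot = (spin * align).as_matrix()
    arm2_coords = (arm2.coords - arm2.coords[0]) @ rot.T + (end + CA_BOND * v2)
    parts.append(arm2_coords)
    end = arm2_coords[-1]
    tail = segs.get("tail")
    if tail is not None:
        direction = arm2_coords[-1] - arm2_coords[-2]
        parts.append(sample_linker(tail.n_residues, end, direction, gen_config,
                                   rng, label="tail"))
    conf = conformer_from_model(BeadModel(np.vstack(parts)), topology)
    if conf.arm_angle is None or abs(conf.arm_angle - angle_deg) > 2.0:
        raise GeometryError(
            f"realized angle {conf.arm_angle} deviates from target {angle_deg}")
    return conf


def simulate_true_ensemble(spec: ScenarioSpec, n_conformers: int = 200,
                           gen_config: GeneratorConfig | None = None
                           ) -> ConformerPool:
    """Sample a ground-truth ensemble with declared angle distribution.

    The ``rigid_linear`` scenario yields a single fully fused straight
    conformer with weight 1; all other scenarios yield ``n_conformers``
    equally weighted conformers with angles drawn from the declared
    distribution (realized exactly, well within 2 deg).
    """
    gen_config = gen_config or GeneratorConfig()
    topo = make_scenario_topology(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    if spec.name == "rigid_linear":
        ext = make_extended_topology(topo)
        conf = generate_conformer(ext, gen_config, rng)
        return ConformerPool([conf], ext, seed=spec.seed,
                             weights=np.array([1.0]))
    angles = spec.arm_angle_distribution.sample(n_conformers, rng)
    conformers = [_conformer_at_angle(topo, float(a), gen_config, rng)
                  for a in angles]
    weights = np.full(n_conformers, 1.0 / n_conformers)
    return ConformerPool(conformers, topo, seed=spec.seed, weights=weights)


# ---------------------------------------------------------------------------
# Synthetic SAXS data
# ---------------------------------------------------------------------------

def average_curve(pool: ConformerPool, q_grid=None) -> ScatteringCurve:
    """Weight-averaged exact Debye curve of a (truth) ensemble."""
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    if pool.curves is None or len(pool.curves[0]) != len(q) or \
            not np.allclose(pool.curves[0], q):
        compute_pool_curves(pool, q)
    qc, curves = pool.curves
    w = pool.weights if pool.weights is not None else \
        np.full(len(pool), 1.0 / len(pool))
    w = w / w.sum()
    return ScatteringCurve(qc, w @ curves, label="true ensemble average")


def synthesize_saxs(true_ensemble: ConformerPool,
                    spec: ScenarioSpec) -> ScatteringCurve:
    """Noisy experimental-style curve from a known ensemble."""
    exact = average_curve(true_ensemble, spec.q_grid)
    i_ref = exact.intensity[-1]
    sigma = spec.noise_fraction * np.sqrt(exact.intensity * i_ref) + \
        spec.noise_fraction * i_ref / 10.0
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    noisy = exact.intensity + rng.normal(0.0, sigma)
    for _ in range(100):  # resample rare negative points
        bad = noisy <= 0
        if not bad.any():
            break
        noisy[bad] = exact.intensity[bad] + rng.normal(0.0, sigma[bad])
    return ScatteringCurve(spec.q_grid, noisy, sigma,
                           label=f"synthetic {spec.name}")


def make_experiment(spec: ScenarioSpec,
                    n_conformers: int = 200) -> SyntheticExperiment:
    """Truth ensemble plus matching noisy data, in one call."""
    truth = simulate_true_ensemble(spec, n_conformers)
    data = synthesize_saxs(truth, spec)
    return SyntheticExperiment(truth, data, spec)


def write_experiment(exp: SyntheticExperiment, out_dir: str | Path) -> None:
    """Persist a complete fixture directory: topology config, truth pool,
    .dat curve and a truth manifest (weights, angles, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_topology(exp.true_ensemble.topology, out / "topology.yaml",
                  template_dir=out / "templates")
    write_beads_pdb([c.model for c in exp.true_ensemble.conformers],
                    out / "truth_pool.pdb")
    exp.true_ensemble.descriptor_table().to_csv(out / "truth_descriptors.tsv",
                                                sep="\t", index=False)
    write_curve(exp.data, out / "data.dat",
                header_extra={"scenario": exp.scenario.name,
                              "noise_fraction": exp.scenario.noise_fraction,
                              "seed": exp.scenario.seed})
    manifest = {
        "scenario": exp.scenario.name,
        "seed": exp.scenario.seed,
        "noise_fraction": exp.scenario.noise_fraction,
        "n_conformers": len(exp.true_ensemble),
        "weights": [float(w) for w in (exp.true_ensemble.weights
                                       if exp.true_ensemble.weights is not None
                                       else [])],
        "angles": [c.arm_angle for c in exp.true_ensemble.conformers],
        "angle_distribution": exp.scenario.arm_angle_distribution.kind,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
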