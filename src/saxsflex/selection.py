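"""Genetic-algorithm sub-ensemble selection and pool-vs-selected summaries.

A candidate solution (chromosome) is a multiset of ``M`` pool indices
(default 50, repetition allowed, i.e. effective weighting).  Fitness is
the reduced chi-square of the unweighted average of the member curves
against the data.  The GA keeps an elite fraction each generation, fills
the rest by tournament selection, single-point crossover and per-gene
mutation to a uniformly random pool index, and returns the best
chromosome across several independent runs.  Chromosomes are kept sorted
so equal-fitness ties break to the lexicographically smallest multiset,
making results deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .conformers import ConformerPool
from .errors import CurveError, FitError
from .fitting import FitResult, chi_squared
from .saxs import ScatteringCurve


@dataclass
class Ensemble:
    """A selected sub-ensemble: multiset of pool indices plus its fit."""

    member_indices: np.ndarray
    fit: FitResult
    generation_found: int = 0

    def __post_init__(self) -> None:
        self.member_indices = np.sort(np.asarray(self.member_indices, dtype=int))

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 1000
    elite_fraction: float = 0.1
    mutation_rate: float = 0.1
    tournament_size: int = 2
    n_repeats: int = 10
    convergence_tol: float = 1e-4
    convergence_window: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class DistributionSummary:
    """Pool-vs-selected descriptor distributions and peak structure."""

    rg_hist_pool: tuple[np.ndarray, np.ndarray]
    rg_hist_selected: tuple[np.ndarray, np.ndarray]
    dmax_hist_pool: tuple[np.ndarray, np.ndarray]
    dmax_hist_selected: tuple[np.ndarray, np.ndarray]
    end_to_end_hist_pool: tuple[np.ndarray, np.ndarray]
    end_to_end_hist_selected: tuple[np.ndarray, np.ndarray]
    rg_rms_pool: float
    rg_rms_selected: float
    peak_count_selected: int
    peak_ratio: float | None
    peak_positions: list[float] = field(default_factory=list)
    peak_masses: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Ensemble curve arithmetic
# ---------------------------------------------------------------------------

def _pool_curves(pool: ConformerPool) -> tuple[np.ndarray, np.ndarray]:
    if pool.curves is None:
        raise CurveError(
            "pool has no cached curves; run saxs.compute_pool_curves(pool, q) first")
    return pool.curves


def ensemble_average_curve(pool: ConformerPool, members) -> ScatteringCurve:
    """Unweighted mean of member curves (repeats count multiply)."""
    q, curves = _pool_curves(pool)
    indices = members.member_indices if isinstance(members, Ensemble) else \
        np.asarray(members, dtype=int)
    if indices.size == 0:
        raise ValueError("ensemble has no members")
    return ScatteringCurve(q, curves[indices].mean(axis=0),
                           label="ensemble average")


def ensemble_rg_rms(rg_values) -> float:
    """Root of the mean of squared Rg values (ensemble-average Rg)."""
    rg = np.asarray(rg_values, dtype=float)
    if rg.size == 0:
        raise ValueError("empty Rg list")
    if np.any(rg < 0):
        raise ValueError("Rg values must be non-negative")
    return float(np.sqrt(np.mean(rg**2)))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _population_fitness(population: np.ndarray, curves: np.ndarray,
                        data: ScatteringCurve) -> np.ndarray:
    """Vectorized reduced chi-square for every chromosome in a population."""
    avg = curves[population].mean(axis=1)  # (pop, nq)
    s2 = data.sigma**2
    num = (avg * data.intensity / s2).sum(axis=1)
    den = (avg**2 / s2).sum(axis=1)
    mu = num / den
    resid = (mu[:, None] * avg - data.intensity) / data.sigma
    return (resid**2).sum(axis=1) / (len(data) - 1)


def _ga_run(curves: np.ndarray, data: ScatteringCurve, m: int,
            cfg: GAConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, float, int]:
    n_pool = curves.shape[0]
    pop = np.sort(rng.integers(0, n_pool, size=(cfg.population_size, m)), axis=1)
    n_elite = max(1, int(round(cfg.elite_fraction * cfg.population_size)))
    best_chrom, best_fit, best_gen = None, np.inf, 0
    history: list[float] = []
    for gen in range(cfg.generations):
        fit = _population_fitness(pop, curves, data)
        order = sorted(range(len(pop)), key=lambda i: (fit[i], tuple(pop[i])))
        leader = order[0]
        if fit[leader] < best_fit - 1e-15:
            best_chrom, best_fit, best_gen = pop[leader].copy(), float(fit[leader]), gen
        elif (math.isclose(fit[leader], best_fit) and best_chrom is not None
              and tuple(pop[leader]) < tuple(best_chrom)):
            # deterministic tie-break; not a fitness improvement
            best_chrom, best_fit = pop[leader].copy(), float(fit[leader])
        history.append(best_fit)
        if (len(history) > cfg.convergence_window and
                history[-cfg.convergence_window - 1] - best_fit < cfg.convergence_tol):
            break
        elites = pop[order[:n_elite]]
        n_child = cfg.population_size - n_elite
        # tournament selection of two parents per child
        cand = rng.integers(0, cfg.population_size, size=(n_child, 2, cfg.tournament_size))
        winners = cand[np.arange(n_child)[:, None], [0, 1],
                       np.argmin(fit[cand], axis=2)]
        p1, p2 = pop[winners[:, 0]], pop[winners[:, 1]]
        # single-point crossover on sorted chromosomes
        cut = rng.integers(1, m, size=n_child) if m > 1 else np.zeros(n_child, int)
        mask = np.arange(m)[None, :] < cut[:, None]
        children = np.where(mask, p1, p2)
        mut = rng.random(size=children.shape) < cfg.mutation_rate
        children[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
        children.sort(axis=1)
        pop = np.vstack([elites, children])
    return best_chrom, best_fit, best_gen


def ga_select(pool: ConformerPool, data_curve: ScatteringCurve, m: int = 50,
              config: GAConfig | None = None) -> Ensemble:
    """Select the size-``m`` sub-ensemble best fitting the data.

    Requires pool curves cached on the data grid (see
    :func:`saxsflex.saxs.compute_pool_curves`).  Deterministic given
    ``config.seed``.
    """
    cfg = config or GAConfig()
    if len(pool) == 0:
        raise ValueError("empty pool")
    if data_curve.sigma is None:
        raise FitError("data curve lacks uncertainties (sigma)")
    q, curves = _pool_curves(pool)
    if len(q) != len(data_curve) or not np.allclose(q, data_curve.q,
                                                    rtol=1e-9, atol=1e-12):
        raise CurveError("pool curves were cached on a different q grid than the data")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    best = None
    for child in children:
        chrom, fit, gen = _ga_run(curves, data_curve, m, cfg,
                                  np.random.default_rng(child))
        key = (fit, tuple(chrom))
        if best is None or key < best[0]:
            best = (key, chrom, gen)
    _, chrom, gen = best
    avg = ensemble_average_curve(pool, chrom).with_label(f"ensemble[{m}]")
    return Ensemble(member_indices=chrom, fit=chi_squared(avg, data_curve),
                    generation_found=gen)


# ---------------------------------------------------------------------------
# Distribution summaries and shape classification
# ---------------------------------------------------------------------------

def _shared_hist(pool_vals: np.ndarray, sel_vals: np.ndarray, n_bins: int):
    lo = min(pool_vals.min(), sel_vals.min())
    hi = max(pool_vals.max(), sel_vals.max())
    pad = max((hi - lo) * 0.02, 1e-6)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    hp, _ = np.histogram(pool_vals, bins=edges)
    hs, _ = np.histogram(sel_vals, bins=edges)
    return edges, hp / hp.sum(), hs / hs.sum()


def _detect_peaks(masses: np.ndarray, bandwidth: float,
                  rel_height: float = 0.05):
    """Peaks of the kernel-smoothed histogram; returns (indices, smoothed)."""
    smoothed = gaussian_filter1d(masses, sigma=bandwidth, mode="constant")
    padded = np.r_[0.0, smoothed, 0.0]
    peaks, _ = find_peaks(padded, height=rel_height * padded.max())
    return peaks - 1, smoothed


@dataclass
class PeakAnalysis:
    """Peak structure of a (selected-descriptor) histogram."""

    peak_count: int
    positions: list[float]
    masses: list[float]          # [low-side, high-side] when >= 2 peaks
    ratio: float | None          # larger peak mass / smaller, when bimodal


def analyze_peaks(values, n_bins: int = 40, smooth_bandwidth: float = 2.0,
                  value_range: tuple[float, float] | None = None) -> PeakAnalysis:
    """Detect peaks of a sample's kernel-smoothed histogram.

    When >= 2 peaks are found the histogram is split at the minimum
    between the two largest and the mass on each side is reported
    (low-Rg side first).  Useful for pooling selected members across
    independent runs before the peak readout.
    """
    values = np.asarray(values, dtype=float)
    if value_range is None:
        pad = max((values.max() - values.min()) * 0.02, 1e-6)
        value_range = (values.min() - pad, values.max() + pad)
    edges = np.linspace(value_range[0], value_range[1], n_bins + 1)
    hist, _ = np.histogram(values, bins=edges)
    hist = hist / hist.sum()
    return _analyze_hist(hist, edges, smooth_bandwidth)


def _analyze_hist(hist: np.ndarray, edges: np.ndarray,
                  smooth_bandwidth: float) -> PeakAnalysis:
    peaks, smoothed = _detect_peaks(hist, smooth_bandwidth)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(peaks) == 0:  # degenerate (all mass in one bin after smoothing)
        peaks = np.array([int(np.argmax(hist))])
    ratio = None
    masses: list[float] = []
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(smoothed[peaks])[::-1][:2]]
        a, b = np.sort(top2)
        valley = a + int(np.argmin(smoothed[a:b + 1]))
        mass_left, mass_right = float(hist[:valley].sum()), float(hist[valley:].sum())
        big, small = max(mass_left, mass_right), min(mass_left, mass_right)
        ratio = big / small if small > 0 else float("inf")
        masses = [mass_left, mass_right]
    return PeakAnalysis(peak_count=int(len(peaks)),
                        positions=[float(centers[p]) for p in peaks],
                        masses=masses, ratio=ratio)


def summarize_distributions(pool: ConformerPool, ensemble: Ensemble,
                            n_bins: int = 40,
                            smooth_bandwidth: float = 2.0) -> DistributionSummary:
    """Pool-vs-selected histograms (shared binning) plus selected-Rg peaks.

    Peak detection runs on the kernel-smoothed selected-Rg histogram
    (Gaussian bandwidth in bins); local maxima above 5% of the global
    maximum count as peaks.  When >= 2 peaks are present, the histogram
    is split at the minimum between the two largest peaks and
    ``peak_ratio`` is the larger peak mass over the smaller.
    """
    idx = ensemble.member_indices
    rg_p, rg_s = pool.descriptor("rg"), pool.descriptor("rg")[idx]
    dm_p, dm_s = pool.descriptor("dmax"), pool.descriptor("dmax")[idx]
    ee_p, ee_s = pool.descriptor("end_to_end"), pool.descriptor("end_to_end")[idx]

    rg_edges, rg_hp, rg_hs = _shared_hist(rg_p, rg_s, n_bins)
    dm_edges, dm_hp, dm_hs = _shared_hist(dm_p, dm_s, n_bins)
    ee_edges, ee_hp, ee_hs = _shared_hist(ee_p, ee_s, n_bins)

    pa = _analyze_hist(rg_hs, rg_edges, smooth_bandwidth)
    return DistributionSummary(
        rg_hist_pool=(rg_edges, rg_hp), rg_hist_selected=(rg_edges, rg_hs),
        dmax_hist_pool=(dm_edges, dm_hp), dmax_hist_selected=(dm_edges, dm_hs),
        end_to_end_hist_pool=(ee_edges, ee_hp),
        end_to_end_hist_selected=(ee_edges, ee_hs),
        rg_rms_pool=ensemble_rg_rms(rg_p), rg_rms_selected=ensemble_rg_rms(rg_s),
        peak_count_selected=pa.peak_count, peak_ratio=pa.ratio,
        peak_positions=pa.positions, peak_masses=pa.masses)


def classify_shapes(conformers) -> dict[str, float]:
    """Fractions of L/U/I shape classes over a set of conformers.

    Accepts a :class:`ConformerPool` or any iterable of conformers.
    """
    if isinstance(conformers, ConformerPool):
        conformers = conformers.conformers
    conformers = list(conformers)
    if not conformers:
        raise ValueError("no conformers to classify")
    classes = [c.shape_class for c in conformers]
    if any(cl is None for cl in classes):
        raise ValueError("conformer(s) missing arm_angle/shape_class "
                         "(topology has fewer than two rigid segments?)")
    n = len(classes)
    return {k: classes.count(k) / n for k in ("L", "U", "I")}
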