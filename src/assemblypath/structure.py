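"""Simplified bead-level structural models of snapshots and their scoring.

Each subcomplex instance occupying a site is represented by one spherical bead
(mass weight = total protein copies per instance).  Snapshot structures are
scored by a sum of an excluded-volume penalty, a native-biased (Go-like) term
toward the mature inter-site distances, and a density-fit term
``w_cc * (1 - CC)`` against the time point's map.  Metropolis Monte Carlo over
bead translations produces an ensemble of models per snapshot; the snapshot's
summary score averages Boltzmann factors over the good-scoring subset, and
sampling exhaustiveness is checked with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist
from scipy.special import logsumexp

from .density import DensityGrid, add_bead_density, cross_correlation, simulate_density
from .system import AssemblySystem, Composition

__all__ = [
    "Bead",
    "BeadModel",
    "StructureEnsemble",
    "McParams",
    "bead_model_from_composition",
    "excluded_volume_penalty",
    "go_restraint_score",
    "rmsd_to_reference",
    "snapshot_energy",
    "mc_sample_snapshot",
    "ks_exhaustiveness",
    "KsResult",
    "ensemble_precision",
]

DEFAULT_BEAD_RADIUS = 1.2


@dataclass(frozen=True)
class Bead:
    site_id: str
    center: tuple[float, float, float]
    radius: float = DEFAULT_BEAD_RADIUS
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))
        if not self.radius > 0:
            raise ValueError(f"bead {self.site_id!r}: radius must be > 0")
        if not self.weight > 0:
            raise ValueError(f"bead {self.site_id!r}: weight must be > 0")


@dataclass(frozen=True)
class BeadModel:
    """One structural model: one bead per occupied site of the modeled spoke."""

    beads: tuple[Bead, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))
        ids = [b.site_id for b in self.beads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_id among beads")

    def __len__(self) -> int:
        return len(self.beads)

    def centers(self) -> np.ndarray:
        if not self.beads:
            return np.zeros((0, 3))
        return np.asarray([b.center for b in self.beads], dtype=float)

    def with_centers(self, centers: np.ndarray) -> "BeadModel":
        centers = np.asarray(centers, dtype=float)
        return BeadModel(
            tuple(
                Bead(b.site_id, tuple(c), b.radius, b.weight)
                for b, c in zip(self.beads, centers)
            )
        )


def bead_model_from_composition(
    comp: Composition,
    system: AssemblySystem,
    radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadModel:
    """Beads at the mature reference positions of the occupied sites."""
    if comp.assigned_sites is None:
        raise ValueError("composition has no site assignment")
    beads = []
    for sid in sorted(comp.assigned_sites):
        site = system.site_by_id(sid)
        weight = float(sum(system.type_by_id(site.type_id).stoichiometry.values()))
        beads.append(Bead(sid, site.position, radius, weight))
    return BeadModel(tuple(beads))


# -- restraint terms --------------------------------------------------------


def excluded_volume_penalty(model: BeadModel, k_ev: float = 1.0) -> float:
    """Soft-sphere overlap penalty: sum of k_ev * max(0, r_i + r_j - d_ij)^2."""
    n = len(model)
    if n < 2:
        return 0.0
    centers = model.centers()
    radii = np.asarray([b.radius for b in model.beads])
    d = pdist(centers)
    overlap = np.maximum(0.0, _radius_sums(radii) - d)
    return float(k_ev * np.sum(overlap**2))


def go_restraint_score(
    model: BeadModel, system: AssemblySystem, k_go: float = 1.0
) -> float:
    """Native-biased term: k_go * (d_ij - d_ij^native)^2 over bead pairs.

    Native distances come from the occupied sites' mature reference positions;
    the score is zero exactly when all pairwise distances match the mature
    structure.
    """
    n = len(model)
    if n < 2:
        return 0.0
    centers = model.centers()
    native = np.asarray([system.site_position(b.site_id) for b in model.beads])
    d = pdist(centers)
    d_native = pdist(native)
    return float(k_go * np.sum((d - d_native) ** 2))


def rmsd_to_reference(model: BeadModel, system: AssemblySystem) -> float:
    """RMSD of bead centers to their sites' mature positions, no superposition.

    The laboratory frame is fixed by the density maps, so deviations are
    measured in that common frame.
    """
    if not model.beads:
        raise ValueError("RMSD undefined for an empty model")
    centers = model.centers()
    native = np.asarray([system.site_position(b.site_id) for b in model.beads])
    return float(np.sqrt(np.mean(np.sum((centers - native) ** 2, axis=1))))


# -- snapshot energy and Monte Carlo ----------------------------------------


@dataclass(frozen=True)
class McParams:
    """Tunable knobs of the snapshot Monte Carlo and summary score."""

    n_steps: int = 120
    n_models: int = 4
    w_cc: float = 200.0
    k_ev: float = 1.0
    k_go: float = 5.0
    k_anchor: float = 10.0  # harmonic tether to the assigned site's position
    temperature: float = 0.15
    step_scale: float = 0.4  # proposal SD in units of voxel spacing
    tau: float = 1.0  # Boltzmann scale of the summary score
    good_fraction: float = 0.5  # energy quantile defining the good-scoring subset
    bead_radius: float = DEFAULT_BEAD_RADIUS
    init: str = "reference"  # or "random": uniform inside the grid box

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_models < 1:
            raise ValueError("n_steps and n_models must be >= 1")
        if self.init not in ("reference", "random"):
            raise ValueError(f"unknown init mode {self.init!r}")
        if not 0 < self.good_fraction <= 1:
            raise ValueError("good_fraction must be in (0, 1]")


@dataclass
class StructureEnsemble:
    """Sampled structural models of one snapshot with energies and summary.

    The summary score averages ``exp(-E / tau)`` over the good-scoring subset
    (the best ``good_fraction`` of models by energy); ``log_score`` is that
    average in log space, safe against underflow.
    """

    snapshot_id: str
    models: list[tuple[BeadModel, float]]
    good_mask: np.ndarray
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.good_mask = np.asarray(self.good_mask, dtype=bool)
        if len(self.models) != self.good_mask.size:
            raise ValueError("good_mask length mismatch")
        if self.models and not self.good_mask.any():
            raise ValueError("good-scoring subset empty for non-empty ensemble")

    @property
    def energies(self) -> np.ndarray:
        return np.asarray([e for _, e in self.models], dtype=float)

    @property
    def good_models(self) -> list[tuple[BeadModel, float]]:
        return [me for me, g in zip(self.models, self.good_mask) if g]

    @property
    def log_score(self) -> float:
        if not self.models:
            return 0.0
        e = self.energies[self.good_mask]
        return float(logsumexp(-e / self.tau) - math.log(e.size))

    @property
    def score(self) -> float:
        return math.exp(self.log_score)

    @property
    def best_model(self) -> BeadModel:
        if not self.models:
            raise ValueError("empty ensemble")
        idx = int(np.argmin(self.energies))
        return self.models[idx][0]


def site_anchor_penalty(
    model: BeadModel, system: AssemblySystem, k_anchor: float = 1.0
) -> float:
    """Harmonic tether of each bead to its assigned site's reference position.

    The laboratory frame is fixed by the density maps, so site assignments are
    absolute; without this term a lone bead's location assignment is a gauge
    freedom the density fit can silently re-assign.  Zero at the reference
    configuration.
    """
    if not model.beads:
        return 0.0
    centers = model.centers()
    native = np.asarray([system.site_position(b.site_id) for b in model.beads])
    return float(k_anchor * np.sum((centers - native) ** 2))


def snapshot_energy(
    model: BeadModel,
    system: AssemblySystem,
    target: DensityGrid,
    params: McParams,
    model_density: DensityGrid | None = None,
) -> float:
    """E = w_cc * (1 - CC) + excluded volume + Go-like term + site anchor."""
    if model_density is None:
        model_density = simulate_density(model, target)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cc = cross_correlation(model_density, target)
    return (
        params.w_cc * (1.0 - cc)
        + excluded_volume_penalty(model, params.k_ev)
        + go_restraint_score(model, system, params.k_go)
        + site_anchor_penalty(model, system, params.k_anchor)
    )


class _CorrTracker:
    """Pearson CC of a mutable model grid against a fixed target, O(block) updates."""

    def __init__(self, model: DensityGrid, target: DensityGrid):
        self.grid = model
        self.t = target.data.ravel()
        self.n = self.t.size
        self.t_sum = float(self.t.sum())
        self.t_var = float(np.dot(self.t, self.t)) - self.t_sum**2 / self.n
        d = model.data.ravel()
        self.d_sum = float(d.sum())
        self.d_sq = float(np.dot(d, d))
        self.dt = float(np.dot(d, self.t))
        self.target = target

    def cc(self) -> float:
        d_var = self.d_sq - self.d_sum**2 / self.n
        denom = math.sqrt(max(d_var, 0.0) * max(self.t_var, 0.0))
        if denom <= 0.0:
            return 0.0
        cov = self.dt - self.d_sum * self.t_sum / self.n
        return cov / denom

    def move_bead(self, old_center: np.ndarray, new_center: np.ndarray, radius: float, weight: float) -> None:
        for center, sign in ((old_center, -1.0), (new_center, 1.0)):
            before = self._block_stats(center, radius)
            add_bead_density(self.grid, center, radius, weight, sign=sign)
            after = self._block_stats(center, radius)
            self.d_sum += after[0] - before[0]
            self.d_sq += after[1] - before[1]
            self.dt += after[2] - before[2]

    def _block_stats(self, center: np.ndarray, radius: float) -> tuple[float, float, float]:
        from .density import GAUSS_TRUNCATION_SIGMAS

        g = self.grid
        cutoff = GAUSS_TRUNCATION_SIGMAS * radius
        lo = np.maximum(np.ceil((center - cutoff - g.origin) / g.spacing), 0).astype(int)
        hi = np.minimum(
            np.floor((center + cutoff - g.origin) / g.spacing), np.asarray(g.shape) - 1
        ).astype(int)
        if np.any(hi < lo):
            return (0.0, 0.0, 0.0)
        sl = tuple(slice(lo[a], hi[a] + 1) for a in range(3))
        block = g.data[sl]
        tblock = self.target.data[sl]
        return (float(block.sum()), float((block**2).sum()), float((block * tblock).sum()))


def _radius_sums(radii: np.ndarray) -> np.ndarray:
    """Condensed-form (pdist-ordered) pairwise sums r_i + r_j."""
    n = radii.size
    if n < 2:
        return np.zeros(0)
    i, j = np.triu_indices(n, k=1)
    return radii[i] + radii[j]


def _pair_energy(
    centers: np.ndarray,
    native: np.ndarray,
    d_native: np.ndarray,
    rsum: np.ndarray,
    params: McParams,
) -> float:
    anchor = params.k_anchor * float(np.sum((centers - native) ** 2))
    if centers.shape[0] < 2:
        return anchor
    d = pdist(centers)
    overlap = np.maximum(0.0, rsum - d)
    ev = params.k_ev * float(np.sum(overlap**2))
    go = params.k_go * float(np.sum((d - d_native) ** 2))
    return ev + go + anchor


def mc_sample_snapshot(
    comp: Composition,
    system: AssemblySystem,
    target: DensityGrid,
    params: McParams = McParams(),
    seed: int = 0,
    snapshot_id: str = "",
) -> StructureEnsemble:
    """Metropolis Monte Carlo over bead translations for one snapshot.

    ``params.n_models`` independent chains (seeded from ``seed``) each run
    ``params.n_steps`` single-bead translation moves; the best-energy state of
    each chain is recorded.  An empty composition yields a single empty model
    with energy 0.
    """
    if comp.assigned_sites is None:
        raise ValueError("composition needs a site assignment before structural sampling")
    template = bead_model_from_composition(comp, system, radius=params.bead_radius)
    if not template.beads:
        # constant (all-zero) model density: CC convention is 0, so the
        # density term contributes its full weight and the rest vanish
        empty = BeadModel(())
        return StructureEnsemble(
            snapshot_id, [(empty, params.w_cc)], np.array([True]), params.tau
        )

    native = np.asarray([system.site_position(b.site_id) for b in template.beads])
    radii = np.asarray([b.radius for b in template.beads])
    weights = np.asarray([b.weight for b in template.beads])
    d_native = pdist(native) if len(template) > 1 else np.zeros(0)
    rsum = _radius_sums(radii)
    n_beads = len(template)
    box_lo = target.origin
    box_hi = target.origin + (np.asarray(target.shape) - 1) * target.spacing
    step_sd = params.step_scale * target.spacing

    models: list[tuple[BeadModel, float]] = []
    for chain in range(params.n_models):
        rng = np.random.default_rng([int(seed), chain])
        if params.init == "reference":
            centers = native.copy()
        else:
            centers = rng.uniform(box_lo, box_hi, size=(n_beads, 3))
        model = template.with_centers(centers)
        dens = simulate_density(model, target)
        tracker = _CorrTracker(dens, target)
        pair_e = _pair_energy(centers, native, d_native, rsum, params)
        energy = params.w_cc * (1.0 - tracker.cc()) + pair_e
        best_centers, best_energy = centers.copy(), energy

        for _ in range(params.n_steps):
            i = int(rng.integers(n_beads))
            delta = rng.normal(0.0, step_sd, size=3)
            old = centers[i].copy()
            new = old + delta
            tracker.move_bead(old, new, radii[i], weights[i])
            centers[i] = new
            new_pair = _pair_energy(centers, native, d_native, rsum, params)
            new_energy = params.w_cc * (1.0 - tracker.cc()) + new_pair
            d_e = new_energy - energy
            if d_e <= 0 or rng.random() < math.exp(-d_e / params.temperature):
                energy, pair_e = new_energy, new_pair
                if energy < best_energy:
                    best_energy, best_centers = energy, centers.copy()
            else:
                tracker.move_bead(new, old, radii[i], weights[i])
                centers[i] = old
        models.append((template.with_centers(best_centers), float(best_energy)))

    energies = np.asarray([e for _, e in models])
    cutoff = np.quantile(energies, params.good_fraction)
    good = energies <= cutoff
    if not good.any():  # numerical guard; quantile always admits the minimum
        good[int(np.argmin(energies))] = True
    return StructureEnsemble(snapshot_id, models, good, params.tau)


def ensemble_precision(ensemble: StructureEnsemble) -> float:
    """Structural precision: mean pairwise RMSD within the good-scoring subset."""
    good = [m for m, _ in ensemble.good_models if len(m)]
    if len(good) < 2:
        return 0.0
    rmsds = []
    for i in range(len(good)):
        for j in range(i + 1, len(good)):
            diff = good[i].centers() - good[j].centers()
            rmsds.append(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return float(np.mean(rmsds))


# -- sampling exhaustiveness -------------------------------------------------


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float
    passed: bool
    small_sample: bool = False


def ks_exhaustiveness(
    scores_a,
    scores_b,
    alpha: float = 0.05,
    d_max: float = 0.3,
) -> KsResult:
    """Two-sample KS check that two samplings share a score distribution.

    Passes when the asymptotic p-value exceeds ``alpha`` (no significant
    difference) and the KS statistic D is below ``d_max`` (small in magnitude).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score samples must be non-empty")
    small = a.size < 5 or b.size < 5
    if small:
        warnings.warn("KS exhaustiveness with < 5 samples is unreliable", stacklevel=2)
    res = stats.ks_2samp(a, b, method="asymp")
    d, p = float(res.statistic), float(res.pvalue)
    return KsResult(d, p, passed=bool(p > alpha and d < d_max), small_sample=small)
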