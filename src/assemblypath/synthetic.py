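"""Synthetic benchmark generator: systems, pathways, copy numbers, maps.

Generates self-consistent inputs for the whole pipeline: a symmetric toy
complex with ring-like site geometry, a ground-truth monotone assembly
pathway, Gaussian-noised per-protein copy-number curves (FCS-like), and
density volumes rendered from the ground-truth bead configurations (ET-like).
An NPC-flavoured preset mirrors the pore's organisation: five subcomplex
types (Y-complex, channel, connecting, and the two inner-ring complexes),
8-fold symmetry, time points at 5, 6, 8, 10 and 15 minutes plus the mature
state, with the inner-ring ordering constraint and two held-out proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityGrid, simulate_density
from .structure import BeadModel, bead_model_from_composition, DEFAULT_BEAD_RADIUS
from .system import AssemblySystem, Composition, CopyNumberSeries, Site, SubcomplexType

__all__ = [
    "GroundTruth",
    "generate_system",
    "npc_like_system",
    "NPC_TIME_LABELS",
    "grid_for_system",
    "generate_pathway",
    "simulate_copy_numbers",
    "simulate_maps",
]

NPC_TIME_LABELS = ("5", "6", "8", "10", "15", "mature")


@dataclass
class GroundTruth:
    """A complete synthetic study: system, true pathway, noise settings, seed."""

    system: AssemblySystem
    time_labels: tuple[str, ...]
    compositions: dict[str, Composition]
    bead_models: dict[str, BeadModel]
    copy_noise_sd: float = 0.0
    density_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_labels = tuple(self.time_labels)
        prev: Composition | None = None
        for t in self.time_labels:
            comp = self.compositions[t]
            if prev is not None and not prev.is_subset_of(comp):
                raise ValueError(f"ground-truth pathway not nested at time {t!r}")
            prev = comp
        final = self.compositions[self.time_labels[-1]]
        if final.assigned_sites != frozenset(s.site_id for s in self.system.sites):
            raise ValueError("final ground-truth composition is not the full complex")


def generate_system(
    n_types: int = 3,
    sites_per_type: int = 2,
    symmetry_order: int = 4,
    seed: int = 0,
    ring_radius: float = 10.0,
) -> AssemblySystem:
    """A reproducible toy system with sites on rings (pore-like geometry).

    Each type carries one protein at unit stoichiometry.  Sites of one spoke
    sit within an arc of ``2*pi/symmetry_order``, on a ring of type-dependent
    radius and height, so distinct site assignments render distinct densities.
    """
    if n_types < 1 or sites_per_type < 1 or symmetry_order < 1:
        raise ValueError("n_types, sites_per_type and symmetry_order must be positive")
    del seed  # geometry is deterministic; kept for interface symmetry
    arc = 2.0 * math.pi / symmetry_order
    types, sites = [], []
    for ti in range(n_types):
        tid = f"type{ti}"
        types.append(SubcomplexType(tid, {f"protein{ti}": 1}))
        radius = ring_radius + 2.5 * ti
        z = 3.0 * (ti - (n_types - 1) / 2.0)
        for si in range(sites_per_type):
            theta = arc * (si + 0.5) / sites_per_type
            sites.append(
                Site(
                    f"{tid}_s{si}",
                    tid,
                    (radius * math.cos(theta), radius * math.sin(theta), z),
                )
            )
    return AssemblySystem(tuple(types), tuple(sites), symmetry_order)


def _ring_site(sid: str, tid: str, r: float, theta_deg: float, z: float) -> Site:
    th = math.radians(theta_deg)
    return Site(sid, tid, (r * math.cos(th), r * math.sin(th), z))


def npc_like_system() -> AssemblySystem:
    """The NPC-flavoured preset: one spoke of an 8-fold symmetric pore.

    Types and per-instance stoichiometry:
      y_complex (4 sites, Nup107 + Seh1), channel (4 sites, Nup62),
      connecting (1 site, Nup93), nup205_complex (2 sites, Nup205 + Nup93),
      nup188_complex (2 sites, Nup188 + Nup93).
    Ordering constraint: count(nup205_complex) >= count(nup188_complex).
    Nup188 and Seh1 are the conventional held-out proteins.
    """
    types = (
        SubcomplexType("y_complex", {"Nup107": 1, "Seh1": 1}),
        SubcomplexType("channel", {"Nup62": 1}),
        SubcomplexType("connecting", {"Nup93": 1}),
        SubcomplexType("nup205_complex", {"Nup205": 1, "Nup93": 1}),
        SubcomplexType("nup188_complex", {"Nup188": 1, "Nup93": 1}),
    )
    sites = (
        # two nuclear- and two cytoplasmic-ring Y positions
        _ring_site("y_nuc_1", "y_complex", 12.0, 8.0, -5.0),
        _ring_site("y_nuc_2", "y_complex", 12.0, 32.0, -5.0),
        _ring_site("y_cyt_1", "y_complex", 12.0, 8.0, 5.0),
        _ring_site("y_cyt_2", "y_complex", 12.0, 32.0, 5.0),
        # central channel
        _ring_site("chan_1", "channel", 7.0, 10.0, -2.5),
        _ring_site("chan_2", "channel", 7.0, 34.0, -2.5),
        _ring_site("chan_3", "channel", 7.0, 10.0, 2.5),
        _ring_site("chan_4", "channel", 7.0, 34.0, 2.5),
        _ring_site("conn_1", "connecting", 10.5, 21.0, 0.0),
        _ring_site("n205_1", "nup205_complex", 12.0, 12.0, -2.2),
        _ring_site("n205_2", "nup205_complex", 12.0, 30.0, -2.2),
        _ring_site("n188_1", "nup188_complex", 12.0, 12.0, 2.2),
        _ring_site("n188_2", "nup188_complex", 12.0, 30.0, 2.2),
    )
    return AssemblySystem(
        types, sites, symmetry_order=8,
        ordering_constraints=(("nup205_complex", "nup188_complex"),),
    )


def grid_for_system(
    system: AssemblySystem, spacing: float = 1.0, margin: float = 4.0
) -> DensityGrid:
    """An empty grid whose box covers all site positions plus a margin."""
    pos = np.asarray([s.position for s in system.sites], dtype=float)
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return DensityGrid(lo, spacing, np.zeros(tuple(shape)))


def generate_pathway(
    system: AssemblySystem,
    time_labels,
    seed: int = 0,
    enumerated_types=(),
    assignment_seed: int = 0,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> GroundTruth:
    """A random strictly monotone chain of site sets ending at the full complex.

    The per-type instance counts grow along a random order of addition
    (rejection-sampled so every composition honours the system's ordering
    constraints).  Types in ``enumerated_types`` occupy randomly chosen,
    nested site subsets — the identifiable location assignments a sampler can
    recover.  All other multi-site types fill their sites in the seeded
    conventional order of :func:`~assemblypath.composition.site_fill_orders`
    with ``assignment_seed``: which specific same-type site such an instance
    occupies is a gauge choice, so the generator and any inference run sharing
    ``assignment_seed`` agree on it by convention.  Adjacent compositions are
    nested, so every step satisfies the subset transition rule; the true bead
    model at each time point puts beads at the occupied sites' reference
    positions.
    """
    from .composition import site_fill_orders

    time_labels = tuple(str(t) for t in time_labels)
    if len(time_labels) < 2:
        raise ValueError("need at least two time labels")
    rng = np.random.default_rng(seed)
    n = len(system.sites)
    if n < len(time_labels):
        raise ValueError("fewer sites than time labels; cannot grow strictly")
    enumerated = set(enumerated_types)
    unknown = enumerated - set(system.type_ids)
    if unknown:
        raise ValueError(f"enumerated_types not in system: {sorted(unknown)}")

    slots = [s.type_id for s in system.sites]
    count_vectors: list[dict[str, int]] | None = None
    for _ in range(10_000):
        order = [slots[i] for i in rng.permutation(n)]
        interior = sorted(
            rng.choice(np.arange(1, n), size=len(time_labels) - 1, replace=False)
        )
        sizes = [int(k) for k in interior] + [n]
        vectors = []
        for size in sizes:
            counts = {tid: 0 for tid in system.type_ids}
            for tid in order[:size]:
                counts[tid] += 1
            if not all(counts[a] >= counts[b] for a, b in system.ordering_constraints):
                break
            vectors.append(counts)
        else:
            count_vectors = vectors
            break
    if count_vectors is None:
        raise RuntimeError("could not sample a constraint-satisfying pathway")

    fill = site_fill_orders(system, assignment_seed)
    occupied: dict[str, list[str]] = {tid: [] for tid in system.type_ids}
    compositions, bead_models = {}, {}
    for t, counts in zip(time_labels, count_vectors):
        for tid in system.type_ids:
            need = counts[tid] - len(occupied[tid])
            if need <= 0:
                continue
            if tid in enumerated:
                pool = [
                    s.site_id
                    for s in system.sites_of_type(tid)
                    if s.site_id not in occupied[tid]
                ]
                picks = rng.choice(len(pool), size=need, replace=False)
                occupied[tid].extend(pool[i] for i in sorted(int(i) for i in picks))
            else:
                occupied[tid] = list(fill[tid][: counts[tid]])
        site_ids = [sid for ids in occupied.values() for sid in ids]
        comp = Composition.from_sites(system, t, site_ids)
        compositions[t] = comp
        bead_models[t] = bead_model_from_composition(comp, system, radius=bead_radius)
    return GroundTruth(system, time_labels, compositions, bead_models, seed=seed)


def simulate_copy_numbers(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    heldout_proteins=(),
) -> CopyNumberSeries:
    """FCS-like copy-number table: replicate-averaged noisy true copies.

    Per protein and time point, ``n_replicates`` noisy measurements (true
    copies + Gaussian noise of SD ``noise_sd``) are averaged; the reported SD
    is the replicate sample SD.  ``noise_sd = 0`` reproduces the true copies
    exactly with SD 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates for an empirical SD")
    rng = np.random.default_rng(seed)
    held = set(heldout_proteins)
    unknown = held - set(truth.system.proteins)
    if unknown:
        raise ValueError(f"held-out proteins not in system: {sorted(unknown)}")
    rows = []
    for t in truth.time_labels:
        copies = truth.compositions[t].copy_numbers(truth.system)
        for p in truth.system.proteins:
            reps = copies[p] + rng.normal(0.0, noise_sd, size=n_replicates)
            if noise_sd == 0.0:
                mean, sd = float(copies[p]), 0.0
            else:
                mean, sd = float(reps.mean()), float(reps.std(ddof=1))
            rows.append(
                {
                    "time_min": t,
                    "protein": p,
                    "mean": mean,
                    "sd": sd,
                    "held_out": p in held,
                }
            )
    return CopyNumberSeries(pd.DataFrame(rows), time_order=truth.time_labels)


def simulate_maps(
    truth: GroundTruth,
    template: DensityGrid | None = None,
    noise_level: float = 0.0,
    seed: int = 0,
    spacing: float = 1.0,
) -> dict[str, DensityGrid]:
    """ET-like maps: true bead densities plus i.i.d. Gaussian voxel noise.

    ``noise_level`` scales the noise SD relative to the peak of each clean
    map (0.05 = 5% of peak).  Same seed, same volumes.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if template is None:
        template = grid_for_system(truth.system, spacing=spacing)
    rng = np.random.default_rng(seed)
    out: dict[str, DensityGrid] = {}
    for t in truth.time_labels:
        clean = simulate_density(truth.bead_models[t], template)
        data = clean.data
        if noise_level > 0:
            peak = float(data.max())
            if peak > 0:
                data = data + rng.normal(0.0, noise_level * peak, size=data.shape)
        out[t] = DensityGrid(template.origin.copy(), template.spacing, data)
    return out
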