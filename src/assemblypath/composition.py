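"""Enumeration and compositional scoring of candidate snapshot states.

Candidate compositions of the assembling complex are enumerated as per-type
instance-count vectors (one spoke of the symmetric complex; full copy numbers
follow by multiplying with the symmetry order), filtered by the system's
ordering constraints, and ranked by a Gaussian likelihood against measured
copy-number means and SDs.  Site assignment within a type happens after the
top-k count vectors are selected: configured types are enumerated
combinatorially, all other multi-site types are filled in a seeded random
order that is held fixed across time points.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .system import AssemblySystem, Composition, CopyNumberSeries, MissingTimePointError

__all__ = [
    "enumerate_compositions",
    "composition_likelihood",
    "select_top_compositions",
    "enumerate_site_assignments",
    "site_fill_orders",
]

#: copy-number SDs are floored at one copy before entering the likelihood, so
#: zero-variance (noiseless or plateaued) measurements stay finite.
SD_FLOOR = 1.0


def enumerate_compositions(system: AssemblySystem, time_label: str) -> list[Composition]:
    """All per-type copy-count vectors admissible under the ordering constraints.

    Site choice within a type is deferred to :func:`enumerate_site_assignments`.
    Output order is lexicographic in the copy vector (declared type order), so
    enumeration is deterministic.  A system with no sites yields the single
    empty composition.
    """
    ranges = [range(len(system.sites_of_type(tid)) + 1) for tid in system.type_ids]
    out: list[Composition] = []
    for combo in itertools.product(*ranges):
        comp = Composition(
            time_label, tuple(zip(system.type_ids, combo)), assigned_sites=None
        )
        if comp.satisfies_constraints(system):
            out.append(comp)
    return out


def composition_likelihood(
    comp: Composition,
    system: AssemblySystem,
    data: CopyNumberSeries,
    sd_floor: float = SD_FLOOR,
) -> float:
    """Log-likelihood of a composition against copy-number data at its time point.

    Independent Gaussian terms, one per scored protein, evaluated at the model
    copy number with the measured mean and (floored) SD.  Held-out proteins do
    not contribute.
    """
    if not data.has_time(comp.time_label):
        raise MissingTimePointError(
            f"time {comp.time_label!r} absent from copy-number data; snapshot unscorable"
        )
    model = comp.copy_numbers(system)
    missing = [p for p in data.scored_proteins if p not in model]
    if missing:
        raise ValueError(f"scored proteins not in system stoichiometry: {missing}")
    loglik = 0.0
    for protein in data.scored_proteins:
        mean = data.mean(protein, comp.time_label)
        sd = max(data.sd(protein, comp.time_label), sd_floor)
        loglik += stats.norm.logpdf(model[protein], loc=mean, scale=sd)
    if not math.isfinite(loglik):
        raise ValueError("non-finite compositional likelihood")
    return float(loglik)


def select_top_compositions(
    candidates: Sequence[Composition],
    system: AssemblySystem,
    data: CopyNumberSeries,
    k: int,
    sd_floor: float = SD_FLOOR,
) -> list[Composition]:
    """The ``k`` highest-likelihood copy-count vectors.

    Ties at equal likelihood are broken toward the lexicographically smaller
    copy vector, so selection is deterministic.  Fewer than ``k`` candidates
    are all returned.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    scored = [
        (composition_likelihood(c, system, data, sd_floor=sd_floor), c) for c in candidates
    ]
    scored.sort(key=lambda lc: (-lc[0], lc[1].copy_vector()))
    return [c for _, c in scored[:k]]


def site_fill_orders(
    system: AssemblySystem, seed: int
) -> dict[str, tuple[str, ...]]:
    """One seeded site order per type, shared by every call with the same seed.

    Types are shuffled in declared order from a single generator, so the fill
    order of each type is identical across time points and copy vectors —
    required for assignments of non-enumerated types to nest along a pathway.
    """
    rng = np.random.default_rng(seed)
    orders: dict[str, tuple[str, ...]] = {}
    for tid in system.type_ids:
        ids = [s.site_id for s in system.sites_of_type(tid)]
        rng.shuffle(ids)
        orders[tid] = tuple(ids)
    return orders


def enumerate_site_assignments(
    comp: Composition,
    system: AssemblySystem,
    enumerated_types: Iterable[str] = (),
    seed: int = 0,
) -> list[Composition]:
    """Expand a copy-count vector into site-assigned compositions.

    Types in ``enumerated_types`` contribute every combination of occupied
    sites; every other type is filled in the seeded order from
    :func:`site_fill_orders`.  The number of assignments is the product of
    binomial coefficients over the enumerated types.
    """
    enumerated = set(enumerated_types)
    unknown = enumerated - set(system.type_ids)
    if unknown:
        raise ValueError(f"enumerated_types not declared in system: {sorted(unknown)}")
    orders = site_fill_orders(system, seed)

    per_type_choices: list[list[tuple[str, ...]]] = []
    for tid, n in comp.type_counts:
        sites = [s.site_id for s in system.sites_of_type(tid)]
        if n > len(sites):
            raise ValueError(f"type {tid!r}: count {n} exceeds {len(sites)} available sites")
        if tid in enumerated:
            per_type_choices.append([tuple(c) for c in itertools.combinations(sites, n)])
        else:
            per_type_choices.append([orders[tid][:n]])

    out = []
    for combo in itertools.product(*per_type_choices):
        site_ids = frozenset(itertools.chain.from_iterable(combo))
        out.append(Composition(comp.time_label, comp.type_counts, site_ids))
    return out
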