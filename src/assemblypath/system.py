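"""Declarative description of the mature complex and its compositional states.

The mature complex is described by subcomplex *types* (each with a per-instance
protein stoichiometry), *sites* (specific locations a subcomplex instance can
occupy, with reference positions taken from the mature structure), a rotational
``symmetry_order`` (8 for the nuclear pore complex), and optional ordering
constraints between type counts.  One asymmetric unit (spoke) is modeled
explicitly; per-protein copy numbers are multiplied by the symmetry order.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubcomplexType",
    "Site",
    "AssemblySystem",
    "Composition",
    "CopyNumberSeries",
    "MissingTimePointError",
]


class MissingTimePointError(KeyError):
    """A snapshot references a time point absent from the copy-number data."""


@dataclass(frozen=True)
class SubcomplexType:
    """One rigid subcomplex species: id plus protein copies per instance."""

    type_id: str
    stoichiometry: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"type {self.type_id!r}: empty stoichiometry")
        for protein, copies in self.stoichiometry.items():
            if int(copies) < 1:
                raise ValueError(
                    f"type {self.type_id!r}: protein {protein!r} has copies {copies} < 1"
                )
        object.__setattr__(
            self, "stoichiometry", MappingProxyType(dict(self.stoichiometry))
        )


@dataclass(frozen=True)
class Site:
    """A location in the mature complex occupied by one subcomplex instance."""

    site_id: str
    type_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3:
            raise ValueError(f"site {self.site_id!r}: position must be length 3")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class AssemblySystem:
    """The mature complex: types, sites, symmetry and ordering constraints.

    ``ordering_constraints`` is a list of ``(type_a, type_b)`` pairs, each
    meaning ``count(type_a) >= count(type_b)`` in any admissible composition.
    """

    subcomplex_types: tuple[SubcomplexType, ...]
    sites: tuple[Site, ...]
    symmetry_order: int = 1
    ordering_constraints: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "subcomplex_types", tuple(self.subcomplex_types))
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(
            self,
            "ordering_constraints",
            tuple((a, b) for a, b in self.ordering_constraints),
        )
        if self.symmetry_order < 1:
            raise ValueError(f"symmetry_order must be >= 1, got {self.symmetry_order}")
        type_ids = [t.type_id for t in self.subcomplex_types]
        if len(set(type_ids)) != len(type_ids):
            raise ValueError("duplicate type_id in subcomplex_types")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site_id in sites")
        known = set(type_ids)
        for s in self.sites:
            if s.type_id not in known:
                raise ValueError(f"site {s.site_id!r} references unknown type {s.type_id!r}")
        for a, b in self.ordering_constraints:
            if a not in known or b not in known:
                raise ValueError(f"ordering constraint ({a!r}, {b!r}) references unknown type")

    # -- lookups -----------------------------------------------------------

    @property
    def type_ids(self) -> tuple[str, ...]:
        return tuple(t.type_id for t in self.subcomplex_types)

    def type_by_id(self, type_id: str) -> SubcomplexType:
        for t in self.subcomplex_types:
            if t.type_id == type_id:
                return t
        raise KeyError(type_id)

    def sites_of_type(self, type_id: str) -> tuple[Site, ...]:
        return tuple(s for s in self.sites if s.type_id == type_id)

    def site_by_id(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def site_position(self, site_id: str) -> np.ndarray:
        return np.asarray(self.site_by_id(site_id).position, dtype=float)

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.subcomplex_types:
            for p in t.stoichiometry:
                seen.setdefault(p, None)
        return tuple(seen)

    def mature_copy_numbers(self) -> dict[str, int]:
        """Per-protein copies in the complete complex (all sites, all spokes)."""
        full = Composition.from_sites(self, "mature", (s.site_id for s in self.sites))
        return full.copy_numbers(self)

    def full_composition(self, time_label: str) -> "Composition":
        return Composition.from_sites(self, time_label, (s.site_id for s in self.sites))


@dataclass(frozen=True)
class Composition:
    """A compositional state: per-type instance counts for one spoke.

    ``type_counts`` is ordered by the system's declared type order.  When site
    identities matter (transition rules, structural models) the optional
    ``assigned_sites`` pins each instance to a specific site of the mature
    complex; counts and assignment are kept consistent.
    """

    time_label: str
    type_counts: tuple[tuple[str, int], ...]
    assigned_sites: frozenset[str] | None = None

    @classmethod
    def from_counts(
        cls,
        system: AssemblySystem,
        time_label: str,
        counts: Mapping[str, int],
    ) -> "Composition":
        unknown = set(counts) - set(system.type_ids)
        if unknown:
            raise ValueError(f"unknown type ids in counts: {sorted(unknown)}")
        ordered = []
        for tid in system.type_ids:
            n = int(counts.get(tid, 0))
            avail = len(system.sites_of_type(tid))
            if not 0 <= n <= avail:
                raise ValueError(f"type {tid!r}: count {n} outside [0, {avail}]")
            ordered.append((tid, n))
        return cls(time_label, tuple(ordered))

    @classmethod
    def from_sites(
        cls,
        system: AssemblySystem,
        time_label: str,
        site_ids: Iterable[str],
    ) -> "Composition":
        sites = frozenset(site_ids)
        known = {s.site_id: s.type_id for s in system.sites}
        unknown = sites - set(known)
        if unknown:
            raise ValueError(f"unknown site ids: {sorted(unknown)}")
        counts: dict[str, int] = {tid: 0 for tid in system.type_ids}
        for sid in sites:
            counts[known[sid]] += 1
        ordered = tuple((tid, counts[tid]) for tid in system.type_ids)
        return cls(time_label, ordered, sites)

    # -- derived views -----------------------------------------------------

    def count(self, type_id: str) -> int:
        for tid, n in self.type_counts:
            if tid == type_id:
                return n
        raise KeyError(type_id)

    def copy_vector(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.type_counts)

    def total_instances(self) -> int:
        return sum(n for _, n in self.type_counts)

    def copy_numbers(self, system: AssemblySystem) -> dict[str, int]:
        """Per-protein total copies = symmetry_order x sum over instances."""
        copies = {p: 0 for p in system.proteins}
        for tid, n in self.type_counts:
            stoich = system.type_by_id(tid).stoichiometry
            for p, per_instance in stoich.items():
                copies[p] += n * per_instance
        return {p: system.symmetry_order * c for p, c in copies.items()}

    def satisfies_constraints(self, system: AssemblySystem) -> bool:
        return all(self.count(a) >= self.count(b) for a, b in system.ordering_constraints)

    def with_sites(self, system: AssemblySystem, site_ids: Iterable[str]) -> "Composition":
        comp = Composition.from_sites(system, self.time_label, site_ids)
        if comp.type_counts != self.type_counts:
            raise ValueError("site assignment inconsistent with type counts")
        return comp

    def is_subset_of(self, other: "Composition") -> bool:
        if self.assigned_sites is None or other.assigned_sites is None:
            raise ValueError("is_subset_of requires site assignments on both compositions")
        return self.assigned_sites <= other.assigned_sites


_MATURE_LABELS = ("mature",)


def infer_time_order(labels: Iterable[str]) -> tuple[str, ...]:
    """Order time labels: numeric minutes ascending, then the mature label."""
    labels = list(dict.fromkeys(str(l) for l in labels))
    numeric = [l for l in labels if l not in _MATURE_LABELS]
    try:
        numeric.sort(key=float)
    except ValueError as err:
        raise ValueError(f"non-numeric time label (other than 'mature'): {err}") from err
    tail = [l for l in _MATURE_LABELS if l in labels]
    return tuple(numeric + tail)


class CopyNumberSeries:
    """Per-protein copy-number means and SDs over ordered time points.

    Thin wrapper over a tidy DataFrame with columns
    ``time_min, protein, mean, sd, held_out``.  ``held_out`` proteins are
    excluded from scoring and reserved for validation.
    """

    COLUMNS = ("time_min", "protein", "mean", "sd", "held_out")

    def __init__(self, frame: pd.DataFrame, time_order: Sequence[str] | None = None):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"copy-number table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["time_min"] = frame["time_min"].astype(str)
        frame["protein"] = frame["protein"].astype(str)
        frame["mean"] = frame["mean"].astype(float)
        frame["sd"] = frame["sd"].astype(float)
        frame["held_out"] = frame["held_out"].astype(bool)
        if (frame["sd"] < 0).any():
            raise ValueError("negative SD in copy-number data")
        flags = frame.groupby("protein")["held_out"].nunique()
        if (flags > 1).any():
            bad = flags[flags > 1].index.tolist()
            raise ValueError(f"inconsistent held_out flag for proteins: {bad}")
        self._frame = frame
        if time_order is None:
            self.time_labels = infer_time_order(frame["time_min"])
        else:
            self.time_labels = tuple(str(t) for t in time_order)
            extra = set(frame["time_min"]) - set(self.time_labels)
            if extra:
                raise ValueError(f"data time points missing from declared order: {sorted(extra)}")
        self._lookup = {
            (row.time_min, row.protein): (row.mean, row.sd)
            for row in frame.itertuples(index=False)
        }
        # every scored protein present at every modeled time point
        scored = self.scored_proteins
        for t in self.time_labels:
            for p in scored:
                if (t, p) not in self._lookup:
                    raise ValueError(f"scored protein {p!r} missing at time {t!r}")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._frame["protein"]))

    @property
    def scored_proteins(self) -> tuple[str, ...]:
        return tuple(p for p in self.proteins if not self._is_held_out(p))

    @property
    def heldout_proteins(self) -> tuple[str, ...]:
        return tuple(p for p in self.proteins if self._is_held_out(p))

    def _is_held_out(self, protein: str) -> bool:
        flags = self._frame.loc[self._frame["protein"] == protein, "held_out"]
        return bool(flags.iloc[0])

    def has_time(self, time_label: str) -> bool:
        return time_label in set(self._frame["time_min"])

    def mean(self, protein: str, time_label: str) -> float:
        return self._at(protein, time_label)[0]

    def sd(self, protein: str, time_label: str) -> float:
        return self._at(protein, time_label)[1]

    def _at(self, protein: str, time_label: str) -> tuple[float, float]:
        try:
            return self._lookup[(str(time_label), protein)]
        except KeyError:
            raise MissingTimePointError(
                f"no copy-number entry for protein {protein!r} at time {time_label!r}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberSeries):
            return NotImplemented
        a = self._frame.sort_values(["time_min", "protein"]).reset_index(drop=True)
        b = other._frame.sort_values(["time_min", "protein"]).reset_index(drop=True)
        return self.time_labels == other.time_labels and a.equals(b)
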