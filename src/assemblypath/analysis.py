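"""Validation metrics for weighted trajectory sets.

Two independently sampled weight vectors over the same trajectories are
compared by the temporal precision ``P_temp = 1 - 1/2 * sum |W_A - W_B|``
(1 = perfect overlap, 0 = disjoint support).  The precision of a single model
is ``gamma = sum W^2``, ranging from 1/d (uniform over d trajectories) to 1
(a single dominant trajectory).  Trajectory-weighted copy-number time series
and the held-out-protein agreement table complete the validation report.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import Snapshot, Trajectory
from .system import AssemblySystem, CopyNumberSeries

__all__ = [
    "WeightVector",
    "temporal_precision",
    "model_precision",
    "copy_number_timeseries",
    "heldout_validation",
    "ValidationReport",
]

_NORM_ATOL = 1e-6


@dataclass(frozen=True)
class WeightVector:
    """Normalized weights over an ordered trajectory-id universe."""

    ids: tuple[str, ...]
    weights: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.ids) != w.size:
            raise ValueError("ids and weights length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate trajectory ids")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights outside [0, 1]")
        if abs(float(w.sum()) - 1.0) > _NORM_ATOL:
            raise ValueError(f"weights not normalized (sum={w.sum():.6g})")

    @classmethod
    def from_trajectories(cls, trajectories: Sequence[Trajectory], tag: str = "") -> "WeightVector":
        return cls(
            tuple(t.id for t in trajectories),
            np.asarray([t.weight for t in trajectories]),
            tag,
        )

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.ids, self.weights))


def _aligned(wa: WeightVector, wb: WeightVector) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad both vectors onto the union of their trajectory-id universes."""
    universe = sorted(set(wa.ids) | set(wb.ids))
    ma, mb = wa.as_mapping(), wb.as_mapping()
    a = np.asarray([ma.get(i, 0.0) for i in universe])
    b = np.asarray([mb.get(i, 0.0) for i in universe])
    return a, b


def temporal_precision(wa: WeightVector, wb: WeightVector) -> float:
    """P_temp = 1 - 1/2 sum_i |W_A(i) - W_B(i)|, in [0, 1], symmetric."""
    a, b = _aligned(wa, wb)
    val = 1.0 - 0.5 * float(np.abs(a - b).sum())
    return min(1.0, max(0.0, val))


def model_precision(w: WeightVector) -> float:
    """gamma = sum_i W(i)^2; 1 for a single trajectory, 1/d for uniform weights."""
    return float(np.sum(w.weights**2))


def copy_number_timeseries(
    trajectories: Sequence[Trajectory],
    snapshots: Mapping[str, Snapshot],
    system: AssemblySystem,
    proteins: Iterable[str] | None = None,
    fixed_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Trajectory-weighted per-protein copy-number mean and SD at each time.

    mean(t) = sum_i W_i c_i(t); SD uses the population convention with weights
    as probabilities.  At time points listed in ``fixed_labels`` (the mature
    state, held fixed by construction) the SD is reported as NaN (undefined).
    Zero-weight trajectories do not contribute.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    weights = np.asarray([t.weight for t in trajectories], dtype=float)
    if abs(weights.sum() - 1.0) > _NORM_ATOL:
        raise ValueError("trajectory weights not normalized")
    proteins = tuple(proteins) if proteins is not None else system.proteins
    unknown = set(proteins) - set(system.proteins)
    if unknown:
        raise ValueError(f"proteins absent from system stoichiometry: {sorted(unknown)}")
    fixed = set(fixed_labels)

    some = snapshots[trajectories[0].snapshot_ids[0]]
    n_steps = len(trajectories[0].snapshot_ids)
    time_labels = [
        snapshots[sid].time_label for sid in trajectories[0].snapshot_ids
    ]
    rows = []
    # copies[i, k, p] = copy number of protein p at step k in trajectory i
    copies = np.zeros((len(trajectories), n_steps, len(proteins)))
    for i, traj in enumerate(trajectories):
        if len(traj.snapshot_ids) != n_steps:
            raise ValueError("trajectories of unequal length")
        for k, sid in enumerate(traj.snapshot_ids):
            cn = snapshots[sid].composition.copy_numbers(system)
            for p_idx, p in enumerate(proteins):
                copies[i, k, p_idx] = cn[p]
    for k, t in enumerate(time_labels):
        for p_idx, p in enumerate(proteins):
            c = copies[:, k, p_idx]
            mean = float(np.sum(weights * c))
            if t in fixed:
                sd = float("nan")
            else:
                sd = float(np.sqrt(np.sum(weights * (c - mean) ** 2)))
            rows.append({"time_min": t, "protein": p, "model_mean": mean, "model_sd": sd})
    return pd.DataFrame(rows)


def heldout_validation(
    model_table: pd.DataFrame,
    data: CopyNumberSeries,
    sd_floor: float = 1e-9,
) -> pd.DataFrame:
    """Compare model copy numbers with held-out measurements, never rescoring.

    For each held-out protein and time point: model mean +- SD vs data mean +-
    SD, plus a z-like discrepancy |model - data| / pooled SD (a reporting aid,
    not part of any score).  No held-out proteins yields an empty table with a
    warning.
    """
    held = data.heldout_proteins
    cols = [
        "protein", "time_min", "model_mean", "model_sd",
        "data_mean", "data_sd", "discrepancy",
    ]
    if not held:
        warnings.warn("copy-number data has no held-out proteins", stacklevel=2)
        return pd.DataFrame(columns=cols)
    rows = []
    for p in held:
        sub = model_table[model_table["protein"] == p]
        for row in sub.itertuples(index=False):
            if not data.has_time(row.time_min):
                continue
            dm, ds = data.mean(p, row.time_min), data.sd(p, row.time_min)
            ms = 0.0 if math.isnan(row.model_sd) else row.model_sd
            pooled = max(math.sqrt(ms**2 + ds**2), sd_floor)
            diff = abs(row.model_mean - dm)
            rows.append(
                {
                    "protein": p,
                    "time_min": row.time_min,
                    "model_mean": row.model_mean,
                    "model_sd": row.model_sd,
                    "data_mean": dm,
                    "data_sd": ds,
                    "discrepancy": 0.0 if diff == 0.0 else diff / pooled,
                }
            )
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ValidationReport:
    """Bundle of the validation quantities for one modeling run."""

    temporal_precision: float | None
    model_precision: float
    top_trajectory_id: str
    top_trajectory_weight: float
    n_trajectories: int
    copy_numbers: pd.DataFrame
    heldout: pd.DataFrame
    snapshot_diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.temporal_precision is not None and not 0 <= self.temporal_precision <= 1:
            raise ValueError("temporal precision outside [0, 1]")
        d = max(self.n_trajectories, 1)
        if not (1.0 / d) - 1e-9 <= self.model_precision <= 1 + 1e-9:
            raise ValueError("model precision outside [1/d, 1]")

    def to_dict(self) -> dict:
        return {
            "temporal_precision": self.temporal_precision,
            "model_precision": self.model_precision,
            "top_trajectory": {
                "id": self.top_trajectory_id,
                "weight": self.top_trajectory_weight,
            },
            "n_trajectories": self.n_trajectories,
            "copy_numbers": self.copy_numbers.to_dict(orient="records"),
            "heldout": self.heldout.to_dict(orient="records"),
            "snapshot_diagnostics": self.snapshot_diagnostics.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [
            "Assembly-pathway validation report",
            "----------------------------------",
            f"trajectories (nonzero weight universe): {self.n_trajectories}",
            f"model precision gamma:   {self.model_precision:.4f}",
        ]
        if self.temporal_precision is not None:
            lines.append(f"temporal precision P_temp: {self.temporal_precision:.4f}")
        lines.append(
            f"top trajectory: {self.top_trajectory_id} "
            f"(weight {100 * self.top_trajectory_weight:.1f}%)"
        )
        if not self.heldout.empty:
            lines.append("")
            lines.append("held-out protein agreement (z-like discrepancy):")
            for row in self.heldout.itertuples(index=False):
                lines.append(
                    f"  {row.protein:>10s} @ {row.time_min:>6s}: model "
                    f"{row.model_mean:7.2f} vs data {row.data_mean:7.2f} "
                    f"(discrepancy {row.discrepancy:.2f})"
                )
        return "\n".join(lines) + "\n"
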