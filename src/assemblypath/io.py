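"""Readers and writers for every on-disk format the pipeline touches.

System definitions travel as YAML (or JSON), copy-number series as CSV,
density volumes as CCP4/MRC (through gemmi), snapshot sets, graphs and
trajectory weights as JSON, bead models as PDB (one pseudo-atom per bead,
radius in the B-factor column) or CSV, and graphs additionally as GraphViz
DOT with nodes shaded by marginal weight.  Every write/read pair round-trips
to an equal object (MRC voxels to float32 precision).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .density import DensityGrid
from .graph import Snapshot, Trajectory, TrajectoryGraph
from .structure import Bead, BeadModel
from .system import AssemblySystem, Composition, CopyNumberSeries, Site, SubcomplexType

__all__ = [
    "SchemaError",
    "write_system",
    "read_system",
    "write_copy_numbers",
    "read_copy_numbers",
    "write_density_mrc",
    "read_density_mrc",
    "snapshot_to_dict",
    "snapshot_from_dict",
    "write_snapshots",
    "read_snapshots",
    "write_graph",
    "read_graph",
    "write_trajectories",
    "read_trajectories",
    "write_bead_csv",
    "read_bead_csv",
    "write_bead_pdb",
    "write_graph_dot",
]


class SchemaError(ValueError):
    """An input file violates its documented schema."""


# -- AssemblySystem ----------------------------------------------------------


def _system_to_dict(system: AssemblySystem) -> dict:
    return {
        "symmetry_order": system.symmetry_order,
        "subcomplex_types": [
            {"type_id": t.type_id, "stoichiometry": dict(t.stoichiometry)}
            for t in system.subcomplex_types
        ],
        "sites": [
            {"site_id": s.site_id, "type_id": s.type_id, "position": list(s.position)}
            for s in system.sites
        ],
        "ordering_constraints": [list(c) for c in system.ordering_constraints],
    }


def write_system(system: AssemblySystem, path: str | Path) -> None:
    path = Path(path)
    doc = _system_to_dict(system)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unsupported system format: {path.suffix!r}")


def read_system(path: str | Path) -> AssemblySystem:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    for key in ("symmetry_order", "subcomplex_types", "sites"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    try:
        types = tuple(
            SubcomplexType(t["type_id"], t["stoichiometry"]) for t in doc["subcomplex_types"]
        )
        sites = tuple(
            Site(s["site_id"], s["type_id"], tuple(s["position"])) for s in doc["sites"]
        )
        return AssemblySystem(
            types,
            sites,
            int(doc["symmetry_order"]),
            tuple(tuple(c) for c in doc.get("ordering_constraints", [])),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise SchemaError(f"{path}: {err}") from err


# -- CopyNumberSeries --------------------------------------------------------


def write_copy_numbers(data: CopyNumberSeries, path: str | Path) -> None:
    # %.17g keeps the full float64 precision so read(write(x)) == x
    data.frame.to_csv(path, index=False, float_format="%.17g")


def read_copy_numbers(path: str | Path, time_order: Sequence[str] | None = None) -> CopyNumberSeries:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CopyNumberSeries.COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    try:
        return CopyNumberSeries(frame, time_order=time_order)
    except ValueError as err:
        raise SchemaError(f"{path}: {err}") from err


# -- DensityGrid (CCP4/MRC via gemmi) ---------------------------------------

_ORIGIN_WORDS = (50, 51, 52)  # CCP4 header ORIGIN record


def write_density_mrc(grid: DensityGrid, path: str | Path) -> None:
    nx_, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx_, ny, nz)
    np.array(g, copy=False)[...] = grid.data.astype(np.float32)
    g.spacegroup = gemmi.SpaceGroup("P1")
    g.unit_cell = gemmi.UnitCell(
        nx_ * grid.spacing, ny * grid.spacing, nz * grid.spacing, 90, 90, 90
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for word, value in zip(_ORIGIN_WORDS, grid.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def read_density_mrc(path: str | Path) -> DensityGrid:
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as err:
        raise SchemaError(f"{path}: malformed CCP4/MRC map: {err}") from err
    grid = ccp4.grid
    data = np.array(grid, copy=True).astype(float)
    spacings = np.array(
        [grid.unit_cell.a / grid.nu, grid.unit_cell.b / grid.nv, grid.unit_cell.c / grid.nw]
    )
    if np.ptp(spacings) > 1e-4 * spacings.mean():
        raise SchemaError(f"{path}: anisotropic voxel spacing {spacings} unsupported")
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS], dtype=float)
    return DensityGrid(origin, float(spacings.mean()), data)


# -- snapshots, graphs, trajectories (JSON) ---------------------------------


def snapshot_to_dict(snap: Snapshot) -> dict:
    comp = snap.composition
    return {
        "id": snap.id,
        "time_label": snap.time_label,
        "log_score": snap.log_score,
        "composition": {
            "type_counts": [[tid, n] for tid, n in comp.type_counts],
            "assigned_sites": (
                sorted(comp.assigned_sites) if comp.assigned_sites is not None else None
            ),
        },
    }


def snapshot_from_dict(doc: Mapping, source: str = "<snapshot>") -> Snapshot:
    try:
        comp_doc = doc["composition"]
        sites = comp_doc["assigned_sites"]
        comp = Composition(
            doc["time_label"],
            tuple((tid, int(n)) for tid, n in comp_doc["type_counts"]),
            frozenset(sites) if sites is not None else None,
        )
        return Snapshot(doc["id"], doc["time_label"], comp, float(doc["log_score"]))
    except (KeyError, TypeError, ValueError) as err:
        raise SchemaError(f"{source}: {err}") from err


def write_snapshots(
    snapshots_by_time: Mapping[str, Sequence[Snapshot]], path: str | Path
) -> None:
    doc = {
        "time_labels": list(snapshots_by_time),
        "snapshots": {
            t: [snapshot_to_dict(s) for s in snaps]
            for t, snaps in snapshots_by_time.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_snapshots(path: str | Path) -> dict[str, list[Snapshot]]:
    path = Path(path)
    doc = json.loads(path.read_text())
    for key in ("time_labels", "snapshots"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    return {
        t: [snapshot_from_dict(d, str(path)) for d in doc["snapshots"][t]]
        for t in doc["time_labels"]
    }


def write_graph(graph: TrajectoryGraph, path: str | Path) -> None:
    doc = {
        "mode": graph.mode,
        "time_labels": list(graph.time_labels),
        "snapshots": [snapshot_to_dict(graph.snapshots[sid]) for sid in sorted(graph.snapshots)],
        "edges": sorted(
            [u, v, d["log_weight"]] for u, v, d in graph.graph.edges(data=True)
        ),
        "n_zero_edges": graph.n_zero_edges,
        "counts": {"nodes": graph.n_nodes, "nonzero_edges": graph.n_edges},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_graph(path: str | Path) -> TrajectoryGraph:
    path = Path(path)
    doc = json.loads(path.read_text())
    for key in ("mode", "time_labels", "snapshots", "edges"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    snapshots = {d["id"]: snapshot_from_dict(d, str(path)) for d in doc["snapshots"]}
    g = nx.DiGraph()
    g.add_nodes_from(snapshots)
    for u, v, lw in doc["edges"]:
        g.add_edge(u, v, log_weight=float(lw))
    return TrajectoryGraph(
        doc["time_labels"], snapshots, g, int(doc.get("n_zero_edges", 0)), doc["mode"]
    )


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    doc = [
        {
            "snapshot_ids": list(t.snapshot_ids),
            "log_weight": None if t.log_weight == -math.inf else t.log_weight,
            "weight": t.weight,
        }
        for t in trajectories
    ]
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_trajectories(path: str | Path) -> list[Trajectory]:
    path = Path(path)
    doc = json.loads(path.read_text())
    out = []
    for d in doc:
        try:
            lw = d["log_weight"]
            out.append(
                Trajectory(
                    tuple(d["snapshot_ids"]),
                    -math.inf if lw is None else float(lw),
                    float(d["weight"]),
                )
            )
        except (KeyError, TypeError) as err:
            raise SchemaError(f"{path}: {err}") from err
    return out


# -- bead models -------------------------------------------------------------


def write_bead_csv(model: BeadModel, path: str | Path) -> None:
    rows = [
        {
            "site_id": b.site_id,
            "x": b.center[0],
            "y": b.center[1],
            "z": b.center[2],
            "radius": b.radius,
            "weight": b.weight,
        }
        for b in model.beads
    ]
    pd.DataFrame(rows, columns=["site_id", "x", "y", "z", "radius", "weight"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_bead_csv(path: str | Path) -> BeadModel:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    needed = {"site_id", "x", "y", "z", "radius", "weight"}
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    beads = tuple(
        Bead(str(r.site_id), (r.x, r.y, r.z), float(r.radius), float(r.weight))
        for r in frame.itertuples(index=False)
    )
    return BeadModel(beads)


def write_bead_pdb(model: BeadModel, path: str | Path) -> None:
    """One pseudo-atom (CA) per bead; bead radius goes in the B-factor column."""
    st = gemmi.Structure()
    st.name = "bead model"
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, bead in enumerate(model.beads, start=1):
        res = gemmi.Residue()
        res.name = "BEA"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*bead.center)
        atom.b_iso = bead.radius
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# -- DOT export --------------------------------------------------------------


def write_graph_dot(
    graph: TrajectoryGraph,
    path: str | Path,
    marginals: Mapping[str, float] | None = None,
) -> None:
    """GraphViz export with layers as columns and nodes shaded by weight."""
    lines = ["digraph trajectories {", "  rankdir=LR;", "  node [style=filled];"]
    for t in graph.time_labels:
        lines.append("  { rank=same; " + " ".join(f'"{s}";' for s in graph.layers[t]) + " }")
    for sid in sorted(graph.snapshots):
        w = 0.0 if marginals is None else marginals.get(sid, 0.0)
        gray = int(round(95 - 70 * w))  # heavier nodes darker
        lines.append(f'  "{sid}" [fillcolor="gray{gray}", label="{sid}\\nW={w:.3f}"];')
    for u, v in sorted(graph.graph.edges()):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
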