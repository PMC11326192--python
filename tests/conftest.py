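import numpy as np
import pandas as pd
import pytest

from assemblypath.density import DensityGrid
from assemblypath.system import AssemblySystem, CopyNumberSeries, Site, SubcomplexType
from assemblypath.synthetic import npc_like_system


@pytest.fixture
def two_type_system() -> AssemblySystem:
    """Two types, two sites each, constraint count(A) >= count(B)."""
    return AssemblySystem(
        subcomplex_types=(
            SubcomplexType("A", {"protA": 1}),
            SubcomplexType("B", {"protB": 1}),
        ),
        sites=(
            Site("A_1", "A", (0.0, 0.0, 0.0)),
            Site("A_2", "A", (4.0, 0.0, 0.0)),
            Site("B_1", "B", (0.0, 4.0, 0.0)),
            Site("B_2", "B", (4.0, 4.0, 0.0)),
        ),
        symmetry_order=2,
        ordering_constraints=(("A", "B"),),
    )


@pytest.fixture
def npc_system() -> AssemblySystem:
    return npc_like_system()


@pytest.fixture
def small_grid() -> DensityGrid:
    return DensityGrid(origin=(-6.0, -6.0, -6.0), spacing=1.0, data=np.zeros((13, 13, 13)))


def make_series(rows, time_order=None) -> CopyNumberSeries:
    """rows: (time, protein, mean, sd, held_out) tuples."""
    frame = pd.DataFrame(rows, columns=["time_min", "protein", "mean", "sd", "held_out"])
    return CopyNumberSeries(frame, time_order=time_order)


@pytest.fixture
def series_factory():
    return make_series
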