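import numpy as np
import pytest

from smv.flow_sim import FlowState, Microbubble
from smv.vessel_graph import Edge, RadiusVelocityTable, VesselGraph


def straight_tube_graph(
    length=60, radius=3.0, v_ref=2.0, row=20, col0=5, shape=(40, 80)
) -> VesselGraph:
    """Single horizontal directed edge with constant radius."""
    g = VesselGraph(shape=shape, directed=True)
    cols = np.arange(col0, col0 + length)
    path = np.column_stack([np.full(length, row), cols])
    g.add_edge(
        Edge(
            u=(row, col0),
            v=(row, col0 + length - 1),
            path=path,
            radii=np.full(length, float(radius)),
            v_ref=v_ref,
        )
    )
    return g


def y_junction_graph(r_out=(1.0, 2.0), v_ref=2.0, shape=(64, 64)) -> VesselGraph:
    """One inlet edge feeding two outlet edges of given radii."""
    g = VesselGraph(shape=shape, directed=True)
    inlet_path = np.column_stack([np.full(20, 32), np.arange(2, 22)])
    g.add_edge(
        Edge(u=(32, 2), v=(32, 21), path=inlet_path, radii=np.full(20, 2.0), v_ref=v_ref)
    )
    for k, r in enumerate(r_out):
        rows = 32 + (k * 2 - 1) * np.arange(20)
        out_path = np.column_stack([rows, np.arange(21, 41)])
        g.add_edge(
            Edge(
                u=(32, 21),
                v=(int(rows[-1]), 40),
                path=out_path,
                radii=np.full(20, float(r)),
                v_ref=v_ref,
            )
        )
    return g


def single_bubble_state(g, d_ax=0.0, d_lat=0.0, amp=1.0, seed=0) -> FlowState:
    return FlowState(
        bubbles=[Microbubble(e_orig=0, e_curr=0, d_ax=d_ax, d_lat=d_lat, amp=amp, mb_id=0)],
        rng=np.random.default_rng(seed),
        next_id=1,
    )


@pytest.fixture
def tube():
    return straight_tube_graph()


@pytest.fixture
def default_table():
    radii = np.linspace(0.5, 8.0, 32)
    return RadiusVelocityTable(pairs=np.column_stack([radii, 0.5 * radii]))
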